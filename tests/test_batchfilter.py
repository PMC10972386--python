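"""Welch filtering and PCA diagnostics, with permutation oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from lipicyte.batchfilter import (
    all_sample_batch_filter, batch_separation_score, pca_diagnostics,
    sham_batch_filter, welch_p,
)
from lipicyte.features import log_transform
from lipicyte.synth import SynthConfig, generate_feature_table


def hand_welch(x, y):
    """Independent oracle: Welch statistic and Welch-Satterthwaite df from
    the textbook formulas."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


class TestWelchP:
    def test_identical_groups(self):
        assert welch_p([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """Two well-separated 4-sample groups: t and df from the Welch
        formulas computed by hand; p far below 0.001."""
        from scipy import stats

        a, b = (10, 11, 12, 13), (20, 21, 22, 23)
        t, df = hand_welch(a, b)
        assert t == pytest.approx(-10.9545, abs=1e-4)
        assert df == pytest.approx(6.0, abs=1e-9)
        p_oracle = 2 * stats.t.sf(abs(t), df)
        assert p_oracle < 0.001
        assert welch_p(a, b) == pytest.approx(p_oracle, abs=1e-12)

    def test_degenerate_conventions(self):
        assert welch_p([5.0, 5.0], [5.0, 5.0]) == 1.0
        assert welch_p([5.0, 5.0], [7.0, 7.0]) == 0.0
        with pytest.raises(ValueError):
            welch_p([1.0], [1.0, 2.0])

    def test_matches_exhaustive_permutation_oracle(self):
        """On small normal samples the Welch p agrees with the exact
        (fully enumerated) label-permutation p to within the coarse
        resolution of the small-sample permutation distribution."""
        from itertools import combinations

        rng = np.random.default_rng(5)
        for _ in range(3):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.7, 1.2, 6)
            pooled = np.concatenate([x, y])
            t_obs, _ = hand_welch(x, y)
            count = total = 0
            for idx in combinations(range(12), 6):
                mask = np.zeros(12, dtype=bool)
                mask[list(idx)] = True
                t_perm, _ = hand_welch(pooled[mask], pooled[~mask])
                count += abs(t_perm) >= abs(t_obs) - 1e-12
                total += 1
            p_exact = count / total
            assert abs(welch_p(x, y) - p_exact) < 0.05


@pytest.fixture(scope="module")
def shifted_table(lipid_dict):
    cfg = SynthConfig(
        n_features=1000, frac_batch=0.10, batch_shift=1.5, noise_sd=0.5,
        frac_injury_3x=0.05, frac_injury_1x=0.0, n_coupled_lipids=0,
        n_truth_lipids=0, frac_rt_below=0.0, seed=23,
    )
    table, truth = generate_feature_table(cfg, lipid_dict)
    return log_transform(table, base=2), truth


class TestShamFilter:
    def test_recovers_batch_shifted_features(self, shifted_table):
        table, truth = shifted_table
        filtered, report = sham_batch_filter(table, alpha=0.05)
        removed = set(report.removed_ids)
        shifted = truth.batch_affected
        assert len(removed & shifted) / len(shifted) >= 0.80
        null = set(table.features.index) - shifted - set(truth.injury_affected)
        null_rate = len(removed & null) / len(null)
        assert 0.02 <= null_rate <= 0.08  # type-I error near alpha

    def test_blind_to_injury_signal(self, shifted_table):
        """Perturbing the injured samples cannot change the removal set."""
        table, truth = shifted_table
        _, before = sham_batch_filter(table)
        perturbed = table.copy()
        injured = perturbed.sample_ids(injury=("1X", "3X"))
        perturbed.intensities.loc[:, injured] += 37.0
        _, after = sham_batch_filter(perturbed)
        assert before.removed_ids == after.removed_ids
        # and injury-affected features are removed at ~the null rate
        removed = set(before.removed_ids)
        injury_only = set(truth.injury_affected) - truth.batch_affected
        assert len(removed & injury_only) / len(injury_only) <= 0.10

    def test_alpha_zero_and_identical_batches(self, tiny_table):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(10, 1, (50, 12))
        vals[:, 6:] = vals[:, :6]  # batch 2 byte-identical to batch 1
        table = log_transform(tiny_table(vals), base=2)
        _, rep = sham_batch_filter(table, alpha=0.0)
        assert rep.removed_ids == []
        _, rep2 = sham_batch_filter(table, alpha=0.05)
        assert rep2.removed_ids == []

    def test_requires_log_scale(self, shifted_table):
        table, _ = shifted_table
        raw = table.copy()
        raw.log_base = None
        with pytest.raises(ValueError, match="log"):
            sham_batch_filter(raw)

    def test_report_partition(self, shifted_table):
        table, _ = shifted_table
        _, rep = sham_batch_filter(table)
        assert set(rep.kept_ids) | set(rep.removed_ids) == set(table.features.index)
        assert not set(rep.kept_ids) & set(rep.removed_ids)
        assert rep.p_values.between(0, 1).all()


class TestAllSampleFilter:
    def test_null_removal_near_alpha(self, lipid_dict):
        cfg = SynthConfig(n_features=1000, frac_batch=0.0, frac_injury_3x=0.0,
                          frac_injury_1x=0.0, n_coupled_lipids=0, n_truth_lipids=0,
                          seed=3)
        table, _ = generate_feature_table(cfg, lipid_dict)
        _, rep = all_sample_batch_filter(log_transform(table, base=2))
        assert 0.02 <= len(rep.removed_ids) / 1000 <= 0.08

    def test_single_feature_strong_shift_removed(self, tiny_table):
        vals = np.ones((1, 12))
        vals[0, 6:] = 1000.0
        table = tiny_table(vals)
        table.samples["batch"] = [1] * 6 + [2] * 6
        _, rep = all_sample_batch_filter(log_transform(table, base=2))
        assert rep.removed_ids == ["F000"]


class TestPCA:
    def test_two_clusters_dominate_pc1(self, tiny_table):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 0.05, (40, 12))
        base[:, 6:] += 2.0  # rank-1 shift of half the samples
        diag = pca_diagnostics(tiny_table(base + 10), n_components=3)
        assert diag.variance_fraction[0] > 0.9
        side = np.sign(diag.scores["PC1"])
        assert abs(side[:6].sum()) == 6 and abs(side[6:].sum()) == 6

    def test_rotation_invariance_of_variance_fractions(self, tiny_table):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (30, 10))
        q, _ = np.linalg.qr(rng.normal(0, 1, (30, 30)))
        d1 = pca_diagnostics(tiny_table(X + 10), n_components=5)
        d2 = pca_diagnostics(tiny_table((q @ X) - (q @ X).min() + 1), n_components=5)
        np.testing.assert_allclose(d1.variance_fraction, d2.variance_fraction, atol=1e-9)

    def test_variance_fractions_sorted_and_bounded(self, bundle):
        _, table, *_ = bundle
        diag = pca_diagnostics(log_transform(table, base=2), n_components=5)
        vf = diag.variance_fraction
        assert (np.diff(vf) <= 1e-12).all()
        assert (vf >= 0).all() and vf.sum() <= 1 + 1e-9

    def test_constant_matrix_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="constant"):
            pca_diagnostics(tiny_table(np.ones((5, 6))))


class TestSeparationScore:
    def test_shift_confined_to_one_direction(self, tiny_table):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (50, 12))
        X[10, 6:] += 30.0  # one feature (one PC direction) carries the batch
        table = tiny_table(X - X.min() + 1)
        table.samples["batch"] = [1] * 6 + [2] * 6
        diag = pca_diagnostics(table, n_components=4)
        score = batch_separation_score(diag)
        assert score.idxmax() == "PC1"
        # sign-flip invariance
        diag.scores["PC1"] *= -1
        score2 = batch_separation_score(diag)
        assert score2["PC1"] == pytest.approx(score["PC1"])

    def test_identical_distributions_score_near_zero(self, tiny_table):
        rng = np.random.default_rng(10)
        table = tiny_table(rng.lognormal(3, 1, (50, 12)))
        diag = pca_diagnostics(table)
        assert batch_separation_score(diag).max() < 1.5

    def test_single_batch_rejected(self, tiny_table):
        table = tiny_table(np.random.default_rng(1).lognormal(3, 1, (10, 6)))
        table.samples["batch"] = 1
        diag = pca_diagnostics(table)
        with pytest.raises(ValueError, match="2 label groups"):
            batch_separation_score(diag)


def test_filter_reduces_batch_separation(shifted_table):
    table, _ = shifted_table
    before = batch_separation_score(pca_diagnostics(table)).max()
    filtered, _ = sham_batch_filter(table)
    after = batch_separation_score(pca_diagnostics(filtered)).max()
    assert after < before
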