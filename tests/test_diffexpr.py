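"""ANOVA + Tukey volcano analysis against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipicyte.diffexpr import (
    _tukey_rows, anova_tukey, fold_change, subclass_tally, volcano,
)
from lipicyte.features import log_transform
from lipicyte.synth import SynthConfig, generate_feature_table


class TestAnovaTukey:
    def test_identical_groups_all_one(self):
        g = {"sham": [1.0, 1.0, 1.0], "1X": [1.0, 1.0, 1.0], "3X": [1.0, 1.0, 1.0]}
        p, pairs = anova_tukey(g)
        assert p == 1.0 and all(v == 1.0 for v in pairs.values())

    def test_single_separated_group(self):
        rng = np.random.default_rng(0)
        g = {
            "sham": rng.normal(0, 1e-3, 4),
            "1X": rng.normal(0, 1e-3, 4),
            "3X": 5 + rng.normal(0, 1e-3, 4),
        }
        p, pairs = anova_tukey(g)
        assert p < 1e-6
        assert pairs[("sham", "3X")] < 1e-6 and pairs[("1X", "3X")] < 1e-6
        assert pairs[("sham", "1X")] > 0.5

    def test_tukey_at_least_unadjusted_pairwise(self):
        """For the same contrast statistic (pooled MSE, residual df) the
        studentized-range adjustment can only raise the p-value."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = {k: rng.normal(rng.normal(), 1, 5) for k in ("sham", "1X", "3X")}
            _, pairs = anova_tukey(g)
            mse = np.mean([np.var(v, ddof=1) for v in g.values()])
            df = 12
            for (a, b), p_adj in pairs.items():
                t = abs(np.mean(g[a]) - np.mean(g[b])) / np.sqrt(mse * 2 / 5)
                p_raw = 2 * stats.t.sf(t, df)
                assert p_adj >= p_raw - 1e-9

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(2)
        for _ in range(5):
            g = {k: rng.normal(i * 0.8, 1, 6) for i, k in enumerate(("sham", "1X", "3X"))}
            _, pairs = anova_tukey(g)
            values = np.concatenate(list(g.values()))
            labels = np.repeat(list(g), [len(v) for v in g.values()])
            res = pairwise_tukeyhsd(values, labels, alpha=0.05)
            pair_names = [(r[0], r[1]) for r in res.summary().data[1:]]
            oracle = {
                tuple(sorted(pair)): p for pair, p in zip(pair_names, res.pvalues)
            }
            for (a, b), p in pairs.items():
                assert p == pytest.approx(oracle[tuple(sorted((a, b)))], abs=2e-4)

    def test_matches_permutation_anova(self):
        """Small-sample F-test p agrees with a permutation ANOVA."""
        rng = np.random.default_rng(3)
        g = {"sham": rng.normal(0, 1, 3), "1X": rng.normal(0.5, 1, 3),
             "3X": rng.normal(1.5, 1, 3)}
        p_f, _ = anova_tukey(g)
        values = np.concatenate(list(g.values()))
        f_obs = stats.f_oneway(*g.values()).statistic
        count = 0
        n_mc = 4000
        for _ in range(n_mc):
            perm = rng.permutation(values)
            count += stats.f_oneway(perm[:3], perm[3:6], perm[6:]).statistic >= f_obs
        p_perm = (count + 1) / (n_mc + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_mc)
        assert abs(p_f - p_perm) < 4 * se + 0.03

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"sham": [1.0], "3X": [1.0, 2.0]})


def test_vectorized_rows_match_scalar_tukey():
    """The interpolated studentized-range path agrees with the exact scipy
    Tukey HSD feature by feature."""
    rng = np.random.default_rng(4)
    blocks = [rng.normal(i * 0.5, 1, (30, 6)) for i in range(3)]
    p_anova, p_tukey = _tukey_rows(blocks)
    for row in range(30):
        g = {k: blocks[i][row] for i, k in enumerate(("sham", "1X", "3X"))}
        p_s, pairs_s = anova_tukey(g)
        assert p_anova[row] == pytest.approx(p_s, abs=1e-9)
        expect = [pairs_s[("sham", "1X")], pairs_s[("sham", "3X")], pairs_s[("1X", "3X")]]
        np.testing.assert_allclose(p_tukey[row], expect, atol=2e-4)


class TestFoldChange:
    def test_threshold_boundaries(self):
        assert fold_change([125.0], [100.0]) == pytest.approx(1.25)
        assert fold_change([80.0], [100.0]) == pytest.approx(1 / 1.25)
        assert fold_change([7.0, 7.0], [7.0, 7.0]) == 1.0

    def test_reciprocal_duality(self):
        rng = np.random.default_rng(5)
        a, b = rng.lognormal(3, 1, 8), rng.lognormal(3, 1, 8)
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_change([0.0, 0.0], [1.0])


@pytest.fixture(scope="module")
def planted(lipid_dict):
    cfg = SynthConfig(n_features=800, frac_injury_3x=0.0625,  # 50 features
                      frac_decrease_3x=1.0, injury_log_fc=-1.0,
                      frac_injury_1x=0.0, frac_batch=0.0, n_coupled_lipids=0,
                      n_truth_lipids=0, noise_sd=0.4, seed=31)
    table, truth = generate_feature_table(cfg, lipid_dict)
    return log_transform(table, base=2), truth


class TestVolcano:
    def test_recovers_planted_decreases(self, planted):
        table, truth = planted
        diff = volcano(table, ("3X", "sham"))
        down = set(diff.index[diff["volcano_class"] == "down"])
        planted_ids = {f for f, e in truth.injury_affected.items() if e.get("3X", 0) < 0}
        assert len(down & planted_ids) / len(planted_ids) >= 0.9
        n_up = (diff["volcano_class"] == "up").sum()
        assert n_up <= 0.02 * len(diff)  # null side stays at type-I level

    def test_alpha_zero_all_ns(self, planted):
        table, _ = planted
        diff = volcano(table, ("3X", "sham"), alpha=0.0)
        assert (diff["volcano_class"] == "ns").all()

    def test_contrast_reversal_duality(self, planted):
        table, _ = planted
        fwd = volcano(table, ("3X", "sham"))
        rev = volcano(table, ("sham", "3X"))
        np.testing.assert_allclose(fwd["fold_change"] * rev["fold_change"], 1.0, rtol=1e-9)
        np.testing.assert_allclose(fwd["p_tukey"], rev["p_tukey"], atol=1e-12)
        swap = {"up": "down", "down": "up", "ns": "ns"}
        assert (rev["volcano_class"] == fwd["volcano_class"].map(swap)).all()

    def test_requires_log_table(self, planted):
        table, _ = planted
        raw = table.copy()
        raw.log_base = None
        with pytest.raises(ValueError, match="log"):
            volcano(raw, ("3X", "sham"))


class TestSubclassTally:
    def _diff(self, fcs):
        return pd.DataFrame({"fold_change": fcs},
                            index=[f"F{i}" for i in range(len(fcs))])

    def _ann(self, subclasses):
        return pd.DataFrame({"subclass": subclasses},
                            index=[f"F{i}" for i in range(len(subclasses))])

    def test_percent_increased(self):
        tally = subclass_tally(self._ann(["Car"] * 4), self._diff([1.2, 1.3, 1.1, 0.9]))
        assert tally.loc["Car", "n_increased"] == 3
        assert tally.loc["Car", "fraction_decreased"] == pytest.approx(0.25)

    def test_fc_exactly_one_excluded_and_fractions_sum(self):
        tally = subclass_tally(self._ann(["SM"] * 3), self._diff([1.0, 1.4, 0.6]))
        assert tally.loc["SM", "n_increased"] + tally.loc["SM", "n_decreased"] == 2
        frac_inc = 1 - tally["fraction_decreased"]
        assert ((tally["n_increased"] / (tally["n_increased"] + tally["n_decreased"]))
                == frac_inc).all()

    def test_empty_subclass_omitted(self):
        tally = subclass_tally(self._ann(["Car", "SM"]), self._diff([1.2]))
        assert list(tally.index) == ["Car"]
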