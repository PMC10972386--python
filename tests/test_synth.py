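"""Generator contracts: determinism, planted structure, copula coupling."""

import numpy as np
import pandas as pd
import pytest

from lipicyte.annotate import Spectrum
from lipicyte.integrate import spearman_rho
from lipicyte.masses import ADDUCTS, adduct_mz
from lipicyte.synth import (
    GroundTruth, SynthConfig, generate_cytokines, generate_feature_table,
    generate_ms2,
)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"frac_batch": 1.5}, {"frac_injury_3x": -0.1}, {"noise_sd": 0.0},
        {"noise_sd": float("nan")}, {"batch_shift": float("inf")},
        {"rho_target": 1.0}, {"n_per_cell": 0},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SynthConfig(**kwargs)


class TestFeatureTable:
    def test_bit_reproducible_under_fixed_seed(self, lipid_dict):
        cfg = SynthConfig(n_features=300, seed=7)
        t1, g1 = generate_feature_table(cfg, lipid_dict)
        t2, g2 = generate_feature_table(cfg, lipid_dict)
        pd.testing.assert_frame_equal(t1.intensities, t2.intensities)
        pd.testing.assert_frame_equal(t1.features, t2.features)
        assert g1.to_json_dict() == g2.to_json_dict()
        s1 = generate_ms2(g1, lipid_dict, cfg, t1)
        s2 = generate_ms2(g2, lipid_dict, cfg, t2)
        assert s1 == s2
        p1 = generate_cytokines(t1, g1, cfg)
        p2 = generate_cytokines(t2, g2, cfg)
        pd.testing.assert_frame_equal(p1.concentrations, p2.concentrations)

    def test_seed_changes_output(self, lipid_dict):
        cfg = SynthConfig(n_features=300, seed=7)
        t1, _ = generate_feature_table(cfg, lipid_dict)
        t2, _ = generate_feature_table(SynthConfig(n_features=300, seed=8), lipid_dict)
        assert not t1.intensities.equals(t2.intensities)

    def test_grid_and_truth_structure(self, bundle):
        cfg, table, truth, *_ = bundle
        assert table.n_samples == cfg.n_per_cell * 12
        counts = table.samples.groupby(["batch", "injury", "sex"]).size()
        assert (counts == cfg.n_per_cell).all()
        assert table.n_features == cfg.n_features
        fids = set(table.features.index)
        assert truth.batch_affected <= fids
        assert set(truth.injury_affected) <= fids
        for fid, _, _ in truth.planted_pairs:
            assert truth.injury_affected[fid]["3X"] < 0

    def test_truth_mzs_near_theoretical(self, bundle):
        cfg, table, truth, *_ = bundle
        from lipicyte.dictionary import default_dictionary
        d = default_dictionary()
        errs = []
        for fid, name in truth.dictionary_truth.items():
            mz = table.features.loc[fid, "mz"]
            theo = [
                adduct_mz(d.get(name).monoisotopic_mass, a) for a in d.get(name).adducts
            ]
            errs.append(min(abs(mz - t) / t * 1e6 for t in theo))
        assert np.quantile(errs, 0.95) < 2.5 * cfg.ppm_noise

    def test_batch_shift_realized_in_log_space(self, bundle):
        cfg, table, truth, *_ = bundle
        log2 = np.log2(table.intensities)
        b1 = table.sample_ids(batch=1)
        b2 = table.sample_ids(batch=2)
        shifted = sorted(truth.batch_affected)
        delta = (log2.loc[shifted, b2].mean(axis=1) - log2.loc[shifted, b1].mean(axis=1))
        assert delta.mean() == pytest.approx(cfg.batch_shift, abs=0.15)

    def test_rt_fraction_below_cutoff(self, lipid_dict):
        cfg = SynthConfig(n_features=2000, frac_rt_below=0.2, n_truth_lipids=0,
                          n_coupled_lipids=0, seed=9)
        table, truth = generate_feature_table(cfg, lipid_dict)
        frac = (table.features["rt"] < 0.75).mean()
        assert frac == pytest.approx(0.2, abs=0.03)


class TestMS2:
    def test_truth_spectra_contain_diagnostic_fragment(self, bundle, lipid_dict):
        cfg, table, truth, spectra, _ = bundle
        from lipicyte.masses import fragment_mz
        checked = 0
        for fid, name in truth.dictionary_truth.items():
            entry = lipid_dict.get(name)
            mode = truth.feature_modes[fid]
            frag_mzs = [fragment_mz(f, m) for f, m in entry.fragments if m == mode]
            if not frag_mzs:
                continue
            observed = spectra[fid].fragment_mzs
            for theo in frag_mzs:
                assert np.min(np.abs(observed - theo) / theo * 1e6) < 5 * cfg.ppm_noise
            checked += 1
        assert checked > 50

    def test_decoy_spectra_rarely_hit_fragments(self, bundle, lipid_dict):
        """Uniform noise peaks land in a 10 ppm window around any one
        diagnostic fragment with probability ~ n_peaks * width / range."""
        from lipicyte.masses import fragment_mz
        cfg, table, truth, spectra, _ = bundle
        hits = 0
        for fid in truth.decoy_ids:
            spec = spectra[fid]
            frag = fragment_mz("C5H15NO4P", "+")
            if spec.mode == "+" and spec.fragment_mzs.size and np.any(
                np.abs(spec.fragment_mzs - frag) / frag * 1e6 <= 10
            ):
                hits += 1
        assert hits / max(len(truth.decoy_ids), 1) < 0.02

    def test_empty_truth_gives_decoy_only_spectra(self, lipid_dict):
        cfg = SynthConfig(n_features=50, n_truth_lipids=0, n_coupled_lipids=0, seed=1)
        table, truth = generate_feature_table(cfg, lipid_dict)
        spectra = generate_ms2(truth, lipid_dict, cfg, table)
        assert truth.dictionary_truth == {}
        assert set(spectra) == set(truth.decoy_ids)

    def test_unknown_truth_entry_rejected(self, lipid_dict):
        cfg = SynthConfig(n_features=50, seed=1)
        truth = GroundTruth(dictionary_truth={"F1": "PC(99:9)"},
                            feature_modes={"F1": "+"})
        with pytest.raises(KeyError, match="PC\\(99:9\\)"):
            generate_ms2(truth, lipid_dict, cfg)


class TestCytokines:
    def test_panel_structure(self, bundle):
        cfg, table, truth, _, panel = bundle
        assert len(panel.analytes) >= 14
        assert panel.in_linear_range.sum() >= 14
        assert len(panel.concentrations.columns) == table.n_samples - cfg.n_missing_animals
        assert (panel.concentrations.to_numpy() > 0).all()

    def test_near_perfect_copula_gives_high_rho(self, lipid_dict):
        cfg = SynthConfig(n_features=200, rho_target=0.99, n_coupled_lipids=3,
                          n_coupled_cytokines=3, decreased_analytes=(), seed=13)
        table, truth = generate_feature_table(cfg, lipid_dict)
        panel = generate_cytokines(table, truth, cfg)
        for fid, analyte, _ in truth.planted_pairs:
            rho = spearman_rho(
                table.intensities.loc[fid, panel.concentrations.columns],
                panel.concentrations.loc[analyte],
            )
            assert rho >= 0.9

    def test_zero_copula_matches_null_spearman_oracle(self, lipid_dict):
        """rho_target = 0 decouples the pair: the fraction of planted-pair
        |rho| values below 0.4 at n = 18 matches a Monte-Carlo oracle of
        the null Spearman distribution (~90% at this n) within sampling
        error."""
        rng = np.random.default_rng(99)
        n = 18
        oracle = np.array([
            abs(spearman_rho(rng.normal(size=n), rng.normal(size=n)))
            for _ in range(2000)
        ])
        p_below_oracle = float(np.mean(oracle < 0.4))

        rhos = []
        for seed in range(15):
            cfg = SynthConfig(n_features=150, rho_target=0.0, n_coupled_lipids=3,
                              n_coupled_cytokines=3, decreased_analytes=(),
                              n_per_cell=5, n_missing_animals=0, seed=seed)
            table, truth = generate_feature_table(cfg, lipid_dict)
            panel = generate_cytokines(table, truth, cfg)
            sham = [a for a in panel.concentrations.columns
                    if panel.animals.loc[a, "injury"] == "sham"][:n]
            for fid, analyte, _ in truth.planted_pairs:
                rhos.append(abs(spearman_rho(
                    table.intensities.loc[fid, sham], panel.concentrations.loc[analyte, sham],
                )))
        observed = float(np.mean(np.asarray(rhos) < 0.4))
        se = np.sqrt(p_below_oracle * (1 - p_below_oracle) / len(rhos))
        assert abs(observed - p_below_oracle) < 4 * se + 0.02

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho_target"):
            SynthConfig(rho_target=-1.0)
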