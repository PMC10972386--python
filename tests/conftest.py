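import numpy as np
import pandas as pd
import pytest

from lipicyte.dictionary import default_dictionary
from lipicyte.features import FeatureTable
from lipicyte.synth import (
    SynthConfig, generate_cytokines, generate_feature_table, generate_ms2,
)


@pytest.fixture(scope="session")
def lipid_dict():
    return default_dictionary()


@pytest.fixture(scope="session")
def bundle(lipid_dict):
    """One synthetic study (features, truth, spectra, panel) shared across
    tests that only read it."""
    cfg = SynthConfig(n_features=600, seed=11)
    table, truth = generate_feature_table(cfg, lipid_dict)
    spectra = generate_ms2(truth, lipid_dict, cfg, table)
    panel = generate_cytokines(table, truth, cfg)
    return cfg, table, truth, spectra, panel


def make_table(intensities, mz=None, rt=None, samples=None):
    """Small FeatureTable from a 2-D array; default metadata gives a
    2-batch sham/1X/3X grid covering the columns."""
    intensities = np.asarray(intensities, dtype=float)
    n_feat, n_samp = intensities.shape
    fids = [f"F{i:03d}" for i in range(n_feat)]
    if samples is None:
        rows = []
        injuries = ["sham", "1X", "3X"]
        for j in range(n_samp):
            rows.append({
                "sample_id": f"S{j:02d}",
                "batch": 1 if j < n_samp // 2 else 2,
                "injury": injuries[j % 3],
                "sex": "M" if j % 2 == 0 else "F",
            })
        samples = pd.DataFrame(rows).set_index("sample_id")
    return FeatureTable(
        features=pd.DataFrame(
            {
                "mz": mz if mz is not None else np.linspace(200, 900, n_feat),
                "rt": rt if rt is not None else np.linspace(1, 20, n_feat),
            },
            index=pd.Index(fids, name="feature_id"),
        ),
        intensities=pd.DataFrame(intensities, index=pd.Index(fids, name="feature_id"),
                                 columns=list(samples.index)),
        samples=samples,
    )


@pytest.fixture
def tiny_table():
    return make_table
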