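import numpy as np
import pandas as pd
import pytest

import gkblup as gk


@pytest.fixture(scope="session")
def tiny_sim():
    """Small balanced synthetic dataset shared by model/CV tests."""
    cfg = gk.SyntheticConfig(J=30, I=2, nT=2, p=60, rho_true=0.5, seed=77)
    markers, pheno, truth = gk.simulate(cfg)
    return markers, pheno, truth


@pytest.fixture()
def small_pheno_df():
    rows = [
        ("A", "E1", 1.0, 2.0),
        ("B", "E1", 2.0, 1.0),
        ("A", "E2", 3.0, np.nan),
        ("B", "E2", 4.0, 2.5),
    ]
    return pd.DataFrame(rows, columns=["line", "env", "T1", "T2"])


@pytest.fixture()
def small_markers():
    return gk.MarkerMatrix(("A", "B", "C"), np.array([[0, 1, 2, 0], [2, 1, 0, 1], [1, 0, 1, 2]]))
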