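import numpy as np
import pandas as pd
import pytest

from omsurv.tabular_io import OmicsClinicalTable
from omsurv import synthetic


@pytest.fixture
def small_surv():
    """8-sample fixture with tied times, censoring and two groups."""
    time = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 5.0, 7.0])
    event = np.array([1, 1, 0, 1, 0, 1, 1, 0])
    group = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    return time, event, group


@pytest.fixture
def tiny_table():
    """5-sample, 3-feature table for structural tests."""
    feats = pd.DataFrame(
        {
            "g1": [0.1, 0.4, -0.2, 1.1, 0.0],
            "g2": [1.0, 2.0, 3.0, 4.0, 5.0],
            "m1": [0.5, 0.5, 0.5, 0.5, 0.5],
        },
        index=[f"s{i}" for i in range(5)],
    )
    return OmicsClinicalTable(
        features=feats,
        time=pd.Series([5.0, 3.0, 8.0, 2.0, 6.0], index=feats.index),
        event=pd.Series([1, 0, 1, 1, 0], index=feats.index),
        blocks={"g1": "gene", "g2": "gene", "m1": "methyl"},
    )


@pytest.fixture
def planted_table():
    """Factory: n=300 cohort with 5 planted prognostic features among nulls."""

    def make(seed=0, n_null=195, n_samples=300, **kw):
        kw.setdefault("beta", 1.0)
        cfg = synthetic.GeneratorConfig(
            n_samples=n_samples,
            n_gene=n_null + 5,
            n_methyl=0,
            n_mirna=0,
            n_prognostic=5,
            subtype_shift=0.0,
            seed=seed,
            **kw,
        )
        return synthetic.generate(cfg)

    return make
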