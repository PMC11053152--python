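import numpy as np
import pandas as pd
import pytest

from pptc_protrisk.containers import AbundanceMatrix
from pptc_protrisk.synthetic import SimConfig, generate_cohort


def small_config(**overrides) -> SimConfig:
    """A scaled-down cohort used across tests (fast, still structured)."""
    base = dict(
        n_pb=30, n_pm=40, n_am=20, n_proteins=300, n_batches=6,
        n_replicate_pairs=4, n_dep=30, n_signal=5, seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(seed=1))


@pytest.fixture(scope="session")
def clean_cohort():
    """Complete matrix (no missingness, no batch effects) for oracle tests."""
    return generate_cohort(
        small_config(seed=2, batch_sd=0.0, mnar_slope=0.0, mcar_rate=0.0)
    )


def matrix_from_values(values: np.ndarray, groups=None, batches=None,
                       scale="log2") -> AbundanceMatrix:
    """Wrap a raw array in an AbundanceMatrix with minimal metadata."""
    n_prot, n_samp = values.shape
    pids = [f"P{i:04d}" for i in range(n_prot)]
    sids = [f"S{i:03d}" for i in range(n_samp)]
    meta = pd.DataFrame(
        {
            "group": groups if groups is not None else ["PM"] * n_samp,
            "batch": batches if batches is not None else [1] * n_samp,
            "replicate_of": [None] * n_samp,
        },
        index=pd.Index(sids, name="sample"),
    )
    return AbundanceMatrix(
        pd.DataFrame(values, index=pd.Index(pids, name="protein"), columns=sids),
        meta,
        scale=scale,
    )
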