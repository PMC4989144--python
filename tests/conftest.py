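import numpy as np
import pytest

from nichepls.design import DesignMatrix, EncodingConfig, center_scale
from nichepls.io import Cavity, FactorPanel, Material, SampleRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)


def make_records(n=6):
    """Small condition set spanning materials, cavities and donors."""
    combos = [
        (Material.PDMS_FN, Cavity.CAV15),
        (Material.PDMS_FN, Cavity.CAV40),
        (Material.SPEG_HEP, Cavity.CAV15),
        (Material.SPEG_HEP, Cavity.CAV40),
        (Material.SPEG_SPEG, Cavity.CAV40),
        (Material.TCP, Cavity.PLANAR),
    ]
    records = []
    for i in range(n):
        m, c = combos[i % len(combos)]
        records.append(
            SampleRecord(
                sample_id=f"s{i}",
                material=m,
                cavity=c,
                cytokine_background=10.0,
                donor_id=f"D{i % 2 + 1}",
                replicate=i // len(combos) + 1,
                cell_count_day7=10_000 + 1_000 * i,
            )
        )
    return records


def make_panel(records, factors=("HGF", "IL12"), seed=0):
    rng = np.random.default_rng(seed)
    raw = rng.uniform(50.0, 500.0, size=(len(records), len(factors)))
    return FactorPanel(
        sample_ids=[r.sample_id for r in records],
        factor_names=list(factors),
        raw_levels=raw,
    )


@pytest.fixture
def small_records():
    return make_records(6)


@pytest.fixture
def small_panel(small_records):
    return make_panel(small_records)


def random_scaled_dm(n=8, p=5, seed=0, beta=None, noise=0.0):
    """Generic scaled design matrix for PLS-level tests (no mechanistic names)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = rng.normal(size=p)
    y = X @ np.asarray(beta, dtype=float)
    if noise:
        y = y + rng.normal(scale=noise, size=n)
    dm = DesignMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        column_names=[f"x{j}" for j in range(p)],
        X=X,
        y=y,
        groups=[("G", "G")] * n,
        encoding=EncodingConfig(),
    )
    return center_scale(dm)


def random_unscaled_dm(n=10, p=3, seed=0, noise=0.1, groups=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(scale=noise, size=n)
    return DesignMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        column_names=[f"x{j}" for j in range(p)],
        X=X,
        y=y,
        groups=groups or [("G", "G")] * n,
        encoding=EncodingConfig(),
    )
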