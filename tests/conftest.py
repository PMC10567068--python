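"""Shared fixtures: published reference values and synthetic tables."""

from __future__ import annotations

import numpy as np
import pytest

import flexsol as fx

#: Published outlier worked examples: per drug the flexibility index, the
#: observed log S0, and the printed predictions of each model/consensus
#: column, plus the printed closest-prediction residual.  Column order
#: follows the reference table (used for tie-breaking).
OUTLIER_ROWS = {
    # drug: (phi, obs, consensus_prior, consensus_this, xor, gse_phib,
    #        absolv_grp, gse_classic, closest_residual)
    "folic_acid": (6.6, -5.91, -3.88, -2.51, -4.07, -2.97, -2.05, -1.71, -1.84),
    "cisapride": (8.6, -6.78, -4.21, -4.16, -2.97, -4.24, -4.07, -3.71, -2.54),
    "amiodarone": (9.2, -10.40, -7.86, -7.21, -4.38, -6.48, -7.93, -7.75, -2.47),
    "itraconazole": (9.6, -8.71, -7.27, -7.12, -7.93, -5.69, -8.54, -6.48, -0.17),
    "rifabutin": (13.1, -3.99, -6.81, -5.05, -8.54, -5.21, -4.89, -5.63, 0.90),
    "cyclosporine_a": (31.5, -5.03, -8.27, -4.49, -5.21, -4.38, -4.59, -4.03, -0.44),
}

PRED_COLUMNS = (
    "consensus_prior",
    "consensus_this",
    "xor",
    "gse_phib",
    "absolv_grp",
    "gse_classic",
)


@pytest.fixture(scope="session")
def bundle() -> fx.ParameterBundle:
    return fx.builtin_bundle()


@pytest.fixture(scope="session")
def outlier_rows():
    return OUTLIER_ROWS


@pytest.fixture(scope="session")
def flexacceptor_frame():
    """10k-record synthetic table generated from the builtin GSE(Phi,B)."""
    cfg = fx.SimulationConfig(n_records=10_000, seed=2024, noise_sd=0.5)
    return fx.simulate_frame(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
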