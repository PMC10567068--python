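"""Synthetic compound-table generator.

Emulates the statistical structure of a large curated intrinsic-solubility
database: descriptor tuples drawn from the empirical ranges of drug-like
chemical space (flexibility Phi 0.4-43, Abraham B 0.4-12.9, clogP -5.8 to
+8.7, melting point 25-350 degC), an observed log S0 generated from a known
model plus Gaussian noise, and charge classes drawn with the database's
group proportions.  Everything is reproducible from a single seed, and the
draw stream is per-record: extending n leaves earlier records unchanged.

The generator samples descriptors independently by default; real databases
couple size and flexibility (large molecules are flexible), which the
optional correlated mode emulates with a linear Phi-MW link plus jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .params import (
    ChargeGroup,
    DEFAULT_FLEX_PARAMS,
    DEFAULT_ABSOLV_TABLE,
    CLASSIC_GSE,
    ModelName,
)
from .predict import absolv_grp, gse_linear, gse_phi_b
from .records import AbrahamDescriptors, CompoundRecord, records_to_frame

#: Default descriptor ranges (low, high); Phi, B and clogP follow the
#: published database ranges, the rest are drug-like choices.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "phi": (0.4, 43.0),
    "b": (0.4, 12.9),
    "clogp": (-5.8, 8.7),
    "mp_c": (25.0, 350.0),
    "a": (0.0, 3.0),
    "s": (0.5, 6.0),
    "e": (0.0, 6.0),
    "v": (0.5, 10.0),
}

#: Charge-class mixing proportions (database group counts:
#: acids 1578, bases 945, zwitterions 641, neutrals 4246, big 93, quats 39).
DEFAULT_GROUP_WEIGHTS: dict[ChargeGroup, float] = {
    ChargeGroup.ACID: 1578,
    ChargeGroup.BASE: 945,
    ChargeGroup.ZWITTERION: 641,
    ChargeGroup.NEUTRAL: 4246,
    ChargeGroup.BIG: 93,
    ChargeGroup.QUATERNARY: 39,
}

#: Rough McGowan-volume-to-weight conversion, Da per (cm^3/mol)/100.
MW_PER_V = 140.0


@dataclass
class SimulationConfig:
    """Configuration of one synthetic table draw."""

    n_records: int
    seed: int
    model: ModelName = ModelName.GSE_PHIB
    noise_sd: float = 0.5
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    group_weights: dict[ChargeGroup, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_WEIGHTS)
    )
    #: generating parameters; defaults to the builtin set matching `model`
    params: object | None = None
    #: when set, Phi+B takes only these discrete values (split 70/30 into
    #: Phi and B); used for exact binned-regression inversion studies
    key_levels: Optional[Sequence[float]] = None
    #: couple Phi to molecular size (linear link on MW + 20% jitter)
    correlated_phi_mw: bool = False

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ConfigError(f"n_records must be >= 1, got {self.n_records}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ConfigError(f"range for {name!r} must satisfy low < high")
        try:
            self.model = ModelName(self.model)
        except ValueError as exc:
            raise ConfigError(f"unknown generating model {self.model!r}") from exc
        if self.model == ModelName.CONSENSUS:
            raise ConfigError("consensus is not a generating model")
        if self.params is None:
            self.params = {
                ModelName.GSE_CLASSIC: CLASSIC_GSE,
                ModelName.GSE_PHIB: DEFAULT_FLEX_PARAMS,
                ModelName.ABSOLV_GRP: DEFAULT_ABSOLV_TABLE,
            }[self.model]


_GROUPS = list(ChargeGroup)


def _model_value(rec: CompoundRecord, cfg: SimulationConfig) -> float:
    if cfg.model == ModelName.GSE_CLASSIC:
        return gse_linear(rec, cfg.params)
    if cfg.model == ModelName.GSE_PHIB:
        return gse_phi_b(rec, cfg.params)
    return absolv_grp(rec, cfg.params)


def simulate_records(cfg: SimulationConfig) -> list[CompoundRecord]:
    """Draw a synthetic compound table.

    Descriptors are independent uniforms within the configured ranges
    (unless ``key_levels`` or ``correlated_phi_mw`` modify Phi/B), and
    ``logs0_obs`` is the generating-model value plus N(0, noise_sd) noise.
    The whole table is a deterministic function of ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    # one uniform block per record (row-major) keeps the stream stable
    # when n_records grows
    u = rng.random((cfg.n_records, 11))

    r = cfg.ranges

    def span(col: np.ndarray, key: str) -> np.ndarray:
        lo, hi = r[key]
        return lo + col * (hi - lo)

    phi = span(u[:, 0], "phi")
    b = span(u[:, 1], "b")
    clogp = span(u[:, 2], "clogp")
    mp = span(u[:, 3], "mp_c")
    a = span(u[:, 4], "a")
    s = span(u[:, 5], "s")
    e = span(u[:, 6], "e")
    v = span(u[:, 7], "v")
    mw = MW_PER_V * v

    if cfg.key_levels is not None:
        levels = np.asarray(list(cfg.key_levels), dtype=float)
        idx = np.minimum((u[:, 0] * len(levels)).astype(int), len(levels) - 1)
        x = levels[idx]
        phi, b = 0.7 * x, 0.3 * x
    elif cfg.correlated_phi_mw:
        lo, hi = r["phi"]
        frac = (mw - MW_PER_V * r["v"][0]) / (MW_PER_V * (r["v"][1] - r["v"][0]))
        jitter = 0.2 * (u[:, 0] - 0.5) * (hi - lo)
        phi = np.clip(lo + frac * (hi - lo) + jitter, lo, hi)

    weights = np.array([cfg.group_weights.get(g, 0.0) for g in _GROUPS], dtype=float)
    cum = np.cumsum(weights / weights.sum())
    group_idx = np.searchsorted(cum, u[:, 8], side="right")

    # Box-Muller from the per-record uniform block (stream-stable noise)
    z = np.sqrt(-2.0 * np.log(1.0 - u[:, 9])) * np.cos(2.0 * np.pi * u[:, 10])

    records = []
    for i in range(cfg.n_records):
        rec = CompoundRecord(
            id=f"syn{i:06d}",
            clogp=float(clogp[i]),
            mp_c=float(mp[i]),
            abraham=AbrahamDescriptors(
                A=float(a[i]), B=float(b[i]), S_pi=float(s[i]),
                E=float(e[i]), V=float(v[i]),
            ),
            phi=float(phi[i]),
            mw=float(mw[i]),
            charge_class=_GROUPS[group_idx[i]],
        )
        rec.logs0_obs = _model_value(rec, cfg) + cfg.noise_sd * float(z[i])
        records.append(rec)
    return records


def simulate_frame(cfg: SimulationConfig) -> pd.DataFrame:
    """:func:`simulate_records` flattened to the canonical DataFrame layout."""
    return records_to_frame(simulate_records(cfg))
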