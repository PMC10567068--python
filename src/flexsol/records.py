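"""Compound records and their tabular (DataFrame/CSV) representation.

A record carries everything any of the models may need: the calculated
octanol-water partition coefficient clogP, melting point in deg C (or a
liquid flag), the five Abraham solvation descriptors, the Kier flexibility
index Phi, molecular weight, an optional charge class at pH 7.4, and the
observed log10 molar intrinsic solubility when known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import InputError
from .params import ChargeGroup

#: Canonical input CSV columns (case-insensitive on read).
CANONICAL_COLUMNS = (
    "id",
    "smiles",
    "clogp",
    "mp_c",
    "is_liquid",
    "abraham_a",
    "abraham_b",
    "abraham_s",
    "abraham_e",
    "abraham_v",
    "charge_class",
    "mw",
    "phi",
    "logs0_obs",
)

#: Accepted aliases for canonical column names (all compared lower-case).
COLUMN_ALIASES = {
    "name": "id",
    "compound": "id",
    "logp": "clogp",
    "clog_p": "clogp",
    "mp": "mp_c",
    "melting_point": "mp_c",
    "a": "abraham_a",
    "b": "abraham_b",
    "s": "abraham_s",
    "s_pi": "abraham_s",
    "e": "abraham_e",
    "v": "abraham_v",
    "group": "charge_class",
    "molecular_weight": "mw",
    "logs0": "logs0_obs",
    "log_s0": "logs0_obs",
}


@dataclass(frozen=True)
class AbrahamDescriptors:
    """Abraham solvation descriptors.

    A: H-bond acidity (donor) sum; B: H-bond basicity (acceptor) sum;
    S_pi: dipolarity/polarizability; E: excess molar refractivity,
    (cm^3/mol)/10; V: McGowan volume, (cm^3/mol)/100.
    """

    A: float
    B: float
    S_pi: float
    E: float
    V: float

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise InputError(f"McGowan volume V must be > 0, got {self.V!r}")
        if self.A < 0 or self.B < 0:
            raise InputError(
                f"Abraham A and B must be >= 0, got A={self.A!r}, B={self.B!r}"
            )


@dataclass
class CompoundRecord:
    """One molecule's identity plus all model inputs."""

    id: str
    smiles: Optional[str] = None
    clogp: Optional[float] = None
    mp_c: Optional[float] = None
    is_liquid: bool = False
    abraham: Optional[AbrahamDescriptors] = None
    phi: Optional[float] = None
    mw: Optional[float] = None
    charge_class: Optional[ChargeGroup] = None
    logs0_obs: Optional[float] = None

    def __post_init__(self) -> None:
        if self.logs0_obs is not None and not math.isfinite(self.logs0_obs):
            raise InputError(f"record {self.id}: logs0_obs must be finite")
        if self.mp_c is not None and not (-100.0 <= self.mp_c <= 500.0):
            raise InputError(
                f"record {self.id}: melting point {self.mp_c} degC outside "
                "the plausible range [-100, 500]"
            )


def _opt(value) -> Optional[float]:
    if value is None:
        return None
    v = float(value)
    return None if math.isnan(v) else v


def records_to_frame(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    """Flatten records into the canonical DataFrame layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "smiles": r.smiles,
                "clogp": r.clogp,
                "mp_c": r.mp_c,
                "is_liquid": r.is_liquid,
                "abraham_a": r.abraham.A if r.abraham else np.nan,
                "abraham_b": r.abraham.B if r.abraham else np.nan,
                "abraham_s": r.abraham.S_pi if r.abraham else np.nan,
                "abraham_e": r.abraham.E if r.abraham else np.nan,
                "abraham_v": r.abraham.V if r.abraham else np.nan,
                "charge_class": r.charge_class.value if r.charge_class else None,
                "mw": r.mw,
                "phi": r.phi,
                "logs0_obs": r.logs0_obs,
            }
        )
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[CompoundRecord]:
    """Build records from a canonical-layout DataFrame."""
    records = []
    for i, row in df.iterrows():
        a = _opt(row.get("abraham_a"))
        b = _opt(row.get("abraham_b"))
        s = _opt(row.get("abraham_s"))
        e = _opt(row.get("abraham_e"))
        v = _opt(row.get("abraham_v"))
        abraham = None
        if all(x is not None for x in (a, b, s, e, v)):
            abraham = AbrahamDescriptors(A=a, B=b, S_pi=s, E=e, V=v)
        cls = row.get("charge_class")
        charge = ChargeGroup(str(cls).lower()) if isinstance(cls, str) and cls else None
        smiles = row.get("smiles")
        records.append(
            CompoundRecord(
                id=str(row.get("id", i)),
                smiles=smiles if isinstance(smiles, str) and smiles else None,
                clogp=_opt(row.get("clogp")),
                mp_c=_opt(row.get("mp_c")),
                is_liquid=bool(row.get("is_liquid", False))
                and str(row.get("is_liquid")).lower() not in ("0", "false", "nan"),
                abraham=abraham,
                phi=_opt(row.get("phi")),
                mw=_opt(row.get("mw")),
                charge_class=charge,
                logs0_obs=_opt(row.get("logs0_obs")),
            )
        )
    return records


def normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Map case-insensitive / aliased column names onto canonical names."""
    lowered = {str(c).strip().lower() for c in df.columns}
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key not in CANONICAL_COLUMNS:
            alias = COLUMN_ALIASES.get(key)
            # apply an alias only when the canonical column is not present
            if alias is not None and alias not in lowered:
                key = alias
        if key in CANONICAL_COLUMNS:
            renames[col] = key
    out = df.rename(columns=renames)
    dupes = out.columns[out.columns.duplicated()].tolist()
    if dupes:
        raise InputError(f"duplicate columns after alias resolution: {dupes}")
    return out


def read_records_csv(path) -> pd.DataFrame:
    """Read a compound table from CSV with canonical column resolution.

    Empty cells and "NA" are treated as missing.
    """
    try:
        df = pd.read_csv(path, na_values=["NA"], skipinitialspace=True)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read records CSV {path}: {exc}") from exc
    df = normalize_columns(df)
    if df.empty:
        raise InputError(f"no usable rows in {path}")
    if "id" not in df.columns:
        df.insert(0, "id", [f"row{i}" for i in range(len(df))])
    return df
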