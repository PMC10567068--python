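"""Evaluation of the base solubility models and the consensus average.

Three transparent models predict log10 molar intrinsic solubility:

* classic GSE:       log S0 = 0.5 - clogP - 0.01 (mp - 25)
* grouped ABSOLV:    log S0 = a0 + a1 A + a2 B + a3 S_pi + a4 E + a5 V + a6 A B
  with one coefficient row per compound group
* GSE(Phi,B):        log S0 = c0(x) + c1(x) clogP + c2(x) (mp - 25)/100,
  x = Phi + B, with smooth coefficient functions of flexibility and
  H-bond acceptor strength

plus the consensus, the arithmetic mean of the grouped-ABSOLV and
GSE(Phi,B) predictions.  For liquids and compounds melting at or below
25 degC the melting term is zero.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from rdkit import Chem

from .descriptors import flexibility_index, molecular_weight
from .errors import DescriptorMissingError, InputError
from .records import CompoundRecord, frame_to_records, records_to_frame
from .params import (
    AbsolvGroupTable,
    ChargeGroup,
    FlexAcceptorParams,
    LinearGseParams,
    ModelName,
    ParameterBundle,
    builtin_bundle,
)

#: Molecular weight (Da) above which a compound belongs to the "big" group.
BIG_MW_THRESHOLD = 800.0


def _melting_term(rec: CompoundRecord) -> float:
    """(mp - 25), clamped to 0 for liquids and low-melting compounds."""
    if rec.is_liquid:
        return 0.0
    if rec.mp_c is None:
        raise DescriptorMissingError(
            f"record {rec.id}: melting point missing and not flagged liquid"
        )
    return max(rec.mp_c - 25.0, 0.0)


def gse_linear(rec: CompoundRecord, params: LinearGseParams) -> float:
    """Evaluate a linear GSE variant: c0 + c1*clogP + c2*(mp - 25)."""
    if rec.clogp is None:
        raise DescriptorMissingError(f"record {rec.id}: clogP missing")
    return params.c0 + params.c1 * rec.clogp + params.c2 * _melting_term(rec)


# SMARTS used by the heuristic charge classifier (net charge at pH 7.4).
_ACID_SMARTS = [
    Chem.MolFromSmarts(s)
    for s in (
        "[CX3](=O)[OX2H1]",          # carboxylic acid
        "[SX4](=O)(=O)[OX2H1]",      # sulfonic acid
        "[PX4](=O)([OX2H1])",        # phosphonic/phosphoric acid
        "c1nnn[nH]1",                # tetrazole
        "[NX3H1]([CX3]=O)[CX3]=O",   # imide
    )
]
_BASE_SMARTS = [
    Chem.MolFromSmarts(s)
    for s in (
        "[NX3;H2,H1,H0;+0;!$(N[C,S,P]=[O,S,N]);!$(N~[!#6]);!$(Na)]",  # amine
        "[NX3][CX3]=[NX2]",          # amidine / guanidine
    )
]
_QUAT_SMARTS = Chem.MolFromSmarts("[N+;H0;!$([N+][O-])]")


def classify_group(rec: CompoundRecord) -> ChargeGroup:
    """Assign a compound to one of the six ABSOLV groups.

    A user-supplied ``charge_class`` always wins.  Otherwise the precedence
    is: big (MW > 800 Da) > quaternary nitrogen > substructure-based net
    charge at pH 7.4 (acid / base / zwitterion / neutral).  The heuristic
    needs a SMILES; with neither class nor structure an error is raised.
    """
    if rec.charge_class is not None:
        return rec.charge_class
    mw = rec.mw
    if mw is None and rec.smiles is not None:
        mw = molecular_weight(rec.smiles, rec.id)
    if mw is not None and mw > BIG_MW_THRESHOLD:
        return ChargeGroup.BIG
    if rec.smiles is None:
        raise InputError(
            f"record {rec.id}: cannot classify group without charge_class or SMILES"
        )
    mol = Chem.MolFromSmiles(rec.smiles)
    if mol is None:
        raise InputError(f"record {rec.id}: unparsable SMILES {rec.smiles!r}")
    has_acid = any(mol.HasSubstructMatch(p) for p in _ACID_SMARTS)
    has_base = any(mol.HasSubstructMatch(p) for p in _BASE_SMARTS)
    if mol.HasSubstructMatch(_QUAT_SMARTS) and not has_acid:
        return ChargeGroup.QUATERNARY
    if has_acid and has_base:
        return ChargeGroup.ZWITTERION
    if has_acid:
        return ChargeGroup.ACID
    if has_base:
        return ChargeGroup.BASE
    return ChargeGroup.NEUTRAL


def absolv_grp(rec: CompoundRecord, table: AbsolvGroupTable) -> float:
    """Grouped-ABSOLV prediction for a record (includes the A*B cross term)."""
    if rec.abraham is None:
        raise DescriptorMissingError(
            f"record {rec.id}: Abraham descriptors (A, B, S_pi, E, V) missing"
        )
    c = table[classify_group(rec)]
    d = rec.abraham
    return (
        c.a0
        + c.a1 * d.A
        + c.a2 * d.B
        + c.a3 * d.S_pi
        + c.a4 * d.E
        + c.a5 * d.V
        + c.a6 * d.A * d.B
    )


def c_coefficients(x, params: FlexAcceptorParams):
    """Coefficient functions of the flexible-acceptor model at x = Phi + B.

    c0 decays exponentially, c1 rises exponentially toward its asymptote,
    c2 is linear.  Accepts scalars or arrays; x must be non-negative.
    """
    xs = np.asarray(x, dtype=float)
    if np.any(xs < 0):
        raise ValueError(f"Phi + B must be >= 0, got {x!r}")
    c0 = params.b0 + params.b1 * np.exp(-params.b2 * xs)
    c1 = params.b3 + params.b4 * (1.0 - np.exp(-params.b5 * xs))
    c2 = params.b6 + params.b7 * xs
    if np.isscalar(x) or xs.ndim == 0:
        return float(c0), float(c1), float(c2)
    return c0, c1, c2


def gse_phi_b(rec: CompoundRecord, params: FlexAcceptorParams) -> float:
    """Flexible-acceptor GSE(Phi,B) prediction for a record.

    Note the melting term is scaled (mp - 25)/100, unlike the classic GSE.
    """
    missing = []
    if rec.clogp is None:
        missing.append("clogP")
    if rec.phi is None or math.isnan(rec.phi):
        missing.append("phi")
    if rec.abraham is None:
        missing.append("Abraham B")
    if missing:
        raise DescriptorMissingError(
            f"record {rec.id}: missing descriptors for GSE(Phi,B): {', '.join(missing)}"
        )
    c0, c1, c2 = c_coefficients(rec.phi + rec.abraham.B, params)
    return c0 + c1 * rec.clogp + c2 * _melting_term(rec) / 100.0


def consensus(absolv: Optional[float], gsephib: Optional[float]) -> float:
    """Arithmetic mean of the grouped-ABSOLV and GSE(Phi,B) predictions.

    Returns ``nan`` when either input is missing or non-finite.
    """
    if absolv is None or gsephib is None:
        return math.nan
    if not (math.isfinite(absolv) and math.isfinite(gsephib)):
        return math.nan
    return (absolv + gsephib) / 2.0


def predict_records(
    records: list[CompoundRecord],
    bundle: ParameterBundle | None = None,
    compute_phi: bool = True,
) -> pd.DataFrame:
    """Run all models on a list of records.

    Missing descriptors degrade to ``nan`` cells rather than aborting the
    run.  When ``compute_phi`` is set, records with a SMILES but no Phi get
    Phi (and MW, if absent) computed from structure first.  Returns a frame
    with one row per record: phi, group and the four model predictions.
    """
    bundle = bundle or builtin_bundle()
    rows = []
    for rec in records:
        if compute_phi and rec.smiles is not None:
            if rec.phi is None:
                try:
                    rec.phi = flexibility_index(rec.smiles, record_id=rec.id)
                except InputError:
                    pass
            if rec.mw is None:
                try:
                    rec.mw = molecular_weight(rec.smiles, rec.id)
                except InputError:
                    pass
        row: dict = {"id": rec.id, "phi": rec.phi if rec.phi is not None else np.nan}
        try:
            row["group"] = classify_group(rec).value
        except InputError:
            row["group"] = None
        for col, fn, extra in (
            ("logs0_gse", gse_linear, bundle.linear_gse),
            ("logs0_absolv_grp", absolv_grp, bundle.absolv_table),
            ("logs0_gse_phib", gse_phi_b, bundle.flex_params),
        ):
            try:
                row[col] = fn(rec, extra)
            except (DescriptorMissingError, InputError):
                row[col] = np.nan
        row["logs0_consensus"] = consensus(
            row["logs0_absolv_grp"], row["logs0_gse_phib"]
        )
        row["logs0_obs"] = rec.logs0_obs if rec.logs0_obs is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def predict_frame(
    df: pd.DataFrame,
    bundle: ParameterBundle | None = None,
    compute_phi: bool = True,
) -> pd.DataFrame:
    """:func:`predict_records` for a canonical-layout DataFrame."""
    return predict_records(frame_to_records(df), bundle, compute_phi)


_MODEL_COLUMNS = {
    ModelName.GSE_CLASSIC: "logs0_gse",
    ModelName.ABSOLV_GRP: "logs0_absolv_grp",
    ModelName.GSE_PHIB: "logs0_gse_phib",
    ModelName.CONSENSUS: "logs0_consensus",
}


def model_column(model: ModelName) -> str:
    """Output column name holding a given model's predictions."""
    return _MODEL_COLUMNS[ModelName(model)]
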