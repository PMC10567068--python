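"""Model fitting: binned regression for GSE(Phi,B) and grouped ABSOLV fits.

The flexible-acceptor model is trained in two steps, mirroring how the
published coefficients were derived:

1. records are sorted on ``x = Phi + B`` and split into bins; in each bin
   ordinary least squares fits ``log S0 ~ 1 + clogP + (mp - 25)/100``,
   giving per-bin coefficients (c0, c1, c2);
2. three parametric forms are fitted to the per-bin coefficients against
   the bin-mean x by nonlinear least squares::

       c0(x) = b0 + b1 exp(-b2 x)
       c1(x) = b3 + b4 (1 - exp(-b5 x))
       c2(x) = b6 + b7 x

The module exposes the procedure both as plain functions (``bin_by_key``,
``fit_bin_gse``, ``fit_c_functions``, ``fit_absolv_groups``,
``profile_bins``) and as model classes in the statsmodels idiom:
``FlexibleAcceptorGSE(data).fit()`` and ``GroupedAbsolv(data).fit()``
return results objects carrying estimates, diagnostics and ``summary()``.

Per-bin and per-group fits use OLS: with two near-orthogonal predictors
and n much larger than p a full-rank projection-to-latent-structures fit
converges to the same solution, and OLS removes a latent-component count
that would otherwise be a free parameter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import TrainingError
from .params import (
    AbsolvCoefficients,
    AbsolvGroupTable,
    ChargeGroup,
    DecisionInterval,
    DecisionRule,
    FlexAcceptorParams,
    ModelName,
    PHI_FLEXIBLE_CROSSOVER,
    PHI_RIGID_CROSSOVER,
)
from .predict import model_column, predict_frame
from .records import records_to_frame

logger = logging.getLogger(__name__)

#: Minimum records per bin for a regression to be attempted.
MIN_BIN_SIZE = 3
#: Minimum records per ABSOLV group.
MIN_GROUP_SIZE = 8
#: Decay-rate starting points for the nonlinear coefficient-function fits.
RATE_STARTS = (0.01, 0.03, 0.1, 0.3, 1.0)
#: Objective convergence tolerance of the nonlinear fits.
NLS_TOL = 1e-10


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    return records_to_frame(data)


def _key_values(df: pd.DataFrame, key: str) -> np.ndarray:
    if key == "phi":
        return df["phi"].to_numpy(dtype=float)
    if key == "phi_plus_b":
        return df["phi"].to_numpy(dtype=float) + df["abraham_b"].to_numpy(dtype=float)
    raise ValueError(f"unknown binning key {key!r}")


def bin_by_key(
    data, key: str = "phi_plus_b", n_bins: int = 20, binning: str = "quantile"
) -> list[pd.DataFrame]:
    """Sort records on a key and partition them into contiguous bins.

    ``binning='quantile'`` gives near-equal bin populations (the default:
    it stabilises the per-bin regressions); ``'width'`` gives equal key
    spans.  Records missing the key or the observed solubility raise a
    :class:`TrainingError` via the size floor.
    """
    df = _as_frame(data)
    if n_bins < 2:
        raise TrainingError(f"n_bins must be >= 2, got {n_bins}")
    keys = _key_values(df, key)
    usable = np.isfinite(keys) & np.isfinite(df["logs0_obs"].to_numpy(dtype=float))
    df = df.loc[usable]
    keys = keys[usable]
    if len(df) < n_bins:
        raise TrainingError(
            f"need >= {n_bins} usable records for {n_bins} bins, got {len(df)}"
        )
    order = np.argsort(keys, kind="stable")  # equal keys stay contiguous
    df = df.iloc[order]
    keys = keys[order]
    if binning == "quantile":
        parts = np.array_split(np.arange(len(df)), n_bins)
    elif binning == "width":
        edges = np.linspace(keys[0], keys[-1], n_bins + 1)
        which = np.clip(np.searchsorted(edges, keys, side="right") - 1, 0, n_bins - 1)
        parts = [np.flatnonzero(which == i) for i in range(n_bins)]
    else:
        raise ValueError(f"unknown binning strategy {binning!r}")
    return [df.iloc[p] for p in parts if len(p)]


def _melting_design(df: pd.DataFrame) -> np.ndarray:
    mp = df["mp_c"].to_numpy(dtype=float)
    term = np.maximum(mp - 25.0, 0.0)
    if "is_liquid" in df.columns:
        term = np.where(df["is_liquid"].fillna(False).astype(bool), 0.0, term)
    return term / 100.0


def fit_bin_gse(bin_df: pd.DataFrame, label: str = "bin") -> tuple[float, float, float]:
    """OLS fit of ``log S0 ~ 1 + clogP + (mp - 25)/100`` within one bin."""
    df = bin_df.dropna(subset=["clogp", "mp_c", "logs0_obs"])
    if len(df) < MIN_BIN_SIZE:
        raise TrainingError(f"{label}: needs >= {MIN_BIN_SIZE} complete records")
    design = np.column_stack(
        [
            np.ones(len(df)),
            df["clogp"].to_numpy(dtype=float),
            _melting_design(df),
        ]
    )
    if np.linalg.matrix_rank(design) < 3:
        raise TrainingError(
            f"{label}: rank-deficient design (constant clogP or melting point)"
        )
    coef, *_ = np.linalg.lstsq(design, df["logs0_obs"].to_numpy(dtype=float), rcond=None)
    return tuple(float(c) for c in coef)


def _c0_form(x, b0, b1, b2):
    return b0 + b1 * np.exp(-b2 * x)


def _c1_form(x, b3, b4, b5):
    return b3 + b4 * (1.0 - np.exp(-b5 * x))


def _curve_diag(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    if np.std(y) > 0 and np.std(yhat) > 0:
        r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    else:
        r2 = math.nan
    return {"r2": r2, "rmse": rmse}


def _fit_exp(form, x, y, rate_sign: int) -> tuple[np.ndarray, float]:
    """Multi-start bounded fit of one exponential coefficient form.

    ``rate_sign`` +1 fits a decaying form toward ``y[-1]`` (c0),
    -1 a saturating form from ``y[0]`` (c1); the decay rate stays > 0.
    """
    order = np.argsort(x)
    x, y = np.asarray(x, float)[order], np.asarray(y, float)[order]
    if rate_sign > 0:  # c0: offset is the large-x tail, amplitude the drop
        p_offset, p_amp = y[-1], y[0] - y[-1]
    else:  # c1: offset is the small-x intercept, amplitude the rise
        p_offset, p_amp = y[0], y[-1] - y[0]
    best, best_sse = None, np.inf
    for rate0 in RATE_STARTS:
        try:
            popt, _ = curve_fit(
                form,
                x,
                y,
                p0=(p_offset, p_amp, rate0),
                bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
                ftol=NLS_TOL,
                xtol=NLS_TOL,
                maxfev=20000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((form(x, *popt) - y) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        raise TrainingError(
            f"coefficient-function fit failed to converge from starts {RATE_STARTS}"
        )
    return best, best_sse


def fit_c_functions(bin_fits) -> tuple[FlexAcceptorParams, dict[str, dict[str, float]]]:
    """Fit the three parametric coefficient functions to per-bin (c0, c1, c2).

    ``bin_fits`` is an iterable of (key_mean, c0, c1, c2) or a DataFrame
    with those columns.  Returns the eight b-parameters and per-curve
    diagnostics (Pearson r^2 and RMSE).  Invariant to bin ordering.
    """
    if isinstance(bin_fits, pd.DataFrame):
        arr = bin_fits[["key_mean", "c0", "c1", "c2"]].to_numpy(dtype=float)
    else:
        arr = np.array([tuple(row) for row in bin_fits], dtype=float)
    if arr.shape[0] < 8:
        raise TrainingError(
            f"need >= 8 bins to fit 8 parameters, got {arr.shape[0]}"
        )
    arr = arr[np.argsort(arr[:, 0])]
    x, c0, c1, c2 = arr.T

    (b0, b1, b2), _ = _fit_exp(_c0_form, x, c0, rate_sign=+1)
    (b3, b4, b5), _ = _fit_exp(_c1_form, x, c1, rate_sign=-1)
    b7, b6 = np.polyfit(x, c2, 1)  # linear sub-problem solved by OLS

    params = FlexAcceptorParams(
        b0=float(b0), b1=float(b1), b2=float(b2),
        b3=float(b3), b4=float(b4), b5=float(b5),
        b6=float(b6), b7=float(b7),
    )
    diagnostics = {
        "c0": _curve_diag(c0, _c0_form(x, b0, b1, b2)),
        "c1": _curve_diag(c1, _c1_form(x, b3, b4, b5)),
        "c2": _curve_diag(c2, b6 + b7 * x),
    }
    return params, diagnostics


# --------------------------------------------------------------------------
# statsmodels-style model classes
# --------------------------------------------------------------------------


class FlexibleAcceptorGSE:
    """Two-step binned-regression model for the GSE(Phi,B) coefficients.

    Parameters
    ----------
    data : DataFrame (canonical layout) or list of CompoundRecord
        Training records with phi, abraham_b, clogp, mp_c and logs0_obs.
    key : {"phi_plus_b", "phi"}
        Sorting key for the binning step (default the Phi + B sum).
    n_bins : int
        Number of contiguous bins (default 20).
    binning : {"quantile", "width"}
        Near-equal populations (default) or equal key spans.
    """

    def __init__(self, data, key: str = "phi_plus_b", n_bins: int = 20,
                 binning: str = "quantile"):
        self.data = _as_frame(data)
        self.key = key
        self.n_bins = n_bins
        self.binning = binning

    @classmethod
    def from_records(cls, records, **kwargs) -> "FlexibleAcceptorGSE":
        return cls(records_to_frame(records), **kwargs)

    def fit(self) -> "FlexibleAcceptorGSEResults":
        bins = bin_by_key(self.data, self.key, self.n_bins, self.binning)
        rows = []
        for i, bdf in enumerate(bins):
            c0, c1, c2 = fit_bin_gse(bdf, label=f"bin {i}")
            rows.append(
                {
                    "bin_index": i,
                    "key_mean": float(np.mean(_key_values(bdf, self.key))),
                    "n_entries": len(bdf),
                    "c0": c0,
                    "c1": c1,
                    "c2": c2,
                }
            )
        bin_fits = pd.DataFrame(rows)
        params, diagnostics = fit_c_functions(bin_fits)
        return FlexibleAcceptorGSEResults(self, params, bin_fits, diagnostics)


@dataclass
class FlexibleAcceptorGSEResults:
    """Fitted flexible-acceptor coefficients plus per-bin diagnostics."""

    model: FlexibleAcceptorGSE
    params: FlexAcceptorParams
    bin_fits: pd.DataFrame
    curve_diagnostics: dict[str, dict[str, float]]

    def predict(self, data) -> pd.Series:
        """GSE(Phi,B) predictions for new records using the fitted params."""
        from .params import builtin_bundle
        import dataclasses as _dc

        bundle = _dc.replace(builtin_bundle(), flex_params=self.params,
                             provenance="fitted FlexibleAcceptorGSE")
        out = predict_frame(_as_frame(data), bundle)
        return out["logs0_gse_phib"]

    def summary(self) -> str:
        d = self.curve_diagnostics
        p = self.params
        lines = [
            "Flexible-Acceptor GSE(Phi,B) — two-step binned regression",
            f"  bins: {len(self.bin_fits)} ({self.model.binning}, key={self.model.key})"
            f", records: {int(self.bin_fits['n_entries'].sum())}",
            "  coefficient functions of x = Phi + B:",
            f"    c0(x) = {p.b0:+.4f} + {p.b1:.4f} exp(-{p.b2:.4f} x)"
            f"    [r2={d['c0']['r2']:.3f}, RMSE={d['c0']['rmse']:.3f}]",
            f"    c1(x) = {p.b3:+.4f} + {p.b4:.4f} (1 - exp(-{p.b5:.4f} x))"
            f"    [r2={d['c1']['r2']:.3f}, RMSE={d['c1']['rmse']:.3f}]",
            f"    c2(x) = {p.b6:+.4f} + {p.b7:.4f} x"
            f"    [r2={d['c2']['r2']:.3f}, RMSE={d['c2']['rmse']:.3f}]",
        ]
        return "\n".join(lines)


def fit_absolv_groups(
    data, min_group_size: int = MIN_GROUP_SIZE
) -> tuple[dict[ChargeGroup, AbsolvCoefficients], list[ChargeGroup]]:
    """Per-group OLS fit of the seven-term ABSOLV form.

    Returns the fitted coefficient rows and the list of groups left unfit
    for lack of records.  Raises :class:`TrainingError` when no group
    reaches the size floor.
    """
    df = _as_frame(data).dropna(
        subset=["abraham_a", "abraham_b", "abraham_s", "abraham_e", "abraham_v",
                "logs0_obs"]
    )
    fitted: dict[ChargeGroup, AbsolvCoefficients] = {}
    unfit: list[ChargeGroup] = []
    for group in ChargeGroup:
        gdf = df[df["charge_class"] == group.value]
        if len(gdf) < min_group_size:
            unfit.append(group)
            continue
        A = gdf["abraham_a"].to_numpy(dtype=float)
        B = gdf["abraham_b"].to_numpy(dtype=float)
        design = np.column_stack(
            [
                np.ones(len(gdf)),
                A,
                B,
                gdf["abraham_s"].to_numpy(dtype=float),
                gdf["abraham_e"].to_numpy(dtype=float),
                gdf["abraham_v"].to_numpy(dtype=float),
                A * B,
            ]
        )
        coef, *_ = np.linalg.lstsq(
            design, gdf["logs0_obs"].to_numpy(dtype=float), rcond=None
        )
        fitted[group] = AbsolvCoefficients(*(float(c) for c in coef))
    if not fitted:
        raise TrainingError(
            f"no ABSOLV group reached the size floor of {min_group_size} records"
        )
    if unfit:
        logger.info("ABSOLV groups left unfit (too few records): %s",
                    [g.value for g in unfit])
    return fitted, unfit


class GroupedAbsolv:
    """Grouped ABSOLV model: one seven-term linear fit per compound group."""

    def __init__(self, data, min_group_size: int = MIN_GROUP_SIZE):
        self.data = _as_frame(data)
        self.min_group_size = min_group_size

    @classmethod
    def from_records(cls, records, **kwargs) -> "GroupedAbsolv":
        return cls(records_to_frame(records), **kwargs)

    def fit(self) -> "GroupedAbsolvResults":
        fitted, unfit = fit_absolv_groups(self.data, self.min_group_size)
        return GroupedAbsolvResults(self, fitted, unfit)


@dataclass
class GroupedAbsolvResults:
    """Fitted per-group ABSOLV coefficient rows."""

    model: GroupedAbsolv
    coefficients: dict[ChargeGroup, AbsolvCoefficients]
    unfit_groups: list[ChargeGroup]

    @property
    def table(self) -> AbsolvGroupTable:
        """Complete six-group table; raises if any group is unfit."""
        if self.unfit_groups:
            raise TrainingError(
                "groups left unfit: " + ", ".join(g.value for g in self.unfit_groups)
            )
        return AbsolvGroupTable(groups=dict(self.coefficients))

    def summary(self) -> str:
        header = f"{'group':<12}" + "".join(f"{f'a{i}':>8}" for i in range(7))
        lines = ["Grouped ABSOLV — per-group OLS of the seven-term form", header]
        for g, c in self.coefficients.items():
            lines.append(
                f"{g.value:<12}" + "".join(f"{v:8.3f}" for v in c.as_array())
            )
        if self.unfit_groups:
            lines.append(
                "unfit (too few records): "
                + ", ".join(g.value for g in self.unfit_groups)
            )
        return "\n".join(lines)


# --------------------------------------------------------------------------
# Selector profiling
# --------------------------------------------------------------------------

#: Tie-break preference on exact RMSE ties (flexible-space model first).
_TIE_ORDER = (ModelName.GSE_PHIB, ModelName.ABSOLV_GRP, ModelName.GSE_CLASSIC)


def profile_bins(
    data, bundle=None, n_bins: int = 19, key: str = "phi",
    binning: str = "quantile",
) -> pd.DataFrame:
    """Per-flexibility-bin RMSE of the three base models and the winner.

    Records are sorted on Phi (by default) into ``n_bins`` bins; within each
    bin the RMSE of classic GSE, grouped ABSOLV and GSE(Phi,B) predictions
    against the observations is computed and the argmin model recorded.
    Records missing any model's inputs are excluded (counts logged).
    """
    df = _as_frame(data)
    preds = predict_frame(df, bundle)
    merged = df.reset_index(drop=True).copy()
    for m in _TIE_ORDER:
        merged[model_column(m)] = preds[model_column(m)].to_numpy()
    if "phi" in preds.columns:  # prefer computed phi (SMILES-derived)
        merged["phi"] = preds["phi"].to_numpy()
    complete = merged.dropna(
        subset=["logs0_obs"] + [model_column(m) for m in _TIE_ORDER]
    )
    n_dropped = len(merged) - len(complete)
    if n_dropped:
        logger.info("profile_bins: excluded %d records with missing values", n_dropped)
    bins = bin_by_key(complete, key=key, n_bins=n_bins, binning=binning)
    rows = []
    for i, bdf in enumerate(bins):
        obs = bdf["logs0_obs"].to_numpy(dtype=float)
        rmses = {}
        for m in _TIE_ORDER:
            pred = bdf[model_column(m)].to_numpy(dtype=float)
            rmses[m] = float(np.sqrt(np.mean((obs - pred) ** 2)))
        best = min(_TIE_ORDER, key=lambda m: rmses[m])  # stable: tie order wins
        rows.append(
            {
                "bin_index": i,
                "key_mean": float(np.mean(_key_values(bdf, key))),
                "n_entries": len(bdf),
                "rmse_gse": rmses[ModelName.GSE_CLASSIC],
                "rmse_absolv_grp": rmses[ModelName.ABSOLV_GRP],
                "rmse_gse_phib": rmses[ModelName.GSE_PHIB],
                "best_model": best.value,
            }
        )
    return pd.DataFrame(rows)


def decision_rule_from_profile(
    profile: pd.DataFrame,
    rigid_crossover: float = PHI_RIGID_CROSSOVER,
    flexible_crossover: float = PHI_FLEXIBLE_CROSSOVER,
) -> DecisionRule:
    """Build an XOR decision rule from a :func:`profile_bins` table.

    Middle-domain interval edges sit at midpoints between consecutive
    bin-mean Phi values; the rigid and flexible domains keep their fixed
    crossovers and models.
    """
    mid = profile[
        (profile["key_mean"] >= rigid_crossover)
        & (profile["key_mean"] <= flexible_crossover)
    ].sort_values("key_mean")
    intervals = [DecisionInterval(0.0, rigid_crossover, ModelName.GSE_CLASSIC)]
    centers = list(zip(mid["key_mean"], mid["best_model"]))
    if not centers:  # degenerate profile: whole middle domain to GSE(Phi,B)
        centers = [(rigid_crossover, ModelName.GSE_PHIB.value)]
    lower = rigid_crossover
    for (phi, best), nxt in zip(centers, centers[1:] + [None]):
        upper = flexible_crossover if nxt is None else (phi + nxt[0]) / 2.0
        intervals.append(DecisionInterval(lower, upper, ModelName(best)))
        lower = upper
    intervals.append(
        DecisionInterval(flexible_crossover, math.inf, ModelName.GSE_PHIB)
    )
    return DecisionRule(intervals=tuple(intervals))
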