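"""Validation metrics for solubility predictions.

All metrics are of the validation type: r^2 is computed against the
observed mean, ``1 - SS_res / SS_tot``, and can be negative for a model
worse than the mean predictor.  Bias is ``mean(obs - pred)``, so a model
that overestimates solubility has negative bias.  MPP (measure of
prediction performance) is the percentage of compounds predicted within
+/-0.5 log unit of observation, boundary inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MetricError

#: Half-width of the MPP band in log10 units.
MPP_WINDOW = 0.5


@dataclass(frozen=True)
class MetricReport:
    """Validation metrics of one (observed, predicted) set."""

    n: int
    r2: float
    rmse: float
    bias: float
    mpp: float
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "r2": self.r2,
            "rmse": self.rmse,
            "bias": self.bias,
            "mpp": self.mpp,
            "n_excluded": self.n_excluded,
        }


def evaluate(obs, pred) -> MetricReport:
    """Compute validation r^2, RMSE, bias and MPP for paired predictions.

    Pairs with a non-finite observation or prediction are excluded (the
    count is reported).  At least two finite pairs and non-zero variance in
    the observations are required.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise MetricError(
            f"observed and predicted lengths differ: {obs.shape} vs {pred.shape}"
        )
    keep = np.isfinite(obs) & np.isfinite(pred)
    n_excluded = int((~keep).sum())
    obs, pred = obs[keep], pred[keep]
    n = obs.size
    if n < 2:
        raise MetricError(f"need >= 2 finite pairs, got {n}")
    resid = obs - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise MetricError("observed values have zero variance; r2 undefined")
    return MetricReport(
        n=n,
        r2=1.0 - ss_res / ss_tot,
        rmse=float(np.sqrt(ss_res / n)),
        bias=float(resid.mean()),
        mpp=100.0 * float((np.abs(resid) <= MPP_WINDOW).sum()) / n,
        n_excluded=n_excluded,
    )
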