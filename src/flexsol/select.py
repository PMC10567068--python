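"""Model selection: the XOR decision tree and the simplified recommendation.

The XOR decision tree picks, per compound, whichever base model performed
best in the flexibility bin the compound falls into: the classic GSE for
very rigid molecules (Phi < 1.66), GSE(Phi,B) for very flexible ones
(Phi > 10.83), and the per-bin winner of grouped ABSOLV vs GSE(Phi,B) in
between.  The simplified recommendation instead takes the consensus for
Phi < 11 and GSE(Phi,B) above.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import (
    DecisionRule,
    ModelName,
    PHI_RECOMMENDED_THRESHOLD,
    default_decision_rule,
)
from .predict import model_column

logger = logging.getLogger(__name__)


def xor_select(phi: Optional[float], rule: DecisionRule | None = None) -> ModelName:
    """Select the per-bin best base model for a flexibility value.

    A missing Phi defaults to the classic GSE with a logged warning (the
    Phi-dependent models are meaningless without a defined Phi).
    """
    if phi is None or (isinstance(phi, float) and math.isnan(phi)):
        logger.warning("xor_select: Phi missing, defaulting to classic GSE")
        return ModelName.GSE_CLASSIC
    rule = rule or default_decision_rule()
    return rule.lookup(float(phi))


def recommended_select(phi: float) -> ModelName:
    """Published simplified rule: consensus below Phi = 11, GSE(Phi,B) above."""
    if not phi >= 0:
        raise ValueError(f"phi must be >= 0, got {phi!r}")
    return ModelName.CONSENSUS if phi < PHI_RECOMMENDED_THRESHOLD else ModelName.GSE_PHIB


def closest_prediction(
    obs: float, preds: Sequence[tuple[str, float]]
) -> tuple[str, float]:
    """Find the prediction closest to an observation.

    Returns ``(model, obs - pred)`` for the prediction minimising
    ``|obs - pred|``; non-finite predictions are ignored and ties are broken
    by input order (first listed wins).
    """
    if not math.isfinite(obs):
        raise ValueError(f"observed value must be finite, got {obs!r}")
    usable = [(m, p) for m, p in preds if p is not None and math.isfinite(p)]
    if not usable:
        raise ValueError("closest_prediction needs at least one finite prediction")
    best_model, best_pred = min(usable, key=lambda mp: abs(obs - mp[1]))
    return best_model, obs - best_pred


def apply_selector(
    predictions: pd.DataFrame,
    selector: str = "xor",
    rule: DecisionRule | None = None,
) -> pd.DataFrame:
    """Append ``selected_model`` / ``logs0_selected`` columns to a prediction table.

    ``selector`` is one of ``xor``, ``recommended``, or a fixed model name
    (``consensus``, ``gse``, ``absolv``, ``gsephib``).
    """
    fixed = {
        "consensus": ModelName.CONSENSUS,
        "gse": ModelName.GSE_CLASSIC,
        "absolv": ModelName.ABSOLV_GRP,
        "gsephib": ModelName.GSE_PHIB,
    }
    out = predictions.copy()
    if selector in fixed:
        models = [fixed[selector]] * len(out)
    elif selector == "xor":
        models = [xor_select(phi, rule) for phi in out["phi"]]
    elif selector == "recommended":
        models = [
            recommended_select(phi) if np.isfinite(phi) else ModelName.CONSENSUS
            for phi in out["phi"]
        ]
    else:
        raise ValueError(f"unknown selector {selector!r}")
    out["selected_model"] = [m.value for m in models]
    out["logs0_selected"] = [
        out.at[i, model_column(m)] for i, m in zip(out.index, models)
    ]
    return out
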