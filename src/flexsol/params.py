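"""Model parameter containers and the published default coefficient sets.

The package ships three coefficient sets as builtins:

* the classic General Solubility Equation constants (0.5, -1.0, -0.01);
* the grouped ABSOLV table — one row of a0..a6 coefficients for each of six
  compound groups (acids, bases, zwitterions, neutrals, big, quaternaries),
  where the linear form is
  ``log S0 = a0 + a1*A + a2*B + a3*S_pi + a4*E + a5*V + a6*A*B``;
* the flexible-acceptor GSE(Phi,B) b-parameters defining the three
  coefficient functions of ``x = Phi + B``::

      c0(x) = b0 + b1 * exp(-b2 * x)
      c1(x) = b3 + b4 * (1 - exp(-b5 * x))
      c2(x) = b6 + b7 * x

plus the default Phi-binned model-selection rule used by the XOR decision
tree.  All defaults are stored to exactly their published precision.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import ConfigError


class ModelName(str, enum.Enum):
    """The prediction models the package can evaluate or select between."""

    GSE_CLASSIC = "gse_classic"
    ABSOLV_GRP = "absolv_grp"
    GSE_PHIB = "gse_phib"
    CONSENSUS = "consensus"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ChargeGroup(str, enum.Enum):
    """Compound grouping used by the grouped ABSOLV model."""

    ACID = "acid"
    BASE = "base"
    ZWITTERION = "zwitterion"
    NEUTRAL = "neutral"
    BIG = "big"
    QUATERNARY = "quaternary"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class LinearGseParams:
    """Constants of a linear GSE variant: ``c0 + c1*clogP + c2*(mp - 25)``."""

    c0: float
    c1: float
    c2: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ConfigError(f"LinearGseParams.{f.name} must be finite, got {v!r}")


@dataclass(frozen=True)
class AbsolvCoefficients:
    """One group's a0..a6 row of the grouped ABSOLV equation."""

    a0: float
    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    a6: float

    def as_array(self) -> tuple[float, ...]:
        return (self.a0, self.a1, self.a2, self.a3, self.a4, self.a5, self.a6)


@dataclass(frozen=True)
class AbsolvGroupTable:
    """Grouped ABSOLV coefficients keyed by :class:`ChargeGroup`.

    Exactly six groups must be present.
    """

    groups: dict[ChargeGroup, AbsolvCoefficients]

    def __post_init__(self) -> None:
        missing = [g.value for g in ChargeGroup if g not in self.groups]
        if missing:
            raise ConfigError(f"ABSOLV group table missing groups: {missing}")

    def __getitem__(self, group: ChargeGroup) -> AbsolvCoefficients:
        return self.groups[ChargeGroup(group)]


@dataclass(frozen=True)
class FlexAcceptorParams:
    """The eight b-parameters of the flexible-acceptor coefficient functions.

    ``b2`` and ``b5`` are exponential decay rates and must be positive.
    """

    b0: float
    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    b6: float
    b7: float

    def __post_init__(self) -> None:
        if not self.b2 > 0:
            raise ConfigError(f"FlexAcceptorParams.b2 must be > 0, got {self.b2!r}")
        if not self.b5 > 0:
            raise ConfigError(f"FlexAcceptorParams.b5 must be > 0, got {self.b5!r}")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.b0, self.b1, self.b2, self.b3, self.b4, self.b5, self.b6, self.b7)


@dataclass(frozen=True)
class DecisionInterval:
    """Half-open flexibility interval ``[phi_lower, phi_upper)`` -> model."""

    phi_lower: float
    phi_upper: float
    model: ModelName


@dataclass(frozen=True)
class DecisionRule:
    """Ordered list of half-open Phi intervals partitioning ``[0, inf)``."""

    intervals: tuple[DecisionInterval, ...]

    def __post_init__(self) -> None:
        ivals = self.intervals
        if not ivals:
            raise ConfigError("DecisionRule needs at least one interval")
        if ivals[0].phi_lower != 0.0:
            raise ConfigError("DecisionRule must start at phi = 0")
        if not math.isinf(ivals[-1].phi_upper):
            raise ConfigError("DecisionRule must extend to phi = inf")
        for a, b in zip(ivals, ivals[1:]):
            if a.phi_upper != b.phi_lower:
                raise ConfigError(
                    f"DecisionRule gap/overlap at phi = {a.phi_upper} vs {b.phi_lower}"
                )

    def lookup(self, phi: float) -> ModelName:
        if not phi >= 0:
            raise ConfigError(f"phi must be >= 0, got {phi!r}")
        for iv in self.intervals:
            if iv.phi_lower <= phi < iv.phi_upper:
                return iv.model
        raise AssertionError("unreachable: intervals partition [0, inf)")


# --------------------------------------------------------------------------
# Published defaults
# --------------------------------------------------------------------------

#: Classic GSE constants; the melting term is per (mp - 25) in degrees C.
CLASSIC_GSE = LinearGseParams(c0=0.5, c1=-1.0, c2=-0.01)

#: Grouped ABSOLV coefficients (a0..a6 per group).
DEFAULT_ABSOLV_TABLE = AbsolvGroupTable(
    groups={
        ChargeGroup.ACID: AbsolvCoefficients(-0.30, 0.26, 1.07, 0.04, -0.91, -1.80, 0.43),
        ChargeGroup.BASE: AbsolvCoefficients(-0.39, -0.61, 1.95, 0.25, -1.67, -1.37, 0.09),
        ChargeGroup.ZWITTERION: AbsolvCoefficients(1.52, -1.44, 0.88, -0.23, -1.02, -1.08, 0.38),
        ChargeGroup.NEUTRAL: AbsolvCoefficients(-0.45, -0.18, 1.73, 0.10, -1.48, -1.36, 0.26),
        ChargeGroup.BIG: AbsolvCoefficients(-3.76, 0.72, 0.61, -0.03, -0.47, -0.38, -0.02),
        ChargeGroup.QUATERNARY: AbsolvCoefficients(0.53, -1.23, 0.74, -0.04, -0.62, -0.49, 0.09),
    }
)

#: Flexible-acceptor GSE(Phi,B) b-parameters.
DEFAULT_FLEX_PARAMS = FlexAcceptorParams(
    b0=-4.456, b1=6.049, b2=0.0817,
    b3=-1.326, b4=1.058, b5=0.1226,
    b6=-0.941, b7=0.0389,
)

#: Crossover below which the rigid-molecule regime starts (classic GSE wins).
PHI_RIGID_CROSSOVER = 1.66
#: Crossover above which the flexible regime starts (GSE(Phi,B) wins).
PHI_FLEXIBLE_CROSSOVER = 10.83
#: Threshold of the simplified published recommendation (consensus below).
PHI_RECOMMENDED_THRESHOLD = 11.0

#: Published per-bin model-selection profile: (bin-average Phi, n, RMSE of
#: classic GSE, RMSE of grouped ABSOLV, RMSE of GSE(Phi,B), best model).
#: Rows above the flexible crossover have no listed winner; GSE(Phi,B)
#: applies there by the crossover rule.
DEFAULT_BIN_PROFILE: tuple[tuple[float, int, float, float, float, ModelName | None], ...] = (
    (1.0, 182, 1.42, 1.57, 1.50, ModelName.GSE_CLASSIC),
    (2.0, 1882, 1.03, 0.987, 0.990, ModelName.ABSOLV_GRP),
    (3.0, 1245, 1.11, 0.99, 1.03, ModelName.ABSOLV_GRP),
    (4.0, 1928, 1.06, 1.00, 0.95, ModelName.GSE_PHIB),
    (5.0, 539, 1.37, 1.04, 1.17, ModelName.ABSOLV_GRP),
    (6.0, 953, 1.45, 1.24, 1.14, ModelName.GSE_PHIB),
    (7.0, 122, 1.49, 1.40, 1.19, ModelName.GSE_PHIB),
    (7.4, 100, 1.50, 1.12, 1.23, ModelName.ABSOLV_GRP),
    (7.8, 100, 1.68, 1.50, 1.26, ModelName.GSE_PHIB),
    (8.3, 100, 2.10, 1.37, 1.68, ModelName.ABSOLV_GRP),
    (9.0, 100, 2.09, 1.60, 1.53, ModelName.GSE_PHIB),
    (9.9, 75, 2.36, 1.29, 1.71, ModelName.ABSOLV_GRP),
    (11.0, 75, 1.75, 1.22, 1.15, ModelName.GSE_PHIB),
    (12.7, 75, 2.12, 1.88, 1.64, None),
    (14.6, 50, 1.04, 1.22, 0.93, None),
    (15.7, 50, 1.12, 1.28, 0.91, None),
    (18.1, 50, 1.82, 0.93, 0.85, None),
    (23.6, 25, 2.55, 2.30, 1.01, None),
    (31.2, 17, 5.42, 1.69, 1.53, None),
)


def default_decision_rule() -> DecisionRule:
    """Build the XOR decision rule from the published bin profile.

    The rigid domain ``[0, 1.66)`` maps to the classic GSE and the flexible
    domain ``[10.83, inf)`` to GSE(Phi,B).  In between, interval edges are
    placed at midpoints between consecutive bin-average Phi values and each
    interval inherits its bin's winning model.
    """
    centers = [
        (phi, best)
        for phi, _n, _a, _b, _c, best in DEFAULT_BIN_PROFILE
        if best in (ModelName.ABSOLV_GRP, ModelName.GSE_PHIB)
        and PHI_RIGID_CROSSOVER <= phi <= PHI_FLEXIBLE_CROSSOVER
    ]
    intervals = [DecisionInterval(0.0, PHI_RIGID_CROSSOVER, ModelName.GSE_CLASSIC)]
    lower = PHI_RIGID_CROSSOVER
    for (phi, best), nxt in zip(centers, centers[1:] + [None]):
        upper = PHI_FLEXIBLE_CROSSOVER if nxt is None else (phi + nxt[0]) / 2.0
        intervals.append(DecisionInterval(lower, upper, best))
        lower = upper
    intervals.append(DecisionInterval(PHI_FLEXIBLE_CROSSOVER, math.inf, ModelName.GSE_PHIB))
    return DecisionRule(intervals=tuple(intervals))


# --------------------------------------------------------------------------
# Parameter bundle (JSON serializable)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterBundle:
    """All coefficient sets a prediction run needs, JSON round-trippable."""

    linear_gse: LinearGseParams
    absolv_table: AbsolvGroupTable
    flex_params: FlexAcceptorParams
    decision_rule: DecisionRule
    provenance: str = "builtin published coefficients"

    def to_dict(self) -> dict:
        return {
            "linear_gse": dataclasses.asdict(self.linear_gse),
            "absolv_table": {
                g.value: list(c.as_array()) for g, c in self.absolv_table.groups.items()
            },
            "flex_params": dataclasses.asdict(self.flex_params),
            "decision_rule": [
                [iv.phi_lower, "inf" if math.isinf(iv.phi_upper) else iv.phi_upper, iv.model.value]
                for iv in self.decision_rule.intervals
            ],
            "provenance": self.provenance,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def builtin_bundle() -> ParameterBundle:
    """The published default coefficients as a bundle."""
    return ParameterBundle(
        linear_gse=CLASSIC_GSE,
        absolv_table=DEFAULT_ABSOLV_TABLE,
        flex_params=DEFAULT_FLEX_PARAMS,
        decision_rule=default_decision_rule(),
    )


def _bundle_from_dict(d: dict) -> ParameterBundle:
    base = builtin_bundle()
    try:
        linear = (
            LinearGseParams(**d["linear_gse"]) if "linear_gse" in d else base.linear_gse
        )
        if "absolv_table" in d:
            table = AbsolvGroupTable(
                groups={
                    ChargeGroup(g): AbsolvCoefficients(*map(float, row))
                    for g, row in d["absolv_table"].items()
                }
            )
        else:
            table = base.absolv_table
        flex = (
            FlexAcceptorParams(**d["flex_params"]) if "flex_params" in d else base.flex_params
        )
        if "decision_rule" in d:
            rule = DecisionRule(
                intervals=tuple(
                    DecisionInterval(
                        float(lo),
                        math.inf if hi in ("inf", None) else float(hi),
                        ModelName(m),
                    )
                    for lo, hi, m in d["decision_rule"]
                )
            )
        else:
            rule = base.decision_rule
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed parameter bundle: {exc}") from exc
    return ParameterBundle(
        linear_gse=linear,
        absolv_table=table,
        flex_params=flex,
        decision_rule=rule,
        provenance=d.get("provenance", "user parameter file"),
    )


def load_bundle(path: str | Path | None = "builtin") -> ParameterBundle:
    """Load a parameter bundle from a JSON file, or the builtin defaults.

    Sections absent from the file fall back to the builtins.  Malformed
    JSON or invariant violations raise :class:`ConfigError`.
    """
    if path is None or path == "builtin":
        return builtin_bundle()
    p = Path(path)
    try:
        d = json.loads(p.read_text())
    except OSError as exc:
        raise ConfigError(f"cannot read parameter file {p}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ConfigError(f"parameter file {p} is not valid JSON: {exc}") from exc
    if not isinstance(d, dict):
        raise ConfigError(f"parameter file {p} must contain a JSON object")
    return _bundle_from_dict(d)
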