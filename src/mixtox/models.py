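"""Quantal dose-response model families and benchmark-response inversion.

Eight families in the standard U.S. EPA BMDS quantal parameterizations:
logistic, probit, log-logistic, log-probit, gamma, weibull, two-stage
multistage, and quantal linear.  Each family maps a concentration ``d``
(µM) to an expected affected fraction ``p(d)`` in [0, 1] and supports
inversion at a benchmark response (BMR) on the extra-risk scale

    extra_risk(d) = (p(d) - p(0)) / (1 - p(0)),

so the benchmark concentration BMC_q solves extra_risk(d) = q.  Continuous
endpoints expressed as fraction-of-control are handled upstream by
converting to an effect fraction, which makes relative deviation from the
control mean coincide with extra risk (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "FAMILY_NAMES",
    "ModelFamily",
    "ParameterVector",
    "BenchmarkResponse",
    "ConstraintError",
    "NotEstimableError",
    "get_family",
    "all_families",
    "evaluate",
    "extra_risk",
    "inverse_at_benchmark",
]

FAMILY_NAMES = (
    "logistic",
    "probit",
    "log_logistic",
    "log_probit",
    "gamma",
    "weibull",
    "multistage2",
    "quantal_linear",
)

# shape/slope caps follow the BMDS convention of 18 for power parameters
_SHAPE_MAX = 18.0
_SLOPE_MAX = 1.0e6
_LOC_MAX = 200.0
_G_MAX = 1.0 - 1e-8


class ConstraintError(ValueError):
    """A parameter vector violates its family's bounds."""


class NotEstimableError(ValueError):
    """The requested benchmark response cannot be reached by the curve."""


@dataclass(frozen=True)
class ModelFamily:
    """One dose-response family: names, parameter order and box bounds."""

    name: str
    parameter_names: tuple[str, ...]
    parameter_bounds: tuple[tuple[float, float], ...]
    uses_log_dose: bool = False
    has_background: bool = True

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)


def _bg_bounds() -> tuple[float, float]:
    return (0.0, _G_MAX)


def _build_families(restricted: bool) -> dict[str, ModelFamily]:
    shape_lo = 1.0 if restricted else 1e-6
    logslope_lo = 1.0 if restricted else 1e-6
    return {
        "logistic": ModelFamily(
            "logistic", ("a", "b"),
            ((-_LOC_MAX, _LOC_MAX), (0.0, _SLOPE_MAX)),
            has_background=False,
        ),
        "probit": ModelFamily(
            "probit", ("a", "b"),
            ((-_LOC_MAX, _LOC_MAX), (0.0, _SLOPE_MAX)),
            has_background=False,
        ),
        "log_logistic": ModelFamily(
            "log_logistic", ("g", "a", "b"),
            (_bg_bounds(), (-_LOC_MAX, _LOC_MAX), (logslope_lo, _SHAPE_MAX)),
            uses_log_dose=True,
        ),
        "log_probit": ModelFamily(
            "log_probit", ("g", "a", "b"),
            (_bg_bounds(), (-_LOC_MAX, _LOC_MAX), (logslope_lo, _SHAPE_MAX)),
            uses_log_dose=True,
        ),
        "gamma": ModelFamily(
            "gamma", ("g", "a", "b"),
            (_bg_bounds(), (shape_lo, _SHAPE_MAX), (0.0, _SLOPE_MAX)),
        ),
        "weibull": ModelFamily(
            "weibull", ("g", "a", "b"),
            (_bg_bounds(), (shape_lo, _SHAPE_MAX), (0.0, _SLOPE_MAX)),
        ),
        "multistage2": ModelFamily(
            "multistage2", ("g", "b1", "b2"),
            (_bg_bounds(), (0.0, _SLOPE_MAX), (0.0, _SLOPE_MAX)),
        ),
        "quantal_linear": ModelFamily(
            "quantal_linear", ("g", "b"),
            (_bg_bounds(), (0.0, _SLOPE_MAX)),
        ),
    }


_RESTRICTED = _build_families(restricted=True)
_UNRESTRICTED = _build_families(restricted=False)


def get_family(name: str, restricted: bool = True) -> ModelFamily:
    """Look up a family by its lowercase name.

    ``restricted=True`` (default) constrains weibull/gamma shape and
    log-family slope to >= 1, preventing supralinear low-dose curvature.
    """
    table = _RESTRICTED if restricted else _UNRESTRICTED
    try:
        return table[name]
    except KeyError:
        raise KeyError(
            f"unknown model family {name!r}; choose from {FAMILY_NAMES}"
        ) from None


def all_families(restricted: bool = True) -> tuple[ModelFamily, ...]:
    table = _RESTRICTED if restricted else _UNRESTRICTED
    return tuple(table[n] for n in FAMILY_NAMES)


@dataclass(frozen=True)
class ParameterVector:
    """Ordered parameter values for one family, validated against bounds."""

    family: ModelFamily
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != self.family.n_params:
            raise ConstraintError(
                f"{self.family.name} expects {self.family.n_params} "
                f"parameters, got {len(self.values)}"
            )
        for name, v, (lo, hi) in zip(
            self.family.parameter_names, self.values, self.family.parameter_bounds
        ):
            if not (lo <= v <= hi) or not math.isfinite(v):
                raise ConstraintError(
                    f"{self.family.name} parameter {name}={v} outside [{lo}, {hi}]"
                )
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.family.parameter_names, self.values))


@dataclass(frozen=True)
class BenchmarkResponse:
    """Benchmark response level and the risk scale it is defined on.

    ``extra_risk`` is the quantal convention; ``relative_deviation`` is the
    continuous convention (fractional change from the control mean), which
    this package maps onto extra risk of the effect-fraction curve.
    """

    bmr: float
    risk_type: str = "extra_risk"

    def __post_init__(self) -> None:
        if not 0.0 < self.bmr < 1.0:
            raise ValueError(f"bmr must lie in (0, 1), got {self.bmr}")
        if self.risk_type not in ("extra_risk", "relative_deviation"):
            raise ValueError(f"unknown risk_type {self.risk_type!r}")


# ---------------------------------------------------------------------------
# forward evaluation


def _eval_family(name: str, v: tuple[float, ...], d: np.ndarray) -> np.ndarray:
    if name == "logistic":
        a, b = v
        return special.expit(a + b * d)
    if name == "probit":
        a, b = v
        return special.ndtr(a + b * d)
    if name == "quantal_linear":
        g, b = v
        return g + (1.0 - g) * (-np.expm1(-b * d))
    if name == "weibull":
        g, a, b = v
        return g + (1.0 - g) * (-np.expm1(-b * np.power(d, a)))
    if name == "multistage2":
        g, b1, b2 = v
        return g + (1.0 - g) * (-np.expm1(-(b1 * d + b2 * d * d)))
    if name == "gamma":
        g, a, b = v
        return g + (1.0 - g) * special.gammainc(a, b * d)
    if name in ("log_logistic", "log_probit"):
        g, a, b = v
        out = np.full_like(d, g, dtype=float)
        pos = d > 0.0
        z = a + b * np.log(d[pos])
        tail = special.expit(z) if name == "log_logistic" else special.ndtr(z)
        out[pos] = g + (1.0 - g) * tail
        return out
    raise KeyError(name)


def evaluate(params: ParameterVector, concentration) -> np.ndarray | float:
    """Expected response fraction p(d) for concentrations ``d`` >= 0 (µM)."""
    d = np.asarray(concentration, dtype=float)
    if np.any(d < 0.0):
        raise ValueError("concentrations must be non-negative")
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    p = np.clip(_eval_family(params.family.name, params.values, d), 0.0, 1.0)
    return float(p[0]) if scalar else p


def background(params: ParameterVector) -> float:
    """p(0): the modeled response at zero concentration."""
    return float(evaluate(params, 0.0))


def extra_risk(params: ParameterVector, concentration) -> np.ndarray | float:
    """(p(d) - p(0)) / (1 - p(0)): background-corrected response scale."""
    p0 = background(params)
    p = evaluate(params, concentration)
    return (p - p0) / (1.0 - p0)


# ---------------------------------------------------------------------------
# benchmark inversion

_TOL = 1e-10  # absolute response tolerance for numeric root refinement


def _target_probability(params: ParameterVector, bmr: float) -> float:
    p0 = background(params)
    return p0 + bmr * (1.0 - p0)


def _invert_closed_form(params: ParameterVector, bmr: float) -> float | None:
    """Closed-form BMC where the family admits one; None if degenerate."""
    name = params.family.name
    v = params.values
    if name == "quantal_linear":
        g, b = v
        return -math.log1p(-bmr) / b if b > 0 else None
    if name == "weibull":
        g, a, b = v
        return (-math.log1p(-bmr) / b) ** (1.0 / a) if b > 0 else None
    if name == "multistage2":
        g, b1, b2 = v
        c = math.log1p(-bmr)  # solve b2 d^2 + b1 d + c = 0, c < 0
        if b2 > 0:
            return (-b1 + math.sqrt(b1 * b1 - 4.0 * b2 * c)) / (2.0 * b2)
        return -c / b1 if b1 > 0 else None
    if name == "gamma":
        g, a, b = v
        return float(special.gammaincinv(a, bmr)) / b if b > 0 else None
    if name == "log_logistic":
        g, a, b = v
        return math.exp((special.logit(bmr) - a) / b)
    if name == "log_probit":
        g, a, b = v
        return math.exp((special.ndtri(bmr) - a) / b)
    if name in ("logistic", "probit"):
        a, b = v
        if b <= 0:
            return None
        target = _target_probability(params, bmr)
        if target >= 1.0:
            return None
        z = special.logit(target) if name == "logistic" else special.ndtri(target)
        return (float(z) - a) / b
    raise KeyError(name)


def inverse_at_benchmark(params: ParameterVector, br: BenchmarkResponse) -> float:
    """Benchmark concentration: the unique d with extra_risk(d) = br.bmr.

    Raises :class:`NotEstimableError` when the curve cannot reach the
    benchmark (zero slope, or asymptote below the target).  The returned
    concentration satisfies |extra_risk(d) - bmr| < 1e-8.
    """
    bmr = br.bmr
    d = _invert_closed_form(params, bmr)
    if d is None or not math.isfinite(d) or d <= 0.0:
        raise NotEstimableError(
            f"BMR {bmr} not attainable for {params.family.name} "
            f"with parameters {params.values}"
        )
    # refine numerically if the closed form drifted (guards extreme scales)
    resid = float(extra_risk(params, d)) - bmr
    if abs(resid) > _TOL:
        f = lambda x: float(extra_risk(params, x)) - bmr
        lo, hi = d, d
        while f(lo) > 0 and lo > 1e-300:
            lo /= 2.0
        while f(hi) < 0 and hi < 1e300:
            hi *= 2.0
        d = float(optimize.brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16))
    return d
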