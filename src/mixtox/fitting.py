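"""Maximum-likelihood curve fitting, adequacy assessment and BMC estimation.

For each concentration-response table all eight model families are fit by
bounded maximum likelihood from a deterministic multi-start grid.  A fit is
adequate when it converged off the no-response boundary, its Pearson
goodness-of-fit p-value is >= 0.10 (EPA BMDS quantal default), and the
benchmark concentration it implies falls inside (0, 10 x top tested
concentration].  The adequate fit with the lowest AIC is selected and
inverted at each requested benchmark response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .models import (
    BenchmarkResponse,
    ModelFamily,
    NotEstimableError,
    ParameterVector,
    all_families,
    evaluate,
    get_family,
    inverse_at_benchmark,
)

__all__ = [
    "ConcentrationResponseTable",
    "FitResult",
    "BMCEstimate",
    "InsufficientDataError",
    "fit_family",
    "fit_all_families",
    "assess_adequacy",
    "select_best",
    "estimate_bmc",
    "GOF_P_THRESHOLD",
    "BMC_RANGE_FACTOR",
]

GOF_P_THRESHOLD = 0.10
BMC_RANGE_FACTOR = 10.0  # BMC estimable within (0, 10 x top concentration]
TREND_ALPHA = 0.05
_AIC_TIE = 0.01


class InsufficientDataError(ValueError):
    """Fewer distinct concentrations than the fit requires."""


@dataclass(frozen=True)
class ConcentrationResponseTable:
    """One chemical x endpoint concentration-response data set.

    Quantal tables carry per-concentration (n_tested, n_affected) counts;
    continuous tables carry replicate responses expressed as fraction of
    the vehicle-control mean.  Exactly one zero-concentration (vehicle
    control) row is required and concentrations must be unique.
    """

    chemical_id: str
    endpoint: str
    kind: str  # "quantal" | "continuous"
    concentrations: tuple[float, ...]
    n_tested: tuple[int, ...] | None = None
    n_affected: tuple[int, ...] | None = None
    responses: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if self.kind not in ("quantal", "continuous"):
            raise ValueError(f"kind must be quantal or continuous, got {self.kind}")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if int(np.sum(conc == 0.0)) != 1:
            raise ValueError("exactly one zero-concentration control row required")
        order = np.argsort(conc)
        conc = conc[order]
        if np.any(np.diff(conc) <= 0):
            raise ValueError("duplicate concentrations; aggregate before building")
        object.__setattr__(self, "concentrations", tuple(conc))
        if self.kind == "quantal":
            if self.n_tested is None or self.n_affected is None:
                raise ValueError("quantal tables need n_tested and n_affected")
            nt = np.asarray(self.n_tested)[order]
            na = np.asarray(self.n_affected)[order]
            if np.any(nt <= 0):
                raise ValueError("n_tested must be positive")
            if np.any((na < 0) | (na > nt)):
                raise ValueError("need 0 <= n_affected <= n_tested")
            object.__setattr__(self, "n_tested", tuple(int(x) for x in nt))
            object.__setattr__(self, "n_affected", tuple(int(x) for x in na))
        else:
            if self.responses is None:
                raise ValueError("continuous tables need replicate responses")
            if len(self.responses) != len(conc):
                raise ValueError("one replicate tuple per concentration required")
            reps = tuple(tuple(float(x) for x in self.responses[i]) for i in order)
            if any(len(r) == 0 for r in reps):
                raise ValueError("every concentration needs >= 1 replicate")
            object.__setattr__(self, "responses", reps)

    @property
    def n_groups(self) -> int:
        return len(self.concentrations)

    @property
    def top_concentration(self) -> float:
        return self.concentrations[-1]

    def observed_fractions(self) -> np.ndarray:
        """Per-concentration affected fraction (quantal) or mean effect
        fraction 1 - response (continuous)."""
        if self.kind == "quantal":
            return np.asarray(self.n_affected) / np.asarray(self.n_tested)
        return np.array([1.0 - float(np.mean(r)) for r in self.responses])

    def group_sizes(self) -> np.ndarray:
        if self.kind == "quantal":
            return np.asarray(self.n_tested, dtype=float)
        return np.array([float(len(r)) for r in self.responses])


@dataclass(frozen=True)
class FitResult:
    """One family's maximum-likelihood fit with diagnostics."""

    family: ModelFamily
    params: ParameterVector
    log_likelihood: float
    aic: float
    gof_statistic: float
    gof_pvalue: float
    adequate: bool
    convergence_flag: str  # converged | boundary | failed
    bmc50: float = math.nan  # extra-risk-0.5 inversion used for selection ties

    def bmc(self, bmr: float, risk_type: str = "extra_risk") -> float:
        """Benchmark concentration at ``bmr``; NaN when not estimable."""
        try:
            return inverse_at_benchmark(self.params, BenchmarkResponse(bmr, risk_type))
        except NotEstimableError:
            return math.nan


@dataclass(frozen=True)
class BMCEstimate:
    """Benchmark concentration read off the selected best-fit model."""

    chemical_id: str
    endpoint: str
    bmr: BenchmarkResponse
    bmc: float  # µM; NaN when not estimable
    family_used: str | None

    @property
    def estimable(self) -> bool:
        return math.isfinite(self.bmc)


# ---------------------------------------------------------------------------
# likelihoods


def _nll_quantal(table: ConcentrationResponseTable, pv: ParameterVector) -> float:
    p = np.clip(evaluate(pv, np.asarray(table.concentrations)), 1e-12, 1 - 1e-12)
    y = np.asarray(table.n_affected, dtype=float)
    n = np.asarray(table.n_tested, dtype=float)
    return -float(np.sum(y * np.log(p) + (n - y) * np.log1p(-p)))


def _nll_continuous(table: ConcentrationResponseTable, pv: ParameterVector) -> float:
    # Gaussian with constant variance profiled out of the likelihood
    mu = evaluate(pv, np.asarray(table.concentrations))
    ssr = 0.0
    n_total = 0
    for m, reps in zip(mu, table.responses):
        e = 1.0 - np.asarray(reps)
        ssr += float(np.sum((e - m) ** 2))
        n_total += len(reps)
    sigma2 = max(ssr / n_total, 1e-12)
    return 0.5 * n_total * (math.log(2.0 * math.pi * sigma2) + 1.0)


def negative_log_likelihood(
    table: ConcentrationResponseTable, pv: ParameterVector
) -> float:
    if table.kind == "quantal":
        return _nll_quantal(table, pv)
    return _nll_continuous(table, pv)


def has_dose_response_trend(
    table: ConcentrationResponseTable, alpha: float = TREND_ALPHA
) -> bool:
    """Data-adequacy pre-test: is there a monotone concentration trend?

    Quantal tables use the one-sided Cochran-Armitage trend z-test with the
    tested concentrations as scores; continuous tables use a one-sided
    Spearman correlation of effect fraction against concentration.  Flat
    tables fail this test, which keeps steep curves from being fit just
    beyond the tested range and reported as spuriously estimable BMCs.
    """
    d = np.asarray(table.concentrations)
    if table.kind == "quantal":
        y = np.asarray(table.n_affected, dtype=float)
        n = np.asarray(table.n_tested, dtype=float)
        n_total = n.sum()
        pbar = y.sum() / n_total
        if pbar <= 0.0 or pbar >= 1.0:
            return False
        num = float(np.sum(d * (y - n * pbar)))
        var = pbar * (1 - pbar) * (
            float(np.sum(n * d * d)) - float(np.sum(n * d)) ** 2 / n_total)
        if var <= 0:
            return False
        p = float(stats.norm.sf(num / math.sqrt(var)))
    else:
        conc_long, eff_long = [], []
        for c, reps in zip(d, table.responses):
            for r in reps:
                conc_long.append(c)
                eff_long.append(1.0 - r)
        if np.std(eff_long) == 0:
            return False
        p = float(stats.spearmanr(conc_long, eff_long,
                                  alternative="greater")[1])
    return p < alpha


# ---------------------------------------------------------------------------
# deterministic multi-start


def _start_points(family: ModelFamily, table: ConcentrationResponseTable) -> list[np.ndarray]:
    """Fixed, data-informed start grid: no randomness, so refits are
    bit-identical."""
    frac = table.observed_fractions()
    conc = np.asarray(table.concentrations)
    g0 = float(np.clip(frac[0], 1e-3, 0.90))
    top = table.top_concentration
    pos = conc[conc > 0]
    mid = float(np.median(pos))
    # characteristic concentration scales spanning the tested grid
    scales = [top / 30.0, top / 10.0, top / 3.0, top, 3.0 * top]
    starts: list[np.ndarray] = []
    name = family.name
    if name in ("logistic", "probit"):
        for s in scales:
            b = 1.0 / s
            for a in (-4.0, -2.0, -0.5):
                starts.append(np.array([a, b]))
    elif name == "quantal_linear":
        for s in scales:
            starts.append(np.array([g0, math.log(2.0) / s]))
        starts.append(np.array([g0, 0.0]))
    elif name == "multistage2":
        for s in scales:
            b = math.log(2.0) / s
            starts.append(np.array([g0, b, 0.0]))
            starts.append(np.array([g0, 0.0, b / s]))
            starts.append(np.array([g0, b / 2.0, b / (2.0 * s)]))
    elif name in ("weibull", "gamma"):
        for s in scales:
            for a in (1.0, 2.0, 4.0):
                starts.append(np.array([g0, a, math.log(2.0) / s ** (1.0 if name == "gamma" else a)]))
    elif name in ("log_logistic", "log_probit"):
        for s in (mid, top / 3.0, top):
            for b in (1.0, 2.0, 4.0):
                starts.append(np.array([g0, -b * math.log(s), b]))
    else:  # pragma: no cover
        raise KeyError(name)
    lo = np.array([b[0] for b in family.parameter_bounds])
    hi = np.array([b[1] for b in family.parameter_bounds])
    return [np.clip(x, lo, hi) for x in starts]


def _slope_indices(family: ModelFamily) -> list[int]:
    """Indices of parameters whose lower bound means 'no dose response'."""
    return [
        i
        for i, n in enumerate(family.parameter_names)
        if n in ("b", "b1", "b2") and family.parameter_bounds[i][0] == 0.0
    ]


def fit_family(
    table: ConcentrationResponseTable,
    family: ModelFamily | str,
    restricted: bool = True,
) -> FitResult:
    """Fit one family by bounded maximum likelihood.

    Raises :class:`InsufficientDataError` below 4 distinct concentrations.
    The convergence flag is ``boundary`` when every dose-effect (slope)
    parameter sits at its zero lower bound, i.e. the fitted curve is flat.
    """
    if isinstance(family, str):
        family = get_family(family, restricted=restricted)
    if table.n_groups < 4:
        raise InsufficientDataError(
            f"{table.chemical_id}/{table.endpoint}: need >= 4 concentrations, "
            f"got {table.n_groups}"
        )
    bounds = list(family.parameter_bounds)

    def objective(x: np.ndarray) -> float:
        pv = ParameterVector(family, tuple(x))
        return negative_log_likelihood(table, pv)

    best_x, best_nll, any_ok = None, math.inf, False
    for x0 in _start_points(family, table):
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
        )
        if res.success:
            any_ok = True
        if res.fun < best_nll:
            best_nll, best_x = float(res.fun), np.asarray(res.x)

    if best_x is None or not np.all(np.isfinite(best_x)):
        pv = ParameterVector(family, tuple(np.clip(
            [b[0] if math.isfinite(b[0]) else 0.0 for b in bounds],
            [b[0] for b in bounds], [b[1] for b in bounds])))
        return FitResult(family, pv, -math.inf, math.inf, math.inf, 0.0,
                         False, "failed")

    pv = ParameterVector(family, tuple(best_x))
    slope_idx = _slope_indices(family)
    flat = bool(slope_idx) and all(best_x[i] <= 1e-12 for i in slope_idx)
    if family.name in ("logistic", "probit") and best_x[1] <= 1e-12:
        flat = True
    flag = "failed" if not any_ok else ("boundary" if flat else "converged")

    log_lik = -best_nll
    k = family.n_params + (1 if table.kind == "continuous" else 0)
    aic = 2.0 * k - 2.0 * log_lik
    gof_stat, gof_p = _goodness_of_fit(table, pv, family.n_params)

    try:
        bmc50 = inverse_at_benchmark(pv, BenchmarkResponse(0.5))
    except NotEstimableError:
        bmc50 = math.nan
    adequate = (
        flag == "converged"
        and gof_p >= GOF_P_THRESHOLD
        and math.isfinite(bmc50)
        and 0.0 < bmc50 <= BMC_RANGE_FACTOR * table.top_concentration
        and has_dose_response_trend(table)
    )
    return FitResult(family, pv, log_lik, aic, gof_stat, gof_p, adequate, flag, bmc50)


def _goodness_of_fit(
    table: ConcentrationResponseTable, pv: ParameterVector, k_model: int
) -> tuple[float, float]:
    """Pearson chi-square of observed vs fitted group responses.

    df = n_groups - n_model_params; with df <= 0 the test is saturated and
    reported as a pass (statistic still returned).
    """
    conc = np.asarray(table.concentrations)
    p_hat = np.clip(evaluate(pv, conc), 1e-10, 1 - 1e-10)
    if table.kind == "quantal":
        n = np.asarray(table.n_tested, dtype=float)
        y = np.asarray(table.n_affected, dtype=float)
        stat = float(np.sum((y - n * p_hat) ** 2 / (n * p_hat * (1.0 - p_hat))))
    else:
        m = table.group_sizes()
        e_bar = table.observed_fractions()
        # pooled within-group variance; floored so noiseless fixtures don't 0/0
        ssw = sum(
            float(np.sum(((1.0 - np.asarray(r)) - eb) ** 2))
            for r, eb in zip(table.responses, e_bar)
        )
        df_w = int(np.sum(m)) - table.n_groups
        s2 = max(ssw / df_w, 1e-10) if df_w > 0 else 1e-10
        stat = float(np.sum(m * (e_bar - p_hat) ** 2 / s2))
    df = table.n_groups - k_model
    if df <= 0:
        return stat, 1.0
    return stat, float(stats.chi2.sf(stat, df))


def assess_adequacy(fit: FitResult) -> bool:
    """Convergence + GOF p >= 0.10 + estimable BMC inside the allowed range
    (already evaluated during fitting; exposed for inspection)."""
    return fit.adequate


def fit_all_families(
    table: ConcentrationResponseTable, restricted: bool = True
) -> list[FitResult]:
    """Fit every family in the canonical order."""
    return [fit_family(table, fam) for fam in all_families(restricted)]


def select_best(fits: list[FitResult]) -> FitResult | None:
    """Adequate fit with the lowest AIC; AIC ties (delta < 0.01) broken by
    the smaller (more conservative) BMC50.  None when nothing is adequate."""
    if not fits:
        raise ValueError("select_best requires at least one FitResult")
    adequate = [f for f in fits if f.adequate]
    if not adequate:
        return None
    best = min(adequate, key=lambda f: f.aic)
    ties = [f for f in adequate if f.aic - best.aic < _AIC_TIE]
    if len(ties) > 1:
        ties = [f for f in ties if math.isfinite(f.bmc50)]
        if ties:
            best = min(ties, key=lambda f: f.bmc50)
    return best


def estimate_bmc(
    table: ConcentrationResponseTable,
    bmr_levels: tuple[float, ...] = (0.10, 0.50),
    restricted: bool = True,
    risk_type: str = "extra_risk",
) -> list[BMCEstimate]:
    """Full per-chemical workup: fit all families, select, invert each BMR.

    A BMC is reported not-estimable (NaN) when no model is adequate or the
    inversion falls outside (0, 10 x top tested concentration].
    """
    fits = fit_all_families(table, restricted)
    best = select_best(fits)
    out = []
    for bmr in bmr_levels:
        br = BenchmarkResponse(bmr, risk_type)
        if best is None:
            out.append(BMCEstimate(table.chemical_id, table.endpoint, br,
                                   math.nan, None))
            continue
        try:
            bmc = inverse_at_benchmark(best.params, br)
        except NotEstimableError:
            bmc = math.nan
        if not (0.0 < bmc <= BMC_RANGE_FACTOR * table.top_concentration):
            bmc = math.nan
        out.append(BMCEstimate(table.chemical_id, table.endpoint, br, bmc,
                               best.family.name))
    return out
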