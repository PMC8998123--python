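"""Screening statistics for morphology, in vitro endpoints, behavior and
exposure correlations.

Morphology: per-endpoint incidence across plates (n = 36 per concentration
in the standard design), an "any effect" union endpoint, >80%-normal
vehicle-control plate QC, one-sided Fisher's exact tests against control
and the lowest effect level (LEL).

In vitro (NHBE-style plates): vehicle-control normalization, one-way ANOVA
with Dunnett's comparisons to control and Tukey-Kramer all-pairs tests.

Behavior: embryonic (EPR) and larval (LPR) photomotor response decision
rules - per-period subject summaries, Kolmogorov-Smirnov tests against
control with Bonferroni correction, hypo/hyper direction from the median,
a 70%-normal filter for LPR, and the three-consecutive-concentration
bioactivity rule.

Exposure: deployment-time-normalized pairwise Pearson correlations masked
at p < 0.01.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WellObservation",
    "EndpointIncidenceTable",
    "LELResult",
    "MovementSeries",
    "PlateQCResult",
    "NHBEStatsResult",
    "PeriodVerdicts",
    "MORPHOLOGY_ENDPOINTS_24HPF",
    "MORPHOLOGY_ENDPOINTS_120HPF",
    "EPR_PERIODS",
    "LPR_PHASES",
    "plate_qc",
    "incidence_and_any_effect",
    "fisher_lel",
    "nhbe_stats",
    "epr_period_of_second",
    "lpr_cycle_phase_of_bin",
    "behavior_response_test",
    "bioactivity_call",
    "exposure_correlation",
]

# morphology endpoint vocabulary by assessment timepoint
MORPHOLOGY_ENDPOINTS_24HPF = ("mortality", "delayed_progression",
                              "spontaneous_movement")
MORPHOLOGY_ENDPOINTS_120HPF = (
    "mortality", "edemas", "bent_axis", "touch_response", "craniofacial",
    "musc_circ", "lower_trunk", "brain", "skin", "notochord",
)

EPR_PERIODS = ("background", "excitatory", "refractory")
LPR_PHASES = ("light", "dark")

PLATE_QC_NORMAL_FRACTION = 0.80  # strict: pass requires > 80% normal
LPR_NORMAL_FRACTION = 0.70
MIN_BEHAVIOR_SUBJECTS = 5


@dataclass(frozen=True)
class WellObservation:
    """One animal's screening record: flag true = abnormal or dead.

    When mortality is flagged, morphology endpoints that cannot be scored
    post-mortem are treated as not evaluable; the animal still counts as
    affected under "any effect" and "mortality".
    """

    plate_id: str
    well: str
    chemical_id: str
    concentration: float
    timepoint: str  # "24hpf" | "120hpf"
    endpoint_flags: dict[str, bool]

    def is_dead(self) -> bool:
        return bool(self.endpoint_flags.get("mortality", False))

    def any_effect(self) -> bool:
        return any(bool(v) for v in self.endpoint_flags.values())


@dataclass(frozen=True)
class EndpointIncidenceTable:
    """Per-concentration incidence for one chemical x endpoint."""

    chemical_id: str
    endpoint: str
    concentrations: tuple[float, ...]
    n_evaluated: tuple[int, ...]
    n_affected: tuple[int, ...]

    @property
    def percent_incidence(self) -> tuple[float, ...]:
        return tuple(100.0 * a / n if n else math.nan
                     for a, n in zip(self.n_affected, self.n_evaluated))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chemical": self.chemical_id,
            "endpoint": self.endpoint,
            "conc_uM": self.concentrations,
            "n_evaluated": self.n_evaluated,
            "n_affected": self.n_affected,
            "percent_incidence": self.percent_incidence,
        })


@dataclass(frozen=True)
class LELResult:
    """Lowest effect level for one chemical x endpoint with per-concentration
    Fisher p-values (concentration -> p)."""

    chemical_id: str
    endpoint: str
    lel: float | None
    pvalues: dict[float, float]


@dataclass(frozen=True)
class PlateQCResult:
    passed: bool
    normal_fraction: float
    n_control: int


@dataclass(frozen=True)
class MovementSeries:
    """One animal's binned movement trace.

    EPR: per-second movement index over a 50 s window; two 1 s light pulses
    at 30 s and 40 s define background (21-29 s), excitatory (31-39 s) and
    refractory (41-49 s) periods.  LPR: distance integrated per 6 s bin
    over 24 min = four 3 min light / 3 min dark cycles; cycles 1-3 are
    acclimation, cycle 4 is the test period.
    """

    subject_id: str
    chemical_id: str
    concentration: float
    assay: str  # "EPR" | "LPR"
    values: tuple[float, ...]
    excluded: bool = False
    exclusion_reason: str | None = None


@dataclass(frozen=True)
class PeriodVerdicts:
    """Per-period hypo/hyper/normal calls for one treatment group."""

    chemical_id: str
    concentration: float
    assay: str
    verdicts: dict[str, str]  # period -> hypo | hyper | normal | not_evaluable
    pvalues: dict[str, float]

    def is_evaluable(self) -> bool:
        return all(v != "not_evaluable" for v in self.verdicts.values())


# ---------------------------------------------------------------------------
# morphology


def plate_qc(observations: list[WellObservation]) -> PlateQCResult:
    """Vehicle-control QC: pass iff strictly more than 80% of control
    animals are normal (no mortality or malformation) at 120 hpf."""
    controls = [o for o in observations
                if o.concentration == 0.0 and o.timepoint == "120hpf"]
    if not controls:
        raise ValueError("no vehicle-control (concentration 0) wells found")
    normal = sum(1 for o in controls if not o.any_effect())
    frac = normal / len(controls)
    return PlateQCResult(frac > PLATE_QC_NORMAL_FRACTION, frac, len(controls))


def incidence_and_any_effect(
    observations: list[WellObservation],
) -> dict[str, EndpointIncidenceTable]:
    """Per-endpoint incidence tables plus the "any effect" union endpoint.

    "any effect" counts an animal once if at least one flag (mortality
    included) is true.  Dead animals are excluded from the denominator of
    morphology endpoints that cannot be scored post-mortem, but count in
    the mortality and any-effect denominators.
    """
    if not observations:
        raise ValueError("no observations supplied")
    chem = observations[0].chemical_id
    endpoints: list[str] = []
    for o in observations:
        for e in o.endpoint_flags:
            if e not in endpoints:
                endpoints.append(e)
    concs = sorted({o.concentration for o in observations})
    tables: dict[str, EndpointIncidenceTable] = {}
    for ep in endpoints + ["any_effect"]:
        n_eval, n_aff = [], []
        for c in concs:
            group = [o for o in observations if o.concentration == c]
            if ep == "any_effect":
                n_eval.append(len(group))
                n_aff.append(sum(1 for o in group if o.any_effect()))
            elif ep == "mortality":
                n_eval.append(len(group))
                n_aff.append(sum(1 for o in group if o.is_dead()))
            else:
                evaluable = [o for o in group
                             if not o.is_dead() and ep in o.endpoint_flags]
                n_eval.append(len(evaluable))
                n_aff.append(sum(1 for o in evaluable
                                 if o.endpoint_flags[ep]))
        tables[ep] = EndpointIncidenceTable(
            chem, ep, tuple(concs), tuple(n_eval), tuple(n_aff))
    return tables


def fisher_lel(
    table: EndpointIncidenceTable,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> LELResult:
    """One-sided Fisher's exact test of each concentration against the
    zero-concentration control row; LEL = lowest significant concentration.

    ``alternative="greater"`` tests for increased incidence relative to
    control (the directional choice for malformation screening); pass
    ``"two-sided"`` for the symmetric test.
    """
    concs = table.concentrations
    if 0.0 not in concs:
        raise ValueError("control (concentration 0) row required")
    i0 = concs.index(0.0)
    n0, a0 = table.n_evaluated[i0], table.n_affected[i0]
    pvalues: dict[float, float] = {}
    for i, c in enumerate(concs):
        if c == 0.0:
            continue
        n, a = table.n_evaluated[i], table.n_affected[i]
        if n == 0:
            warnings.warn(
                f"{table.chemical_id}/{table.endpoint}: no evaluable animals "
                f"at {c} µM; concentration skipped")
            continue
        ctab = [[a, n - a], [a0, n0 - a0]]
        pvalues[c] = float(stats.fisher_exact(ctab, alternative=alternative)[1])
    significant = [c for c, p in pvalues.items() if p < alpha]
    lel = min(significant) if significant else None
    return LELResult(table.chemical_id, table.endpoint, lel, pvalues)


# ---------------------------------------------------------------------------
# in vitro plate statistics


@dataclass(frozen=True)
class NHBEStatsResult:
    """Vehicle-normalized responses with ANOVA/Dunnett/Tukey-Kramer flags."""

    normalized: dict[str, np.ndarray]  # group -> fraction-of-control values
    anova_pvalue: float
    dunnett_pvalues: dict[str, float]  # non-control group -> p vs control
    dunnett_flags: dict[str, bool]
    tukey_pvalues: dict[tuple[str, str], float]
    tukey_flags: dict[tuple[str, str], bool]


def nhbe_stats(
    responses: dict[str, np.ndarray | list[float]],
    control_key: str,
    alpha: float = 0.05,
) -> NHBEStatsResult:
    """Plate-level treatment statistics for a continuous endpoint.

    Raw well values are normalized to the vehicle-control mean, then
    compared by one-way ANOVA, Dunnett's many-to-one test against control,
    and the Tukey-Kramer all-pairs test, all at the given alpha.
    """
    if control_key not in responses:
        raise ValueError(f"control group {control_key!r} missing")
    if len(responses) < 2:
        raise ValueError("need at least two groups (control + treatment)")
    groups = {k: np.asarray(v, dtype=float) for k, v in responses.items()}
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("every group needs >= 2 replicates")
    ctrl_mean = float(np.mean(groups[control_key]))
    if ctrl_mean == 0:
        raise ValueError("control mean is zero; cannot normalize")
    normalized = {k: v / ctrl_mean for k, v in groups.items()}

    keys = [k for k in normalized if k != control_key]
    arrays = [normalized[k] for k in keys]
    control = normalized[control_key]

    anova_p = float(stats.f_oneway(control, *arrays)[1])
    # fixed quadrature seed: identical inputs give identical p-values
    dres = stats.dunnett(*arrays, control=control, random_state=1234)
    dunnett_p = {k: float(p) for k, p in zip(keys, dres.pvalue)}
    all_keys = [control_key] + keys
    tres = stats.tukey_hsd(*(normalized[k] for k in all_keys))
    tukey_p: dict[tuple[str, str], float] = {}
    for i, ki in enumerate(all_keys):
        for j in range(i + 1, len(all_keys)):
            tukey_p[(ki, all_keys[j])] = float(tres.pvalue[i, j])
    return NHBEStatsResult(
        normalized=normalized,
        anova_pvalue=anova_p,
        dunnett_pvalues=dunnett_p,
        dunnett_flags={k: p < alpha for k, p in dunnett_p.items()},
        tukey_pvalues=tukey_p,
        tukey_flags={k: p < alpha for k, p in tukey_p.items()},
    )


# ---------------------------------------------------------------------------
# behavior


def epr_period_of_second(t: int) -> str | None:
    """Period label for one second of an EPR trace (pulses at 30 s, 40 s):
    background 21-29 s, excitatory 31-39 s, refractory 41-49 s."""
    if 21 <= t <= 29:
        return "background"
    if 31 <= t <= 39:
        return "excitatory"
    if 41 <= t <= 49:
        return "refractory"
    return None


def lpr_cycle_phase_of_bin(b: int) -> tuple[int, str]:
    """(cycle 1-4, phase) for one 6 s bin of a 24 min LPR trace: each cycle
    is 30 light bins then 30 dark bins."""
    if not 0 <= b < 240:
        raise ValueError("LPR bin index must lie in [0, 240)")
    cycle = b // 60 + 1
    phase = "light" if (b % 60) < 30 else "dark"
    return cycle, phase


def _epr_subject_summaries(series: list[MovementSeries]) -> dict[str, np.ndarray]:
    out = {p: [] for p in EPR_PERIODS}
    for s in series:
        vals = np.asarray(s.values, dtype=float)
        for p in EPR_PERIODS:
            idx = [t for t in range(len(vals)) if epr_period_of_second(t) == p]
            out[p].append(float(np.mean(vals[idx])))
    return {p: np.asarray(v) for p, v in out.items()}


def _lpr_subject_summaries(series: list[MovementSeries]) -> dict[str, np.ndarray]:
    # AUC of the distance-time curve in the test cycle, per light/dark phase
    out = {p: [] for p in LPR_PHASES}
    for s in series:
        vals = np.asarray(s.values, dtype=float)
        for p in LPR_PHASES:
            idx = [b for b in range(len(vals))
                   if lpr_cycle_phase_of_bin(b) == (4, p)]
            out[p].append(float(np.sum(vals[idx])))
    return {p: np.asarray(v) for p, v in out.items()}


def behavior_response_test(
    treatment: list[MovementSeries],
    control: list[MovementSeries],
    assay: str,
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> PeriodVerdicts:
    """Per-period hypo/hyper/normal verdict for one treatment group.

    Excluded subjects (dead/delayed for EPR; dead/malformed for LPR) are
    removed first.  LPR treatments additionally require >= 70% normal
    (non-excluded) animals; groups below that, or with fewer than 5
    subjects after exclusion, are not evaluable.  Each period compares the
    per-subject summary distributions by two-sample Kolmogorov-Smirnov at
    a Bonferroni-corrected level alpha / n_comparisons (caller supplies the
    family size, typically concentrations x periods); direction comes from
    the median difference.
    """
    if assay not in ("EPR", "LPR"):
        raise ValueError(f"assay must be EPR or LPR, got {assay!r}")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    periods = EPR_PERIODS if assay == "EPR" else LPR_PHASES
    chem = treatment[0].chemical_id if treatment else "?"
    conc = treatment[0].concentration if treatment else math.nan

    def _not_evaluable() -> PeriodVerdicts:
        return PeriodVerdicts(chem, conc, assay,
                              {p: "not_evaluable" for p in periods},
                              {p: math.nan for p in periods})

    if assay == "LPR" and treatment:
        normal_frac = sum(1 for s in treatment if not s.excluded) / len(treatment)
        if normal_frac < LPR_NORMAL_FRACTION:
            return _not_evaluable()
    treat = [s for s in treatment if not s.excluded]
    ctrl = [s for s in control if not s.excluded]
    if len(treat) < MIN_BEHAVIOR_SUBJECTS or len(ctrl) < MIN_BEHAVIOR_SUBJECTS:
        return _not_evaluable()

    summarize = _epr_subject_summaries if assay == "EPR" else _lpr_subject_summaries
    t_sum, c_sum = summarize(treat), summarize(ctrl)
    corrected_alpha = alpha / n_comparisons
    verdicts, pvalues = {}, {}
    for p in periods:
        ks_p = float(stats.ks_2samp(t_sum[p], c_sum[p], method="auto")[1])
        pvalues[p] = ks_p
        if ks_p < corrected_alpha:
            delta = float(np.median(t_sum[p]) - np.median(c_sum[p]))
            verdicts[p] = "hypo" if delta < 0 else "hyper"
        else:
            verdicts[p] = "normal"
    return PeriodVerdicts(chem, conc, assay, verdicts, pvalues)


def bioactivity_call(verdicts: list[str], min_run: int = 3) -> bool:
    """True iff >= ``min_run`` consecutive concentrations share the same
    non-normal verdict (same direction).  Input is ordered by increasing
    concentration; only supplied verdicts are considered."""
    run, prev = 0, None
    for v in verdicts:
        if v in ("hypo", "hyper") and v == prev:
            run += 1
        elif v in ("hypo", "hyper"):
            run = 1
        else:
            run = 0
        prev = v if v in ("hypo", "hyper") else None
        if run >= min_run:
            return True
    return False


def bioactivity_call_per_period(
    verdict_sequence: list[PeriodVerdicts], min_run: int = 3
) -> bool:
    """Bioactive iff some single period shows the consecutive-concentration
    pattern across the (concentration-ordered) verdict sequence."""
    if not verdict_sequence:
        return False
    periods = verdict_sequence[0].verdicts.keys()
    return any(
        bioactivity_call([pv.verdicts.get(p, "normal")
                          for pv in verdict_sequence], min_run)
        for p in periods
    )


# ---------------------------------------------------------------------------
# exposure correlations


def exposure_correlation(
    matrix: pd.DataFrame,
    deployment_times: np.ndarray | list[float],
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of time-normalized exposure
    concentrations, masked at significance ``alpha``.

    Returns (correlations rounded to 2 dp, p-values, masked correlations
    with cells at p >= alpha set to NaN).  Constant columns yield an
    undefined r and are masked with a warning.
    """
    times = np.asarray(deployment_times, dtype=float)
    if matrix.shape[0] < 3:
        raise ValueError("need >= 3 samples for correlation screening")
    if len(times) != matrix.shape[0]:
        raise ValueError("one deployment time per sample row required")
    if np.any(times <= 0):
        raise ValueError("deployment times must be positive")
    norm = matrix.div(times, axis=0)
    cols = list(norm.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            xi, xj = norm[cols[i]].to_numpy(), norm[cols[j]].to_numpy()
            ok = np.isfinite(xi) & np.isfinite(xj)
            if ok.sum() < 3:
                continue
            if np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0:
                warnings.warn(f"constant column in pair ({cols[i]}, {cols[j]}); "
                              "correlation undefined and masked")
                continue
            rij, pij = stats.pearsonr(xi[ok], xj[ok])
            r[i, j] = r[j, i] = float(rij)
            p[i, j] = p[j, i] = float(pij)
    r_df = pd.DataFrame(np.round(r, 2), index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    masked = r_df.where(p_df < alpha)
    return r_df, p_df, masked
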