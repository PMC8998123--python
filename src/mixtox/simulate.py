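"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its arguments: the same seed gives a
bit-identical output.  The defaults mirror the screening design this
package targets - zebrafish morphology on the standard eight-point
concentration grid with n = 36 animals per concentration (three 12-well
plate replicates), in vitro viability with six replicate wells per
concentration, photomotor traces with the EPR/LPR period structure, and a
wristband-style exposure matrix over 262 samples.

Concentration-addition mixtures are generated exactly: components share
one curve shape and differ only in potency, so the mixture response at
total T with fractions f_i is the reference curve evaluated at the summed
potency-weighted dose T * sum(rho_i * f_i).  A deviation factor k scales
that effective dose by 1/k, pushing the downstream interaction index above
1 (antagonism, k > 1) or below 1 (synergism, k < 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fitting import ConcentrationResponseTable
from .mixtures import MixtureDesign, component_concentrations
from .models import ParameterVector, evaluate, get_family
from .screening import (
    EPR_PERIODS,
    MovementSeries,
    WellObservation,
    epr_period_of_second,
    lpr_cycle_phase_of_bin,
)

__all__ = [
    "ZF_GRID",
    "NHBE_GRID",
    "N_PER_CONCENTRATION",
    "gen_quantal_table",
    "gen_continuous_table",
    "gen_ca_mixture_tables",
    "gen_morphology_wells",
    "gen_movement",
    "gen_exposure_matrix",
]

# standard eight-point zebrafish water-concentration grid (µM)
ZF_GRID = (0.0, 1.0, 2.54, 6.45, 16.4, 35.0, 74.8, 100.0)
# standard in vitro grid (µM), vehicle control plus the tested range
NHBE_GRID = (0.0, 10.0, 25.0, 50.0, 75.0, 100.0, 200.0)
N_PER_CONCENTRATION = 36  # three plate replicates of 12 animals


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_quantal_table(
    seed: int,
    chemical_id: str,
    params: ParameterVector,
    grid: tuple[float, ...] = ZF_GRID,
    n: int = N_PER_CONCENTRATION,
    endpoint: str = "any_effect",
) -> ConcentrationResponseTable:
    """Binomial incidence counts from a known dose-response curve:
    n_affected ~ Binomial(n, p(d)) at each grid concentration."""
    rng = _rng(seed)
    p = np.asarray(evaluate(params, np.asarray(grid)))
    affected = rng.binomial(n, p)
    return ConcentrationResponseTable(
        chemical_id, endpoint, "quantal",
        concentrations=tuple(grid),
        n_tested=tuple(n for _ in grid),
        n_affected=tuple(int(a) for a in affected),
    )


def gen_continuous_table(
    seed: int,
    chemical_id: str,
    params: ParameterVector,
    grid: tuple[float, ...] = NHBE_GRID,
    n_replicates: int = 6,
    noise_sd: float = 0.05,
    endpoint: str = "cell_viability",
) -> ConcentrationResponseTable:
    """Replicate fraction-of-control responses 1 - e(d) + Gaussian noise,
    floored at 0, where e is the effect-fraction curve ``params``."""
    rng = _rng(seed)
    e = np.asarray(evaluate(params, np.asarray(grid)))
    reps = []
    for ei in e:
        vals = np.maximum(0.0, (1.0 - ei) + rng.normal(0.0, noise_sd,
                                                       n_replicates))
        reps.append(tuple(float(v) for v in vals))
    return ConcentrationResponseTable(
        chemical_id, endpoint, "continuous",
        concentrations=tuple(grid), responses=tuple(reps),
    )


def gen_ca_mixture_tables(
    seed: int,
    design: MixtureDesign,
    reference_params: ParameterVector,
    potencies: tuple[float, ...],
    component_grids: dict[str, tuple[float, ...]] | None = None,
    mixture_grid: tuple[float, ...] = ZF_GRID,
    n: int = N_PER_CONCENTRATION,
    interaction_factor: float = 1.0,
    endpoint: str = "any_effect",
) -> dict[str, ConcentrationResponseTable]:
    """Component tables plus a mixture table under exact concentration
    addition (optionally perturbed by ``interaction_factor``).

    Component i responds like the reference curve at dose rho_i * d, i.e.
    all components share the reference shape and differ only in potency
    rho_i (> 1 means more potent than the reference).  The mixture dosed at
    total T therefore responds at effective reference dose
    ``T * sum(rho_i * f_i) / interaction_factor``; with factor 1 the joint
    response obeys concentration addition exactly, so the interaction index
    recovered downstream converges to 1.
    """
    if len(potencies) != design.c:
        raise ValueError("one potency per design component required")
    if any(r <= 0 for r in potencies):
        raise ValueError("potencies must be positive")
    if interaction_factor <= 0:
        raise ValueError("interaction_factor must be positive")
    rng = _rng(seed)
    out: dict[str, ConcentrationResponseTable] = {}
    for (chem, _), rho in zip(design.components, potencies):
        grid = (component_grids or {}).get(chem, mixture_grid)
        p = np.asarray(evaluate(reference_params, rho * np.asarray(grid)))
        affected = rng.binomial(n, p)
        out[chem] = ConcentrationResponseTable(
            chem, endpoint, "quantal",
            concentrations=tuple(grid),
            n_tested=tuple(n for _ in grid),
            n_affected=tuple(int(a) for a in affected),
        )
    fractions = design.fractions()
    eff_rate = sum(r * f for r, f in zip(potencies, fractions))
    eff_dose = np.asarray(mixture_grid) * eff_rate / interaction_factor
    p_mix = np.asarray(evaluate(reference_params, eff_dose))
    affected = rng.binomial(n, p_mix)
    out[design.name] = ConcentrationResponseTable(
        design.name, endpoint, "quantal",
        concentrations=tuple(mixture_grid),
        n_tested=tuple(n for _ in mixture_grid),
        n_affected=tuple(int(a) for a in affected),
    )
    return out


def gen_morphology_wells(
    seed: int,
    chemical_id: str,
    endpoint_rates: dict[str, ParameterVector],
    grid: tuple[float, ...] = ZF_GRID,
    n: int = N_PER_CONCENTRATION,
    timepoint: str = "120hpf",
) -> list[WellObservation]:
    """Well-level morphology observations with per-endpoint incidence
    curves; endpoints are drawn independently per animal."""
    rng = _rng(seed)
    wells: list[WellObservation] = []
    endpoints = list(endpoint_rates)
    for c in grid:
        rates = {e: float(evaluate(endpoint_rates[e], c)) for e in endpoints}
        for i in range(n):
            flags = {e: bool(rng.random() < rates[e]) for e in endpoints}
            plate = f"P{i % 3 + 1}"
            wells.append(WellObservation(
                plate_id=plate, well=f"{plate}-{c:g}-{i:02d}",
                chemical_id=chemical_id, concentration=float(c),
                timepoint=timepoint, endpoint_flags=flags))
    return wells


# baseline per-period movement means: quiescent background, strong
# photomotor burst after the first pulse, partial refractory response
_EPR_BASE = {"background": 0.05, "excitatory": 0.60, "refractory": 0.25,
             None: 0.10}
_LPR_BASE = {"light": 2.0, "dark": 6.0}  # mm distance per 6 s bin


def gen_movement(
    seed: int,
    chemical_id: str,
    concentration: float,
    assay: str,
    n_subjects: int = 32,
    effect: dict[str, float] | None = None,
    excluded_fraction: float = 0.0,
) -> list[MovementSeries]:
    """Per-animal movement traces with the assay's period structure.

    ``effect`` maps period (EPR: background/excitatory/refractory; LPR:
    light/dark) to a multiplicative treatment effect on mean movement
    (1.0 = null, < 1 hypoactive, > 1 hyperactive).  ``excluded_fraction``
    marks that fraction of animals excluded (dead/malformed) to exercise
    the LPR 70%-normal filter.
    """
    if assay not in ("EPR", "LPR"):
        raise ValueError(f"assay must be EPR or LPR, got {assay!r}")
    rng = _rng(seed)
    effect = effect or {}
    series: list[MovementSeries] = []
    n_excluded = int(round(excluded_fraction * n_subjects))
    for i in range(n_subjects):
        subject_scale = rng.lognormal(0.0, 0.25)
        if assay == "EPR":
            vals = np.empty(50)
            for t in range(50):
                period = epr_period_of_second(t)
                mean = _EPR_BASE[period] * effect.get(period, 1.0)
                vals[t] = np.clip(
                    subject_scale * mean + rng.normal(0.0, 0.05), 0.0, 1.0)
        else:
            vals = np.empty(240)
            for b in range(240):
                cycle, phase = lpr_cycle_phase_of_bin(b)
                mean = _LPR_BASE[phase]
                if cycle == 4:
                    mean *= effect.get(phase, 1.0)
                vals[b] = max(0.0, subject_scale * mean +
                              rng.normal(0.0, 0.5))
        excluded = i < n_excluded
        series.append(MovementSeries(
            subject_id=f"{chemical_id}-{concentration:g}-{i:02d}",
            chemical_id=chemical_id, concentration=concentration,
            assay=assay, values=tuple(float(v) for v in vals),
            excluded=excluded,
            exclusion_reason="malformed" if excluded else None))
    return series


def gen_exposure_matrix(
    seed: int,
    chemicals: tuple[str, ...],
    target_corr: np.ndarray | None = None,
    n_samples: int = 262,
    log_mean: float = 1.0,
    log_sd: float = 1.0,
) -> tuple["pd.DataFrame", np.ndarray]:
    """Log-normal exposure concentrations with a target log-scale
    correlation structure, plus per-sample deployment times (days).

    The observed concentration is intensity x deployment time, so the
    downstream analysis must normalize by time before correlating.
    Raises ValueError when the target matrix is not positive semi-definite.
    """
    import pandas as pd

    k = len(chemicals)
    if target_corr is None:
        target_corr = np.eye(k)
    target_corr = np.asarray(target_corr, dtype=float)
    if target_corr.shape != (k, k):
        raise ValueError("target correlation must be k x k")
    eigvals = np.linalg.eigvalsh(target_corr)
    if eigvals.min() < -1e-10:
        raise ValueError("target correlation matrix is not positive "
                         "semi-definite")
    rng = _rng(seed)
    chol = np.linalg.cholesky(target_corr + 1e-12 * np.eye(k))
    z = rng.standard_normal((n_samples, k)) @ chol.T
    intensity = np.exp(log_mean + log_sd * z)
    times = rng.uniform(5.0, 10.0, n_samples)  # typical week-scale wear
    conc = intensity * times[:, None]
    return pd.DataFrame(conc, columns=list(chemicals)), times
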