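"""Delimited-text readers/writers, mixture-design configs, and the
end-to-end pipeline runner.

All interchange formats are plain CSV (concentrations always in µM);
mixture designs and pipeline configuration are JSON or YAML.  Every
pipeline output directory carries a run log embedding the SHA-256 digest
of the configuration that produced it, so results are traceable to their
exact settings.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import ConcentrationResponseTable, FitResult, estimate_bmc, fit_all_families, select_best
from .mixtures import (
    DEFAULT_ADDITIVITY_TOLERANCE,
    InteractionAssessment,
    MixtureDesign,
    interaction_index,
)
from .screening import (
    LELResult,
    WellObservation,
    exposure_correlation,
    fisher_lel,
    incidence_and_any_effect,
    plate_qc,
)

__all__ = [
    "SchemaError",
    "QCError",
    "read_quantal_csv",
    "write_quantal_csv",
    "read_continuous_csv",
    "write_continuous_csv",
    "read_wells_csv",
    "write_wells_csv",
    "load_reference_bmcs",
    "read_bmc_table",
    "write_bmc_table",
    "load_designs",
    "write_assessments",
    "export_lel_heatmap",
    "fit_report",
    "PipelineConfig",
    "run_pipeline",
]

_QUANTAL_COLS = ["chemical", "endpoint", "conc_uM", "n_tested", "n_affected"]
_CONTINUOUS_COLS = ["chemical", "endpoint", "conc_uM", "response"]
_WELL_META_COLS = ["plate_id", "well", "chemical", "conc_uM", "timepoint"]


class SchemaError(ValueError):
    """An input file is missing required columns or malformed."""


class QCError(ValueError):
    """A plate failed vehicle-control quality control."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")


# ---------------------------------------------------------------------------
# concentration-response tables


def read_quantal_csv(path) -> list[ConcentrationResponseTable]:
    """Read per-concentration incidence counts, one table per
    chemical x endpoint."""
    df = pd.read_csv(path)
    _require_columns(df, _QUANTAL_COLS, path)
    tables = []
    for (chem, ep), grp in df.groupby(["chemical", "endpoint"], sort=True):
        grp = grp.sort_values("conc_uM")
        tables.append(ConcentrationResponseTable(
            str(chem), str(ep), "quantal",
            concentrations=tuple(grp["conc_uM"].astype(float)),
            n_tested=tuple(grp["n_tested"].astype(int)),
            n_affected=tuple(grp["n_affected"].astype(int))))
    return tables


def write_quantal_csv(tables: list[ConcentrationResponseTable], path) -> None:
    rows = []
    for t in tables:
        for c, n, a in zip(t.concentrations, t.n_tested, t.n_affected):
            rows.append((t.chemical_id, t.endpoint, c, n, a))
    pd.DataFrame(rows, columns=_QUANTAL_COLS).to_csv(path, index=False)


def read_continuous_csv(path) -> list[ConcentrationResponseTable]:
    """Read replicate continuous responses (fraction of vehicle control),
    one row per replicate well."""
    df = pd.read_csv(path)
    _require_columns(df, _CONTINUOUS_COLS, path)
    tables = []
    for (chem, ep), grp in df.groupby(["chemical", "endpoint"], sort=True):
        concs, reps = [], []
        for c, g in grp.groupby("conc_uM", sort=True):
            concs.append(float(c))
            reps.append(tuple(g["response"].astype(float)))
        tables.append(ConcentrationResponseTable(
            str(chem), str(ep), "continuous",
            concentrations=tuple(concs), responses=tuple(reps)))
    return tables


def write_continuous_csv(tables: list[ConcentrationResponseTable], path) -> None:
    rows = []
    for t in tables:
        for c, replicates in zip(t.concentrations, t.responses):
            for r in replicates:
                rows.append((t.chemical_id, t.endpoint, c, r))
    pd.DataFrame(rows, columns=_CONTINUOUS_COLS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# well-level morphology observations


def read_wells_csv(path) -> list[WellObservation]:
    """Read well-level screening records: metadata columns plus one 0/1
    column per morphology endpoint."""
    df = pd.read_csv(path)
    _require_columns(df, _WELL_META_COLS, path)
    flag_cols = [c for c in df.columns if c not in _WELL_META_COLS]
    if not flag_cols:
        raise SchemaError(f"{path}: no endpoint flag columns found")
    obs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        obs.append(WellObservation(
            plate_id=str(d["plate_id"]), well=str(d["well"]),
            chemical_id=str(d["chemical"]),
            concentration=float(d["conc_uM"]), timepoint=str(d["timepoint"]),
            endpoint_flags={c: bool(d[c]) for c in flag_cols}))
    return obs


def write_wells_csv(observations: list[WellObservation], path) -> None:
    endpoints: list[str] = []
    for o in observations:
        for e in o.endpoint_flags:
            if e not in endpoints:
                endpoints.append(e)
    rows = []
    for o in observations:
        row = {"plate_id": o.plate_id, "well": o.well,
               "chemical": o.chemical_id, "conc_uM": o.concentration,
               "timepoint": o.timepoint}
        row.update({e: int(bool(o.endpoint_flags.get(e, False)))
                    for e in endpoints})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# BMC tables and mixture designs


def load_reference_bmcs() -> pd.DataFrame:
    """Packaged BMC_10/BMC_50 table for the G14 screening campaign's
    bioactive components and mixtures in both model systems."""
    with resources.files("mixtox.data").joinpath("reference_bmcs.csv").open() as f:
        return pd.read_csv(f)


def read_bmc_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["chemical", "bmc50_uM"], path)
    return df


def write_bmc_table(rows: list[dict], path) -> None:
    """Write a BMC summary (chemical, bmc10_uM, bmc50_uM, regression_model)."""
    pd.DataFrame(rows).to_csv(path, index=False)


def load_designs(path) -> list[MixtureDesign]:
    """Read mixture designs from JSON or YAML.

    Schema: {"designs": [{"name", "mode", "components":
    [{"chemical", "anchor"?}], "totals"?}]}; anchors are required for
    bmc_anchored designs and ignored for equimolar ones.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict) or "designs" not in cfg:
        raise SchemaError(f"{path}: expected a top-level 'designs' list")
    designs = []
    for d in cfg["designs"]:
        try:
            designs.append(MixtureDesign(
                name=d["name"], mode=d["mode"],
                components=tuple((c["chemical"], c.get("anchor"))
                                 for c in d["components"]),
                total_concentrations=tuple(d.get("totals", ()))))
        except (KeyError, TypeError, ValueError) as err:
            raise SchemaError(f"{path}: bad design entry {d!r}: {err}") from err
    return designs


def write_assessments(assessments: list[InteractionAssessment], path) -> None:
    rows = [{
        "mixture": a.mixture_name,
        "mixture_bmc_uM": a.mixture_bmc,
        "interaction_index": a.index_2dp,
        "interaction_index_full": a.index,
        "call": a.call,
    } for a in assessments]
    pd.DataFrame(rows).to_csv(path, index=False)


def export_lel_heatmap(lel_results: list[LELResult], path=None) -> pd.DataFrame:
    """Chemicals x endpoints matrix of LEL values (µM); blank cells mean no
    significant effect at any tested concentration."""
    chems, endpoints = [], []
    for r in lel_results:
        if r.chemical_id not in chems:
            chems.append(r.chemical_id)
        if r.endpoint not in endpoints:
            endpoints.append(r.endpoint)
    mat = pd.DataFrame(np.nan, index=chems, columns=endpoints)
    for r in lel_results:
        if r.lel is not None:
            mat.loc[r.chemical_id, r.endpoint] = r.lel
    if path is not None:
        mat.to_csv(path, index_label="chemical")
    return mat


def fit_report(fits: list[FitResult]) -> list[dict]:
    """JSON-serializable per-family diagnostics for one table."""
    return [{
        "family": f.family.name,
        "params": f.params.as_dict(),
        "log_likelihood": f.log_likelihood,
        "aic": f.aic,
        "gof_statistic": f.gof_statistic,
        "gof_pvalue": f.gof_pvalue,
        "adequate": f.adequate,
        "convergence_flag": f.convergence_flag,
        "bmc50_uM": None if not math.isfinite(f.bmc50) else f.bmc50,
    } for f in fits]


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and settings for one end-to-end run; fully serializable."""

    output_dir: str
    quantal_csv: str | None = None
    continuous_csv: str | None = None
    wells_csv: str | None = None
    designs_file: str | None = None
    bmc_table_csv: str | None = None  # external BMC table for mix-index
    exposure_csv: str | None = None  # samples x chemicals + deployment_days
    bmr_levels: tuple[float, ...] = (0.10, 0.50)
    restricted_models: bool = True
    fisher_alternative: str = "greater"
    alpha_morphology: float = 0.05
    alpha_correlation: float = 0.01
    additivity_tolerance: float = DEFAULT_ADDITIVITY_TOLERANCE
    seed: int = 0

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for which the config names an input.

    Stages: morphology screening (plate QC, incidence, Fisher LEL,
    heatmap export), concentration-response fitting and BMC estimation,
    mixture interaction assessment, and exposure correlation.  Outputs are
    CSVs under ``config.output_dir`` plus ``run_log.json`` carrying the
    config digest.  Raises SchemaError for malformed inputs and QCError
    when a wells file fails vehicle-control QC.
    """
    if not any([config.quantal_csv, config.continuous_csv, config.wells_csv,
                config.designs_file, config.exposure_csv]):
        raise SchemaError("pipeline config names no inputs")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_digest": config.digest()}

    tables: list[ConcentrationResponseTable] = []
    if config.quantal_csv:
        tables += read_quantal_csv(config.quantal_csv)
    if config.continuous_csv:
        tables += read_continuous_csv(config.continuous_csv)

    if config.wells_csv:
        wells = read_wells_csv(config.wells_csv)
        by_chem: dict[str, list[WellObservation]] = {}
        for w in wells:
            by_chem.setdefault(w.chemical_id, []).append(w)
        lels, incidence_frames = [], []
        for chem, obs in by_chem.items():
            qc = plate_qc(obs)
            if not qc.passed:
                raise QCError(
                    f"{chem}: vehicle control {qc.normal_fraction:.1%} normal "
                    "(<= 80%); plate excluded")
            inc = incidence_and_any_effect(obs)
            for ep, t in inc.items():
                incidence_frames.append(t.to_frame())
                lels.append(fisher_lel(t, alpha=config.alpha_morphology,
                                       alternative=config.fisher_alternative))
        pd.concat(incidence_frames).to_csv(out / "incidence.csv", index=False)
        lel_mat = export_lel_heatmap(lels, out / "lel_matrix.csv")
        results["lel_matrix"] = lel_mat
        results["lel_results"] = lels

    if tables:
        bmc_rows, reports = [], {}
        for t in tables:
            fits = fit_all_families(t, config.restricted_models)
            best = select_best(fits)
            reports[f"{t.chemical_id}/{t.endpoint}"] = fit_report(fits)
            row = {"chemical": t.chemical_id, "endpoint": t.endpoint,
                   "regression_model": best.family.name if best else "not_modelable"}
            for bmr in config.bmr_levels:
                est = estimate_bmc(t, (bmr,), config.restricted_models)[0]
                row[f"bmc{int(round(bmr * 100))}_uM"] = (
                    est.bmc if est.estimable else None)
            bmc_rows.append(row)
        write_bmc_table(bmc_rows, out / "bmc_table.csv")
        (out / "fit_report.json").write_text(json.dumps(reports, indent=2))
        results["bmc_table"] = pd.DataFrame(bmc_rows)

    if config.designs_file:
        designs = load_designs(config.designs_file)
        if config.bmc_table_csv:
            bmcs = read_bmc_table(config.bmc_table_csv)
        elif "bmc_table" in results:
            bmcs = results["bmc_table"].rename(columns={"bmc50_uM": "bmc50_uM"})
        else:
            raise SchemaError("mixture assessment needs a BMC table "
                              "(bmc_table_csv or fitted tables)")
        assessments = []
        for design in designs:
            lookup = dict(zip(bmcs["chemical"].astype(str),
                              bmcs["bmc50_uM"].astype(float)))
            missing = [c for c in (design.chemical_ids + (design.name,))
                       if c not in lookup]
            if missing:
                raise SchemaError(
                    f"BMC table lacks rows for {missing} (design {design.name})")
            assessments.append(interaction_index(
                design, lookup[design.name],
                [lookup[c] for c in design.chemical_ids],
                tolerance=config.additivity_tolerance))
        write_assessments(assessments, out / "interaction_assessments.csv")
        results["assessments"] = assessments

    if config.exposure_csv:
        df = pd.read_csv(config.exposure_csv)
        if "deployment_days" not in df.columns:
            raise SchemaError(f"{config.exposure_csv}: needs a "
                              "deployment_days column")
        times = df.pop("deployment_days").to_numpy()
        r, p, masked = exposure_correlation(df, times,
                                            alpha=config.alpha_correlation)
        masked.to_csv(out / "correlation_masked.csv", index_label="chemical")
        r.to_csv(out / "correlation_full.csv", index_label="chemical")
        results["correlation_masked"] = masked

    (out / "run_log.json").write_text(json.dumps({
        "config": asdict(config), "config_digest": config.digest(),
        "outputs": sorted(q.name for q in out.iterdir() if q.is_file()),
    }, indent=2, default=str))
    return results
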