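"""Morphology and behavior screening statistics on the synthetic campaign.

Morphology: vehicle-control plate QC, per-endpoint incidence with the
"any effect" union, one-sided Fisher's exact tests against control, and
the LEL matrix export.  Behavior: EPR verdicts per concentration with
Bonferroni-corrected KS tests and the three-consecutive-concentration
bioactivity rule, for one null chemical and one hypoactive chemical.
"""

from pathlib import Path

import pandas as pd

from mixtox.io import export_lel_heatmap, read_wells_csv
from mixtox.screening import (
    behavior_response_test,
    bioactivity_call_per_period,
    fisher_lel,
    incidence_and_any_effect,
    plate_qc,
)
from mixtox.simulate import ZF_GRID, gen_movement

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20220400


def morphology() -> None:
    wells = read_wells_csv(ROOT / "synthetic" / "wells.csv")
    qc = plate_qc(wells)
    print(f"plate QC: {qc.normal_fraction:.1%} normal controls -> "
          f"{'pass' if qc.passed else 'fail'}")
    tables = incidence_and_any_effect(wells)
    lels = [fisher_lel(t) for t in tables.values()]
    frames = [t.to_frame() for t in tables.values()]
    pd.concat(frames).to_csv(ROOT / "incidence.csv", index=False)
    mat = export_lel_heatmap(lels, ROOT / "lel_matrix.csv")
    for r in lels:
        lel = "none" if r.lel is None else f"{r.lel:g} µM"
        print(f"  {r.endpoint:15s} LEL = {lel}")
    print(f"incidence -> {ROOT / 'incidence.csv'}; LEL matrix "
          f"({mat.shape[0]} x {mat.shape[1]}) -> {ROOT / 'lel_matrix.csv'}")


def behavior() -> None:
    concs = [c for c in ZF_GRID if c > 0]
    n_comp = len(concs) * 3  # Bonferroni family: concentrations x periods
    rows = []
    for k, (chem, suppression) in enumerate(
            (("null_chem", 1.0), ("hypo_chem", 0.25))):
        verdict_seq = []
        for i, c in enumerate(concs):
            ctrl = gen_movement(SEED + i, "DMSO", 0.0, "EPR", n_subjects=24)
            effect = ({"excitatory": suppression} if c >= 6.45 else {})
            treat = gen_movement(SEED + 100 + 1000 * k + i, chem, c,
                                 "EPR", n_subjects=24, effect=effect)
            v = behavior_response_test(treat, ctrl, "EPR",
                                       n_comparisons=n_comp)
            verdict_seq.append(v)
            rows.append({"chemical": chem, "conc_uM": c, **v.verdicts})
        bioactive = bioactivity_call_per_period(verdict_seq)
        print(f"{chem}: bioactive = {bioactive}")
    pd.DataFrame(rows).to_csv(ROOT / "behavior_verdicts.csv", index=False)
    print(f"behavior verdicts -> {ROOT / 'behavior_verdicts.csv'}")


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    morphology()
    behavior()


if __name__ == "__main__":
    main()
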