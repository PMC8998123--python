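"""Generate the synthetic screening campaign all later stages consume.

Emulates the study design: binomial malformation incidence for four
chemicals with distinct dose-response shapes on the standard zebrafish
grid (n = 36 per concentration), well-level morphology observations,
EPR movement traces, exact concentration-addition mixture tables for an
equimolar three-component design, and a wristband-style exposure matrix
(262 samples) with a known correlation structure.
"""

from pathlib import Path

import numpy as np

from mixtox.io import write_quantal_csv, write_wells_csv
from mixtox.mixtures import MixtureDesign
from mixtox.models import ParameterVector, get_family
from mixtox.simulate import (
    gen_ca_mixture_tables,
    gen_exposure_matrix,
    gen_morphology_wells,
    gen_quantal_table,
)

SEED = 20220323
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

# one generating truth per chemical, spanning four model families
TRUTHS = {
    "phthalate_A": ("log_logistic", (0.02, -6.0, 2.0)),
    "phthalate_B": ("weibull", (0.02, 1.5, 0.005)),
    "musk_C": ("gamma", (0.02, 2.0, 0.15)),
    "phenol_D": ("quantal_linear", (0.02, 0.05)),
}

CA_DESIGN = MixtureDesign(
    "Equi-Mix3", (("phthalate_A", None), ("phthalate_B", None),
                  ("musk_C", None)), "equimolar")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    tables = []
    for i, (chem, (family, vals)) in enumerate(TRUTHS.items()):
        pv = ParameterVector(get_family(family), vals)
        tables.append(gen_quantal_table(SEED + i, chem, pv))
    write_quantal_csv(tables, OUT / "quantal.csv")
    print(f"wrote {len(tables)} single-chemical incidence tables "
          f"(n = 36/concentration) -> {OUT / 'quantal.csv'}")

    ref = ParameterVector(get_family("log_logistic"), (0.01, -6.0, 2.0))
    mix_tables = gen_ca_mixture_tables(SEED + 10, CA_DESIGN, ref,
                                       potencies=(1.0, 1.6, 0.7), n=36)
    write_quantal_csv(list(mix_tables.values()), OUT / "ca_mixture.csv")
    print(f"wrote exact-CA mixture + component tables -> "
          f"{OUT / 'ca_mixture.csv'}")

    quiet = ParameterVector(get_family("quantal_linear"), (0.01, 0.0))
    hot = ParameterVector(get_family("log_logistic"), (0.02, -6.0, 2.0))
    mild = ParameterVector(get_family("quantal_linear"), (0.01, 0.01))
    wells = gen_morphology_wells(SEED + 20, "phthalate_A", {
        "mortality": mild, "edemas": hot, "bent_axis": mild,
        "touch_response": quiet})
    write_wells_csv(wells, OUT / "wells.csv")
    print(f"wrote {len(wells)} well-level morphology records -> "
          f"{OUT / 'wells.csv'}")

    target = np.eye(4)
    target[0, 1] = target[1, 0] = 0.65  # strongly co-occurring pair
    target[0, 2] = target[2, 0] = 0.40
    df, times = gen_exposure_matrix(
        SEED + 30, ("DBP", "DIBP", "BBP", "DEET"), target, n_samples=262)
    df["deployment_days"] = times
    df.to_csv(OUT / "exposure.csv", index=False)
    print(f"wrote 262-sample exposure matrix -> {OUT / 'exposure.csv'}")


if __name__ == "__main__":
    main()
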