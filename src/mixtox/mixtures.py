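"""Mixture design arithmetic and the concentration-addition interaction index.

A mixture is declared either *equimolar* (every component at 1/c of the
total molar concentration) or *BMC-anchored* (components in proportion to
their individual benchmark concentrations, so each contributes the same
fraction of its own potency).  Interactions are assessed against the
concentration-addition null: with x_i the concentration of component i at
the mixture's own BMC and E_i the component's individual BMC_50, the index

    I = sum_i x_i / E_i

equals 1 under exact additivity; I > 1 indicates antagonism (the mixture
needs more than the additive prediction) and I < 1 synergism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MixtureDesign",
    "InteractionAssessment",
    "component_concentrations",
    "interaction_index",
    "classify_interaction",
    "DEFAULT_ADDITIVITY_TOLERANCE",
]

DEFAULT_ADDITIVITY_TOLERANCE = 0.05


@dataclass(frozen=True)
class MixtureDesign:
    """Component identities, anchoring mode and the tested total grid.

    ``components`` maps chemical_id -> anchor value (µM) for bmc_anchored
    designs, or -> None for equimolar designs.  Totals are the summed
    concentration of all components, the convention all mixture exposure
    levels are reported in.
    """

    name: str
    components: tuple[tuple[str, float | None], ...]
    mode: str  # "equimolar" | "bmc_anchored"
    total_concentrations: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("equimolar", "bmc_anchored"):
            raise ValueError(f"unknown mixture mode {self.mode!r}")
        if len(self.components) == 0:
            raise ValueError("a mixture needs at least one component")
        comps = tuple((str(c), None if a is None else float(a))
                      for c, a in self.components)
        if self.mode == "bmc_anchored":
            if any(a is None or a <= 0 for _, a in comps):
                raise ValueError("bmc_anchored designs need a positive anchor "
                                 "value for every component")
        if any(t <= 0 for t in self.total_concentrations):
            raise ValueError("total concentrations must be positive")
        object.__setattr__(self, "components", comps)
        object.__setattr__(
            self, "total_concentrations",
            tuple(float(t) for t in self.total_concentrations))

    @property
    def c(self) -> int:
        """Number of components."""
        return len(self.components)

    @property
    def chemical_ids(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.components)

    def fractions(self) -> tuple[float, ...]:
        """Molar fraction of each component in the mixture (sums to 1)."""
        if self.mode == "equimolar":
            return tuple(1.0 / self.c for _ in self.components)
        total = sum(a for _, a in self.components)
        return tuple(a / total for _, a in self.components)


@dataclass(frozen=True)
class InteractionAssessment:
    """Eq.-style concentration-addition index and its categorical call."""

    mixture_name: str
    mixture_bmc: float
    component_concentrations: tuple[float, ...]  # x_i at the mixture BMC
    component_bmcs: tuple[float, ...]  # E_i
    index: float
    call: str  # synergism | additivity | antagonism

    @property
    def index_2dp(self) -> float:
        """The index rounded to two decimals, the reporting convention."""
        return round(self.index, 2)


def component_concentrations(
    design: MixtureDesign, total: float
) -> list[tuple[str, float]]:
    """Per-component concentration when the mixture is dosed at ``total`` µM.

    concentration_i = total x fraction_i; the returned values sum to the
    total to within 1e-9.
    """
    if total <= 0:
        raise ValueError("total concentration must be positive")
    return [(chem, total * f)
            for (chem, _), f in zip(design.components, design.fractions())]


def interaction_index(
    design: MixtureDesign,
    mixture_bmc: float,
    component_bmcs: list[float] | tuple[float, ...],
    tolerance: float = DEFAULT_ADDITIVITY_TOLERANCE,
) -> InteractionAssessment:
    """Concentration-addition interaction index at the mixture's BMC.

    ``component_bmcs`` are the individual-chemical benchmark concentrations
    E_i, ordered as in the design.  The x_i are the component concentrations
    implied by the design composition at ``mixture_bmc``.
    """
    if mixture_bmc <= 0:
        raise ValueError("mixture_bmc must be positive")
    if len(component_bmcs) != design.c:
        raise ValueError(
            f"{design.name}: expected {design.c} component BMCs, "
            f"got {len(component_bmcs)}")
    bmcs = tuple(float(e) for e in component_bmcs)
    if any(e <= 0 for e in bmcs):
        raise ValueError("component BMCs must be positive (index undefined "
                         "at E_i = 0)")
    x = tuple(xc for _, xc in component_concentrations(design, mixture_bmc))
    index = math.fsum(xi / ei for xi, ei in zip(x, bmcs))
    return InteractionAssessment(
        mixture_name=design.name,
        mixture_bmc=float(mixture_bmc),
        component_concentrations=x,
        component_bmcs=bmcs,
        index=index,
        call=classify_interaction(index, tolerance),
    )


def classify_interaction(
    index: float, tolerance: float = DEFAULT_ADDITIVITY_TOLERANCE
) -> str:
    """Categorical call: antagonism above 1, synergism below 1, additivity
    inside the +/- ``tolerance`` band around 1."""
    if index <= 0:
        raise ValueError("interaction index must be positive")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if index > 1.0 + tolerance:
        return "antagonism"
    if index < 1.0 - tolerance:
        return "synergism"
    return "additivity"
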