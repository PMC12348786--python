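"""Factorial irrigation-experiment designs.

The reference field trial crossed shrub species with irrigation treatments,
treatment-application periods, and replicates: three species x three
treatments x three periods x three replicates (81 plots) in the first year,
with a deficit-irrigation treatment added in the second year (4 treatments,
108 plots).  ``build_design`` enumerates the plot units for either standard
year or for a custom factor specification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

DEFAULT_SPECIES: tuple[str, ...] = ("euonymus", "ligustrum", "berberis")
DEFAULT_PERIODS: tuple[str, ...] = ("early", "middle", "late")

#: treatment factor levels per standard year label
STANDARD_TREATMENTS: dict[str, tuple[str, ...]] = {
    "2022": ("full", "rainfed", "drought"),
    "2023": ("full", "deficit", "rainfed", "drought"),
}

KNOWN_TREATMENTS = ("full", "deficit", "rainfed", "drought")


@dataclass(frozen=True)
class PlotUnit:
    """One experimental plot: a species x treatment x period x replicate cell."""

    plot_id: str
    species: str
    treatment: str
    period: str
    replicate: int


@dataclass(frozen=True)
class ExperimentDesign:
    """Fully enumerated factorial design with deterministic plot ordering."""

    year_label: str
    species: tuple[str, ...]
    treatments: tuple[str, ...]
    periods: tuple[str, ...]
    replicates: int
    plots: tuple[PlotUnit, ...]

    def __post_init__(self) -> None:
        expected = (
            len(self.species) * len(self.treatments) * len(self.periods) * self.replicates
        )
        if len(self.plots) != expected:
            raise ValueError(
                f"plot count {len(self.plots)} != factor-level product {expected}"
            )
        ids = [p.plot_id for p in self.plots]
        if len(set(ids)) != len(ids):
            raise ValueError("plot ids are not unique")

    @property
    def n_plots(self) -> int:
        return len(self.plots)


def build_design(
    year_label: str,
    *,
    species: Sequence[str] | None = None,
    treatments: Sequence[str] | None = None,
    periods: Sequence[str] | None = None,
    replicates: int | None = None,
) -> ExperimentDesign:
    """Enumerate the plot units of a factorial irrigation experiment.

    ``year_label`` of ``"2022"`` or ``"2023"`` selects the standard treatment
    sets (3 and 4 treatments respectively); any other label requires a full
    custom factor specification.  Plots are ordered species-major, then
    treatment, period, replicate, which fixes plot ids deterministically.
    """
    if year_label in STANDARD_TREATMENTS:
        treatments = tuple(treatments) if treatments is not None else STANDARD_TREATMENTS[year_label]
    elif treatments is None or species is None and replicates is None:
        raise ValueError(
            f"unknown year label {year_label!r}: supply species/treatments/"
            "periods/replicates explicitly for a custom design"
        )
    species = tuple(species) if species is not None else DEFAULT_SPECIES
    treatments = tuple(treatments)
    periods = tuple(periods) if periods is not None else DEFAULT_PERIODS
    replicates = int(replicates) if replicates is not None else 3
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not species or not treatments or not periods:
        raise ValueError("every factor needs at least one level")

    plots = tuple(
        PlotUnit(
            plot_id=f"{year_label}-{sp}-{tr}-{pe}-r{rep}",
            species=sp,
            treatment=tr,
            period=pe,
            replicate=rep,
        )
        for sp in species
        for tr in treatments
        for pe in periods
        for rep in range(1, replicates + 1)
    )
    return ExperimentDesign(
        year_label=year_label,
        species=species,
        treatments=treatments,
        periods=periods,
        replicates=replicates,
        plots=plots,
    )
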