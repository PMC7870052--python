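"""Convert sightings into per-transect density and biomass.

Abundance classes are converted to counts via class midpoints, length
classes to lengths via their midpoint, and lengths to individual mass
through the allometric relationship W = a * L**b.  Per transect and
descriptor, density is individuals per 250 m2 and biomass g per 250 m2.

A *descriptor* selects the species aggregated: ``total`` (all species),
a trophic-group code (``PISC`` ...), and any of those with a
``_reduced`` suffix, which excludes pelagic species (``total_reduced``
is the community without pelagics; ``PISC_reduced`` the piscivores
without pelagics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .survey import TROPHIC_GROUPS, SpeciesTraits, SurveyDataset

__all__ = [
    "AbundanceClassScheme",
    "DEFAULT_SCHEME",
    "TransectMeasure",
    "DEFAULT_DESCRIPTORS",
    "abundance_midpoint",
    "size_midpoint",
    "individual_weight",
    "descriptor_species",
    "transect_measures",
    "count_to_class",
]

#: Default nine-class abundance scheme (configurable; the original class
#: boundaries are a field convention for Mediterranean UVC work).
_DEFAULT_BOUNDS = (
    (1, 1),
    (2, 5),
    (6, 10),
    (11, 30),
    (31, 50),
    (51, 100),
    (101, 200),
    (201, 500),
    (501, 1000),
)


@dataclass(frozen=True)
class AbundanceClassScheme:
    """Nine ordered integer count ranges with a midpoint rule."""

    bounds: tuple[tuple[int, int], ...] = _DEFAULT_BOUNDS
    midpoint_rule: str = "arithmetic"  # or "geometric"

    def __post_init__(self) -> None:
        if len(self.bounds) != 9:
            raise ValueError(f"expected 9 classes, got {len(self.bounds)}")
        if self.midpoint_rule not in ("arithmetic", "geometric"):
            raise ValueError(f"unknown midpoint rule {self.midpoint_rule!r}")
        prev_high = 0
        for lo, hi in self.bounds:
            if lo > hi:
                raise ValueError(f"class ({lo}, {hi}) has low > high")
            if lo != prev_high + 1:
                raise ValueError(
                    "classes must be contiguous, non-overlapping, ascending"
                )
            prev_high = hi
        if self.bounds[0][0] < 1:
            raise ValueError("class 1 must start at >= 1")

    def midpoint(self, class_index: int) -> float:
        if not 1 <= class_index <= 9:
            raise ValueError(f"abundance class {class_index} outside 1..9")
        lo, hi = self.bounds[class_index - 1]
        if self.midpoint_rule == "arithmetic":
            return (lo + hi) / 2.0
        return math.sqrt(lo * hi)

    def class_for_count(self, count: int) -> int:
        """Class index whose range contains ``count`` (clipped to class 9)."""
        if count < 1:
            raise ValueError("count must be >= 1 to fall in a class")
        for i, (lo, hi) in enumerate(self.bounds, start=1):
            if lo <= count <= hi:
                return i
        return 9


DEFAULT_SCHEME = AbundanceClassScheme()


def abundance_midpoint(
    class_index: int, scheme: AbundanceClassScheme = DEFAULT_SCHEME
) -> float:
    """Representative count for an abundance class under the scheme."""
    return scheme.midpoint(class_index)


def count_to_class(
    count: int, scheme: AbundanceClassScheme = DEFAULT_SCHEME
) -> int:
    """Inverse direction: bin an exact count into its abundance class."""
    return scheme.class_for_count(count)


def size_midpoint(size_class_cm: float, width_cm: float) -> float:
    """Midpoint length of a size class given its lower bound and width."""
    if width_cm not in (2, 5):
        raise ValueError(f"size-class width must be 2 or 5 cm, got {width_cm}")
    if size_class_cm < 0:
        raise ValueError("size-class lower bound must be non-negative")
    return size_class_cm + width_cm / 2.0


def individual_weight(length_cm: float, a: float, b: float) -> float:
    """Allometric weight W = a * L**b in grams (L in cm)."""
    if length_cm < 0:
        raise ValueError("length must be non-negative")
    if a <= 0 or b <= 0:
        raise ValueError("length-weight coefficients must be positive")
    return a * length_cm**b


@dataclass(frozen=True)
class TransectMeasure:
    """Density and biomass of one descriptor on one transect-year."""

    year: int
    site: str
    transect: str
    descriptor: str
    density: float  # individuals per 250 m2
    biomass: float  # g per 250 m2

    def __post_init__(self) -> None:
        if self.density < 0 or self.biomass < 0:
            raise ValueError("density and biomass must be non-negative")
        if self.density == 0 and self.biomass != 0:
            raise ValueError("biomass must be 0 when density is 0")


#: Descriptors analysed by default: community-wide, community without
#: pelagics, the seven trophic groups, and piscivores without pelagics.
DEFAULT_DESCRIPTORS = (
    "total",
    "total_reduced",
    *TROPHIC_GROUPS,
    "PISC_reduced",
)


def descriptor_species(
    descriptor: str, traits: dict[str, SpeciesTraits]
) -> set[str]:
    """Species selected by a descriptor name.

    ``total`` selects everything; a trophic-group code selects that
    group; a ``_reduced`` suffix additionally excludes pelagic species.
    """
    name = descriptor
    reduced = False
    if name.endswith("_reduced"):
        reduced = True
        name = name[: -len("_reduced")]
    if name == "total":
        selected = {s for s in traits}
    elif name in TROPHIC_GROUPS:
        selected = {s for s, t in traits.items() if t.trophic_group == name}
    else:
        raise ValueError(
            f"unknown descriptor {descriptor!r}; expected 'total', one of "
            f"{TROPHIC_GROUPS}, or a '_reduced' variant"
        )
    if reduced:
        selected = {s for s in selected if not traits[s].pelagic}
    return selected


def transect_measures(
    dataset: SurveyDataset,
    descriptor: str,
    scheme: AbundanceClassScheme = DEFAULT_SCHEME,
) -> list[TransectMeasure]:
    """Per-transect density and biomass for one descriptor.

    Every surveyed (year, site, transect) appears exactly once; transects
    with no matching sightings contribute explicit zeros so that yearly
    means are computed over complete transect panels.  Counts come from
    ``exact_count`` when present, otherwise the scheme midpoint of the
    abundance class; areas are normalised to 250 m2.
    """
    selected = descriptor_species(descriptor, dict(dataset.traits))
    norm = 250.0 / dataset.transect_area_m2
    acc: dict[tuple[int, str, str], list[float]] = {
        key: [0.0, 0.0] for key in dataset.transect_index()
    }
    for r in dataset.records:
        if r.species not in selected:
            continue
        count = (
            float(r.exact_count)
            if r.exact_count is not None
            else scheme.midpoint(r.abundance_class)
        )
        t = dataset.traits[r.species]
        length = size_midpoint(r.size_class_cm, r.size_class_width_cm)
        cell = acc[(r.year, r.site, r.transect)]
        cell[0] += count * norm
        cell[1] += count * individual_weight(length, t.lw_a, t.lw_b) * norm
    return [
        TransectMeasure(year, site, transect, descriptor, dens, biom)
        for (year, site, transect), (dens, biom) in sorted(acc.items())
    ]


def measures_frame(measures: Iterable[TransectMeasure]) -> pd.DataFrame:
    """Tidy DataFrame view of transect measures."""
    return pd.DataFrame(
        [
            {
                "year": m.year,
                "site": m.site,
                "transect": m.transect,
                "descriptor": m.descriptor,
                "density": m.density,
                "biomass": m.biomass,
            }
            for m in measures
        ]
    )
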