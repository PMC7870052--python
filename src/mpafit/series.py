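"""Yearly mean +/- SE descriptor series.

Transect measures are pooled per year into a global mean and standard
error (sample SD over transects divided by sqrt(n)).  The time
coordinate ``t`` counts years since protection began (reference year
1995 by default, so the first survey year 1996 is t = 1).  Years
without surveys are simply absent from the series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .biomass import TransectMeasure

__all__ = [
    "SeriesPoint",
    "DescriptorSeries",
    "yearly_series",
    "count_survey_years",
    "series_frame",
]

#: Year protection began at the study MPA; t = year - REFERENCE_YEAR.
REFERENCE_YEAR = 1995


@dataclass(frozen=True)
class SeriesPoint:
    year: int
    t: float
    mean: float
    se: float
    n_transects: int
    single_transect: bool = False  # SE reported as 0 from one replicate

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("SE must be non-negative")
        if self.n_transects < 1:
            raise ValueError("n_transects must be >= 1")


@dataclass(frozen=True)
class DescriptorSeries:
    """Yearly mean +/- SE of one response variable for one descriptor."""

    descriptor: str
    variable: str  # "biomass" or "density"
    area: str  # "protected" or "control"
    points: tuple[SeriesPoint, ...]
    reference_year: int = REFERENCE_YEAR

    def __post_init__(self) -> None:
        if self.variable not in ("biomass", "density"):
            raise ValueError(f"unknown variable {self.variable!r}")
        years = [p.year for p in self.points]
        if years != sorted(set(years)):
            raise ValueError("years must be strictly increasing")
        for p in self.points:
            if p.t != p.year - self.reference_year:
                raise ValueError(
                    f"point {p.year}: t={p.t} inconsistent with reference "
                    f"year {self.reference_year}"
                )

    @property
    def t(self) -> np.ndarray:
        return np.array([p.t for p in self.points], dtype=float)

    @property
    def mean(self) -> np.ndarray:
        return np.array([p.mean for p in self.points], dtype=float)

    @property
    def se(self) -> np.ndarray:
        return np.array([p.se for p in self.points], dtype=float)

    def __len__(self) -> int:
        return len(self.points)

    def subset_years(self, start: int, end: int) -> "DescriptorSeries":
        """Points within [start, end]; t stays anchored to reference_year."""
        return replace(
            self,
            points=tuple(p for p in self.points if start <= p.year <= end),
        )


def yearly_series(
    measures: Sequence[TransectMeasure],
    variable: str,
    reference_year: int = REFERENCE_YEAR,
    area: str = "protected",
    pooling: str = "transect",
) -> DescriptorSeries:
    """Aggregate transect measures into a yearly mean +/- SE series.

    ``pooling='transect'`` (default) pools all transects of a year, the
    unit matching the survey's variable replicate count per site;
    ``pooling='site_mean'`` averages transects within sites first and
    computes the SE over site means.
    """
    if not measures:
        raise ValueError("no measures to aggregate")
    if pooling not in ("transect", "site_mean"):
        raise ValueError(f"unknown pooling {pooling!r}")
    descriptor = measures[0].descriptor
    if any(m.descriptor != descriptor for m in measures):
        raise ValueError("measures mix descriptors")

    by_year: dict[int, list[float]] = {}
    if pooling == "transect":
        for m in measures:
            by_year.setdefault(m.year, []).append(getattr(m, variable))
    else:
        by_site: dict[tuple[int, str], list[float]] = {}
        for m in measures:
            by_site.setdefault((m.year, m.site), []).append(getattr(m, variable))
        for (year, _site), vals in by_site.items():
            by_year.setdefault(year, []).append(float(np.mean(vals)))

    points = []
    for year in sorted(by_year):
        vals = np.asarray(by_year[year], dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        if n > 1:
            se = float(vals.std(ddof=1) / math.sqrt(n))
            single = False
        else:
            se = 0.0
            single = True
        points.append(
            SeriesPoint(
                year=year,
                t=year - reference_year,
                mean=mean,
                se=se,
                n_transects=n,
                single_transect=single,
            )
        )
    return DescriptorSeries(
        descriptor=descriptor,
        variable=variable,
        area=area,
        points=tuple(points),
        reference_year=reference_year,
    )


def count_survey_years(series: DescriptorSeries) -> int:
    """Number of distinct surveyed years in the series."""
    return len({p.year for p in series.points})


def series_frame(series: Iterable[DescriptorSeries]) -> pd.DataFrame:
    """Tidy CSV-ready frame: descriptor, variable, area, year, t, mean, se, n."""
    rows = []
    for s in series:
        for p in s.points:
            rows.append(
                {
                    "descriptor": s.descriptor,
                    "variable": s.variable,
                    "area": s.area,
                    "year": p.year,
                    "t": p.t,
                    "mean": p.mean,
                    "se": p.se,
                    "n_transects": p.n_transects,
                }
            )
    return pd.DataFrame(rows)
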