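"""Full-pipeline orchestration over enforcement periods.

The study history splits into three fitted windows: the whole monitored
span (1996-2018), the early well-enforced years before surveillance
lapsed (1996-2009), and the years after surveillance was fully restored
(2015-2018).  For every descriptor x response variable x period, the
pipeline builds the yearly series, fits all growth families, applies the
AICc selection rule and derives a capacity estimate; when the first
period selects exponential growth, its projection to the study horizon
is reported alongside.  Control-area data are summarised as series only
(no growth-curve fitting) unless requested.

Sub-period series keep the absolute time coordinate (years since
protection began) so that N0-type parameters keep their meaning across
periods.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import pandas as pd

from .biomass import (
    AbundanceClassScheme,
    DEFAULT_DESCRIPTORS,
    DEFAULT_SCHEME,
    transect_measures,
)
from .capacity import (
    CAPACITY_FRACTION,
    DEFAULT_HORIZON,
    CapacityEstimate,
    capacity_from_fit,
    exponential_projection,
)
from .fitting import FitConfig, SelectionResult, fit_all
from .series import REFERENCE_YEAR, DescriptorSeries, yearly_series
from .survey import SurveyDataset

__all__ = [
    "PeriodSpec",
    "DEFAULT_PERIODS",
    "AnalysisConfig",
    "AnalysisCell",
    "AnalysisBundle",
    "split_periods",
    "run_analysis",
    "capacity_table",
]

#: Minimum points for any fit: smallest family has 2 curve parameters,
#: and AICc needs n - k - 1 >= 1 with k = n_params + 1.
_MIN_POINTS = 4


@dataclass(frozen=True)
class PeriodSpec:
    """A named inclusive year window."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"period {self.name}: start > end")

    def contains(self, year: int) -> bool:
        return self.start <= year <= self.end


DEFAULT_PERIODS: tuple[PeriodSpec, ...] = (
    PeriodSpec("whole", 1996, 2018),
    PeriodSpec("first", 1996, 2009),
    PeriodSpec("last", 2015, 2018),
)


def split_periods(
    series: DescriptorSeries, periods: Sequence[PeriodSpec]
) -> dict[str, DescriptorSeries]:
    """Filter the series by each period's year range (t unchanged)."""
    return {
        p.name: series.subset_years(p.start, p.end) for p in periods
    }


@dataclass(frozen=True)
class AnalysisConfig:
    """Options for a full analysis run."""

    descriptors: tuple[str, ...] = DEFAULT_DESCRIPTORS
    variables: tuple[str, ...] = ("biomass", "density")
    periods: tuple[PeriodSpec, ...] = DEFAULT_PERIODS
    scheme: AbundanceClassScheme = DEFAULT_SCHEME
    fit: FitConfig = FitConfig()
    reference_year: int = REFERENCE_YEAR
    pooling: str = "transect"
    seed: int | None = None
    fit_control: bool = False
    capacity_fraction: float = CAPACITY_FRACTION
    projection_horizon: float = DEFAULT_HORIZON

    def to_dict(self) -> dict:
        return {
            "descriptors": list(self.descriptors),
            "variables": list(self.variables),
            "periods": [(p.name, p.start, p.end) for p in self.periods],
            "scheme": {
                "bounds": list(map(list, self.scheme.bounds)),
                "midpoint_rule": self.scheme.midpoint_rule,
            },
            "fit": asdict(self.fit),
            "reference_year": self.reference_year,
            "pooling": self.pooling,
            "seed": self.seed,
            "fit_control": self.fit_control,
            "capacity_fraction": self.capacity_fraction,
            "projection_horizon": self.projection_horizon,
        }


@dataclass(frozen=True)
class AnalysisCell:
    """Result for one (descriptor, variable, period, area) combination."""

    descriptor: str
    variable: str
    period: str
    area: str
    series: DescriptorSeries
    selection: SelectionResult | None = None
    capacity: CapacityEstimate | None = None
    projection: CapacityEstimate | None = None
    skip_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "descriptor": self.descriptor,
            "variable": self.variable,
            "period": self.period,
            "area": self.area,
            "n_points": len(self.series),
            "years": [p.year for p in self.series.points],
            "selection": self.selection.to_dict() if self.selection else None,
            "capacity": self.capacity.to_dict() if self.capacity else None,
            "projection": self.projection.to_dict() if self.projection else None,
            "skip_reason": self.skip_reason,
        }


@dataclass(frozen=True)
class AnalysisBundle:
    """Every requested analysis cell plus run metadata."""

    cells: tuple[AnalysisCell, ...]
    config: AnalysisConfig

    def get(
        self, descriptor: str, variable: str, period: str, area: str = "protected"
    ) -> AnalysisCell:
        for c in self.cells:
            if (c.descriptor, c.variable, c.period, c.area) == (
                descriptor,
                variable,
                period,
                area,
            ):
                return c
        raise KeyError((descriptor, variable, period, area))

    def to_json(self, indent: int | None = 2) -> str:
        payload = {
            "config": self.config.to_dict(),
            "cells": [c.to_dict() for c in self.cells],
        }
        return json.dumps(payload, indent=indent, sort_keys=True,
                          allow_nan=True, default=float)


def _cell_seed(base: int | None, key: str) -> int:
    """Stable per-cell seed: independent of cell enumeration order."""
    h = zlib.crc32(key.encode()) & 0x7FFFFFFF
    if base is None:
        return h
    return (base * 1_000_003 + h) % (2**31)


def _analyse_series(
    series: DescriptorSeries,
    period: PeriodSpec,
    config: AnalysisConfig,
    area: str,
) -> AnalysisCell:
    sub = series.subset_years(period.start, period.end)
    base = dict(
        descriptor=series.descriptor,
        variable=series.variable,
        period=period.name,
        area=area,
        series=sub,
    )
    if len(sub) == 0:
        return AnalysisCell(**base, skip_reason="no surveyed years in period")
    if len(sub) < _MIN_POINTS:
        return AnalysisCell(
            **base,
            skip_reason=f"insufficient data ({len(sub)} points < {_MIN_POINTS})",
        )
    key = f"{series.descriptor}|{series.variable}|{period.name}|{area}"
    fit_cfg = FitConfig(
        n_restarts=config.fit.n_restarts,
        jitter=config.fit.jitter,
        seed=_cell_seed(config.seed, key),
        weighted=config.fit.weighted,
        max_nfev=config.fit.max_nfev,
    )
    try:
        selection = fit_all(sub.t, sub.mean, fit_cfg, se=sub.se)
    except ValueError as exc:
        return AnalysisCell(**base, skip_reason=f"fit failed: {exc}")
    cap = capacity_from_fit(
        selection,
        descriptor=series.descriptor,
        variable=series.variable,
        period=period.name,
        fraction=config.capacity_fraction,
    )
    projection = None
    if (
        period.name == "first"
        and selection.selected.family == "exponential"
        and selection.selected.spec.params.get("b", 0) > 0
    ):
        projection = exponential_projection(
            selection.selected,
            t_end=config.projection_horizon,
            descriptor=series.descriptor,
            variable=series.variable,
        )
    return AnalysisCell(
        **base, selection=selection, capacity=cap, projection=projection
    )


def run_analysis(
    dataset: SurveyDataset,
    config: AnalysisConfig = AnalysisConfig(),
    control: SurveyDataset | None = None,
) -> AnalysisBundle:
    """Run the full pipeline: series, fits, selection, capacities.

    ``dataset`` holds the protected-area records; ``control`` optionally
    holds the unprotected reference area, which is summarised as series
    (and only model-fitted when ``config.fit_control`` is true).
    Per-cell failures are recorded in the cell, never aborting the run.
    """
    cells: list[AnalysisCell] = []
    areas: list[tuple[str, SurveyDataset, bool]] = [("protected", dataset, True)]
    if control is not None:
        areas.append(("control", control, config.fit_control))
    for area, ds, do_fit in areas:
        for descriptor in config.descriptors:
            for variable in config.variables:
                measures = transect_measures(ds, descriptor, config.scheme)
                series = yearly_series(
                    measures,
                    variable,
                    reference_year=config.reference_year,
                    area=area,
                    pooling=config.pooling,
                )
                for period in config.periods:
                    if do_fit:
                        cells.append(
                            _analyse_series(series, period, config, area)
                        )
                    else:
                        cells.append(
                            AnalysisCell(
                                descriptor=descriptor,
                                variable=variable,
                                period=period.name,
                                area=area,
                                series=series.subset_years(
                                    period.start, period.end
                                ),
                                skip_reason="control area summarised only",
                            )
                        )
    return AnalysisBundle(cells=tuple(cells), config=config)


def capacity_table(bundle: AnalysisBundle) -> pd.DataFrame:
    """Capacity summary: whole-period K and first-period projection.

    One row per (variable, descriptor) with a finite whole-period
    capacity, mirroring the layout of a carrying-capacity results table.
    """
    rows = []
    for cell in bundle.cells:
        if cell.period != "whole" or cell.area != "protected":
            continue
        if cell.capacity is None or cell.capacity.value is None:
            continue
        proj = None
        try:
            first = bundle.get(cell.descriptor, cell.variable, "first", cell.area)
            if first.projection is not None:
                proj = first.projection.value
        except KeyError:
            pass
        rows.append(
            {
                "variable": cell.variable,
                "descriptor": cell.descriptor,
                "capacity_whole_period": cell.capacity.value,
                "capacity_method": cell.capacity.method,
                "capacity_exponential_projection": proj,
                "time_to_95pct": cell.capacity.time_to_95pct,
                "selected_family": cell.selection.selected.family,
            }
        )
    return pd.DataFrame(rows)
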