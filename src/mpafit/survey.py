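"""Domain types and tabular I/O for underwater visual census (UVC) data.

A UVC survey produces one row per species sighting per belt transect:
the observer records the species, assigns the number of individuals to
one of nine predetermined abundance classes (or notes an exact count),
and bins the estimated total length into 2-cm classes (5-cm for large
species).  Species carry a trophic-group label, a pelagic flag, a flag
for presence at the unprotected control area, and allometric
length-weight coefficients (W = a * L**b, W in g, L in cm).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TROPHIC_GROUPS",
    "SightingRecord",
    "SpeciesTraits",
    "SurveyDataset",
    "SchemaError",
    "ValidationError",
    "read_sightings",
    "write_sightings",
    "read_traits",
    "load_packaged_traits",
    "composition_summary",
]

#: Diet-based species classes: piscivores, macro-invertivores,
#: micro-invertivores, omnivores, herbivores, planktivores, detritivores.
TROPHIC_GROUPS = ("PISC", "MACRO", "MICRO", "OMNI", "HERB", "PLAN", "DETR")

#: Cube-law fallback used when a species has no length-weight entry.
DEFAULT_LW_A = 0.01
DEFAULT_LW_B = 3.0


class SchemaError(ValueError):
    """A required column is missing or a file cannot be interpreted."""


class ValidationError(ValueError):
    """A row violates a field invariant; the message names the row."""


@dataclass(frozen=True)
class SightingRecord:
    """One UVC observation on one transect.

    Exactly one of ``abundance_class`` (1..9) and ``exact_count`` is set.
    ``size_class_cm`` is the lower bound of the length class;
    ``size_class_width_cm`` is 2 or 5.
    """

    year: int
    site: str
    transect: str
    species: str
    size_class_cm: float
    size_class_width_cm: float = 2.0
    abundance_class: int | None = None
    exact_count: int | None = None

    def __post_init__(self) -> None:
        if (self.abundance_class is None) == (self.exact_count is None):
            raise ValidationError(
                f"record {self!r}: exactly one of abundance_class and "
                "exact_count must be present"
            )
        if self.abundance_class is not None and not 1 <= self.abundance_class <= 9:
            raise ValidationError(
                f"record {self!r}: abundance_class {self.abundance_class} "
                "outside 1..9"
            )
        if self.exact_count is not None and self.exact_count < 0:
            raise ValidationError(f"record {self!r}: negative exact_count")
        if self.size_class_width_cm not in (2, 5):
            raise ValidationError(
                f"record {self!r}: size_class_width_cm must be 2 or 5, "
                f"got {self.size_class_width_cm}"
            )
        if self.size_class_cm < 0:
            raise ValidationError(f"record {self!r}: negative size_class_cm")


@dataclass(frozen=True)
class SpeciesTraits:
    """Trophic position, mobility and allometry of one species."""

    species: str
    trophic_group: str
    pelagic: bool
    present_at_control: bool = True
    lw_a: float = DEFAULT_LW_A
    lw_b: float = DEFAULT_LW_B

    def __post_init__(self) -> None:
        if self.trophic_group not in TROPHIC_GROUPS:
            raise ValidationError(
                f"species {self.species!r}: unknown trophic group "
                f"{self.trophic_group!r}; valid labels are {TROPHIC_GROUPS}"
            )
        if self.lw_a <= 0 or self.lw_b <= 0:
            raise ValidationError(
                f"species {self.species!r}: length-weight coefficients must "
                f"be positive (a={self.lw_a}, b={self.lw_b})"
            )


@dataclass
class SurveyDataset:
    """Validated sighting records plus the species trait table.

    ``transect_area_m2`` defaults to the 50 x 5 m belt transect (250 m2);
    densities and biomasses downstream are normalised to 250 m2.
    """

    records: Sequence[SightingRecord]
    traits: Mapping[str, SpeciesTraits]
    transect_area_m2: float = 250.0
    #: optional explicit survey panel of (year, site, transect) keys; lets
    #: transects that recorded no sightings still contribute zeros downstream
    panel: Sequence[tuple[int, str, str]] | None = None

    def __post_init__(self) -> None:
        if self.transect_area_m2 <= 0:
            raise ValidationError("transect_area_m2 must be positive")
        unknown = sorted({r.species for r in self.records} - set(self.traits))
        if unknown:
            raise ValidationError(
                f"{len(unknown)} species in records missing from the trait "
                f"table: {unknown}"
            )
        if self.panel is not None:
            keys = {(r.year, r.site, r.transect) for r in self.records}
            outside = keys - set(self.panel)
            if outside:
                raise ValidationError(
                    f"records outside the declared panel: {sorted(outside)[:5]}"
                )

    @property
    def years(self) -> list[int]:
        if self.panel is not None:
            return sorted({k[0] for k in self.panel})
        return sorted({r.year for r in self.records})

    def transect_index(self) -> list[tuple[int, str, str]]:
        """Distinct (year, site, transect) keys, sorted."""
        if self.panel is not None:
            return sorted(set(self.panel))
        return sorted({(r.year, r.site, r.transect) for r in self.records})


_SIGHTING_COLUMNS = {
    "year": "year",
    "site": "site",
    "transect": "transect",
    "species": "species",
    "abundance_class": "abundance_class",
    "exact_count": "exact_count",
    "size_class_cm": "size_class_cm",
    "size_class_width_cm": "size_class_width_cm",
}


def _opt_int(value: str | None) -> int | None:
    if value is None or value == "":
        return None
    return int(value)


def read_sightings(
    path: str | Path,
    format_config: Mapping[str, str] | None = None,
) -> list[SightingRecord]:
    """Read sighting records from a delimited text file with header.

    ``format_config`` maps canonical field names (the keys of the default
    mapping) to the column names used in the file, so other dialects plug
    in without rewriting the file.  Mandatory fields: year, site, transect,
    species, size_class_cm, and at least one of abundance_class /
    exact_count per row.
    """
    colmap = dict(_SIGHTING_COLUMNS)
    if format_config:
        colmap.update(format_config)
    path = Path(path)
    records: list[SightingRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        mandatory = ("year", "site", "transect", "species", "size_class_cm")
        missing = [colmap[f] for f in mandatory if colmap[f] not in header]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
        has_class = colmap["abundance_class"] in header
        has_count = colmap["exact_count"] in header
        if not (has_class or has_count):
            raise SchemaError(
                f"{path}: need an abundance_class or exact_count column"
            )
        for i, row in enumerate(reader, start=2):
            try:
                records.append(
                    SightingRecord(
                        year=int(row[colmap["year"]]),
                        site=row[colmap["site"]],
                        transect=row[colmap["transect"]],
                        species=row[colmap["species"]],
                        size_class_cm=float(row[colmap["size_class_cm"]]),
                        size_class_width_cm=float(
                            row.get(colmap["size_class_width_cm"]) or 2
                        ),
                        abundance_class=_opt_int(
                            row.get(colmap["abundance_class"])
                        )
                        if has_class
                        else None,
                        exact_count=_opt_int(row.get(colmap["exact_count"]))
                        if has_count
                        else None,
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path}, line {i}: {exc}") from exc
    return records


def write_sightings(records: Iterable[SightingRecord], path: str | Path) -> None:
    """Write records as CSV, inverse of :func:`read_sightings`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SIGHTING_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.year,
                    r.site,
                    r.transect,
                    r.species,
                    "" if r.abundance_class is None else r.abundance_class,
                    "" if r.exact_count is None else r.exact_count,
                    r.size_class_cm,
                    r.size_class_width_cm,
                ]
            )


_TRUTHY = {"true", "t", "1", "yes", "x"}
_FALSY = {"false", "f", "0", "no", ""}


def _parse_bool(value: str, *, context: str) -> bool:
    v = value.strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise ValidationError(f"{context}: cannot interpret boolean {value!r}")


def read_traits(
    path: str | Path,
    lw_table: str | Path | None = None,
    default_lw: tuple[float, float] = (DEFAULT_LW_A, DEFAULT_LW_B),
) -> dict[str, SpeciesTraits]:
    """Read the species trait table, optionally merging length-weight data.

    The trait file needs columns species, trophic_group, pelagic and
    present_at_control; lw_a/lw_b columns are optional.  ``lw_table`` may
    point to a separate CSV with species, lw_a, lw_b columns.  Species
    without coefficients fall back to ``default_lw`` (cube law) with a
    warning.
    """
    path = Path(path)
    lw: dict[str, tuple[float, float]] = {}
    if lw_table is not None:
        with Path(lw_table).open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                lw[row["species"]] = (float(row["lw_a"]), float(row["lw_b"]))

    traits: dict[str, SpeciesTraits] = {}
    defaulted: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        needed = ["species", "trophic_group", "pelagic", "present_at_control"]
        missing = [c for c in needed if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        for i, row in enumerate(reader, start=2):
            name = row["species"].strip()
            if name in traits:
                raise ValidationError(f"{path}, line {i}: duplicate species {name!r}")
            if name in lw:
                a, b = lw[name]
            elif row.get("lw_a") and row.get("lw_b"):
                a, b = float(row["lw_a"]), float(row["lw_b"])
            else:
                a, b = default_lw
                defaulted.append(name)
            traits[name] = SpeciesTraits(
                species=name,
                trophic_group=row["trophic_group"].strip(),
                pelagic=_parse_bool(row["pelagic"], context=f"{path}, line {i}"),
                present_at_control=_parse_bool(
                    row["present_at_control"], context=f"{path}, line {i}"
                ),
                lw_a=a,
                lw_b=b,
            )
    if defaulted:
        warnings.warn(
            f"{len(defaulted)} species without length-weight coefficients; "
            f"using default a={default_lw[0]}, b={default_lw[1]}",
            stacklevel=2,
        )
    return traits


def load_packaged_traits(
    lw_table: str | Path | None = None,
) -> dict[str, SpeciesTraits]:
    """Load the packaged 62-species Mediterranean reef-fish trait table."""
    ref = resources.files("mpafit.data").joinpath("species_traits.csv")
    with resources.as_file(ref) as p:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return read_traits(p, lw_table=lw_table)


def composition_summary(traits: Mapping[str, SpeciesTraits]) -> pd.DataFrame:
    """Species counts and percentages per trophic group.

    Returns one row per trophic group (all seven, zero-count groups
    included), with percentages over the total species count rounded to
    one decimal.
    """
    if not traits:
        raise ValueError("empty trait mapping")
    total = len(traits)
    counts = {g: 0 for g in TROPHIC_GROUPS}
    for t in traits.values():
        counts[t.trophic_group] += 1
    return pd.DataFrame(
        {
            "trophic_group": list(TROPHIC_GROUPS),
            "n_species": [counts[g] for g in TROPHIC_GROUPS],
            "percent": [round(100.0 * counts[g] / total, 1) for g in TROPHIC_GROUPS],
        }
    )
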