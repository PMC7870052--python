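"""Shared fixtures: small trait tables and survey datasets."""

import pytest

from mpafit.survey import (
    SightingRecord,
    SpeciesTraits,
    SurveyDataset,
    load_packaged_traits,
)


@pytest.fixture(scope="session")
def packaged_traits():
    return load_packaged_traits()


@pytest.fixture()
def mini_traits():
    """Four-species table covering pelagic/benthic and two trophic groups."""
    return {
        "Pisciv benthicus": SpeciesTraits(
            species="Pisciv benthicus", trophic_group="PISC", pelagic=False,
            lw_a=0.01, lw_b=3.0,
        ),
        "Pisciv pelagicus": SpeciesTraits(
            species="Pisciv pelagicus", trophic_group="PISC", pelagic=True,
            lw_a=0.01, lw_b=3.0,
        ),
        "Herbiv communis": SpeciesTraits(
            species="Herbiv communis", trophic_group="HERB", pelagic=False,
            lw_a=0.02, lw_b=2.9,
        ),
        "Plankt minutus": SpeciesTraits(
            species="Plankt minutus", trophic_group="PLAN", pelagic=True,
            lw_a=0.015, lw_b=3.1,
        ),
    }


@pytest.fixture()
def mini_dataset(mini_traits):
    records = [
        SightingRecord(year=1996, site="S01", transect="T1",
                       species="Pisciv benthicus", size_class_cm=20,
                       abundance_class=1),
        SightingRecord(year=1996, site="S01", transect="T1",
                       species="Pisciv pelagicus", size_class_cm=30,
                       size_class_width_cm=5, abundance_class=2),
        SightingRecord(year=1996, site="S01", transect="T2",
                       species="Herbiv communis", size_class_cm=10,
                       exact_count=4),
        SightingRecord(year=1997, site="S01", transect="T1",
                       species="Plankt minutus", size_class_cm=6,
                       abundance_class=3),
    ]
    return SurveyDataset(records=records, traits=mini_traits)
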