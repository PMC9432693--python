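"""Shared fixtures: small hand-built capture tables, traits, and survey designs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from retdiv.capture_data import CAPTURE_COLUMNS, CaptureTable, SurveyDesign


def make_record(**kwargs) -> dict:
    base = {
        "block": "B01",
        "stand": "B01-RA",
        "treatment": "RA",
        "subplot": "B01-RA-G1",
        "cover_type": "patch",
        "patch_context": "riparian",
        "year": 1,
        "week": 3,
        "occasion": 1,
        "species": "PERMAN",
        "individual_tag": None,
        "tail_mm": np.nan,
        "mass_g": 20.0,
    }
    base.update(kwargs)
    return base


def make_table(records: list[dict], registry=None) -> CaptureTable:
    df = pd.DataFrame(records, columns=list(CAPTURE_COLUMNS))
    if registry is None:
        registry = frozenset(df["species"]) | {"PERMAN", "SORTRO", "DIDVIR"}
    return CaptureTable(records=df, species_registry=frozenset(registry))


@pytest.fixture
def registry() -> frozenset:
    return frozenset(
        {"PERMAN", "PERKEE", "SORTRO", "SORVAG", "SORSPP", "NEOTOW", "MICORE",
         "GLAORE", "TAMHUD", "DIDVIR", "NEOCIN", "MYOCAL"}
    )


@pytest.fixture
def small_table(registry) -> CaptureTable:
    """Two stands, two years; includes a tagged recapture and untagged shrews."""
    recs = [
        make_record(species="PERMAN", individual_tag="t1", occasion=1),
        make_record(species="PERMAN", individual_tag="t1", occasion=3),  # recapture
        make_record(species="PERMAN", individual_tag="t2", occasion=2,
                    cover_type="clearcut", patch_context="none", subplot="B01-RA-G2"),
        make_record(species="SORTRO", occasion=1),
        make_record(species="SORTRO", occasion=2),  # untagged: new individual
        make_record(species="NEOTOW", individual_tag="t3", occasion=4),
        make_record(species="DIDVIR", individual_tag="t4", occasion=1),
        make_record(species="DIDVIR", individual_tag="t5", occasion=2, year=2, week=8),
        make_record(species="GLAORE", individual_tag="t6", occasion=2),
        make_record(species="MICORE", individual_tag="t7", occasion=1,
                    stand="B02-UA", block="B02", treatment="UA",
                    cover_type="patch", patch_context="upland", subplot="B02-UA-G1"),
    ]
    return make_table(recs, registry)


@pytest.fixture
def tiny_design() -> SurveyDesign:
    units = pd.DataFrame(
        [
            {"unit": "B01-RA-G1:1", "block": "B01", "stand": "B01-RA",
             "treatment": "RA", "subplot": "B01-RA-G1", "cover_type": "patch",
             "patch_context": "riparian", "subplot_class": "riparian_patch",
             "year": 1, "week": 3, "occasions_sampled": 4},
            {"unit": "B01-RA-G2:1", "block": "B01", "stand": "B01-RA",
             "treatment": "RA", "subplot": "B01-RA-G2", "cover_type": "clearcut",
             "patch_context": "none", "subplot_class": "clearcut",
             "year": 1, "week": 3, "occasions_sampled": 4},
            {"unit": "B01-RA-G1:2", "block": "B01", "stand": "B01-RA",
             "treatment": "RA", "subplot": "B01-RA-G1", "cover_type": "patch",
             "patch_context": "riparian", "subplot_class": "riparian_patch",
             "year": 2, "week": 8, "occasions_sampled": 3},
            {"unit": "B02-UA-G1:1", "block": "B02", "stand": "B02-UA",
             "treatment": "UA", "subplot": "B02-UA-G1", "cover_type": "patch",
             "patch_context": "upland", "subplot_class": "upland_patch",
             "year": 1, "week": 4, "occasions_sampled": 4},
        ]
    )
    return SurveyDesign(units=units)
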