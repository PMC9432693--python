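"""Capture records, survey design, and the study's cleaning/classification rules.

Live-trapping data arrive as long-format CSV, one capture event per row,
anchored to the block / stand / subplot / occasion hierarchy of the
experiment.  This module provides the in-memory containers (thin wrappers
around :class:`pandas.DataFrame` / :class:`numpy.ndarray`), the CSV reader
with row-level validation, and the field rules used to clean and classify
captures:

* tail-length classification of ambiguous shrews and *Peromyscus* mice,
* the "captured more than once" species filter for richness analyses,
* per-unit abundance tallies at the stand and cover-type scales
  (tagged individuals deduplicated, untagged shrews counted per capture),
* species x unit x occasion detection histories for occupancy modelling,
* vegetation cover-class midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

TREATMENTS = ("RA", "UA", "S", "SS", "DS", "ROT")
COVER_TYPES = ("patch", "clearcut", "rotation")
PATCH_CONTEXTS = ("riparian", "upland", "none")
#: Grid-location classes used as the occupancy covariate; clearcut is reference.
SUBPLOT_CLASSES = ("clearcut", "upland_patch", "riparian_patch", "rotation")
N_OCCASIONS = 4

#: Columns of a capture CSV, in order. ``individual_tag``, ``tail_mm`` and
#: ``mass_g`` may be empty.
CAPTURE_COLUMNS = (
    "block",
    "stand",
    "treatment",
    "subplot",
    "cover_type",
    "patch_context",
    "year",
    "week",
    "occasion",
    "species",
    "individual_tag",
    "tail_mm",
    "mass_g",
)

#: Midpoints (percent) of the seven ground-vegetation cover classes.
COVER_CLASS_MIDPOINTS = (0.5, 3.0, 15.0, 37.5, 62.5, 85.0, 97.5)

#: Species codes produced by the shrew tail-length rule.
VAGRANT_SHREW = "SORVAG"
POOLED_SHREW = "SORSPP"
KEENS_MOUSE = "PERKEE"
DEER_MOUSE = "PERMAN"


class CaptureDataError(ValueError):
    """Structured error for malformed or inconsistent capture data."""


def subplot_class(cover_type: str, patch_context: str) -> str:
    """Map (cover_type, patch_context) to the grid-location class.

    clearcut -> ``clearcut``; patch in riparian context -> ``riparian_patch``;
    patch in upland context -> ``upland_patch``; rotation-aged forest ->
    ``rotation``.
    """
    if cover_type == "clearcut":
        return "clearcut"
    if cover_type == "rotation":
        return "rotation"
    if cover_type == "patch":
        if patch_context == "riparian":
            return "riparian_patch"
        if patch_context == "upland":
            return "upland_patch"
        raise CaptureDataError(
            f"patch cover type requires riparian/upland context, got {patch_context!r}"
        )
    raise CaptureDataError(f"unknown cover type {cover_type!r}")


@dataclass(frozen=True)
class CaptureTable:
    """Ordered collection of capture events plus the valid species registry.

    ``records`` is a DataFrame with :data:`CAPTURE_COLUMNS`.  Every record's
    species code must belong to ``species_registry``; occasions are 1..4.
    """

    records: pd.DataFrame
    species_registry: frozenset[str]

    def __post_init__(self) -> None:
        df = self.records
        missing = set(CAPTURE_COLUMNS) - set(df.columns)
        if missing:
            raise CaptureDataError(f"capture table missing columns: {sorted(missing)}")
        bad_species = set(df["species"]) - set(self.species_registry)
        if bad_species:
            raise CaptureDataError(f"species codes not in registry: {sorted(bad_species)}")
        occ = df["occasion"]
        if len(df) and not occ.isin(range(1, N_OCCASIONS + 1)).all():
            bad = df.loc[~occ.isin(range(1, N_OCCASIONS + 1))].index[0]
            raise CaptureDataError(f"row {bad}: occasion must be in 1..{N_OCCASIONS}")
        for col in ("tail_mm", "mass_g"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if (vals.dropna() < 0).any():
                raise CaptureDataError(f"negative {col} present")
        rot_mismatch = (df["cover_type"].eq("rotation")) != (df["treatment"].eq("ROT"))
        if len(df) and rot_mismatch.any():
            bad = df.loc[rot_mismatch].index[0]
            raise CaptureDataError(
                f"row {bad}: cover_type 'rotation' must coincide with treatment 'ROT'"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_species_observed(self) -> int:
        return self.records["species"].nunique()

    def individuals(self) -> pd.DataFrame:
        """One row per individual with its first-capture context.

        Tagged animals are identified by (species, individual_tag) and
        deduplicated to their first capture (records are assumed to be in
        chronological order within year/occasion; we sort by year, week,
        occasion to be safe).  Untagged captures (shrews by protocol) each
        count as a new individual.
        """
        df = self.records.sort_values(
            ["year", "week", "occasion"], kind="stable"
        ).reset_index(drop=True)
        tag = df["individual_tag"]
        tagged = df[tag.notna() & (tag.astype(str) != "")]
        untagged = df[~(tag.notna() & (tag.astype(str) != ""))]
        # a tagged individual is one per (species, tag) study-wide, but may be
        # counted once per stand-year unit downstream; keep all its captures'
        # context via first occurrence per (species, tag, year)
        first_any = tagged.drop_duplicates(subset=["species", "individual_tag"])
        return pd.concat([first_any, untagged], ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False, columns=list(CAPTURE_COLUMNS))


@dataclass(frozen=True)
class AbundanceTally:
    """Species -> individual counts for one estimation unit.

    The unit is a stand-year (stand scale) or a stand-year x cover type
    (cover-type scale).  ``meta`` carries the unit covariates used by the
    downstream richness models.
    """

    unit: str
    counts: Mapping[str, int]
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise CaptureDataError(f"unit {self.unit}: negative count")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class SurveyDesign:
    """Enumeration of all subplot-years in the survey, sampled or not.

    ``units`` has one row per subplot-year with columns: ``unit`` (identifier),
    ``block``, ``stand``, ``treatment``, ``subplot``, ``cover_type``,
    ``patch_context``, ``subplot_class``, ``year``, ``week``, and
    ``occasions_sampled`` (how many of the 4 nights were realized; fewer than
    4 flags the remaining occasions as missing, never zero).
    """

    units: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "unit",
            "stand",
            "subplot",
            "subplot_class",
            "year",
            "week",
            "occasions_sampled",
        }
        missing = required - set(self.units.columns)
        if missing:
            raise CaptureDataError(f"survey design missing columns: {sorted(missing)}")
        if self.units["unit"].duplicated().any():
            raise CaptureDataError("duplicate unit identifiers in survey design")

    def __len__(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class DetectionArray:
    """Binary species x unit x occasion detection histories.

    ``y[i, j, k]`` is 1 if species ``i`` was captured at unit ``j`` on
    occasion ``k``, 0 if sampled without capture, and NaN if occasion ``k``
    was not realized at that unit (missing, never zero).
    """

    y: np.ndarray  # float array with NaN for missing
    species: tuple[str, ...]
    units: pd.DataFrame  # one row per unit, aligned with axis 1 of y

    def __post_init__(self) -> None:
        if self.y.ndim != 3:
            raise CaptureDataError("detection array must be 3-dimensional")
        vals = self.y[~np.isnan(self.y)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise CaptureDataError("detection array entries must be 0, 1, or NaN")
        if self.y.shape[0] != len(self.species) or self.y.shape[1] != len(self.units):
            raise CaptureDataError("detection array axes do not match species/units")

    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def n_units(self) -> int:
        return self.y.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[2]


def read_captures(path: str | Path, registry: Iterable[str]) -> CaptureTable:
    """Read a capture CSV, validating every row against the registry.

    The dialect is UTF-8, comma-separated, required header matching
    :data:`CAPTURE_COLUMNS`.  Errors name the offending row (0-based data
    row index) and the problem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    registry = frozenset(registry)
    df = pd.read_csv(path, dtype={"individual_tag": "string", "species": "string"})
    got = tuple(df.columns)
    if got != CAPTURE_COLUMNS:
        raise CaptureDataError(
            f"unexpected header {list(got)}; expected {list(CAPTURE_COLUMNS)}"
        )
    for col in ("year", "week", "occasion"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise CaptureDataError(f"row {row}: non-integer {col}")
        df[col] = vals.astype(int)
    bad_occ = ~df["occasion"].isin(range(1, N_OCCASIONS + 1))
    if bad_occ.any():
        row = int(df.index[bad_occ][0])
        raise CaptureDataError(
            f"row {row}: occasion {df.loc[row, 'occasion']} outside 1..{N_OCCASIONS}"
        )
    df["species"] = df["species"].astype(str)
    unknown = ~df["species"].isin(registry)
    if unknown.any():
        row = int(df.index[unknown][0])
        raise CaptureDataError(
            f"row {row}: unknown species code {df.loc[row, 'species']!r}"
        )
    for col in ("tail_mm", "mass_g"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["individual_tag"] = df["individual_tag"].where(
        df["individual_tag"].notna() & (df["individual_tag"].astype(str) != ""), None
    )
    return CaptureTable(records=df, species_registry=registry)


def read_species_registry(path: str | Path) -> frozenset[str]:
    """Read the species registry CSV (column ``species``)."""
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise CaptureDataError("species registry CSV must have a 'species' column")
    return frozenset(df["species"].astype(str))


def classify_shrew(tail_mm: float) -> str:
    """Classify a shrew by tail length.

    Tail length below 42 mm identifies the vagrant shrew (*Sorex vagrans*),
    characteristic of open habitats; all longer-tailed unidentified shrews
    are pooled into the single ambiguous code ``SORSPP`` (four largely
    allopatric *Sorex* species not separable in the field).
    """
    if tail_mm <= 0:
        raise ValueError(f"tail length must be positive, got {tail_mm}")
    return VAGRANT_SHREW if tail_mm < 42.0 else POOLED_SHREW


def classify_peromyscus(tail_mm: float, region: Literal["WA", "OR"]) -> str:
    """Classify a deer mouse by tail length, applying the rule only in Washington.

    In the Washington blocks, tail length >= 95 mm identifies Keen's mouse
    (*Peromyscus keeni*); shorter-tailed animals are the American deer mouse
    (*P. maniculatus*).  In Oregon only *P. maniculatus* occurs, so every
    animal is classified as such regardless of tail length.
    """
    if tail_mm <= 0:
        raise ValueError(f"tail length must be positive, got {tail_mm}")
    if region not in ("WA", "OR"):
        raise ValueError(f"region must be 'WA' or 'OR', got {region!r}")
    if region == "OR":
        return DEER_MOUSE
    return KEENS_MOUSE if tail_mm >= 95.0 else DEER_MOUSE


def _individual_totals(table: CaptureTable) -> pd.Series:
    """Study-wide individuals per species (tagged deduped, untagged per capture)."""
    ind = table.individuals()
    return ind.groupby("species").size()


def filter_richness_species(
    table: CaptureTable, exclude: Iterable[str] = ()
) -> set[str]:
    """Species retained for richness analyses.

    Keeps species with at least 2 captured individuals study-wide and drops
    any code in ``exclude`` (used for the non-native Virginia opossum, which
    is excluded despite its two captures).
    """
    if len(table) == 0:
        return set()
    totals = _individual_totals(table)
    keep = set(totals.index[totals >= 2])
    return keep - set(exclude)


def tally_abundance(
    table: CaptureTable, scale: Literal["stand", "cover_type"]
) -> list[AbundanceTally]:
    """Per-unit species abundance tallies at one of the two estimation scales.

    Units are stand-years (``scale="stand"``) or stand-year x cover type
    (``scale="cover_type"``).  A tagged individual is counted once per unit;
    for the cover-type scale an individual recaptured in both patch and
    clearcut is attributed to the cover type of its first capture, so the
    cover-type tallies of a stand-year partition its stand-scale tally.
    Untagged shrews are counted per capture (every captured shrew treated
    as a new individual).
    """
    if scale not in ("stand", "cover_type"):
        raise ValueError(f"scale must be 'stand' or 'cover_type', got {scale!r}")
    if len(table) == 0:
        return []
    df = table.records.sort_values(["year", "week", "occasion"], kind="stable")
    tag = df["individual_tag"]
    has_tag = tag.notna() & (tag.astype(str) != "")
    # dedupe tagged individuals within stand-year to first capture; untagged
    # captures each count
    tagged = df[has_tag].drop_duplicates(subset=["species", "individual_tag", "stand", "year"])
    individuals = pd.concat([tagged, df[~has_tag]], ignore_index=True)

    keys = ["stand", "year"] if scale == "stand" else ["stand", "year", "cover_type"]
    tallies: list[AbundanceTally] = []
    for key_vals, grp in individuals.groupby(keys, sort=True):
        unit = ":".join(str(v) for v in key_vals)
        counts = grp.groupby("species").size().to_dict()
        meta = {
            "stand": key_vals[0],
            "year": int(key_vals[1]),
            "block": grp["block"].iloc[0],
            "treatment": grp["treatment"].iloc[0],
            "week": int(grp["week"].iloc[0]),
        }
        if scale == "cover_type":
            meta["cover_type"] = key_vals[2]
        tallies.append(AbundanceTally(unit=unit, counts=counts, meta=meta))
    return tallies


def build_detection_histories(
    table: CaptureTable, design: SurveyDesign
) -> DetectionArray:
    """Species x subplot-year x occasion binary detection histories.

    ``y[i,j,k] = 1`` iff at least one capture of species ``i`` occurred at
    unit ``j`` on occasion ``k`` (idempotent under duplicate records).
    Occasions beyond a unit's ``occasions_sampled`` are NaN (missing), e.g.
    the stand trapped for only three nights in one year.  Species axis is the
    sorted registry of species observed in the table; pass the table through
    the richness filter first if a restricted community is wanted.
    """
    units = design.units.reset_index(drop=True)
    unit_index = {u: j for j, u in enumerate(units["unit"])}
    species = tuple(sorted(table.records["species"].unique())) if len(table) else ()
    sp_index = {s: i for i, s in enumerate(species)}

    y = np.zeros((len(species), len(units), N_OCCASIONS), dtype=float)
    occ_sampled = units["occasions_sampled"].to_numpy(dtype=int)
    for j in range(len(units)):
        y[:, j, occ_sampled[j]:] = np.nan

    if len(table):
        df = table.records
        rec_units = (
            df["subplot"].astype(str) + ":" + df["year"].astype(str)
        )
        for row, (unit, sp, occ) in enumerate(
            zip(rec_units, df["species"], df["occasion"])
        ):
            j = unit_index.get(unit)
            if j is None:
                raise CaptureDataError(
                    f"row {row}: capture at unit {unit!r} absent from survey design"
                )
            k = int(occ) - 1
            if k >= occ_sampled[j]:
                raise CaptureDataError(
                    f"row {row}: capture on unsampled occasion {occ} at unit {unit!r}"
                )
            y[sp_index[sp], j, k] = 1.0
    return DetectionArray(y=y, species=species, units=units)


def capture_summary(table: CaptureTable, k: int) -> float:
    """Share (percent) of all individuals belonging to the ``k`` most-captured species."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(table) == 0:
        raise ValueError("capture table is empty")
    totals = _individual_totals(table)
    if k > len(totals):
        raise ValueError(f"k={k} exceeds the {len(totals)} species observed")
    return dominance_share(totals.to_dict(), k)


def dominance_share(totals: Mapping[str, int] | Sequence[int], k: int) -> float:
    """Percent of individuals in the ``k`` largest per-species totals.

    Accepts either a species->count mapping or a bare sequence of counts, so
    published per-species totals can be summarised directly.
    """
    counts = sorted(
        (totals.values() if isinstance(totals, Mapping) else totals), reverse=True
    )
    if k < 1 or k > len(counts):
        raise ValueError(f"k={k} out of range for {len(counts)} species")
    total = sum(counts)
    if total == 0:
        raise ValueError("no individuals")
    return 100.0 * sum(counts[:k]) / total


def cover_class_midpoint(class_index: int) -> float:
    """Midpoint percent cover of vegetation cover class 1..7."""
    if not 1 <= class_index <= 7:
        raise ValueError(f"cover class index must be 1..7, got {class_index}")
    return COVER_CLASS_MIDPOINTS[class_index - 1]
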