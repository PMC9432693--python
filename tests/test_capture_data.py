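"""Cleaning, classification and tallying rules for capture records."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from retdiv.capture_data import (
    CAPTURE_COLUMNS,
    CaptureDataError,
    CaptureTable,
    build_detection_histories,
    capture_summary,
    classify_peromyscus,
    classify_shrew,
    cover_class_midpoint,
    dominance_share,
    filter_richness_species,
    read_captures,
    subplot_class,
    tally_abundance,
)
from tests.conftest import make_record, make_table


class TestReader:
    def test_header_only_file_gives_empty_table(self, tmp_path, registry):
        p = tmp_path / "c.csv"
        p.write_text(",".join(CAPTURE_COLUMNS) + "\n")
        table = read_captures(p, registry)
        assert len(table) == 0

    def test_round_trip_preserves_rows(self, tmp_path, small_table, registry):
        p = tmp_path / "c.csv"
        small_table.to_csv(p)
        back = read_captures(p, registry)
        assert len(back) == len(small_table)
        assert list(back.records["species"]) == list(small_table.records["species"])

    def test_unknown_species_names_row_and_code(self, tmp_path, small_table):
        p = tmp_path / "c.csv"
        small_table.to_csv(p)
        with pytest.raises(CaptureDataError, match=r"row 0.*'PERMAN'"):
            read_captures(p, registry={"SORTRO"})

    def test_occasion_out_of_range_rejected(self, tmp_path, registry):
        p = tmp_path / "c.csv"
        df = pd.DataFrame([make_record(occasion=5)], columns=list(CAPTURE_COLUMNS))
        df.to_csv(p, index=False)
        with pytest.raises(CaptureDataError, match="occasion 5"):
            read_captures(p, registry)

    def test_wrong_header_rejected(self, tmp_path, registry):
        p = tmp_path / "c.csv"
        p.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(CaptureDataError, match="header"):
            read_captures(p, registry)


class TestClassification:
    @pytest.mark.parametrize(
        "tail,expected",
        [(41.0, "SORVAG"), (41.9, "SORVAG"), (42.0, "SORSPP"), (60.0, "SORSPP")],
    )
    def test_shrew_tail_rule(self, tail, expected):
        # below 42 mm -> vagrant shrew; at or above -> pooled ambiguous code
        assert classify_shrew(tail) == expected

    @pytest.mark.parametrize(
        "tail,region,expected",
        [
            (95.0, "WA", "PERKEE"),
            (94.9, "WA", "PERMAN"),
            (120.0, "WA", "PERKEE"),
            (120.0, "OR", "PERMAN"),  # rule applies only in Washington blocks
            (50.0, "OR", "PERMAN"),
        ],
    )
    def test_peromyscus_tail_rule(self, tail, region, expected):
        assert classify_peromyscus(tail, region) == expected

    @pytest.mark.parametrize("func", [classify_shrew])
    def test_nonpositive_tail_rejected(self, func):
        with pytest.raises(ValueError):
            func(-1.0)
        with pytest.raises(ValueError):
            func(0.0)

    def test_peromyscus_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_peromyscus(-1.0, "WA")
        with pytest.raises(ValueError):
            classify_peromyscus(50.0, "CA")


class TestRichnessFilter:
    def test_singletons_excluded_and_exclusion_list_applied(self, small_table):
        kept = filter_richness_species(small_table, exclude={"DIDVIR"})
        # PERMAN 2 tagged ind, SORTRO 2 untagged captures -> kept;
        # DIDVIR has 2 ind but is excluded; the rest are singletons
        assert kept == {"PERMAN", "SORTRO"}

    def test_doubleton_without_exclusion_is_retained(self, small_table):
        assert "DIDVIR" in filter_richness_species(small_table)

    def test_empty_table_gives_empty_set(self, registry):
        empty = make_table([], registry)
        assert filter_richness_species(empty) == set()

    def test_monotone_under_added_captures(self, small_table, registry):
        base = filter_richness_species(small_table, exclude={"DIDVIR"})
        extra = small_table.records.to_dict("records") + [
            make_record(species="GLAORE", individual_tag="t9", occasion=3)
        ]
        bigger = filter_richness_species(make_table(extra, registry), exclude={"DIDVIR"})
        assert base <= bigger


class TestTally:
    def test_recaptured_individual_counted_once_per_stand_year(self, small_table):
        tallies = {t.unit: t for t in tally_abundance(small_table, "stand")}
        assert tallies["B01-RA:1"].counts["PERMAN"] == 2  # t1 (recaptured) + t2

    def test_untagged_shrews_counted_per_capture(self, small_table):
        tallies = {t.unit: t for t in tally_abundance(small_table, "stand")}
        assert tallies["B01-RA:1"].counts["SORTRO"] == 2

    def test_empty_table_gives_no_tallies(self, registry):
        assert tally_abundance(make_table([], registry), "stand") == []

    def test_cover_type_tallies_partition_stand_totals(self, small_table):
        stand = {t.unit: t.total for t in tally_abundance(small_table, "stand")}
        cover = tally_abundance(small_table, "cover_type")
        by_stand_year: dict[str, int] = {}
        for t in cover:
            key = f"{t.meta['stand']}:{t.meta['year']}"
            by_stand_year[key] = by_stand_year.get(key, 0) + t.total
        assert by_stand_year == stand

    def test_cross_cover_recapture_attributed_to_first_capture(self, registry):
        recs = [
            make_record(species="PERMAN", individual_tag="t1", occasion=1,
                        cover_type="patch", patch_context="riparian"),
            make_record(species="PERMAN", individual_tag="t1", occasion=3,
                        cover_type="clearcut", patch_context="none",
                        subplot="B01-RA-G2"),
        ]
        cover = tally_abundance(make_table(recs, registry), "cover_type")
        counts = {t.unit: t.total for t in cover}
        assert counts == {"B01-RA:1:patch": 1}


class TestDetectionHistories:
    def test_no_captures_gives_zero_array_with_missing_flags(self, tiny_design, registry):
        det = build_detection_histories(make_table([], registry), tiny_design)
        assert det.y.shape == (0, 4, 4)

    def test_detections_marked_on_capture_occasions_only(self, small_table, tiny_design):
        det = build_detection_histories(small_table, tiny_design)
        i = det.species.index("PERMAN")
        j = list(det.units["unit"]).index("B01-RA-G1:1")
        assert det.y[i, j].tolist() == [1.0, 0.0, 1.0, 0.0]

    def test_idempotent_under_duplicate_records(self, small_table, tiny_design, registry):
        doubled = make_table(
            small_table.records.to_dict("records") * 2, registry
        )
        det1 = build_detection_histories(small_table, tiny_design)
        det2 = build_detection_histories(doubled, tiny_design)
        assert np.array_equal(det1.y, det2.y, equal_nan=True)

    def test_unsampled_occasions_are_missing_not_zero(self, small_table, tiny_design):
        det = build_detection_histories(small_table, tiny_design)
        j = list(det.units["unit"]).index("B01-RA-G1:2")  # 3-night unit
        assert np.isnan(det.y[:, j, 3]).all()
        assert not np.isnan(det.y[:, j, :3]).any()

    def test_capture_at_unknown_unit_rejected(self, tiny_design, registry):
        stray = make_table([make_record(subplot="NOPE", year=1)], registry)
        with pytest.raises(CaptureDataError, match="NOPE"):
            build_detection_histories(stray, tiny_design)


class TestSummaries:
    def test_dominance_share_matches_published_totals(self):
        # the four commonest species of 5,150 captured individuals
        top = [2065, 1434, 656, 252]
        rest = 5150 - sum(top)
        totals = top + [rest // 20] * 19 + [rest // 20 + rest % 20]
        assert dominance_share(totals, 4) == pytest.approx(100 * 4407 / 5150, abs=1e-9)
        assert dominance_share(totals, 4) == pytest.approx(85.57, abs=0.01)

    def test_single_species_is_all_of_the_catch(self, registry):
        t = make_table([make_record(species="PERMAN", individual_tag="t1")], registry)
        assert capture_summary(t, 1) == 100.0

    def test_equal_counts_k2(self):
        assert dominance_share({"a": 5, "b": 5}, 2) == 100.0

    def test_k_beyond_species_count_rejected(self, registry):
        t = make_table([make_record(species="PERMAN", individual_tag="t1")], registry)
        with pytest.raises(ValueError):
            capture_summary(t, 2)


class TestCoverClasses:
    @pytest.mark.parametrize(
        "idx,mid", [(1, 0.5), (2, 3.0), (3, 15.0), (4, 37.5), (5, 62.5), (6, 85.0), (7, 97.5)]
    )
    def test_midpoints(self, idx, mid):
        assert cover_class_midpoint(idx) == mid

    @pytest.mark.parametrize("idx", [0, 8, -1])
    def test_out_of_range_rejected(self, idx):
        with pytest.raises(ValueError):
            cover_class_midpoint(idx)


def test_subplot_class_mapping():
    assert subplot_class("clearcut", "none") == "clearcut"
    assert subplot_class("patch", "riparian") == "riparian_patch"
    assert subplot_class("patch", "upland") == "upland_patch"
    assert subplot_class("rotation", "none") == "rotation"
    with pytest.raises(CaptureDataError):
        subplot_class("patch", "none")


def test_rotation_cover_requires_rotation_treatment(registry):
    with pytest.raises(CaptureDataError, match="rotation"):
        make_table(
            [make_record(cover_type="rotation", patch_context="none")], registry
        )
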