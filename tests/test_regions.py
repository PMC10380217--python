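"""Region mapping, extraction, length tables and LVR L subdivision."""

import pytest

from lvr.alignment import Alignment
from lvr.regions import (
    PAIRED_SUBREGIONS,
    SUBREGION_ORDER,
    Region,
    RegionAnnotation,
    SubregionTemplate,
    collapse_by_group,
    extract_region,
    format_value_set,
    map_region_to_columns,
    parse_value_set,
    read_annotation,
    region_length_table,
    subdivide_lvr_l,
    write_annotation,
)


@pytest.fixture
def simple_alignment():
    return Alignment((("ref", "AC-GT"), ("s2", "ACAGT")))


class TestMapping:
    def test_gap_skip_arithmetic(self, simple_alignment):
        ann = RegionAnnotation("ref", (Region("R1", 2, 3),))
        spans = map_region_to_columns(simple_alignment, ann)
        # ungapped ref "ACGT": residues 2..3 are C (col 1) and G (col 3);
        # the span runs to the column of residue 4 (T, col 4)
        assert spans["R1"] == (1, 4)

    def test_empty_region_convention(self, simple_alignment):
        ann = RegionAnnotation("ref", (Region("G", 3, 2),))
        lo, hi = map_region_to_columns(simple_alignment, ann)["G"]
        assert lo == hi

    def test_last_residue_extends_to_alignment_end(self):
        aln = Alignment((("ref", "ACG--"), ("s2", "ACGTT")))
        ann = RegionAnnotation("ref", (Region("R1", 2, 3),))
        assert map_region_to_columns(aln, ann)["R1"] == (1, 5)

    def test_reference_absent_rejected(self, simple_alignment):
        ann = RegionAnnotation("nope", (Region("R1", 1, 2),))
        with pytest.raises(ValueError, match="absent"):
            map_region_to_columns(simple_alignment, ann)

    def test_coordinate_beyond_reference_rejected(self, simple_alignment):
        ann = RegionAnnotation("ref", (Region("R1", 2, 9),))
        with pytest.raises(ValueError, match="beyond"):
            map_region_to_columns(simple_alignment, ann)

    def test_planted_coordinates_recovered(self, cohort):
        spans = map_region_to_columns(cohort.alignment, cohort.annotation)
        ref = cohort.alignment.sequence(cohort.annotation.reference_id)
        for region in cohort.annotation.regions:
            lo, hi = spans[region.region_id]
            residues = ref[lo:hi].replace("-", "")
            assert len(residues) == region.length


class TestExtraction:
    def test_identity_sequence(self, simple_alignment):
        ann = RegionAnnotation("ref", (Region("R1", 2, 3),))
        assert extract_region(simple_alignment, ann, "R1", "ref") == "CG"

    def test_deletion_shortens_by_three(self):
        aln = Alignment((("ref", "AACCGGTT"), ("s2", "AA---GTT")))
        ann = RegionAnnotation("ref", (Region("R1", 2, 7),))
        assert len(extract_region(aln, ann, "R1", "ref")) == 6
        assert len(extract_region(aln, ann, "R1", "s2")) == 3

    def test_unknown_ids_rejected(self, simple_alignment):
        ann = RegionAnnotation("ref", (Region("R1", 2, 3),))
        with pytest.raises(KeyError):
            extract_region(simple_alignment, ann, "nope", "ref")
        with pytest.raises(KeyError):
            extract_region(simple_alignment, ann, "R1", "nope")

    def test_cohort_lengths_match_planted_truth(self, cohort):
        for row in cohort.region_table.itertuples(index=False):
            got = extract_region(
                cohort.alignment, cohort.annotation, "X", row.sequence_id
            )
            assert len(got) == row.X


class TestLengthTable:
    def test_missing_group_assignment_listed(self, cohort):
        groups = dict(cohort.groups)
        groups.pop("Tingini_03")
        with pytest.raises(ValueError, match="Tingini_03"):
            region_length_table(cohort.alignment, cohort.annotation, groups)

    def test_cohort_table_equals_truth(self, cohort):
        table = region_length_table(
            cohort.alignment, cohort.annotation, cohort.groups
        )
        for col in cohort.region_table.columns:
            assert list(table[col]) == list(cohort.region_table[col])

    def test_group_collapse_sets(self, cohort):
        table = region_length_table(
            cohort.alignment, cohort.annotation, cohort.groups
        )
        collapsed = collapse_by_group(table)
        assert collapsed["Acalyptaini"]["X"] == frozenset({3, 4})
        assert collapsed["Litadeini"]["X"] == frozenset({6})
        assert collapsed["Cantacaderinae"]["L"] == frozenset({57})

    def test_single_sequence_sets_are_singletons(self, cohort):
        table = region_length_table(
            cohort.alignment, cohort.annotation, cohort.groups
        )
        collapsed = collapse_by_group(table)
        for region, values in collapsed["Litadeini"].items():
            assert len(values) == 1, region

    def test_gap_columns_outside_region_do_not_matter(self, cohort):
        spans = map_region_to_columns(cohort.alignment, cohort.annotation)
        lo, _ = spans["L"]
        padded = Alignment(
            tuple(
                (sid, seq[: lo - 5] + "-" + seq[lo - 5 :])
                for sid, seq in cohort.alignment.records
            )
        )
        table = region_length_table(padded, cohort.annotation, cohort.groups)
        for col in ("L", "X", "V4"):
            assert list(table[col]) == list(cohort.region_table[col])


class TestValueSets:
    @pytest.mark.parametrize(
        "values,text", [({3}, "3"), ({3, 4}, "3-4"), ({60, 63, 78}, "60-78")]
    )
    def test_format(self, values, text):
        assert format_value_set(values) == text

    @pytest.mark.parametrize(
        "text,values",
        [("5", {5}), ("3-4", {3, 4}), ("3–4", {3, 4}), ("60-62", {60, 61, 62})],
    )
    def test_parse(self, text, values):
        assert parse_value_set(text) == frozenset(values)

    def test_descending_range_rejected(self):
        with pytest.raises(ValueError):
            parse_value_set("5-3")


class TestSubdivision:
    def test_template_must_tile(self):
        segments = list(
            Region(lbl, i * 2 + 1, i * 2 + 2) for i, lbl in enumerate(SUBREGION_ORDER)
        )
        tmpl = SubregionTemplate(tuple(segments))
        assert tmpl.total_length == 22
        bad = segments.copy()
        bad[3] = Region(bad[3].region_id, bad[3].start + 1, bad[3].end)
        with pytest.raises(ValueError, match="tile"):
            SubregionTemplate(tuple(bad))

    def test_reference_counts_equal_template_lengths(self, cohort):
        ref = cohort.annotation.reference_id
        counts = subdivide_lvr_l(ref, cohort.alignment, cohort.annotation, cohort.template)
        for seg in cohort.template.segments:
            assert counts[seg.region_id] == seg.length

    def test_litadeini_planted_vector_recovered(self, cohort):
        counts = subdivide_lvr_l(
            "Litadeini_01", cohort.alignment, cohort.annotation, cohort.template
        )
        assert (
            counts["L2"],
            counts["LA"],
            counts["LB"],
            counts["LC"],
            counts["LD"],
            counts["LE"],
        ) == (4, 19, 24, 8, 10, 16)
        assert counts["total"] == 81

    def test_deleted_subregion_counts_zero(self, cohort):
        counts = subdivide_lvr_l(
            "Cantacaderinae_01", cohort.alignment, cohort.annotation, cohort.template
        )
        assert counts["LB"] == 0
        for name in ("L2", "LA", "LC", "LD", "LE"):
            assert counts[name] > 0

    def test_sum_property_for_every_sequence(self, cohort):
        for sid in cohort.alignment.ids:
            counts = subdivide_lvr_l(
                sid, cohort.alignment, cohort.annotation, cohort.template
            )
            assert counts["total"] == sum(
                counts[lbl] for lbl in SUBREGION_ORDER
            )
            for name in PAIRED_SUBREGIONS:
                half = name[1]
                assert counts[name] == counts[f"{half}1"] + counts[f"{half}2"]

    def test_deleting_k_residues_reduces_one_subregion_by_k(self, cohort):
        sid = "Outgroup_02"
        spans = map_region_to_columns(cohort.alignment, cohort.annotation)
        lo, _ = spans["L"]
        # the B1 segment of the outgroup starts 13 residues into LVR L
        seq = cohort.alignment.sequence(sid)
        cols = [i for i in range(lo, len(seq)) if seq[i] != "-"]
        target = cols[13:16]  # three residues inside B1
        edited = "".join(
            "-" if i in target else c for i, c in enumerate(seq)
        )
        mutated = Alignment(
            tuple(
                (rid, edited if rid == sid else s)
                for rid, s in cohort.alignment.records
            )
        )
        before = subdivide_lvr_l(sid, cohort.alignment, cohort.annotation, cohort.template)
        after = subdivide_lvr_l(sid, mutated, cohort.annotation, cohort.template)
        assert after["B1"] == before["B1"] - 3
        for key in before:
            if key not in ("B1", "LB", "total"):
                assert after[key] == before[key], key

    def test_non_tiling_template_rejected_against_lvr_l(self, cohort):
        short = SubregionTemplate(
            tuple(
                Region(lbl, i + 1, i + 1) for i, lbl in enumerate(SUBREGION_ORDER)
            )
        )
        with pytest.raises(ValueError, match="does not tile"):
            subdivide_lvr_l(
                "Outgroup_01", cohort.alignment, cohort.annotation, short
            )


class TestAnnotationIO:
    def test_round_trip(self, tmp_path, cohort):
        p = tmp_path / "regions.tsv"
        write_annotation(cohort.annotation, p)
        back = read_annotation(p)
        assert back == cohort.annotation

    def test_missing_reference_rejected(self, tmp_path):
        p = tmp_path / "regions.tsv"
        p.write_text("region_id\tstart\tend\nB\t5\t10\n")
        with pytest.raises(ValueError, match="reference"):
            read_annotation(p)
        assert read_annotation(p, reference_id="r").reference_id == "r"
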