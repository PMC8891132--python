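"""Mutation classification, cohort filtering and contingency construction."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from csbayes.cohort import (
    AMBIGUOUS_LABELS,
    ConsistencyError,
    ContingencyTable,
    MalformedRecordError,
    MutationDescriptor,
    MutationGroup,
    PatientRecord,
    Region,
    SeverityLevel,
    SubtypeLabel,
    VariantClass,
    VariantGroup,
    build_contingency,
    classify_pair,
    classify_position,
    classify_position_full,
    classify_variant_group,
    filter_analyzable,
    read_cohort,
    record_from_row,
    variant_class_from_consequence,
    write_cohort,
)
from csbayes.datasets import example_cohort, load_severity_table
from csbayes.synthgen import expand_table


def D(**kw):
    return MutationDescriptor(**kw)


class TestClassifyPosition:
    @pytest.mark.parametrize(
        "descriptor, region, flagged",
        [
            (D(cdna_position=1397), Region.UPSTREAM, False),   # last exon-5 base
            (D(cdna_position=1398), Region.DOWNSTREAM, False), # first exon-6 base
            (D(cdna_position=1), Region.UPSTREAM, False),
            (D(cdna_position=4000), Region.DOWNSTREAM, False),
            # intron 5: decided by the insertion offset, always flagged
            (D(cdna_position=1397, intronic_offset=6913), Region.DOWNSTREAM, True),
            (D(cdna_position=1397, intronic_offset=6912), Region.UPSTREAM, True),
            (D(cdna_position=1397, intronic_offset=1), Region.UPSTREAM, True),
            (D(cdna_position=1398, intronic_offset=-5), Region.DOWNSTREAM, True),
            # other introns: anchor side, unflagged
            (D(cdna_position=500, intronic_offset=3), Region.UPSTREAM, False),
            (D(cdna_position=2000, intronic_offset=-2), Region.DOWNSTREAM, False),
            # label passthrough
            (D(region_label=Region.DOWNSTREAM), Region.DOWNSTREAM, False),
        ],
    )
    def test_boundary_and_intronic_calls(self, descriptor, region, flagged):
        got_region, got_flag = classify_position_full(descriptor)
        assert got_region is region
        assert got_flag is flagged

    def test_missing_both_forms_is_malformed(self):
        with pytest.raises(MalformedRecordError):
            MutationDescriptor()

    def test_invalid_coordinate_and_offset(self):
        with pytest.raises(MalformedRecordError):
            MutationDescriptor(cdna_position=0)
        with pytest.raises(MalformedRecordError):
            MutationDescriptor(cdna_position=10, intronic_offset=0)
        with pytest.raises(MalformedRecordError):
            MutationDescriptor(intronic_offset=5, region_label=Region.UPSTREAM)

    def test_contradictory_label_raises(self):
        with pytest.raises(ConsistencyError):
            classify_position(D(cdna_position=100, region_label=Region.DOWNSTREAM))

    def test_agreeing_label_passes(self):
        assert classify_position(
            D(cdna_position=100, region_label=Region.UPSTREAM)
        ) is Region.UPSTREAM


descriptors = st.one_of(
    st.integers(min_value=1, max_value=5000).map(lambda p: D(cdna_position=p)),
    st.tuples(
        st.integers(min_value=1, max_value=5000),
        st.integers(min_value=-8000, max_value=8000).filter(lambda o: o != 0),
    ).map(lambda t: D(cdna_position=t[0], intronic_offset=t[1])),
    st.sampled_from(list(Region)).map(lambda r: D(region_label=r)),
)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "ra, rb, group",
        [
            (Region.UPSTREAM, Region.UPSTREAM, MutationGroup.TWO_UP),
            (Region.UPSTREAM, Region.DOWNSTREAM, MutationGroup.ONE_ONE),
            (Region.DOWNSTREAM, Region.UPSTREAM, MutationGroup.ONE_ONE),
            (Region.DOWNSTREAM, Region.DOWNSTREAM, MutationGroup.TWO_DOWN),
        ],
    )
    def test_pairing_rules(self, ra, rb, group):
        assert classify_pair(D(region_label=ra), D(region_label=rb)) is group

    @hyp_settings(max_examples=200, derandomize=True)
    @given(a=descriptors, b=descriptors)
    def test_symmetry(self, a, b):
        assert classify_pair(a, b) is classify_pair(b, a)


class TestVariantGroup:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (VariantClass.PTV, VariantClass.PTV, VariantGroup.PTV_GROUP),
            (VariantClass.PTV, VariantClass.PAV, VariantGroup.PAV_GROUP),
            (VariantClass.PAV, VariantClass.PTV, VariantGroup.PAV_GROUP),
            (VariantClass.PAV, VariantClass.PAV, VariantGroup.PAV_GROUP),
            (VariantClass.PTV, VariantClass.UNKNOWN, VariantGroup.UNKNOWN),
            (VariantClass.UNKNOWN, VariantClass.PAV, VariantGroup.PAV_GROUP),
        ],
    )
    def test_pav_dominates_then_unknown(self, a, b, expected):
        assert classify_variant_group(a, b) is expected

    @pytest.mark.parametrize(
        "consequence, expected",
        [
            ("nonsense", VariantClass.PTV),
            ("Frameshift deletion", VariantClass.PTV),
            ("canonical splice donor", VariantClass.PTV),
            ("missense", VariantClass.PAV),
            ("in-frame deletion", VariantClass.PAV),
            ("synonymous", VariantClass.UNKNOWN),
        ],
    )
    def test_consequence_keyword_helper(self, consequence, expected):
        assert variant_class_from_consequence(consequence) is expected


class TestFilterAndTabulate:
    def test_study_cohort_retains_136_of_147(self):
        cohort = example_cohort()
        assert len(cohort) == 147
        kept, excluded = filter_analyzable(cohort)
        assert len(kept) == 136
        assert len(excluded) == 11
        reasons = [e.reason for e in excluded]
        assert sum("I_OR_II" in r for r in reasons) == 4
        assert sum("I_SLASH_II" in r for r in reasons) == 6
        assert sum("UNCLASSIFIED" in r for r in reasons) == 1

    def test_unambiguous_cohort_is_untouched(self):
        cohort = expand_table(load_severity_table())
        kept, excluded = filter_analyzable(cohort)
        assert kept == cohort
        assert excluded == []

    def test_cofs_maps_to_type_ii(self):
        rec = PatientRecord(
            "p1",
            D(region_label=Region.UPSTREAM),
            D(region_label=Region.UPSTREAM),
            SubtypeLabel.COFS,
        )
        kept, _ = filter_analyzable([rec])
        assert kept[0].subtype_label is SubtypeLabel.II
        assert kept[0].severity is SeverityLevel.II

    def test_idempotent(self):
        cohort = example_cohort()
        once, _ = filter_analyzable(cohort)
        twice, log2 = filter_analyzable(once)
        assert twice == once and log2 == []

    def test_published_table_counts(self):
        kept, _ = filter_analyzable(example_cohort())
        table = build_contingency(kept)
        assert table.counts.tolist() == [[9, 11, 3], [5, 11, 1], [57, 32, 7]]
        assert table.total == 136

    def test_count_conservation(self):
        kept, _ = filter_analyzable(example_cohort())
        assert build_contingency(kept).total == len(kept)

    def test_empty_and_singleton_tables(self):
        assert build_contingency([]).counts.tolist() == [[0] * 3] * 3
        rec = PatientRecord(
            "x",
            D(region_label=Region.DOWNSTREAM),
            D(region_label=Region.DOWNSTREAM),
            SubtypeLabel.I,
        )
        table = build_contingency([rec])
        assert table.total == 1
        assert table.counts[table.row_index(MutationGroup.TWO_DOWN),
                            table.col_index(SeverityLevel.I)] == 1

    def test_ambiguous_record_rejected_by_tabulation(self):
        rec = PatientRecord(
            "x",
            D(region_label=Region.UPSTREAM),
            D(region_label=Region.UPSTREAM),
            SubtypeLabel.I_OR_II,
        )
        with pytest.raises(MalformedRecordError):
            build_contingency([rec])

    def test_table_roundtrip_through_records(self, table2):
        assert build_contingency(expand_table(table2)) == table2

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1, -1, 0], [0, 0, 0], [0, 0, 0]]))


class TestCsvDialect:
    def test_roundtrip(self, tmp_path):
        cohort = example_cohort()
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        assert back == cohort

    def test_malformed_subtype_raises_with_row_context(self):
        row = dict(patient_id="p9", mut1_region="UPSTREAM", mut2_region="UPSTREAM",
                   subtype="IV")
        with pytest.raises(MalformedRecordError, match="p9"):
            record_from_row(row)

    def test_na_fields_parse_as_missing(self):
        row = dict(patient_id="p1", sex="NA", mut1_region="UPSTREAM",
                   mut2_region="DOWNSTREAM", subtype="I/II", onset_age_months="NA")
        rec = record_from_row(row)
        assert rec.onset_age_months is None
        assert rec.subtype_label is SubtypeLabel.I_SLASH_II
        assert rec.subtype_label in AMBIGUOUS_LABELS
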