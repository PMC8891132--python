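"""Patient data model and mutation-position classification for CSB/ERCC6 cohorts.

The *CSB/ERCC6* gene carries the PGBD3 (PiggyBac) transposon insertion in
intron 5, at NM_000124.3:c.1397+6912.  Mutations 5' of the insertion abolish
both the full-length CSB protein and the CSB-PGBD3 fusion protein, whereas
mutations 3' of it leave the fusion protein intact.  Each biallelic patient
is therefore stratified by the position of the two mutations relative to the
insertion: both upstream (``2U``), one of each (``1U1D``) or both downstream
(``2D``).

Clinical severity is the ordered Cockayne-syndrome subtype scale
``III < I < II``, with COFS (the most severe presentation) pooled into the
type II class before any analysis.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# cDNA coordinate of the last exon-5 base and the intron-5 offset of the
# PGBD3 insertion point (NM_000124.3:c.1397+6912).
INTRON5_ANCHOR = 1397
PGBD3_OFFSET = 6912


class Region(str, enum.Enum):
    """Position of a mutation relative to the PGBD3 insertion."""

    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"


class VariantClass(str, enum.Enum):
    PTV = "PTV"          # protein-truncating variant
    PAV = "PAV"          # protein-altering variant
    UNKNOWN = "UNKNOWN"


class VariantGroup(str, enum.Enum):
    """Biallelic variant-class group; a PTV+PAV pair counts as PAV."""

    PTV_GROUP = "PTV_GROUP"
    PAV_GROUP = "PAV_GROUP"
    UNKNOWN = "UNKNOWN"


class MutationGroup(str, enum.Enum):
    """Biallelic mutation-position group; ``2U`` is the regression reference."""

    TWO_UP = "2U"
    ONE_ONE = "1U1D"
    TWO_DOWN = "2D"


#: Fixed row order used everywhere a table is built or reported.
GROUP_ORDER: tuple[MutationGroup, ...] = (
    MutationGroup.TWO_UP,
    MutationGroup.ONE_ONE,
    MutationGroup.TWO_DOWN,
)


class SeverityLevel(enum.IntEnum):
    """Ordered clinical severity: III (mild) < I (classical) < II/COFS (severe)."""

    III = 1
    I = 2
    II = 3


#: Fixed column order for report parity with the published contingency table.
SEVERITY_ORDER: tuple[SeverityLevel, ...] = (
    SeverityLevel.II,
    SeverityLevel.I,
    SeverityLevel.III,
)


class SubtypeLabel(str, enum.Enum):
    II = "II"
    COFS = "COFS"
    I = "I"
    III = "III"
    I_OR_II = "I_OR_II"        # could be either subtype
    I_SLASH_II = "I_SLASH_II"  # at the boundary between I and II
    UNCLASSIFIED = "UNCLASSIFIED"


#: Labels that cannot be placed on the ordered severity scale.
AMBIGUOUS_LABELS = frozenset(
    {SubtypeLabel.I_OR_II, SubtypeLabel.I_SLASH_II, SubtypeLabel.UNCLASSIFIED}
)

_LABEL_TO_SEVERITY = {
    SubtypeLabel.III: SeverityLevel.III,
    SubtypeLabel.I: SeverityLevel.I,
    SubtypeLabel.II: SeverityLevel.II,
    SubtypeLabel.COFS: SeverityLevel.II,  # COFS pooled with type II
}


class MalformedRecordError(ValueError):
    """A mutation descriptor or patient record violates its invariants."""


class ConsistencyError(ValueError):
    """Coordinate-based classification contradicts a precomputed region label."""


@dataclass(frozen=True)
class MutationDescriptor:
    """One *CSB/ERCC6* mutation, located either by cDNA coordinate or by label.

    Parameters
    ----------
    cdna_position
        1-based coding-sequence coordinate (HGVS c. convention).  For an
        intronic variant this is the exonic anchor of the HGVS description
        (e.g. 1397 for c.1397+N) and `intronic_offset` carries the signed
        offset.
    intronic_offset
        Signed intronic offset; ``None`` for exonic variants.
    region_label
        Precomputed UPSTREAM/DOWNSTREAM call; may be given instead of (or in
        addition to) the coordinate.
    variant_class
        PTV / PAV / UNKNOWN consequence class, taken from the input.
    """

    cdna_position: int | None = None
    intronic_offset: int | None = None
    region_label: Region | None = None
    variant_class: VariantClass = VariantClass.UNKNOWN

    def __post_init__(self) -> None:
        if self.cdna_position is None and self.region_label is None:
            raise MalformedRecordError(
                "mutation needs a cDNA coordinate or a region label"
            )
        if self.cdna_position is not None and self.cdna_position < 1:
            raise MalformedRecordError(
                f"cdna_position must be >= 1, got {self.cdna_position}"
            )
        if self.intronic_offset is not None:
            if self.cdna_position is None:
                raise MalformedRecordError("intronic_offset requires an anchor")
            if self.intronic_offset == 0:
                raise MalformedRecordError("intronic_offset must be nonzero")


@dataclass(frozen=True)
class PatientRecord:
    """One biallelic Cockayne patient."""

    patient_id: str
    mutation_a: MutationDescriptor
    mutation_b: MutationDescriptor
    subtype_label: SubtypeLabel
    sex: str = "NA"
    onset_age_months: float | None = None
    source: str = "database"

    def __post_init__(self) -> None:
        if self.onset_age_months is not None and self.onset_age_months < 0:
            raise MalformedRecordError("onset_age_months must be >= 0")

    @property
    def mutation_group(self) -> MutationGroup:
        return classify_pair(self.mutation_a, self.mutation_b)

    @property
    def variant_group(self) -> VariantGroup:
        return classify_variant_group(
            self.mutation_a.variant_class, self.mutation_b.variant_class
        )

    @property
    def severity(self) -> SeverityLevel | None:
        """Ordered severity code, or None for ambiguous/unclassified labels."""
        return _LABEL_TO_SEVERITY.get(self.subtype_label)


def classify_position_full(m: MutationDescriptor) -> tuple[Region, bool]:
    """Classify one mutation relative to the PGBD3 insertion.

    Returns ``(region, intron5_flag)``.  The flag marks variants lying inside
    intron 5 itself: the upstream/downstream dichotomy is exon-based, so
    intron-5 variants are decided by the insertion coordinate (c.1397+6912)
    and flagged for review.
    """
    if m.cdna_position is None:
        assert m.region_label is not None
        return m.region_label, False

    if m.intronic_offset is None:
        region = (
            Region.UPSTREAM if m.cdna_position <= INTRON5_ANCHOR else Region.DOWNSTREAM
        )
    elif m.cdna_position == INTRON5_ANCHOR and m.intronic_offset > 0:
        # c.1397+N: inside intron 5, 5' side; split at the insertion point
        region = Region.UPSTREAM if m.intronic_offset <= PGBD3_OFFSET else Region.DOWNSTREAM
    elif m.cdna_position == INTRON5_ANCHOR + 1 and m.intronic_offset < 0:
        # c.1398-N: intron 5 approached from its 3' end, past the insertion
        region = Region.DOWNSTREAM
    else:
        # other introns: classify by the exonic anchor
        region = (
            Region.UPSTREAM if m.cdna_position <= INTRON5_ANCHOR else Region.DOWNSTREAM
        )

    flag = m.intronic_offset is not None and (
        (m.cdna_position == INTRON5_ANCHOR and m.intronic_offset > 0)
        or (m.cdna_position == INTRON5_ANCHOR + 1 and m.intronic_offset < 0)
    )

    if m.region_label is not None and m.region_label != region:
        raise ConsistencyError(
            f"coordinate classifies as {region.value} but label says "
            f"{m.region_label.value}"
        )
    return region, flag


def classify_position(m: MutationDescriptor) -> Region:
    """UPSTREAM/DOWNSTREAM call for one mutation (see `classify_position_full`)."""
    return classify_position_full(m)[0]


def classify_pair(a: MutationDescriptor, b: MutationDescriptor) -> MutationGroup:
    """Biallelic position group: {U,U} -> 2U, {D,D} -> 2D, mixed -> 1U1D."""
    ra, rb = classify_position(a), classify_position(b)
    if ra == rb:
        return MutationGroup.TWO_UP if ra is Region.UPSTREAM else MutationGroup.TWO_DOWN
    return MutationGroup.ONE_ONE


def classify_variant_group(
    a_class: VariantClass, b_class: VariantClass
) -> VariantGroup:
    """Pair-level variant class: any PAV -> PAV group (the more permissive
    allele dominates), both PTV -> PTV group, any UNKNOWN -> UNKNOWN."""
    classes = {a_class, b_class}
    if VariantClass.PAV in classes:
        return VariantGroup.PAV_GROUP
    if VariantClass.UNKNOWN in classes:
        return VariantGroup.UNKNOWN
    return VariantGroup.PTV_GROUP


_PTV_KEYWORDS = ("nonsense", "frameshift", "stop_gained", "stopgain", "splice")
_PAV_KEYWORDS = ("missense", "in-frame", "inframe", "in_frame")


def variant_class_from_consequence(consequence: str) -> VariantClass:
    """Opt-in helper mapping common consequence keywords to PTV/PAV.

    Nonsense, frameshift and canonical-splice consequences are truncating;
    missense and in-frame changes are protein-altering.  Anything else is
    UNKNOWN — the analysis normally trusts the input's variant_class column.
    """
    c = consequence.strip().lower()
    if any(k in c for k in _PTV_KEYWORDS):
        return VariantClass.PTV
    if any(k in c for k in _PAV_KEYWORDS):
        return VariantClass.PAV
    return VariantClass.UNKNOWN


@dataclass(frozen=True)
class ContingencyTable:
    """Mutation-group x ordered-severity counts.

    Rows follow `GROUP_ORDER` (2U, 1U1D, 2D) and columns `SEVERITY_ORDER`
    (II, I, III), matching the published presentation.
    """

    counts: np.ndarray
    row_labels: tuple[MutationGroup, ...] = GROUP_ORDER
    col_labels: tuple[SeverityLevel, ...] = SEVERITY_ORDER

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"counts shape {counts.shape} does not match labels "
                f"({len(self.row_labels)}, {len(self.col_labels)})"
            )
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_index(self, group: MutationGroup) -> int:
        return self.row_labels.index(group)

    def col_index(self, level: SeverityLevel) -> int:
        return self.col_labels.index(level)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[g.value for g in self.row_labels],
            columns=[s.name for s in self.col_labels],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContingencyTable):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class Exclusion:
    patient_id: str
    reason: str


def filter_analyzable(
    cohort: Iterable[PatientRecord],
) -> tuple[list[PatientRecord], list[Exclusion]]:
    """Drop patients whose subtype cannot be placed on the severity scale.

    Removes I_OR_II / I_SLASH_II / UNCLASSIFIED labels and maps COFS to the
    type II class.  Idempotent; returns the retained records and a per-record
    exclusion log.
    """
    kept: list[PatientRecord] = []
    excluded: list[Exclusion] = []
    for rec in cohort:
        if rec.subtype_label in AMBIGUOUS_LABELS:
            excluded.append(
                Exclusion(rec.patient_id, f"ambiguous subtype {rec.subtype_label.value}")
            )
            continue
        if rec.subtype_label is SubtypeLabel.COFS:
            rec = replace(rec, subtype_label=SubtypeLabel.II)
        kept.append(rec)
    return kept, excluded


def build_contingency(cohort: Sequence[PatientRecord]) -> ContingencyTable:
    """Cross-tabulate mutation group by severity for an analyzable cohort."""
    counts = np.zeros((len(GROUP_ORDER), len(SEVERITY_ORDER)), dtype=int)
    for rec in cohort:
        sev = rec.severity
        if sev is None:
            raise MalformedRecordError(
                f"patient {rec.patient_id} has ambiguous subtype "
                f"{rec.subtype_label.value}; run filter_analyzable first"
            )
        counts[GROUP_ORDER.index(rec.mutation_group), SEVERITY_ORDER.index(sev)] += 1
    return ContingencyTable(counts)


# ---------------------------------------------------------------------------
# Cohort CSV dialect
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "patient_id", "sex",
    "mut1_cdna", "mut1_offset", "mut1_region", "mut1_class",
    "mut2_cdna", "mut2_offset", "mut2_region", "mut2_class",
    "subtype", "onset_age_months", "source",
]

_SUBTYPE_ALIASES = {
    "II": SubtypeLabel.II,
    "COFS": SubtypeLabel.COFS,
    "I": SubtypeLabel.I,
    "III": SubtypeLabel.III,
    "I_OR_II": SubtypeLabel.I_OR_II,
    "I OR II": SubtypeLabel.I_OR_II,
    "I_SLASH_II": SubtypeLabel.I_SLASH_II,
    "I/II": SubtypeLabel.I_SLASH_II,
    "UNCLASSIFIED": SubtypeLabel.UNCLASSIFIED,
}


def _parse_optional(value: str | None) -> str | None:
    if value is None:
        return None
    value = value.strip()
    return None if value in ("", "NA") else value


def _descriptor_from_row(row: dict, slot: int) -> MutationDescriptor:
    cdna = _parse_optional(row.get(f"mut{slot}_cdna"))
    offset = _parse_optional(row.get(f"mut{slot}_offset"))
    region = _parse_optional(row.get(f"mut{slot}_region"))
    vclass = _parse_optional(row.get(f"mut{slot}_class"))
    return MutationDescriptor(
        cdna_position=int(cdna) if cdna is not None else None,
        intronic_offset=int(offset) if offset is not None else None,
        region_label=Region(region.upper()) if region is not None else None,
        variant_class=VariantClass(vclass.upper()) if vclass is not None else VariantClass.UNKNOWN,
    )


def record_from_row(row: dict) -> PatientRecord:
    """Build a `PatientRecord` from one cohort CSV/TSV row (dict of strings)."""
    subtype_raw = _parse_optional(row.get("subtype"))
    if subtype_raw is None:
        raise MalformedRecordError(f"row {row.get('patient_id')}: missing subtype")
    try:
        subtype = _SUBTYPE_ALIASES[subtype_raw.upper()]
    except KeyError as exc:
        raise MalformedRecordError(
            f"row {row.get('patient_id')}: unknown subtype label {subtype_raw!r}"
        ) from exc
    onset = _parse_optional(row.get("onset_age_months"))
    return PatientRecord(
        patient_id=str(row.get("patient_id", "")),
        sex=_parse_optional(row.get("sex")) or "NA",
        mutation_a=_descriptor_from_row(row, 1),
        mutation_b=_descriptor_from_row(row, 2),
        subtype_label=subtype,
        onset_age_months=float(onset) if onset is not None else None,
        source=_parse_optional(row.get("source")) or "database",
    )


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV/TSV file (delimiter sniffed from the extension)."""
    delim = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter=delim):
            records.append(record_from_row(row))
    return records


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    """Write records in the cohort CSV/TSV dialect (missing values as NA)."""
    delim = "\t" if str(path).endswith((".tsv", ".txt")) else ","

    def fmt(value) -> str:
        if value is None:
            return "NA"
        if isinstance(value, float):
            return "NA" if math.isnan(value) else f"{value:g}"
        if isinstance(value, enum.Enum):
            return value.value
        return str(value)

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(COHORT_COLUMNS)
        for rec in records:
            row = [rec.patient_id, rec.sex]
            for m in (rec.mutation_a, rec.mutation_b):
                row += [
                    fmt(m.cdna_position), fmt(m.intronic_offset),
                    fmt(m.region_label), fmt(m.variant_class),
                ]
            row += [rec.subtype_label.value, fmt(rec.onset_age_months), rec.source]
            writer.writerow(row)


def write_exclusions(exclusions: Sequence[Exclusion], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["patient_id", "reason"])
        for e in exclusions:
            writer.writerow([e.patient_id, e.reason])
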