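"""Packaged fixtures: the published severity x genotype table and an example cohort.

The complete analyzable dataset of the source study is its printed 3x3
contingency table of Cockayne subtype by mutation-position group (n = 136);
it ships here as `load_severity_table`.  `example_cohort` reconstructs a
147-record patient list with the study's composition: the 136 analyzable
patients expanded from the table, plus 4 "I or II", 6 "I/II" boundary and
1 unclassifiable patient that the ordinal analysis excludes.
"""

from __future__ import annotations

import numpy as np

from .cohort import (
    ContingencyTable,
    MutationDescriptor,
    PatientRecord,
    Region,
    SubtypeLabel,
)

# Severity (II, I, III) counts per mutation group (2U, 1U1D, 2D), n = 136.
_SEVERITY_COUNTS = [
    [9, 11, 3],
    [5, 11, 1],
    [57, 32, 7],
]


def load_severity_table() -> ContingencyTable:
    """The published mutation-group x subtype contingency table (n = 136)."""
    return ContingencyTable(np.array(_SEVERITY_COUNTS))


_REGIONS_BY_GROUP = {
    "2U": (Region.UPSTREAM, Region.UPSTREAM),
    "1U1D": (Region.UPSTREAM, Region.DOWNSTREAM),
    "2D": (Region.DOWNSTREAM, Region.DOWNSTREAM),
}


def _minimal_record(patient_id: str, group: str, subtype: SubtypeLabel) -> PatientRecord:
    ra, rb = _REGIONS_BY_GROUP[group]
    return PatientRecord(
        patient_id=patient_id,
        mutation_a=MutationDescriptor(region_label=ra),
        mutation_b=MutationDescriptor(region_label=rb),
        subtype_label=subtype,
    )


def example_cohort() -> list[PatientRecord]:
    """A 147-record cohort with the study's inclusion structure.

    136 records reproduce the analyzable contingency table exactly; 11
    additional records carry the ambiguous labels (4 I_OR_II, 6 I_SLASH_II,
    1 UNCLASSIFIED) that `filter_analyzable` removes.  The ambiguous records
    are assigned to the majority 2D group; their group plays no role since
    they are excluded before tabulation.
    """
    from .synthgen import expand_table  # local import to avoid a cycle

    records = expand_table(load_severity_table())
    n = len(records)
    extra: list[PatientRecord] = []
    for label, count in (
        (SubtypeLabel.I_OR_II, 4),
        (SubtypeLabel.I_SLASH_II, 6),
        (SubtypeLabel.UNCLASSIFIED, 1),
    ):
        for _ in range(count):
            n += 1
            extra.append(_minimal_record(f"P{n:03d}", "2D", label))
    return records + extra
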