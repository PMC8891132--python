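"""Synthetic Cockayne-B cohorts with the statistical structure the models assume.

The study's per-patient data is restricted, so tests, demos and
parameter-recovery experiments run on cohorts drawn from the generative
model the analysis itself posits: mutation-position group from a fixed
3-simplex, ordinal severity from a cumulative-logit model, onset age from a
moment-matched Gamma (mean 8, SD 13.4 months, truncated at 72), with a
configurable fraction of missing ages and of ambiguous I/II subtype labels.

Defaults mirror the study cohort: n = 147, group proportions 24/18/105,
severity effects at the published point estimates (log 0.9 for 1U1D,
log 2.0 for 2D vs the 2U reference), ~16% missing onset ages and 10/147
ambiguous labels.  Every upstream allele is truncating (as observed);
downstream alleles are PAV with probability 37/92.

Reproducibility: one master seed; per-patient substreams are spawned
deterministically by patient index, so records are stable under changes of
``n_patients`` prefix length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .cohort import (
    ContingencyTable,
    MutationDescriptor,
    MutationGroup,
    PatientRecord,
    Region,
    SeverityLevel,
    SubtypeLabel,
    VariantClass,
    GROUP_ORDER,
)

__all__ = ["CohortSimSpec", "generate_cohort", "expand_table", "sample_raw_onset_ages"]


class SimSpecError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSimSpec:
    """Generative settings for one synthetic cohort."""

    n_patients: int = 147
    group_probs: tuple[float, float, float] = (24 / 147, 18 / 147, 105 / 147)
    true_beta: tuple[float, ...] = (math.log(0.9), math.log(2.0))
    true_cutpoints: tuple[float, float] = (-1.96, 0.46)
    onset_mean_months: float = 8.0
    onset_sd_months: float = 13.4
    onset_max_months: float = 72.0
    onset_missing_prob: float = 24 / 147
    ambiguous_label_prob: float = 10 / 147
    downstream_pav_prob: float = 37 / 92
    variant_beta: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SimSpecError("n_patients must be positive")
        probs = np.asarray(self.group_probs, dtype=float)
        if probs.size != 3 or (probs < 0).any() or abs(probs.sum() - 1.0) > 0.01:
            raise SimSpecError("group_probs must be a 3-simplex")
        if probs.sum() != 1.0:  # tolerate rounded published proportions
            object.__setattr__(self, "group_probs", tuple(probs / probs.sum()))
        if len(self.true_beta) != 2:
            raise SimSpecError("true_beta needs one log-OR per non-reference group")
        t1, t2 = self.true_cutpoints
        if not t1 < t2:
            raise SimSpecError("cutpoints must be strictly increasing")
        for p in (self.onset_missing_prob, self.ambiguous_label_prob, self.downstream_pav_prob):
            if not 0.0 <= p <= 1.0:
                raise SimSpecError("probabilities must lie in [0, 1]")
        if min(self.onset_mean_months, self.onset_sd_months, self.onset_max_months) <= 0:
            raise SimSpecError("onset moments and cap must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSimSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("group_probs", "true_beta", "true_cutpoints"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


_REGIONS_BY_GROUP = {
    MutationGroup.TWO_UP: (Region.UPSTREAM, Region.UPSTREAM),
    MutationGroup.ONE_ONE: (Region.UPSTREAM, Region.DOWNSTREAM),
    MutationGroup.TWO_DOWN: (Region.DOWNSTREAM, Region.DOWNSTREAM),
}

_SEVERITY_BY_CODE = {1: SubtypeLabel.III, 2: SubtypeLabel.I, 3: SubtypeLabel.II}


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def _draw_onset(rng: np.random.Generator, shape: float, scale: float, cap: float) -> float:
    # rejection sampling keeps the Gamma shape below the cap
    for _ in range(10_000):
        x = rng.gamma(shape, scale)
        if x <= cap:
            return max(x, 0.0)
    return cap  # pragma: no cover - cap far in the tail for realistic specs


def sample_raw_onset_ages(spec: CohortSimSpec, n_samples: int) -> np.ndarray:
    """Untruncated, non-missing onset-age draws (for moment checks)."""
    shape, scale = _gamma_params(spec.onset_mean_months, spec.onset_sd_months)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    return rng.gamma(shape, scale, size=n_samples)


def severity_cell_probs(spec: CohortSimSpec) -> np.ndarray:
    """Closed-form severity probabilities per group, columns III/I/II ascending."""
    t1, t2 = spec.true_cutpoints
    out = np.empty((3, 3))
    for gi, eta in enumerate((0.0,) + tuple(spec.true_beta)):
        c1 = 1.0 / (1.0 + math.exp(-(t1 - eta)))
        c2 = 1.0 / (1.0 + math.exp(-(t2 - eta)))
        out[gi] = (c1, c2 - c1, 1.0 - c2)
    return out


def generate_cohort(spec: CohortSimSpec) -> list[PatientRecord]:
    """Draw one synthetic cohort; fully reproducible given ``spec.seed``."""
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(spec.n_patients)
    shape, scale = _gamma_params(spec.onset_mean_months, spec.onset_sd_months)
    probs = np.asarray(spec.group_probs)
    cum_group = np.cumsum(probs)
    t1, t2 = spec.true_cutpoints

    records: list[PatientRecord] = []
    for i in range(spec.n_patients):
        rng = np.random.Generator(np.random.PCG64(children[i]))
        # mutation-position group
        u = rng.random()
        gi = int(np.searchsorted(cum_group, u, side="right"))
        gi = min(gi, 2)
        group = GROUP_ORDER[gi]

        # allele regions and variant classes (upstream alleles always PTV)
        regions = _REGIONS_BY_GROUP[group]
        classes = tuple(
            VariantClass.PTV
            if r is Region.UPSTREAM
            else (
                VariantClass.PAV
                if rng.random() < spec.downstream_pav_prob
                else VariantClass.PTV
            )
            for r in regions
        )

        # ordinal severity from the cumulative-logit model
        eta = (0.0, spec.true_beta[0], spec.true_beta[1])[gi]
        if spec.variant_beta is not None and VariantClass.PAV not in classes:
            eta += spec.variant_beta  # PTV pair effect, PAV reference
        c1 = 1.0 / (1.0 + math.exp(-(t1 - eta)))
        c2 = 1.0 / (1.0 + math.exp(-(t2 - eta)))
        u = rng.random()
        code = 1 if u < c1 else (2 if u < c2 else 3)
        label = _SEVERITY_BY_CODE[code]

        # boundary I/II cases occasionally get an ambiguous label
        if label in (SubtypeLabel.I, SubtypeLabel.II) and rng.random() < spec.ambiguous_label_prob:
            label = SubtypeLabel.I_OR_II if rng.random() < 0.4 else SubtypeLabel.I_SLASH_II

        onset: float | None = _draw_onset(rng, shape, scale, spec.onset_max_months)
        if rng.random() < spec.onset_missing_prob:
            onset = None

        records.append(
            PatientRecord(
                patient_id=f"S{i + 1:05d}",
                sex="M" if rng.random() < 0.58 else "F",
                mutation_a=MutationDescriptor(region_label=regions[0], variant_class=classes[0]),
                mutation_b=MutationDescriptor(region_label=regions[1], variant_class=classes[1]),
                subtype_label=label,
                onset_age_months=onset,
                source="database",
            )
        )
    return records


def expand_table(table: ContingencyTable) -> list[PatientRecord]:
    """One minimal patient record per count unit of a contingency table.

    Group and subtype are set from the cell; all other fields are NA.  The
    inverse of `csbayes.cohort.build_contingency`.
    """
    label_by_level = {
        SeverityLevel.III: SubtypeLabel.III,
        SeverityLevel.I: SubtypeLabel.I,
        SeverityLevel.II: SubtypeLabel.II,
    }
    records: list[PatientRecord] = []
    k = 0
    for gi, group in enumerate(table.row_labels):
        regions = _REGIONS_BY_GROUP[group]
        for ci, level in enumerate(table.col_labels):
            for _ in range(int(table.counts[gi, ci])):
                k += 1
                records.append(
                    PatientRecord(
                        patient_id=f"P{k:03d}",
                        mutation_a=MutationDescriptor(region_label=regions[0]),
                        mutation_b=MutationDescriptor(region_label=regions[1]),
                        subtype_label=label_by_level[level],
                    )
                )
    return records
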