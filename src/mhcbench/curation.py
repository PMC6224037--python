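"""Blind-test-set curation from raw affinity tables.

The filter chain, applied in a fixed order, mirrors how blind benchmark sets
are built from an IEDB-style export:

1. keep quantitative records of allowed assay types (KD / IC50 / EC50);
2. drop measurements above the 50 000 nM ceiling;
3. keep peptides of the target length (9/10-mers for class I, 15-mers for II);
4. drop (peptide, allele) pairs present in the predictors' training data;
5. optionally drop alleles no benchmarked tool covers.

Every step logs its survivor count so fixtures can pin each filter
independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import geometric_mean
from typing import Iterable, Mapping, Sequence

from .core import (
    AffinityMeasurement,
    AssayType,
    BinderClass,
    ClassScheme,
    DomainError,
    classify_affinity,
)

__all__ = [
    "CurationConfig",
    "CurationLog",
    "CompositionSummary",
    "RawRecord",
    "curate_testset",
    "collapse_duplicates",
    "summarize_composition",
]


@dataclass(frozen=True)
class RawRecord:
    """An uncurated row: the value may be qualitative or unparseable."""

    peptide: str
    allele: str
    assay: str
    value: object  # float, numeric string, or qualitative text
    source: str = ""


@dataclass(frozen=True)
class CurationConfig:
    allowed_assays: frozenset[AssayType] = frozenset(
        {AssayType.KD, AssayType.IC50, AssayType.EC50}
    )
    ceiling_nm: float = 50000.0
    peptide_length: int = 9
    drop_untrained_alleles: bool = False
    training_index: frozenset[tuple[str, str]] = frozenset()
    covered_alleles: frozenset[str] = frozenset()
    #: de-duplicate against training on (peptide, allele) or peptide alone
    overlap_key: str = "pair"

    def __post_init__(self) -> None:
        if self.peptide_length < 1 or self.ceiling_nm <= 0:
            raise DomainError("peptide_length >= 1 and ceiling_nm > 0 required")
        if self.overlap_key not in ("pair", "peptide"):
            raise DomainError("overlap_key must be 'pair' or 'peptide'")


@dataclass
class CurationLog:
    """Survivor counts after each filter step, plus parse failures."""

    n_input: int = 0
    n_after_assay: int = 0
    n_after_ceiling: int = 0
    n_after_length: int = 0
    n_after_training_overlap: int = 0
    n_after_allele_coverage: int = 0
    n_unparseable: int = 0

    @property
    def step_counts(self) -> list[int]:
        return [
            self.n_input,
            self.n_after_assay,
            self.n_after_ceiling,
            self.n_after_length,
            self.n_after_training_overlap,
            self.n_after_allele_coverage,
        ]

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "after_assay_filter": self.n_after_assay,
            "after_ceiling_filter": self.n_after_ceiling,
            "after_length_filter": self.n_after_length,
            "after_training_overlap_filter": self.n_after_training_overlap,
            "after_allele_coverage_filter": self.n_after_allele_coverage,
            "unparseable": self.n_unparseable,
        }


def _parse_value(value: object) -> float | None:
    if isinstance(value, (int, float)):
        v = float(value)
        return v if math.isfinite(v) and v > 0 else None
    if isinstance(value, str):
        try:
            v = float(value.strip())
        except ValueError:
            return None  # qualitative, e.g. "Positive"
        return v if math.isfinite(v) and v > 0 else None
    return None


def curate_testset(
    raw: Sequence[RawRecord], config: CurationConfig = CurationConfig()
) -> tuple[list[AffinityMeasurement], CurationLog]:
    """Apply the five-step filter chain; returns survivors and the step log.

    Idempotent: re-curating the output (wrapped back into raw records)
    changes nothing.  Unparseable or qualitative values are dropped at step 1
    and counted, never fatal.
    """
    log = CurationLog(n_input=len(raw))

    step1: list[AffinityMeasurement] = []
    for rec in raw:
        try:
            assay = AssayType(rec.assay.upper())
        except ValueError:
            continue
        if assay not in config.allowed_assays:
            continue
        value = _parse_value(rec.value)
        if value is None:
            log.n_unparseable += 1
            continue
        try:
            step1.append(
                AffinityMeasurement(rec.peptide, rec.allele, assay, value, rec.source)
            )
        except DomainError:
            log.n_unparseable += 1
    log.n_after_assay = len(step1)

    step2 = [m for m in step1 if m.value_nm <= config.ceiling_nm]
    log.n_after_ceiling = len(step2)

    step3 = [m for m in step2 if len(m.peptide) == config.peptide_length]
    log.n_after_length = len(step3)

    if config.overlap_key == "pair":
        trained = config.training_index
        step4 = [m for m in step3 if (m.peptide, m.allele) not in trained]
    else:
        trained_peptides = {p for p, _ in config.training_index}
        step4 = [m for m in step3 if m.peptide not in trained_peptides]
    log.n_after_training_overlap = len(step4)

    if config.drop_untrained_alleles:
        step5 = [m for m in step4 if m.allele in config.covered_alleles]
    else:
        step5 = step4
    log.n_after_allele_coverage = len(step5)

    return step5, log


def collapse_duplicates(
    records: Sequence[AffinityMeasurement],
) -> list[AffinityMeasurement]:
    """Merge replicate (peptide, allele) records by geometric-mean affinity.

    Affinities live on a log scale, so the geometric mean is the natural
    replicate average.  Provenance strings of merged replicates are joined.
    """
    groups: dict[tuple[str, str], list[AffinityMeasurement]] = {}
    for m in records:
        groups.setdefault((m.peptide, m.allele), []).append(m)
    out: list[AffinityMeasurement] = []
    for (peptide, allele), members in groups.items():
        if len(members) == 1:
            out.append(members[0])
            continue
        value = geometric_mean([m.value_nm for m in members])
        sources = ";".join(dict.fromkeys(m.source for m in members if m.source))
        out.append(AffinityMeasurement(peptide, allele, members[0].assay, value, sources))
    return out


@dataclass(frozen=True)
class CompositionSummary:
    n_records: int
    n_alleles: int
    pct_strong: float
    pct_weak: float
    pct_non: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_records": self.n_records,
            "n_alleles": self.n_alleles,
            "pct_strong": self.pct_strong,
            "pct_weak": self.pct_weak,
            "pct_non": self.pct_non,
        }


def summarize_composition(
    records: Sequence[AffinityMeasurement], scheme: ClassScheme = ClassScheme()
) -> CompositionSummary:
    """Record/allele counts and the strong/weak/non percentage split."""
    if not records:
        raise DomainError("cannot summarise an empty record set")
    n = len(records)
    counts = {cls: 0 for cls in BinderClass}
    alleles = set()
    for m in records:
        counts[classify_affinity(m.value_nm, scheme)] += 1
        alleles.add(m.allele)
    return CompositionSummary(
        n_records=n,
        n_alleles=len(alleles),
        pct_strong=100.0 * counts[BinderClass.STRONG] / n,
        pct_weak=100.0 * counts[BinderClass.WEAK] / n,
        pct_non=100.0 * counts[BinderClass.NON] / n,
    )
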