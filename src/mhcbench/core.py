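"""Shared domain types, the log-affinity transform and allele-name handling.

Binding strengths are handled on two scales throughout the package:

* raw half-maximal concentrations in nM (IC50 / K_D / EC50; lower = stronger),
* a normalised log scale ``y = 1 - log10(nM) / log10(ceiling)`` with ceiling
  50 000 nM, so that y = 1 is a 1 nM binder and y = 0 the weakest measurable
  one.  The conventional class-I thresholds map to y(50) ≈ 0.638 and
  y(500) ≈ 0.426.

All predictors are compared on the "higher = stronger" orientation of the
normalised scale; adapters in :mod:`mhcbench.io` convert external outputs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np

__all__ = [
    "VALID_RESIDUES",
    "AMINO_ACIDS",
    "AffinityMeasurement",
    "AssayType",
    "BinderClass",
    "ClassScheme",
    "DomainError",
    "AlleleNameError",
    "classify_affinity",
    "inverse_transform",
    "normalize_allele_name",
    "transform_affinity",
]

#: The 20 proteinogenic amino acids, in the fixed order used by all encoders.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in peptides: the 20-letter alphabet plus 'X' (unknown).
VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}

DEFAULT_CEILING_NM = 50000.0


class DomainError(ValueError):
    """An input violates a documented precondition."""


class AlleleNameError(DomainError):
    """An allele name does not match any accepted dialect."""


class AssayType(str, Enum):
    KD = "KD"
    IC50 = "IC50"
    EC50 = "EC50"


class BinderClass(str, Enum):
    """Three-class binder label under a :class:`ClassScheme`."""

    STRONG = "strong"
    WEAK = "weak"
    NON = "non"


@dataclass(frozen=True)
class ClassScheme:
    """Affinity thresholds for the strong / weak / non-binder partition.

    Defaults follow the field's conventions: strong binders below 50 nM,
    binders below 500 nM for MHC class I and 1000 nM for class II.
    """

    strong_cutoff_nm: float = 50.0
    binder_cutoff_nm: float = 500.0
    mhc_class: str = "I"

    def __post_init__(self) -> None:
        if not (0 < self.strong_cutoff_nm < self.binder_cutoff_nm):
            raise DomainError(
                "require 0 < strong_cutoff_nm < binder_cutoff_nm, got "
                f"{self.strong_cutoff_nm} and {self.binder_cutoff_nm}"
            )

    @classmethod
    def for_class(cls, mhc_class: str) -> "ClassScheme":
        """Conventional scheme for MHC class ``"I"`` (500 nM) or ``"II"`` (1000 nM)."""
        mhc_class = mhc_class.upper()
        if mhc_class == "I":
            return cls(50.0, 500.0, "I")
        if mhc_class == "II":
            return cls(50.0, 1000.0, "II")
        raise DomainError(f"unknown MHC class {mhc_class!r}")


@dataclass(frozen=True)
class AffinityMeasurement:
    """One quantitative peptide/allele binding measurement (the benchmark atom)."""

    peptide: str
    allele: str
    assay: AssayType
    value_nm: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.peptide:
            raise DomainError("peptide must be non-empty")
        bad = set(self.peptide) - VALID_RESIDUES
        if bad:
            raise DomainError(
                f"peptide {self.peptide!r} contains invalid residues {sorted(bad)}"
            )
        if not (self.value_nm > 0 and math.isfinite(self.value_nm)):
            raise DomainError(f"value_nm must be positive and finite, got {self.value_nm}")

    @property
    def has_unknown_residue(self) -> bool:
        return "X" in self.peptide


def transform_affinity(value_nm, ceiling_nm: float = DEFAULT_CEILING_NM):
    """Map a concentration in nM to the normalised [0, 1] log-affinity scale.

    ``y = 1 - log10(value_nm) / log10(ceiling_nm)``; values above the ceiling
    clamp to 0 and values below 1 nM clamp to 1.  Accepts scalars or arrays.
    """
    if ceiling_nm <= 1:
        raise DomainError(f"ceiling_nm must exceed 1 nM, got {ceiling_nm}")
    arr = np.asarray(value_nm, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError("affinity values must be positive and finite")
    y = 1.0 - np.log10(arr) / np.log10(ceiling_nm)
    y = np.clip(y, 0.0, 1.0)
    return float(y) if np.isscalar(value_nm) or arr.ndim == 0 else y


def inverse_transform(y, ceiling_nm: float = DEFAULT_CEILING_NM):
    """Invert :func:`transform_affinity`: ``nM = ceiling_nm ** (1 - y)``."""
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise DomainError("transformed scores must lie in [0, 1]")
    nm = np.power(ceiling_nm, 1.0 - arr)
    return float(nm) if np.isscalar(y) or arr.ndim == 0 else nm


def classify_affinity(value_nm: float, scheme: ClassScheme = ClassScheme()) -> BinderClass:
    """Assign the three-class binder label.

    Boundary convention (the partition choice): strong iff value < strong
    cutoff; binder (strong or weak) iff value <= binder cutoff.
    """
    if not value_nm > 0:
        raise DomainError(f"value_nm must be positive, got {value_nm}")
    if value_nm < scheme.strong_cutoff_nm:
        return BinderClass.STRONG
    if value_nm <= scheme.binder_cutoff_nm:
        return BinderClass.WEAK
    return BinderClass.NON


# Accepted allele-name dialects.  The canonical form is star/colon-free and
# locus-prefixed, e.g. HLA-A0201, HLA-DRB10101.
_CLASS_I_RE = re.compile(r"^(?:HLA-?)?([ABC])\s*\*?\s*(\d{2}):?(\d{2,3})$", re.IGNORECASE)
_CLASS_II_RE = re.compile(
    r"^(?:HLA-?)?(D[PQR][AB]\d?)\s*\*?\s*(\d{2}):?(\d{2,3})$", re.IGNORECASE
)
_CANONICAL_RE = re.compile(r"^HLA-(?:[ABC]|D[PQR][AB]\d?)\d{4,6}$")
_SYNTHETIC_RE = re.compile(r"^SYN-[A-Z0-9_]+$", re.IGNORECASE)


def normalize_allele_name(raw: str) -> str:
    """Return the canonical compact allele id for any accepted dialect.

    Accepts e.g. ``HLA-A*02:01``, ``A0201``, ``HLA-DRB1*01:01`` and is
    idempotent and case-insensitive.  Synthetic allele ids (``SYN-...``) used
    by the simulator pass through upper-cased.
    """
    if not raw or not raw.strip():
        raise AlleleNameError("empty allele name")
    name = raw.strip()
    if _SYNTHETIC_RE.match(name):
        return name.upper()
    compact = name.replace(" ", "")
    if _CANONICAL_RE.match(compact.upper()):
        return compact.upper()
    for pattern in (_CLASS_I_RE, _CLASS_II_RE):
        m = pattern.match(compact)
        if m:
            locus, group, protein = m.groups()
            return f"HLA-{locus.upper()}{group}{protein}"
    raise AlleleNameError(
        f"cannot parse allele name {raw!r}; accepted dialects: 'HLA-A*02:01', "
        "'A*02:01', 'A0201', 'HLA-A0201', class II analogues such as "
        "'HLA-DRB1*01:01', and synthetic ids 'SYN-...'"
    )


def unique_alleles(measurements: Iterable[AffinityMeasurement]) -> list[str]:
    """Distinct allele ids, in first-seen order."""
    seen: dict[str, None] = {}
    for m in measurements:
        seen.setdefault(m.allele)
    return list(seen)
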