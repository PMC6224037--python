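"""Synthetic benchmark data with the statistical structure the toolkit assumes.

The generator emulates what pan-allele binding prediction relies on:

* each allele carries a position-weight-matrix (PSSM) binding motif over
  9-mer peptides with anchor-heavy positions 2 and 9 (the class-I anchor
  convention);
* alleles come in families — similar binding-pocket pseudo-sequences imply
  similar motifs — so models can generalise across related alleles;
* measured affinities are the motif energy on a log10(nM) scale plus
  Gaussian measurement noise (affinities span orders of magnitude, so the
  noise is log-scale), clamped to the 1–50 000 nM assay window;
* eluted-ligand sets are the strongest true binders inside a random
  proteome, so elution benchmarks see motif-positive peptides against
  motif-free decoys.

Everything is deterministic for a fixed seed.  An optional neighbour
coupling term adds pairwise residue interactions that a purely additive
(linear) scorer cannot represent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AMINO_ACIDS, AffinityMeasurement, AssayType, DomainError
from .curation import RawRecord
from .elution import ElutionRecord

__all__ = [
    "SyntheticAlleleModel",
    "make_synthetic_alleles",
    "simulate_binding_data",
    "simulate_elution_data",
    "make_curation_fixture",
]

_N_AA = len(AMINO_ACIDS)
_AA_ARR = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class SyntheticAlleleModel:
    """Ground-truth binding model for one synthetic allele.

    ``true log10(IC50 nM) = offset - energy(peptide) + N(0, noise_sd)`` where
    the energy is the sum of per-position PSSM scores (anchor positions 2
    and 9 carry the largest weights) plus, optionally, neighbour-coupling
    terms.
    """

    allele: str
    pseudo: str
    pssm: np.ndarray  # (k, 20)
    noise_sd: float = 0.05
    offset: float = 4.5
    family: int = 0
    coupling: np.ndarray | None = None  # (k-1, 20, 20) or None

    def __post_init__(self) -> None:
        if self.pssm.shape[1] != _N_AA:
            raise DomainError("pssm must have 20 residue columns")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")

    @property
    def k(self) -> int:
        return self.pssm.shape[0]

    def energy(self, codes: np.ndarray) -> np.ndarray:
        """Motif energy for encoded peptides, shape (n, k) int codes."""
        codes = np.atleast_2d(codes)
        e = np.zeros(codes.shape[0])
        for j in range(self.k):
            e += self.pssm[j, codes[:, j]]
        if self.coupling is not None:
            for j in range(self.k - 1):
                e += self.coupling[j, codes[:, j], codes[:, j + 1]]
        return e

    def true_log10_ic50(self, peptides: Sequence[str]) -> np.ndarray:
        codes = encode_peptides(peptides)
        return self.offset - self.energy(codes)


def encode_peptides(peptides: Sequence[str]) -> np.ndarray:
    try:
        return np.array([[_CODE[a] for a in p] for p in peptides], dtype=np.int64)
    except KeyError as exc:
        raise DomainError(f"residue {exc} outside the 20-letter alphabet") from None


def _random_pseudo(rng: np.random.Generator, length: int = 34) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, _N_AA, size=length))


def _mutate_pseudo(rng: np.random.Generator, pseudo: str, n_mut: int) -> str:
    chars = list(pseudo)
    sites = rng.choice(len(chars), size=min(n_mut, len(chars)), replace=False)
    for s in sites:
        choices = [aa for aa in AMINO_ACIDS if aa != chars[s]]
        chars[s] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def make_synthetic_alleles(
    n_alleles: int,
    n_families: int,
    seed: int = 0,
    *,
    k: int = 9,
    family_sizes: Sequence[int] | None = None,
    anchor_positions: Sequence[int] = (2, 9),
    anchor_scale: float = 1.0,
    background_scale: float = 0.2,
    pssm_jitter_sd: float = 0.1,
    pseudo_mutations: int = 3,
    noise_sd: float = 0.05,
    offset: float = 4.5,
    with_coupling: bool = False,
    coupling_scale: float = 0.3,
) -> list[SyntheticAlleleModel]:
    """Generate allele families: prototype motifs plus per-allele jitter.

    Each family has a prototype pseudo-sequence and PSSM; member alleles
    copy the prototype with ``pseudo_mutations`` pseudo-sequence
    substitutions and Gaussian PSSM jitter — except the first two members
    of a family, which share the prototype pseudo-sequence exactly (an
    identical-pocket pair, the best case for cross-allele generalisation).
    A singleton family yields an isolated allele with no near neighbour.
    Within-family pseudo-sequence identity and motif correlation therefore
    exceed the across-family ones by construction.
    """
    if n_families > n_alleles:
        raise DomainError("n_families must be <= n_alleles")
    if family_sizes is not None:
        if len(family_sizes) != n_families or sum(family_sizes) != n_alleles:
            raise DomainError("family_sizes must sum to n_alleles over n_families entries")
        sizes = list(family_sizes)
    else:
        base, extra = divmod(n_alleles, n_families)
        sizes = [base + (1 if f < extra else 0) for f in range(n_families)]
    anchors = {p - 1 for p in anchor_positions}  # 1-based -> 0-based
    rng = np.random.default_rng(seed)

    models: list[SyntheticAlleleModel] = []
    for fam, size in enumerate(sizes):
        proto_pseudo = _random_pseudo(rng)
        scale = np.array(
            [anchor_scale if j in anchors else background_scale for j in range(k)]
        )
        proto_pssm = rng.normal(0.0, 1.0, size=(k, _N_AA)) * scale[:, None]
        proto_coupling = (
            rng.normal(0.0, coupling_scale, size=(k - 1, _N_AA, _N_AA))
            if with_coupling
            else None
        )
        for i in range(size):
            if i < 2:
                pseudo = proto_pseudo
            else:
                pseudo = _mutate_pseudo(rng, proto_pseudo, pseudo_mutations)
            pssm = proto_pssm + rng.normal(0.0, pssm_jitter_sd, size=(k, _N_AA))
            models.append(
                SyntheticAlleleModel(
                    allele=f"SYN-F{fam}A{i}",
                    pseudo=pseudo,
                    pssm=pssm,
                    noise_sd=noise_sd,
                    offset=offset,
                    family=fam,
                    coupling=proto_coupling,
                )
            )
    return models


def pseudo_table(models: Sequence[SyntheticAlleleModel]) -> dict[str, str]:
    """Allele -> pseudo-sequence mapping for the pan-allele model."""
    return {m.allele: m.pseudo for m in models}


def _sample_peptides(
    rng: np.random.Generator, model: SyntheticAlleleModel, n: int, betas: np.ndarray
) -> np.ndarray:
    """Sample peptides position-wise from softmax(beta * pssm).

    beta = 0 is the uniform residue background (typical non-binders);
    larger beta enriches for motif-matching (stronger) peptides, giving a
    broad affinity spread reminiscent of curated assay panels.
    """
    k = model.k
    codes = np.empty((n, k), dtype=np.int64)
    for j in range(k):
        logits = betas[:, None] * model.pssm[j][None, :]
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        cum = probs.cumsum(axis=1)
        u = rng.random(n)
        codes[:, j] = (u[:, None] > cum).sum(axis=1)
    return codes


def _decode(codes: np.ndarray) -> list[str]:
    return ["".join(AMINO_ACIDS[c] for c in row) for row in codes]


def simulate_binding_data(
    models: Sequence[SyntheticAlleleModel],
    n_per_allele: int,
    seed: int = 0,
    *,
    composition: tuple[float, float, float] | None = None,
    beta_max: float = 2.5,
    strong_cutoff_nm: float = 50.0,
    binder_cutoff_nm: float = 500.0,
    max_batches: int = 400,
) -> list[AffinityMeasurement]:
    """Draw noisy affinity measurements from the allele ground truths.

    Peptides are sampled with a per-peptide enrichment temperature in
    [0, beta_max], mixing motif-free background with motif-biased binders.
    With ``composition`` given (strong, weak, non fractions summing to 1)
    class quotas are filled by rejection, matching the target exactly up to
    integer rounding.  Measured values clamp to the [1, 50000] nM window.
    """
    if n_per_allele < 1:
        raise DomainError("n_per_allele must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[AffinityMeasurement] = []
    for model in models:
        if composition is None:
            betas = rng.uniform(0.0, beta_max, size=n_per_allele)
            codes = _sample_peptides(rng, model, n_per_allele, betas)
            log_ic50 = (
                model.offset
                - model.energy(codes)
                + rng.normal(0.0, model.noise_sd, size=n_per_allele)
            )
            values = np.clip(10.0**log_ic50, 1.0, 50000.0)
            for pep, v in zip(_decode(codes), values):
                out.append(
                    AffinityMeasurement(pep, model.allele, AssayType.IC50, float(v), "synth")
                )
            continue
        ps, pw, pn = composition
        if abs(ps + pw + pn - 1.0) > 1e-6:
            raise DomainError("composition fractions must sum to 1")
        quota = {
            "strong": round(ps * n_per_allele),
            "weak": round(pw * n_per_allele),
        }
        quota["non"] = n_per_allele - quota["strong"] - quota["weak"]
        got = {c: 0 for c in quota}
        kept: list[tuple[str, float]] = []
        for _ in range(max_batches):
            if all(got[c] >= quota[c] for c in quota):
                break
            batch = max(n_per_allele, 256)
            betas = rng.uniform(0.0, beta_max, size=batch)
            codes = _sample_peptides(rng, model, batch, betas)
            log_ic50 = (
                model.offset
                - model.energy(codes)
                + rng.normal(0.0, model.noise_sd, size=batch)
            )
            values = np.clip(10.0**log_ic50, 1.0, 50000.0)
            for pep, v in zip(_decode(codes), values):
                cls = (
                    "strong"
                    if v < strong_cutoff_nm
                    else "weak" if v <= binder_cutoff_nm else "non"
                )
                if got[cls] < quota[cls]:
                    got[cls] += 1
                    kept.append((pep, float(v)))
        if any(got[c] < quota[c] for c in quota):
            raise DomainError(
                f"could not fill class quotas for {model.allele}: {got} of {quota}"
            )
        for pep, v in kept:
            out.append(
                AffinityMeasurement(pep, model.allele, AssayType.IC50, v, "synth")
            )
    return out


def simulate_elution_data(
    models: Sequence[SyntheticAlleleModel],
    proteome_length: int = 50000,
    threshold_nm: float = 50.0,
    seed: int = 0,
    *,
    n_positives_per_allele: int | None = None,
    n_sequences: int = 25,
) -> tuple[dict[str, str], list[ElutionRecord]]:
    """Random proteome plus motif-positive eluted sets drawn from it.

    The proteome is uniform-random sequence split over ``n_sequences``
    records.  Per allele, every k-mer is scored by the noise-free ground
    truth and the qualifying binders (true IC50 below ``threshold_nm``)
    become the eluted repertoire, ordered strongest first; with
    ``n_positives_per_allele`` set only the strongest that many are kept —
    presentation favours the strongest binders, which is the feature of
    real ligandomes the benchmark depends on.  A benchmark that subsamples
    these positives should still pass the full repertoire to the decoy
    sampler's ``exclude`` so leftover binders cannot masquerade as decoys.
    Positives are verbatim proteome substrings, suitable input for decoy
    sampling and elution evaluation.
    """
    if proteome_length < 1000:
        raise DomainError("proteome_length must be >= 1000 residues")
    rng = np.random.default_rng(seed)
    lengths = np.full(n_sequences, proteome_length // n_sequences)
    lengths[: proteome_length % n_sequences] += 1
    proteome = {
        f"synprot{i:04d}": "".join(
            AMINO_ACIDS[c] for c in rng.integers(0, _N_AA, size=int(L))
        )
        for i, L in enumerate(lengths)
    }

    records: list[ElutionRecord] = []
    for model in models:
        k = model.k
        best: list[tuple[float, str]] = []
        for seq in proteome.values():
            if len(seq) < k:
                continue
            codes = encode_peptides([seq])[0]
            windows = np.lib.stride_tricks.sliding_window_view(codes, k)
            log_ic50 = model.offset - model.energy(windows)
            hit = np.flatnonzero(log_ic50 < np.log10(threshold_nm))
            for i in hit:
                best.append((float(log_ic50[i]), seq[i : i + k]))
        if not best:
            raise DomainError(
                f"no proteome {k}-mer binds {model.allele} below {threshold_nm} nM; "
                "raise threshold_nm or proteome_length"
            )
        best.sort()
        seen: set[str] = set()
        for _, pep in best:
            if pep in seen:
                continue
            seen.add(pep)
            records.append(ElutionRecord(pep, model.allele, "eluted", "synthetic"))
            if n_positives_per_allele is not None and len(seen) >= n_positives_per_allele:
                break
    return proteome, records


def make_curation_fixture() -> tuple[list[RawRecord], dict]:
    """Small raw-record set exercising every curation filter exactly once.

    The manifest carries the hand-counted expected survivor count after
    each step plus the training index the overlap filter needs.  Six
    records: one qualitative, one above the 50 000 nM ceiling, one 8-mer,
    one training-set duplicate, and two clean 9-mers.
    """
    records = [
        RawRecord("SIINFEKLM", "HLA-A0201", "IC50", "Positive", "fix-qualitative"),
        RawRecord("GILGFVFTL", "HLA-A0201", "IC50", 60000.0, "fix-over-ceiling"),
        RawRecord("NLVPMVAT", "HLA-A0201", "IC50", 30.0, "fix-8mer"),
        RawRecord("YLEPGPVTA", "HLA-A0201", "IC50", 120.0, "fix-train-dup"),
        RawRecord("FLSHDFTLV", "HLA-A0201", "IC50", 1.0, "fix-clean-1"),
        RawRecord("FLGGTPVCL", "HLA-A0201", "KD", 238.0, "fix-clean-2"),
    ]
    manifest = {
        "training_index": [("YLEPGPVTA", "HLA-A0201")],
        "expected_counts": {
            "input": 6,
            "after_assay_filter": 5,       # qualitative record dropped
            "after_ceiling_filter": 4,     # 60000 nM dropped
            "after_length_filter": 3,      # 8-mer dropped
            "after_training_overlap_filter": 2,  # training duplicate dropped
            "after_allele_coverage_filter": 2,   # coverage filter disabled
            "unparseable": 1,
        },
        "n_survivors": 2,
        "survivor_peptides": ["FLSHDFTLV", "FLGGTPVCL"],
    }
    return records, manifest
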