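"""MS-elution benchmarking: decoy generation, percentile ranks, FDr/FNr.

Eluted-ligand benchmarks score a predictor on separating peptides actually
recovered from MHC molecules (positives) from proteome-sampled decoys
(negatives).  Two of the three canonical dataset designs draw random
proteome k-mers as negatives — at 1:1 or 1:50 positive:negative ratio —
excluding any k-mer that aligns locally to a positive; the third design
(verified-binder negatives) is ingested as pre-labelled records and needs
no decoy generation.

Predictions are summarised at the conventional "top 2% percentile rank"
cutoff: a peptide is called presented if its score ranks within the
strongest 2% of a background score distribution for the same allele, and
per-allele false-discovery (FDr) and false-negative (FNr) rates are
reported alongside ROC/AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, DomainError
from .metrics import MetricUndefinedError, auc as _auc

__all__ = [
    "ElutionRecord",
    "DecoyConfig",
    "DecoySamplingError",
    "sample_decoys",
    "max_local_identity",
    "percentile_rank",
    "percentile_ranks",
    "evaluate_elution",
]

_AA_CODES = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class ElutionRecord:
    """One peptide with its eluted-positive or decoy-negative label."""

    peptide: str
    allele: str
    label: str  # "eluted" | "decoy"
    dataset: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("eluted", "decoy"):
            raise DomainError(f"label must be 'eluted' or 'decoy', got {self.label!r}")


@dataclass(frozen=True)
class DecoyConfig:
    """Decoy-sampling parameters: k-mer length, ratio, exclusion threshold."""

    k: int = 9
    ratio: int = 1
    exclusion_min_identity: int = 8
    seed: int = 0
    max_attempts_per_decoy: int = 1000

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise DomainError("ratio must be >= 1")
        if not (0 < self.exclusion_min_identity <= self.k):
            raise DomainError("need 0 < exclusion_min_identity <= k")


class DecoySamplingError(RuntimeError):
    """Raised when the proteome cannot supply enough admissible decoys."""

    def __init__(self, achieved: int, requested: int):
        self.achieved = achieved
        self.requested = requested
        super().__init__(
            f"could only sample {achieved} of {requested} decoys before the "
            "rejection budget ran out; supply a larger proteome or relax the "
            "exclusion threshold"
        )


def _encode_peptide(pep: str) -> np.ndarray | None:
    try:
        return np.array([_AA_CODES[a] for a in pep], dtype=np.int8)
    except KeyError:
        return None


def max_local_identity(candidate: str, positives_enc: np.ndarray, k: int,
                       min_overlap: int) -> int:
    """Best ungapped local-alignment identity count of a k-mer vs positives.

    Equal-length, gap-free identity scoring: the candidate is slid against
    each positive at every offset whose overlap is at least ``min_overlap``,
    and the maximum number of matching residues over all offsets and
    positives is returned.  For the default 8-of-9 threshold only offsets
    -1, 0 and +1 can matter.
    """
    cand = _encode_peptide(candidate)
    if cand is None:
        raise DomainError(f"candidate {candidate!r} has residues outside the alphabet")
    best = 0
    max_shift = k - min_overlap
    for d in range(-max_shift, max_shift + 1):
        if d >= 0:
            a, b = d, k
            ids = (positives_enc[:, a:b] == cand[: k - d]).sum(axis=1)
        else:
            a, b = -d, k
            ids = (positives_enc[:, : k + d] == cand[a:b]).sum(axis=1)
        m = int(ids.max()) if ids.size else 0
        best = max(best, m)
    return best


def sample_decoys(
    proteome: Mapping[str, str],
    positives: Iterable[str],
    config: DecoyConfig = DecoyConfig(),
    *,
    allele: str = "",
    dataset: str = "",
    exclude: Iterable[str] | None = None,
) -> list[ElutionRecord]:
    """Draw ``ratio x |positives|`` decoy k-mers uniformly from the proteome.

    A candidate is rejected if it contains a residue outside the 20-letter
    alphabet, equals an excluded peptide verbatim, or reaches
    ``exclusion_min_identity`` identities against any excluded peptide under
    ungapped local alignment.  The exclusion list defaults to the positives
    themselves; pass ``exclude`` to screen against a superset — e.g. the
    full presented repertoire when the benchmarked positives are a
    subsample of it.  Sampling is reproducible for a fixed seed; every
    emitted decoy is a verbatim substring of a proteome sequence.
    """
    pos_list = sorted(set(positives))
    if not pos_list:
        raise DomainError("positives must be non-empty")
    k = config.k
    excl_list = sorted(set(exclude)) if exclude is not None else pos_list
    if not set(pos_list) <= set(excl_list):
        raise DomainError("exclude must be a superset of positives")
    if any(len(p) != k for p in excl_list):
        raise DomainError(f"all positives/excluded peptides must be {k}-mers")
    enc = [_encode_peptide(p) for p in excl_list]
    if any(e is None for e in enc):
        raise DomainError("positives contain residues outside the alphabet")
    positives_enc = np.stack(enc)
    pos_set = set(excl_list)

    seq_ids = [sid for sid, seq in proteome.items() if len(seq) >= k]
    if not seq_ids:
        raise DomainError(f"no proteome sequence of length >= {k}")
    n_positions = np.array([len(proteome[sid]) - k + 1 for sid in seq_ids], dtype=float)
    weights = n_positions / n_positions.sum()

    n_needed = config.ratio * len(pos_list)
    rng = np.random.default_rng(config.seed)
    decoys: list[ElutionRecord] = []
    seen: set[str] = set()
    budget = config.max_attempts_per_decoy * n_needed
    attempts = 0
    while len(decoys) < n_needed:
        if attempts >= budget:
            raise DecoySamplingError(len(decoys), n_needed)
        attempts += 1
        sid = seq_ids[rng.choice(len(seq_ids), p=weights)]
        seq = proteome[sid]
        start = int(rng.integers(0, len(seq) - k + 1))
        cand = seq[start : start + k]
        if cand in seen or cand in pos_set:
            continue
        if any(a not in _AA_CODES for a in cand):
            continue
        if (
            max_local_identity(cand, positives_enc, k, config.exclusion_min_identity)
            >= config.exclusion_min_identity
        ):
            continue
        seen.add(cand)
        decoys.append(ElutionRecord(cand, allele, "decoy", dataset))
    return decoys


def percentile_rank(score: float, background: Sequence[float]) -> float:
    """Percent of background scores strictly stronger than ``score``.

    Scores follow the "higher = stronger" orientation, so the best possible
    score ranks 0.0 and a score weaker than the entire background ranks
    100.0.  Monotone: a strictly stronger score never gets a larger rank.
    """
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise DomainError("background must be non-empty")
    return float(100.0 * (bg > score).sum() / bg.size)


def percentile_ranks(scores: Sequence[float], background: Sequence[float]) -> np.ndarray:
    """Vectorised :func:`percentile_rank` for many scores at once."""
    bg = np.sort(np.asarray(background, dtype=float))
    if bg.size == 0:
        raise DomainError("background must be non-empty")
    s = np.asarray(scores, dtype=float)
    stronger = bg.size - np.searchsorted(bg, s, side="right")
    return 100.0 * stronger / bg.size


def evaluate_elution(
    records: Sequence[ElutionRecord],
    predictions: pd.DataFrame,
    cutoff_pct: float = 2.0,
) -> pd.DataFrame:
    """Per-allele, per-dataset confusion rates at a percentile-rank cutoff.

    ``predictions`` needs columns ``peptide, allele, rank_pct`` and
    optionally ``score`` (for eluted-vs-decoy AUC).  A record is predicted
    presented when its rank is <= ``cutoff_pct`` (a rank exactly at the
    cutoff counts positive).  FDr = FP/(FP+TP) among predicted positives;
    FNr = FN/(FN+TP) among the truly eluted; an allele with no eluted
    records gets NaN FNr and an ``fnr_undefined`` flag.
    """
    rec_df = pd.DataFrame(
        {
            "peptide": [r.peptide for r in records],
            "allele": [r.allele for r in records],
            "label": [r.label for r in records],
            "dataset": [r.dataset for r in records],
        }
    )
    need = {"peptide", "allele", "rank_pct"}
    if need - set(predictions.columns):
        raise DomainError(f"predictions lack columns {sorted(need - set(predictions.columns))}")
    merged = rec_df.merge(predictions, on=["peptide", "allele"], how="left")
    if merged["rank_pct"].isna().any():
        missing = merged.loc[merged["rank_pct"].isna(), "peptide"].head(3).tolist()
        raise DomainError(f"records without a rank, e.g. {missing}")

    rows = []
    for (dataset, allele), grp in merged.groupby(["dataset", "allele"], sort=True):
        eluted = grp["label"] == "eluted"
        called = grp["rank_pct"] <= cutoff_pct
        tp = int((eluted & called).sum())
        fp = int((~eluted & called).sum())
        fn = int((eluted & ~called).sum())
        tn = int((~eluted & ~called).sum())
        flags = []
        fdr = fp / (fp + tp) if (fp + tp) else np.nan
        if not (fp + tp):
            flags.append("no_predicted_positives")
        if eluted.any():
            fnr = fn / (fn + tp)
            tpr = tp / (tp + fn)
        else:
            fnr = tpr = np.nan
            flags.append("fnr_undefined")
        fpr = fp / (fp + tn) if (fp + tn) else np.nan
        if "score" in grp.columns and eluted.any() and (~eluted).any():
            try:
                roc_auc = _auc(eluted.astype(int), grp["score"].to_numpy(float))
            except MetricUndefinedError:
                roc_auc = np.nan
        else:
            roc_auc = np.nan
        rows.append(
            {
                "dataset": dataset,
                "allele": allele,
                "n_eluted": int(eluted.sum()),
                "n_decoy": int((~eluted).sum()),
                "fdr": fdr,
                "fnr": fnr,
                "tpr": tpr,
                "fpr": fpr,
                "auc": roc_auc,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)
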