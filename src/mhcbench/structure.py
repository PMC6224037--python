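"""Post-docking computation: score normalisation, RMSD clustering, selection.

Peptide-protein docking runs emit, per modelled peptide, an ensemble of
candidate structures ("decoys") each with a reweighted energy score (lower
= better) and pairwise structural RMSDs.  This module implements the three
post-processing steps such a run needs: per-allele min-max normalisation of
peptide scores onto (0, 1), greedy leader clustering of a decoy ensemble at
an RMSD threshold (default 2.5 Å), and selection of the lowest-scoring
model inside the largest cluster.  The docking itself (modelling,
refinement, energy evaluation) is out of scope; only its score and RMSD
tables are consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import DomainError
from .metrics import MetricUndefinedError

__all__ = [
    "StructureDecoy",
    "PairwiseRMSD",
    "Cluster",
    "normalize_scores",
    "cluster_decoys",
    "select_model",
]


@dataclass(frozen=True)
class StructureDecoy:
    """One docked candidate structure with its reweighted (energy-like) score."""

    decoy_id: str
    peptide: str
    allele: str
    reweighted_score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.reweighted_score):
            raise DomainError(f"decoy {self.decoy_id}: score must be finite")


class PairwiseRMSD:
    """Symmetric pairwise RMSD lookup (Å) over decoy ids, zero diagonal."""

    def __init__(self, entries: Mapping[tuple[str, str], float]):
        self._d: dict[frozenset[str], float] = {}
        for (i, j), v in entries.items():
            if v < 0:
                raise DomainError(f"negative RMSD for pair ({i}, {j})")
            if i == j and v != 0:
                raise DomainError(f"nonzero self-RMSD for {i}")
            self._d[frozenset((i, j))] = float(v)

    def get(self, i: str, j: str) -> float:
        if i == j:
            return 0.0
        try:
            return self._d[frozenset((i, j))]
        except KeyError:
            raise DomainError(f"missing RMSD entry for pair ({i}, {j})") from None

    @classmethod
    def from_long_table(cls, rows: Sequence[tuple[str, str, float]]) -> "PairwiseRMSD":
        return cls({(i, j): v for i, j, v in rows})


@dataclass
class Cluster:
    """A leader-clustered group; members include the leader."""

    leader: StructureDecoy
    members: list[StructureDecoy] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    def best(self) -> StructureDecoy:
        return min(self.members, key=lambda d: (d.reweighted_score, d.decoy_id))


def normalize_scores(
    scores: Sequence[tuple[str, float]]
) -> list[tuple[str, float]]:
    """Min-max normalise one allele's peptide scores onto [0, 1].

    Energies are "lower = better", so the strongest (lowest-energy) peptide
    maps to 1 and the weakest to 0; the map is monotone, hence
    rank-preserving.  All-identical scores are undefined for this allele.
    """
    if len(scores) < 2:
        raise DomainError("need at least two scored peptides per allele")
    values = np.array([s for _, s in scores], dtype=float)
    if not np.all(np.isfinite(values)):
        raise DomainError("scores must be finite")
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise MetricUndefinedError("all scores identical; normalisation undefined")
    norm = (hi - values) / (hi - lo)
    return [(name, float(v)) for (name, _), v in zip(scores, norm)]


def cluster_decoys(
    decoys: Sequence[StructureDecoy],
    rmsd: PairwiseRMSD,
    threshold_angstrom: float = 2.5,
) -> list[Cluster]:
    """Greedy score-ordered leader clustering at an RMSD threshold.

    Repeatedly take the lowest-score unassigned decoy as a leader and
    assign every unassigned decoy within the threshold of it.  The result
    partitions the ensemble, every member lies within the threshold of its
    leader, and the procedure is deterministic (score, then id, order).
    """
    if not decoys:
        raise DomainError("no decoys to cluster")
    remaining = sorted(decoys, key=lambda d: (d.reweighted_score, d.decoy_id))
    clusters: list[Cluster] = []
    while remaining:
        leader = remaining[0]
        members = [d for d in remaining if rmsd.get(leader.decoy_id, d.decoy_id) <= threshold_angstrom]
        clusters.append(Cluster(leader=leader, members=members))
        taken = {d.decoy_id for d in members}
        remaining = [d for d in remaining if d.decoy_id not in taken]
    return clusters


def select_model(clusters: Sequence[Cluster]) -> StructureDecoy:
    """Lowest-scoring member of the largest cluster.

    Tie-breaks, for full determinism: equal cluster sizes -> the cluster
    whose best score is lower; equal scores -> lexicographic decoy id.
    """
    if not clusters:
        raise DomainError("no clusters supplied")
    best_cluster = min(
        clusters,
        key=lambda c: (-c.size, c.best().reweighted_score, c.best().decoy_id),
    )
    return best_cluster.best()
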