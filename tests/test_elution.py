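"""Decoy sampling, percentile ranks and the elution confusion table."""

import numpy as np
import pandas as pd
import pytest

from mhcbench.core import DomainError
from mhcbench.elution import (
    DecoyConfig,
    DecoySamplingError,
    ElutionRecord,
    evaluate_elution,
    max_local_identity,
    percentile_rank,
    percentile_ranks,
    sample_decoys,
)


@pytest.fixture(scope="module")
def small_proteome():
    rng = np.random.default_rng(21)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    return {
        f"prot{i}": "".join(rng.choice(aas, size=400)) for i in range(5)
    }


@pytest.fixture(scope="module")
def positives(small_proteome):
    # real substrings, so the identity filter has work to do
    seq = small_proteome["prot0"]
    return [seq[i : i + 9] for i in range(0, 180, 9)]


class TestSampleDecoys:
    @pytest.mark.parametrize("n_pos,ratio", [(20, 1), (4, 50)])
    def test_exact_counts(self, small_proteome, positives, n_pos, ratio):
        decoys = sample_decoys(
            small_proteome, positives[:n_pos], DecoyConfig(ratio=ratio, seed=3)
        )
        assert len(decoys) == ratio * n_pos
        assert all(d.label == "decoy" for d in decoys)

    def test_decoys_are_substrings_and_dissimilar(self, small_proteome, positives):
        config = DecoyConfig(ratio=2, seed=4)
        decoys = sample_decoys(small_proteome, positives, config)
        enc = np.stack(
            [[list("ACDEFGHIKLMNPQRSTVWY").index(a) for a in p] for p in positives]
        ).astype(np.int8)
        for d in decoys:
            assert any(d.peptide in seq for seq in small_proteome.values())
            assert d.peptide not in positives
            assert max_local_identity(d.peptide, enc, 9, 8) < 8

    def test_seed_reproducibility(self, small_proteome, positives):
        a = sample_decoys(small_proteome, positives, DecoyConfig(seed=7))
        b = sample_decoys(small_proteome, positives, DecoyConfig(seed=7))
        c = sample_decoys(small_proteome, positives, DecoyConfig(seed=8))
        assert [d.peptide for d in a] == [d.peptide for d in b]
        assert [d.peptide for d in a] != [d.peptide for d in c]

    def test_exhaustion_reports_achieved_count(self):
        tiny = {"p": "ACDEFGHIKLMNP"}  # 5 distinct 9-mers at most
        with pytest.raises(DecoySamplingError) as err:
            sample_decoys(
                tiny, ["ACDEFGHIK"],
                DecoyConfig(ratio=50, seed=1, max_attempts_per_decoy=10),
            )
        assert err.value.achieved < err.value.requested

    def test_exclude_superset(self, small_proteome, positives):
        # decoys must also avoid the excluded (non-benchmarked) repertoire
        exclude = positives
        decoys = sample_decoys(
            small_proteome, positives[:5], DecoyConfig(ratio=1, seed=5),
            exclude=exclude,
        )
        assert all(d.peptide not in set(exclude) for d in decoys)
        with pytest.raises(DomainError, match="superset"):
            sample_decoys(
                small_proteome, positives[:5], DecoyConfig(seed=5),
                exclude=positives[1:3],
            )


class TestLocalIdentity:
    def test_against_scikit_bio_smith_waterman(self):
        """Cross-check the ungapped identity count with a real SW aligner."""
        pytest.importorskip("skbio")
        from skbio import Protein
        from skbio.alignment import local_pairwise_align

        rng = np.random.default_rng(17)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        # identity scoring with prohibitive mismatch/gap penalties: the SW
        # score is then the longest exact common run, which can only be <=
        # our best whole-window identity count
        matrix = {x: {y: (1.0 if x == y else -9.0) for y in aas} for x in aas}
        for _ in range(15):
            a = "".join(rng.choice(list(aas), size=9))
            b = "".join(rng.choice(list(aas), size=9))
            enc = np.array([[aas.index(x) for x in b]], dtype=np.int8)
            ours = max_local_identity(a, enc, 9, 1)
            try:
                _, score, _ = local_pairwise_align(
                    Protein(a), Protein(b), gap_open_penalty=10,
                    gap_extend_penalty=10, substitution_matrix=matrix,
                )
            except Exception:
                continue  # no positive-scoring alignment exists
            assert ours >= score
        # and on a designed shifted pair the two agree exactly
        enc = np.array([[aas.index(x) for x in "ACDEFGHIK"]], dtype=np.int8)
        _, score, _ = local_pairwise_align(
            Protein("CDEFGHIKW"), Protein("ACDEFGHIK"), gap_open_penalty=10,
            gap_extend_penalty=10, substitution_matrix=matrix,
        )
        assert max_local_identity("CDEFGHIKW", enc, 9, 8) == score == 8

    def test_detects_shifted_overlap(self):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        pos = "ACDEFGHIK"
        enc = np.array([[aas.index(x) for x in pos]], dtype=np.int8)
        shifted = "CDEFGHIKW"  # 8 identities at offset +1
        assert max_local_identity(shifted, enc, 9, 8) == 8


class TestPercentileRank:
    def test_extremes_and_median(self):
        bg = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert percentile_rank(9.0, bg) == 0.0
        assert percentile_rank(3.0, bg) == pytest.approx(40.0)
        assert percentile_rank(0.5, bg) == 100.0
        with pytest.raises(DomainError):
            percentile_rank(1.0, [])

    def test_monotone_and_vectorised(self):
        rng = np.random.default_rng(2)
        bg = rng.normal(size=101)
        scores = np.sort(rng.normal(size=20))
        ranks = percentile_ranks(scores, bg)
        assert np.all(np.diff(ranks) <= 0)  # stronger score, never larger rank
        assert np.allclose(ranks, [percentile_rank(s, bg) for s in scores])


class TestEvaluateElution:
    AA = "ACDEFGHIKLMNPQRSTVWY"

    def _records(self, allele="SYN-A0", n_eluted=10, n_decoy=10):
        eluted = [
            ElutionRecord(f"AAAAAAAA{self.AA[i]}", allele, "eluted", "d1")
            for i in range(n_eluted)
        ]
        decoys = [
            ElutionRecord(f"CCCCCCCC{self.AA[i]}", allele, "decoy", "d1")
            for i in range(n_decoy)
        ]
        return eluted + decoys

    def test_contingency_arithmetic(self):
        records = self._records()
        # 7 of 10 eluted inside the cutoff, 3 decoys inside
        ranks = [1.0] * 7 + [50.0] * 3 + [1.5] * 3 + [80.0] * 7
        pred = pd.DataFrame(
            {
                "peptide": [r.peptide for r in records],
                "allele": [r.allele for r in records],
                "rank_pct": ranks,
            }
        )
        out = evaluate_elution(records, pred, cutoff_pct=2.0)
        row = out.iloc[0]
        assert row["fnr"] == pytest.approx(0.3)
        assert row["fdr"] == pytest.approx(0.3)
        assert row["tpr"] == pytest.approx(0.7)

    def test_perfect_separation(self):
        records = self._records()
        pred = pd.DataFrame(
            {
                "peptide": [r.peptide for r in records],
                "allele": [r.allele for r in records],
                "rank_pct": [0.5] * 10 + [60.0] * 10,
                "score": list(range(20, 0, -1)),
            }
        )
        row = evaluate_elution(records, pred).iloc[0]
        assert row["fdr"] == 0.0 and row["fnr"] == 0.0 and row["auc"] == 1.0

    def test_rank_exactly_at_cutoff_counts_positive(self):
        records = self._records(n_eluted=1, n_decoy=1)
        pred = pd.DataFrame(
            {
                "peptide": [r.peptide for r in records],
                "allele": [r.allele for r in records],
                "rank_pct": [2.0, 2.01],
            }
        )
        row = evaluate_elution(records, pred, cutoff_pct=2.0).iloc[0]
        assert row["fnr"] == 0.0 and row["fdr"] == 0.0

    def test_two_alleles_two_rows_and_undefined_fnr(self):
        records = self._records("SYN-A0") + [
            ElutionRecord("DDDDDDDDD", "SYN-A1", "decoy", "d1")
        ]
        pred = pd.DataFrame(
            {
                "peptide": [r.peptide for r in records],
                "allele": [r.allele for r in records],
                "rank_pct": [1.0] * len(records),
            }
        )
        out = evaluate_elution(records, pred)
        assert len(out) == 2
        a1 = out[out["allele"] == "SYN-A1"].iloc[0]
        assert np.isnan(a1["fnr"]) and "fnr_undefined" in a1["flags"]
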