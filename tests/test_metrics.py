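"""Metric suite: brute-force oracles, analytic limits, report plumbing."""

import numpy as np
import pandas as pd
import pytest

from mhcbench.core import AffinityMeasurement, AssayType, ClassScheme
from mhcbench.metrics import (
    MetricUndefinedError,
    ThreeClassSample,
    allele_cutoff_75,
    auc,
    benchmark_report,
    bootstrap_ci,
    r_squared_transformed,
    reports_to_frame,
    roc_points,
    spe_strong,
    srcc,
    vus,
)


def brute_force_auc(labels, scores):
    """Oracle: explicit pair counting with half credit for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos, neg = scores[labels == 1], scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_vus(s, w, n):
    """Oracle: explicit triple counting, multiplicative half credit per tie."""
    total = 0.0
    for a in s:
        for b in w:
            for c in n:
                sw = 1.0 if a > b else (0.5 if a == b else 0.0)
                wn = 1.0 if b > c else (0.5 if b == c else 0.0)
                total += sw * wn
    return total / (len(s) * len(w) * len(n))


class TestAUC:
    def test_worked_example(self):
        assert auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]) == pytest.approx(0.75)

    def test_limits(self):
        assert auc([1, 1, 0], [3.0, 2.0, 1.0]) == 1.0
        assert auc([1, 0, 1, 0], [1.0, 1.0, 1.0, 1.0]) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(MetricUndefinedError):
            auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(4, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # coarse grid forces plenty of tied scores
            scores = rng.integers(0, 5, size=n).astype(float)
            assert auc(labels, scores) == pytest.approx(
                brute_force_auc(labels, scores), abs=1e-12
            )

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(3)
        labels = np.array([1] * 10 + [0] * 15)
        scores = rng.normal(size=25)  # continuous: tie-free
        assert auc(labels, scores) + auc(labels, -scores) == pytest.approx(1.0)

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(4)
        pts = roc_points(rng.integers(0, 2, 50), rng.normal(size=50))
        assert (np.diff(pts["fpr"]) >= 0).all() and (np.diff(pts["tpr"]) >= 0).all()


class TestVUS:
    def test_worked_example(self):
        s = ThreeClassSample(np.array([0.9, 0.5]), np.array([0.6]), np.array([0.1]))
        assert vus(s) == pytest.approx(0.5)

    def test_limits(self):
        ordered = ThreeClassSample(np.array([3.0, 2.5]), np.array([2.0]), np.array([1.0]))
        assert vus(ordered) == 1.0
        reversed_ = ThreeClassSample(np.array([1.0]), np.array([2.0]), np.array([3.0]))
        assert vus(reversed_) == 0.0

    def test_empty_class_undefined(self):
        with pytest.raises(MetricUndefinedError):
            vus(ThreeClassSample(np.array([1.0]), np.array([]), np.array([0.0])))

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            s = rng.integers(0, 6, size=int(rng.integers(2, 25))).astype(float)
            w = rng.integers(0, 6, size=int(rng.integers(2, 25))).astype(float)
            n = rng.integers(0, 6, size=int(rng.integers(2, 25))).astype(float)
            assert vus(ThreeClassSample(s, w, n)) == pytest.approx(
                brute_force_vus(s, w, n), abs=1e-12
            )

    def test_reversal_symmetry_tie_free(self):
        # negating scores and swapping the outer class roles is an exact
        # symmetry of the triple-ordering volume (note: plain score negation
        # does NOT give 1 - VUS — the four middle orderings of a triple
        # count in neither direction)
        rng = np.random.default_rng(12)
        s, w, n = rng.normal(size=9), rng.normal(size=7), rng.normal(size=8)
        forward = vus(ThreeClassSample(s, w, n))
        backward = vus(ThreeClassSample(-n, -w, -s))
        assert backward == pytest.approx(forward)
        assert vus(ThreeClassSample(-s, -w, -n)) <= 1.0 - forward

    def test_from_measurements_classifies(self):
        sample = ThreeClassSample.from_measurements(
            [10.0, 300.0, 5000.0], [0.9, 0.6, 0.1], ClassScheme.for_class("I")
        )
        assert sample.scores_strong.tolist() == [0.9]
        assert sample.scores_weak.tolist() == [0.6]
        assert sample.scores_non.tolist() == [0.1]


class TestAffinityMetrics:
    def test_spe_strong_arithmetic(self):
        measured = [10.0] * 10 + [900.0] * 5
        predicted = [20.0] * 7 + [80.0] * 3 + [900.0] * 5
        spe, fnr = spe_strong(measured, predicted)
        assert spe == pytest.approx(0.7) and fnr == pytest.approx(0.3)
        assert spe + fnr == pytest.approx(1.0)

    def test_spe_limits_and_undefined(self):
        assert spe_strong([10.0, 20.0], [30.0, 5.0])[0] == 1.0
        assert spe_strong([10.0, 20.0], [60000.0, 60000.0])[0] == 0.0
        with pytest.raises(MetricUndefinedError):
            spe_strong([1000.0], [10.0])

    def test_srcc_examples(self):
        assert srcc([1, 2, 3, 4], [1, 2, 4, 3]) == pytest.approx(0.8)
        assert srcc([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert srcc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        with pytest.raises(MetricUndefinedError):
            srcc([1.0, 1.0, 1.0], [1, 2, 3])

    def test_r_squared(self):
        measured = [5.0, 50.0, 500.0, 5000.0]
        assert r_squared_transformed(measured, measured) == pytest.approx(1.0)
        with pytest.raises(MetricUndefinedError):
            r_squared_transformed([100.0] * 4, measured)
        # closed-form OLS oracle on the transformed scale
        from mhcbench.core import transform_affinity

        predicted = [10.0, 30.0, 900.0, 2000.0]
        x = np.array(transform_affinity(measured))
        y = np.array(transform_affinity(predicted))
        r = np.corrcoef(x, y)[0, 1]
        assert r_squared_transformed(predicted, measured) == pytest.approx(r**2)


class TestBootstrap:
    def test_deterministic_and_degenerate(self):
        data = (np.array([1, 1, 0, 0, 1, 0]), np.array([0.9, 0.8, 0.3, 0.2, 0.7, 0.1]))
        ci1 = bootstrap_ci(auc, data, n_boot=200, seed=5, stratify=data[0])
        ci2 = bootstrap_ci(auc, data, n_boot=200, seed=5, stratify=data[0])
        assert ci1 == ci2
        const = (np.ones(6), np.ones(6) * 2.5)
        lo, hi = bootstrap_ci(lambda a, b: float(b.mean()), const, n_boot=50, seed=1)
        assert lo == hi == 2.5

    def test_coverage_on_separated_classes(self):
        """CI covers the true AUC for the generating model ~95% of the time."""
        rng = np.random.default_rng(99)
        true_auc = 0.8389  # P(N(1.4,1) > N(0,1)) = Phi(1.4 / sqrt(2))
        covered = 0
        runs = 60
        for _ in range(runs):
            labels = np.array([1] * 40 + [0] * 40)
            scores = np.concatenate([rng.normal(1.4, 1, 40), rng.normal(0, 1, 40)])
            lo, hi = bootstrap_ci(
                auc, (labels, scores), n_boot=150,
                seed=int(rng.integers(2**31)), stratify=labels,
            )
            covered += lo <= true_auc <= hi
        assert covered / runs >= 0.85  # loose: 60 runs at n_boot 150


class TestAlleleCutoff:
    @pytest.mark.parametrize(
        "values,expected",
        [([10, 20, 30, 40], 30.0), ([100], 100.0), ([50, 50, 50, 50], 50.0)],
    )
    def test_examples(self, values, expected):
        assert allele_cutoff_75(values) == expected

    def test_covers_75_percent(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(1, 500, size=37)
        t = allele_cutoff_75(values)
        assert (values <= t).mean() >= 0.75
        # smallest such measured value
        smaller = values[values < t]
        if smaller.size:
            assert (values <= smaller.max()).mean() < 0.75


def _measurements(n_per_allele=30, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for allele in ("SYN-A0", "SYN-A1"):
        values = 10 ** rng.uniform(0.5, 4.5, size=n_per_allele)
        for i, v in enumerate(values):
            pep = "".join(rng.choice(list("ACDEFGHIK"), size=9))
            out.append(AffinityMeasurement(pep + str(), allele, AssayType.IC50, float(v)))
    return out


class TestBenchmarkReport:
    def test_oracle_predictor_perfect_everywhere(self):
        measurements = _measurements()
        from mhcbench.core import transform_affinity

        pred = pd.DataFrame(
            {
                "peptide": [m.peptide for m in measurements],
                "allele": [m.allele for m in measurements],
                "predictor": "oracle",
                "score": transform_affinity([m.value_nm for m in measurements]),
                "predicted_nm": [m.value_nm for m in measurements],
            }
        )
        reports, log = benchmark_report(measurements, pred)
        assert {r.allele for r in reports} == {"SYN-A0", "SYN-A1", "ALL"}
        for r in reports:
            assert r.auc == pytest.approx(1.0)
            assert r.vus == pytest.approx(1.0)
            assert r.srcc == pytest.approx(1.0)
            assert r.r_squared == pytest.approx(1.0)
            assert r.spe == pytest.approx(1.0)
        assert log["oracle"]["n_unmatched"] == 0
        frame = reports_to_frame(reports)
        assert len(frame) == 3

    def test_no_overlap_predictor_reported_empty(self):
        measurements = _measurements()
        pred = pd.DataFrame(
            {
                "peptide": ["WWWWWWWWW"],
                "allele": ["SYN-A0"],
                "predictor": "stranger",
                "score": [0.5],
            }
        )
        reports, log = benchmark_report(measurements, pred)
        assert reports[0].n == 0 and "no joinable records" in reports[0].flags
        assert log["stranger"]["n_unmatched"] == 1

    def test_low_n_flagged_and_allele_cutoffs(self):
        measurements = _measurements(n_per_allele=8, seed=3)
        pred = pd.DataFrame(
            {
                "peptide": [m.peptide for m in measurements],
                "allele": [m.allele for m in measurements],
                "predictor": "p",
                "score": np.linspace(0, 1, len(measurements)),
            }
        )
        reports, _ = benchmark_report(
            measurements, pred, min_n=10, allele_specific_cutoffs=True
        )
        per_allele = [r for r in reports if r.allele != "ALL"]
        assert all(any(f.startswith("low_n") for f in r.flags) for r in per_allele)
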