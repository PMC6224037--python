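"""Evaluation-metric suite for binding predictors.

Binary classification is scored by ROC/AUC (Mann-Whitney estimator, tied
pairs credited 1/2), affinity ranking by Spearman correlation, absolute
affinity recovery by OLS R^2 on the normalised log scale, and three-class
(strong / weak / non-binder) discrimination by the volume under the
three-class ROC surface (VUS): the probability that a random
(strong, weak, non) score triple is correctly ordered.  Strong-binder recall
(SPE) and its complement FNr quantify how many sub-50 nM binders a predictor
misses.  Uncertainty is reported as bootstrap percentile confidence
intervals, stratified by class for the classification metrics.

All metrics operate on the internal "higher score = stronger binding"
orientation.  A metric that is mathematically undefined on its input (single
class, constant vector, empty stratum) raises :class:`MetricUndefinedError`
rather than returning a number; the report aggregator converts that into a
flagged empty cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .core import (
    AffinityMeasurement,
    BinderClass,
    ClassScheme,
    DomainError,
    classify_affinity,
    transform_affinity,
)

__all__ = [
    "MetricUndefinedError",
    "ThreeClassSample",
    "MetricReport",
    "auc",
    "roc_points",
    "vus",
    "spe_strong",
    "srcc",
    "r_squared_transformed",
    "bootstrap_ci",
    "allele_cutoff_75",
    "benchmark_report",
]


class MetricUndefinedError(ValueError):
    """The metric is mathematically undefined on this input."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite values")
    return arr


# ---------------------------------------------------------------------------
# binary classification


def auc(labels, scores) -> float:
    """Area under the ROC curve (probability a positive outranks a negative).

    Ties between a positive and a negative score receive 1/2 credit, the
    Mann-Whitney convention.
    """
    y = np.asarray(labels).ravel().astype(int)
    s = _as_float_array(scores, "scores")
    if y.shape != s.shape:
        raise DomainError("labels and scores must have equal length")
    if len(np.unique(y)) < 2:
        raise MetricUndefinedError("AUC needs both classes present")
    return float(roc_auc_score(y, s))


def roc_points(labels, scores) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for plotting/export."""
    y = np.asarray(labels).ravel().astype(int)
    s = _as_float_array(scores, "scores")
    if len(np.unique(y)) < 2:
        raise MetricUndefinedError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------------
# three-class VUS


@dataclass(frozen=True)
class ThreeClassSample:
    """Predictor scores grouped by the measured strong/weak/non class."""

    scores_strong: np.ndarray
    scores_weak: np.ndarray
    scores_non: np.ndarray

    @classmethod
    def from_measurements(
        cls,
        measured_nm: Sequence[float],
        scores: Sequence[float],
        scheme: ClassScheme = ClassScheme(),
    ) -> "ThreeClassSample":
        nm = _as_float_array(measured_nm, "measured_nm")
        s = _as_float_array(scores, "scores")
        if nm.shape != s.shape:
            raise DomainError("measured_nm and scores must have equal length")
        labels = np.array([classify_affinity(v, scheme).value for v in nm])
        return cls(
            scores_strong=s[labels == "strong"],
            scores_weak=s[labels == "weak"],
            scores_non=s[labels == "non"],
        )


def vus(sample: ThreeClassSample) -> float:
    """Empirical volume under the three-class ROC surface.

    The mean over all (strong, weak, non) score triples of the ordering
    indicator I(s > w > n); a tied adjacent comparison contributes
    multiplicative 1/2 credit (both tied: 1/4).  Chance level for continuous
    scores is 1/6.  Computed exactly in O(N log N) by factorising the triple
    sum over the weak score; tests pin it to brute-force triple counting.
    """
    s = _as_float_array(sample.scores_strong, "scores_strong")
    w = _as_float_array(sample.scores_weak, "scores_weak")
    n = _as_float_array(sample.scores_non, "scores_non")
    if min(s.size, w.size, n.size) == 0:
        raise MetricUndefinedError("VUS needs all three classes non-empty")
    s_sorted = np.sort(s)
    n_sorted = np.sort(n)
    # per weak score: (# strong above + half ties) * (# non below + half ties)
    s_above = s.size - np.searchsorted(s_sorted, w, side="right")
    s_tied = np.searchsorted(s_sorted, w, side="right") - np.searchsorted(
        s_sorted, w, side="left"
    )
    n_below = np.searchsorted(n_sorted, w, side="left")
    n_tied = np.searchsorted(n_sorted, w, side="right") - n_below
    credit = (s_above + 0.5 * s_tied) * (n_below + 0.5 * n_tied)
    return float(credit.sum() / (s.size * w.size * n.size))


# ---------------------------------------------------------------------------
# strong-binder recall, rank correlation, regression


def spe_strong(
    measured_nm: Sequence[float],
    predicted_nm: Sequence[float],
    strong_cutoff_nm: float = 50.0,
) -> tuple[float, float]:
    """Strong-binder recall (SPE) and its complement FNr.

    SPE is the fraction of measured sub-cutoff binders whose predicted
    affinity is also below the cutoff; FNr = 1 - SPE is the rate at which
    strong binders are falsely filtered out at the 50 nM threshold.
    """
    m = _as_float_array(measured_nm, "measured_nm")
    p = _as_float_array(predicted_nm, "predicted_nm")
    if m.shape != p.shape:
        raise DomainError("paired lists must have equal length")
    strong = m < strong_cutoff_nm
    if not strong.any():
        raise MetricUndefinedError("no measured strong binders in sample")
    spe = float((p[strong] < strong_cutoff_nm).mean())
    return spe, 1.0 - spe


def srcc(predicted, measured) -> float:
    """Spearman rank correlation between predicted and measured strengths.

    Both vectors must share one orientation; a perfect predictor gives +1.
    Average ranks are assigned to ties.
    """
    p = _as_float_array(predicted, "predicted")
    m = _as_float_array(measured, "measured")
    if p.shape != m.shape or p.size < 3:
        raise DomainError("need paired vectors of length >= 3")
    if np.all(p == p[0]) or np.all(m == m[0]):
        raise MetricUndefinedError("rank correlation undefined for constant vector")
    return float(stats.spearmanr(p, m).statistic)


def r_squared_transformed(
    predicted_nm, measured_nm, *, transformed: bool = True
) -> float:
    """Coefficient of determination of predicted-on-measured OLS.

    By default both affinities are mapped to the normalised log scale first,
    matching how affinity regressions are conventionally plotted; set
    ``transformed=False`` for raw-nM regression.
    """
    p = _as_float_array(predicted_nm, "predicted_nm")
    m = _as_float_array(measured_nm, "measured_nm")
    if p.shape != m.shape or p.size < 3:
        raise DomainError("need paired vectors of length >= 3")
    if transformed:
        p, m = transform_affinity(p), transform_affinity(m)
        p, m = np.atleast_1d(p), np.atleast_1d(m)
    if np.ptp(p) == 0 or np.ptp(m) == 0:
        raise MetricUndefinedError("R^2 undefined for zero-variance vector")
    fit = stats.linregress(m, p)
    return float(fit.rvalue**2)


# ---------------------------------------------------------------------------
# uncertainty and cutoffs


def bootstrap_ci(
    metric: Callable[..., float],
    data: Sequence[np.ndarray],
    *,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    stratify: np.ndarray | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for ``metric(*columns)``.

    ``data`` is a sequence of equal-length arrays resampled row-wise with
    replacement; with ``stratify`` given, resampling is done within each
    stratum so classification metrics keep every class represented.
    Deterministic for a fixed seed.  Fails if the metric is undefined on more
    than half of the resamples.
    """
    cols = [np.asarray(c) for c in data]
    n = cols[0].shape[0]
    if any(c.shape[0] != n for c in cols):
        raise DomainError("bootstrap columns must share length")
    rng = np.random.default_rng(seed)
    if stratify is not None:
        strata = [np.flatnonzero(np.asarray(stratify) == g) for g in
                  pd.unique(np.asarray(stratify))]
    values = []
    n_undefined = 0
    for _ in range(n_boot):
        if stratify is None:
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.concatenate(
                [s[rng.integers(0, s.size, size=s.size)] for s in strata]
            )
        try:
            values.append(metric(*(c[idx] for c in cols)))
        except MetricUndefinedError:
            n_undefined += 1
    if n_undefined > n_boot / 2:
        raise MetricUndefinedError(
            f"metric undefined on {n_undefined}/{n_boot} bootstrap resamples"
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def allele_cutoff_75(binder_ic50s: Sequence[float]) -> float:
    """Allele-specific IC50 cutoff capturing at least 75% of its binders.

    The smallest measured value t such that >= 75% of the allele's binder
    affinities satisfy IC50 <= t (empirical 75th percentile, lower-value
    convention).
    """
    v = np.sort(_as_float_array(binder_ic50s, "binder_ic50s"))
    if v.size == 0:
        raise MetricUndefinedError("no binder affinities supplied")
    k = int(np.ceil(0.75 * v.size))
    return float(v[k - 1])


# ---------------------------------------------------------------------------
# report aggregation


@dataclass
class MetricReport:
    """Per-predictor, per-allele metric bundle (allele ``"ALL"`` = pooled)."""

    predictor: str
    allele: str
    n: int
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    srcc: float | None = None
    srcc_ci: tuple[float, float] | None = None
    vus: float | None = None
    vus_ci: tuple[float, float] | None = None
    spe: float | None = None
    fnr_strong: float | None = None
    r_squared: float | None = None
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {
            "predictor": self.predictor,
            "allele": self.allele,
            "n": self.n,
            "auc": self.auc,
            "srcc": self.srcc,
            "vus": self.vus,
            "spe": self.spe,
            "fnr_strong": self.fnr_strong,
            "r_squared": self.r_squared,
            "flags": ";".join(self.flags),
        }
        for name, ci in (("auc", self.auc_ci), ("srcc", self.srcc_ci), ("vus", self.vus_ci)):
            d[f"{name}_lo"], d[f"{name}_hi"] = ci if ci else (None, None)
        return d


def _metric_cell(fn, *args):
    try:
        return fn(*args), None
    except MetricUndefinedError as exc:
        return None, str(exc)


def _report_for_group(
    predictor: str,
    allele: str,
    group: pd.DataFrame,
    scheme: ClassScheme,
    *,
    min_n: int,
    compute_ci: bool,
    n_boot: int,
    seed: int,
) -> MetricReport:
    n = len(group)
    rep = MetricReport(predictor=predictor, allele=allele, n=n)
    if n < min_n:
        rep.flags.append(f"low_n<{min_n}")
    measured = group["value_nm"].to_numpy(float)
    scores = group["score"].to_numpy(float)
    labels = (measured <= scheme.binder_cutoff_nm).astype(int)
    cls = np.array([classify_affinity(v, scheme).value for v in measured])

    rep.auc, err = _metric_cell(auc, labels, scores)
    if err:
        rep.flags.append(f"auc:{err}")
    sample = ThreeClassSample.from_measurements(measured, scores, scheme)
    rep.vus, err = _metric_cell(vus, sample)
    if err:
        rep.flags.append(f"vus:{err}")

    has_nm = "predicted_nm" in group and group["predicted_nm"].notna().all()
    if has_nm:
        pred_nm = group["predicted_nm"].to_numpy(float)
        spe_pair, err = _metric_cell(spe_strong, measured, pred_nm, scheme.strong_cutoff_nm)
        if err:
            rep.flags.append(f"spe:{err}")
        else:
            rep.spe, rep.fnr_strong = spe_pair
        rep.r_squared, err = _metric_cell(r_squared_transformed, pred_nm, measured)
        if err:
            rep.flags.append(f"r2:{err}")
    else:
        rep.flags.append("score_only:no predicted_nm; SPE/R2 not comparable")
    # SRCC on the shared "higher = stronger" orientation (score vs -log nM)
    rep.srcc, err = _metric_cell(srcc, scores, -np.log10(measured))
    if err:
        rep.flags.append(f"srcc:{err}")

    if compute_ci and n >= min_n:
        if rep.auc is not None:
            rep.auc_ci = bootstrap_ci(
                auc, (labels, scores), n_boot=n_boot, seed=seed, stratify=labels
            )
        if rep.vus is not None:
            rep.vus_ci = bootstrap_ci(
                lambda m, s: vus(ThreeClassSample.from_measurements(m, s, scheme)),
                (measured, scores),
                n_boot=n_boot,
                seed=seed,
                stratify=cls,
            )
        if rep.srcc is not None:
            rep.srcc_ci = bootstrap_ci(
                srcc, (scores, -np.log10(measured)), n_boot=n_boot, seed=seed
            )
    return rep


def benchmark_report(
    measurements: Sequence[AffinityMeasurement],
    predictions: pd.DataFrame,
    scheme: ClassScheme = ClassScheme(),
    *,
    min_n: int = 10,
    compute_ci: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
    allele_specific_cutoffs: bool = False,
) -> tuple[list[MetricReport], dict]:
    """Join predictions to measurements and score every predictor x allele.

    ``predictions`` needs columns ``peptide, allele, predictor, score``
    (internal orientation) and optionally ``predicted_nm``; see
    :func:`mhcbench.io.read_prediction_table` for the adapters.  Emits one
    report per predictor per allele plus a pooled ``"ALL"`` row; alleles with
    fewer than ``min_n`` records are flagged, not dropped.  With
    ``allele_specific_cutoffs`` the binary binder cutoff per allele is the
    75%-coverage cutoff of that allele's measured binders instead of the
    fixed scheme value.  Returns the reports and a join log (unmatched
    counts per predictor).
    """
    meas_df = pd.DataFrame(
        {
            "peptide": [m.peptide for m in measurements],
            "allele": [m.allele for m in measurements],
            "value_nm": [m.value_nm for m in measurements],
        }
    )
    required = {"peptide", "allele", "predictor", "score"}
    missing = required - set(predictions.columns)
    if missing:
        raise DomainError(f"prediction table lacks columns {sorted(missing)}")

    reports: list[MetricReport] = []
    join_log: dict[str, dict[str, int]] = {}
    for predictor, pred in predictions.groupby("predictor", sort=True):
        merged = meas_df.merge(pred, on=["peptide", "allele"], how="inner")
        join_log[str(predictor)] = {
            "n_predictions": len(pred),
            "n_matched": len(merged),
            "n_unmatched": len(pred) - len(merged),
        }
        if merged.empty:
            reports.append(
                MetricReport(str(predictor), "ALL", 0, flags=["no joinable records"])
            )
            continue
        for allele, group in merged.groupby("allele", sort=True):
            grp_scheme = scheme
            if allele_specific_cutoffs:
                binders = group.loc[
                    group["value_nm"] <= scheme.binder_cutoff_nm, "value_nm"
                ]
                if len(binders):
                    cut = allele_cutoff_75(binders.to_numpy())
                    if cut > scheme.strong_cutoff_nm:
                        grp_scheme = ClassScheme(
                            scheme.strong_cutoff_nm, cut, scheme.mhc_class
                        )
            reports.append(
                _report_for_group(
                    str(predictor), str(allele), group, grp_scheme,
                    min_n=min_n, compute_ci=compute_ci, n_boot=n_boot, seed=seed,
                )
            )
        reports.append(
            _report_for_group(
                str(predictor), "ALL", merged, scheme,
                min_n=min_n, compute_ci=compute_ci, n_boot=n_boot, seed=seed,
            )
        )
    return reports, join_log


def reports_to_frame(reports: Iterable[MetricReport]) -> pd.DataFrame:
    """Tidy one-row-per-report DataFrame, ready for TSV export."""
    return pd.DataFrame([r.as_dict() for r in reports])
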