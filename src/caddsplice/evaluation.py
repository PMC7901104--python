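"""Benchmark statistics: PR/ROC curves, frequency-bin enrichment, rank
correlation between score versions.

Enrichment follows the population-frequency depletion logic: variants are
assigned to ``frequent`` (MAF > 0.001), ``rare`` (MAF < 0.001, allele count
> 1) and ``singleton`` (allele count = 1) bins; at a score percentile
threshold, the observed number of variants per bin above the threshold is
divided by the number expected if high scores were distributed at random
across bins. Deleterious scores should deplete frequent variants and enrich
singletons. Variance is estimated by a percentile bootstrap over variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as skmetrics

__all__ = [
    "FrequencyRecord",
    "EnrichmentResult",
    "BINS",
    "pr_curve",
    "roc_curve",
    "assign_bin",
    "assign_bins",
    "enrichment",
    "rank_correlation",
    "filter_missing_scores",
]

BINS = ("frequent", "rare", "singleton")


@dataclass
class FrequencyRecord:
    """A variant's population frequency summary."""

    variant: object
    maf: float
    ac: int
    bin: str | None = None

    def __post_init__(self) -> None:
        if self.ac < 1:
            raise ValueError(f"allele count must be >= 1, got {self.ac}")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"MAF {self.maf} outside [0, 0.5]")


@dataclass
class EnrichmentResult:
    """Observed/expected ratios per frequency bin at one percentile."""

    percentile: float
    threshold: float
    observed: dict[str, int]
    expected: dict[str, float]
    ratio: dict[str, float | None]
    ci_low: dict[str, float | None]
    ci_high: dict[str, float | None]


def _check_two_classes(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError(
            f"need both classes for a curve, got labels {classes.tolist()}"
        )


def pr_curve(scores, labels):
    """Precision-recall curve and its area (trapezoid over recall).

    Higher score = predicted positive. Variants without a score must be
    filtered (or imputed) upstream; see :func:`filter_missing_scores`.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    precision, recall, thresholds = skmetrics.precision_recall_curve(labels, scores)
    auprc = float(skmetrics.auc(recall, precision))
    return precision, recall, thresholds, auprc


def roc_curve(scores, labels):
    """ROC curve and auROC (the probability that a random positive outranks
    a random negative, ties counting one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    fpr, tpr, thresholds = skmetrics.roc_curve(labels, scores)
    auroc = float(skmetrics.roc_auc_score(labels, scores))
    return fpr, tpr, thresholds, auroc


def assign_bin(maf: float, ac: int) -> str:
    """Frequency bin: singleton (AC = 1), frequent (MAF > 0.001), rare
    (MAF < 0.001, AC > 1). The boundary MAF = 0.001 goes to frequent so the
    three bins partition all records."""
    if ac < 1:
        raise ValueError(f"allele count must be >= 1, got {ac}")
    if ac == 1:
        return "singleton"
    return "frequent" if maf >= 0.001 else "rare"


def assign_bins(records: Sequence[FrequencyRecord]) -> list[FrequencyRecord]:
    for rec in records:
        rec.bin = assign_bin(rec.maf, rec.ac)
    return list(records)


def _enrichment_ratios(scores: np.ndarray, bins: np.ndarray, percentile: float):
    threshold = float(np.percentile(scores, percentile))
    above = scores > threshold
    frac_above = above.mean()
    observed, expected, ratio = {}, {}, {}
    for b in BINS:
        members = bins == b
        n_members = int(members.sum())
        observed[b] = int((members & above).sum())
        expected[b] = n_members * frac_above
        ratio[b] = observed[b] / expected[b] if expected[b] > 0 else None
    return threshold, observed, expected, ratio


def enrichment(
    scores,
    records: Sequence[FrequencyRecord],
    percentile: float,
    n_boot: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Observed/expected variant counts above a score percentile, per bin.

    The threshold is the given percentile of the full score distribution
    (linear-interpolation definition); expected counts assume bins are
    independent of score. The 95% CI is a percentile bootstrap over variants
    (resampled with replacement, ``n_boot`` iterations).
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must be in (0, 100)")
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(records):
        raise ValueError("scores and records must align")
    bins = np.asarray([
        rec.bin if rec.bin is not None else assign_bin(rec.maf, rec.ac)
        for rec in records
    ])

    threshold, observed, expected, ratio = _enrichment_ratios(
        scores, bins, percentile
    )

    rng = np.random.default_rng(seed)
    boot: dict[str, list[float]] = {b: [] for b in BINS}
    n = len(scores)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        _, _, _, r = _enrichment_ratios(scores[idx], bins[idx], percentile)
        for b in BINS:
            if r[b] is not None:
                boot[b].append(r[b])
    ci_low, ci_high = {}, {}
    for b in BINS:
        if ratio[b] is None or not boot[b]:
            ci_low[b] = ci_high[b] = None
        else:
            ci_low[b] = float(np.percentile(boot[b], 2.5))
            ci_high[b] = float(np.percentile(boot[b], 97.5))
    return EnrichmentResult(
        percentile=percentile, threshold=threshold,
        observed=observed, expected=expected, ratio=ratio,
        ci_low=ci_low, ci_high=ci_high,
    )


def rank_correlation(scores_a, scores_b) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise ValueError("need at least two observations")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def filter_missing_scores(
    score_table: dict[str, np.ndarray],
    labels: np.ndarray,
    policy: str = "exclude",
):
    """Harmonise a multi-predictor comparison with missing scores (NaN).

    ``exclude`` keeps only variants for which every compared score is
    defined; ``benign`` replaces missing scores by 0 (interpreting an
    unscored variant as predicted benign).
    """
    labels = np.asarray(labels)
    arrays = {k: np.asarray(v, dtype=float) for k, v in score_table.items()}
    if policy == "exclude":
        keep = np.ones(len(labels), dtype=bool)
        for arr in arrays.values():
            keep &= ~np.isnan(arr)
        return {k: v[keep] for k, v in arrays.items()}, labels[keep]
    if policy == "benign":
        return {k: np.nan_to_num(v, nan=0.0) for k, v in arrays.items()}, labels
    raise ValueError(f"unknown missing-score policy {policy!r}")
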