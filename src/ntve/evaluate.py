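"""Classifier evaluation, sliding-window differential expression, preranked
GSEA, time-to-peak ordering, and contraction-frequency estimation.

The central question: can the exported (supernatant) fraction substitute for
lysate sequencing when calling a perturbation response?  Ground truth comes
from interval-null Wald tests on the lysate (genes with |log2 FC| > theta =
positives, |log2 FC| < theta = negatives, both at FDR < 0.05); supernatant
adjusted p-values then act as prediction scores and are evaluated by ROC and
precision-recall curves.

For time courses, consecutive two-day bins are compared in a sliding window
(stride one day), per-window fold changes feed a preranked gene set
enrichment analysis (weighted Kolmogorov-Smirnov running-sum statistic with
a gene-permutation null), and significant genes are ordered by time of peak
expression for heatmap display.  Contraction frequency of differentiating
cardiomyocytes is estimated from the mean frame-intensity trace of a
bright-field movie via peak detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.metrics import auc as sk_auc, precision_recall_curve, roc_curve

from .glm import bh_adjust, nb_wald_de
from .io import CountMatrix

__all__ = [
    "GroundTruthLabels",
    "build_ground_truth",
    "roc_pr_curves",
    "sliding_window_de",
    "GseaResult",
    "enrichment_score",
    "preranked_gsea",
    "time_to_peak_ordering",
    "contraction_frequency",
]


@dataclass
class GroundTruthLabels:
    """Gene labels derived from lysate interval-null tests."""

    positives: set
    negatives: set
    unlabeled: set

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"{len(overlap)} gene(s) labeled both positive and negative")

    def counts(self) -> dict:
        return {
            "positives": len(self.positives),
            "negatives": len(self.negatives),
            "unlabeled": len(self.unlabeled),
        }


def build_ground_truth(
    greater_abs: pd.DataFrame,
    less_abs: pd.DataFrame,
    fdr: float = 0.05,
) -> GroundTruthLabels:
    """Label genes from lysate Wald results under both interval alternatives.

    ``greater_abs`` and ``less_abs`` are per-gene result frames (as from
    :func:`ntve.glm.nb_wald_de`) with a ``padj`` column, indexed by gene.
    Positives: padj(greaterAbs) < fdr; negatives: padj(lessAbs) < fdr;
    everything else is unlabeled and excluded from curves.
    """
    genes = greater_abs.index.union(less_abs.index)
    pos = set(greater_abs.index[greater_abs["padj"] < fdr])
    neg = set(less_abs.index[less_abs["padj"] < fdr]) - pos
    return GroundTruthLabels(pos, neg, set(genes) - pos - neg)


def roc_pr_curves(labels: GroundTruthLabels, scores: pd.Series) -> dict:
    """ROC and PR curves for adjusted-p prediction scores.

    ``scores`` maps gene id to the supernatant adjusted p-value; smaller
    means "more positive", so scores are negated internally.  Only labeled
    genes enter the curves.  Returns roc_auc, pr_auc, prevalence (the random
    classifier's precision) and the curve arrays.
    """
    labeled = sorted(labels.positives | labels.negatives)
    missing = [g for g in labeled if g not in scores.index]
    if missing:
        raise ValueError(f"{len(missing)} labeled gene(s) have no prediction score")
    y_true = np.array([g in labels.positives for g in labeled], dtype=int)
    if y_true.sum() == 0 or y_true.sum() == len(y_true):
        raise ValueError("need at least one positive and one negative gene")
    y_score = -scores.loc[labeled].to_numpy(dtype=float)
    fpr, tpr, roc_thresh = roc_curve(y_true, y_score)
    precision, recall, pr_thresh = precision_recall_curve(y_true, y_score)
    # PR AUC by trapezoid along the curve's own point order (recall is
    # returned decreasing; re-sorting would mispair tied recalls)
    pr_auc = float(np.trapezoid(precision[::-1], recall[::-1]))
    return {
        "roc_auc": float(sk_auc(fpr, tpr)),
        "pr_auc": pr_auc,
        "prevalence": float(y_true.mean()),
        "fpr": fpr,
        "tpr": tpr,
        "precision": precision,
        "recall": recall,
    }


def sliding_window_de(
    timecourse: CountMatrix,
    bin_days: int = 2,
    stride_days: int = 1,
    alternative: str = "standard",
) -> list[dict]:
    """Two-day-bin sliding-window differential expression along a time course.

    For each anchor day t, samples from days [t-2, t-1] (reference bin) are
    compared against days [t, t+1] (current bin) by an NB Wald test; windows
    advance with a one-day stride and are emitted in temporal order.  For T
    consecutive daily time points the number of comparisons is T - 3.
    Non-integer sampling times are assigned to days by flooring.  Windows
    with fewer than 2 samples on either side are skipped with a warning.
    """
    if timecourse.sample_meta is None or "time_days" not in timecourse.sample_meta:
        raise ValueError("timecourse matrix needs a time_days metadata column")
    day = np.floor(timecourse.sample_meta["time_days"].to_numpy(dtype=float)).astype(int)
    days = np.unique(day)
    if len(days) < 2 * bin_days:
        raise ValueError(f"need samples spanning at least {2 * bin_days} days")
    results = []
    for t in range(days.min() + bin_days, days.max() - bin_days + 2, stride_days):
        ref_mask = (day >= t - bin_days) & (day < t)
        cur_mask = (day >= t) & (day < t + bin_days)
        if ref_mask.sum() < 2 or cur_mask.sum() < 2:
            warnings.warn(f"window anchored at day {t} has fewer than 2 samples on one side; skipped", stacklevel=2)
            continue
        sample_ids = list(timecourse.sample_ids[ref_mask | cur_mask])
        sub = timecourse.subset_samples(sample_ids)
        cond = np.where(cur_mask[ref_mask | cur_mask], "current", "reference")
        table = nb_wald_de(sub, cond, "current", alternative=alternative)
        results.append({"anchor_day": t, "reference_days": (t - bin_days, t - 1), "current_days": (t, t + bin_days - 1), "table": table})
    return results


@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p_value: float
    p_adjusted: float
    size: int
    leading_edge: list


def enrichment_score(ranked_genes, stats, gene_set) -> tuple[float, list]:
    """Weighted Kolmogorov-Smirnov enrichment score (weight exponent 1).

    ``ranked_genes`` must already be sorted by decreasing statistic.  The
    running sum increments by |stat| / sum(|stat| over hits) at hits and
    decrements by 1 / (N - Nh) at misses; ES is the extremum of largest
    magnitude.  A set covering the whole universe has ES 0 by convention.
    Returns (ES, leading-edge genes).
    """
    hits = np.array([g in gene_set for g in ranked_genes])
    n = len(ranked_genes)
    nh = int(hits.sum())
    if nh == 0 or nh == n:
        return 0.0, []
    w = np.abs(np.asarray(stats, dtype=float))
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hits.astype(float)  # all-zero stats: unweighted fallback
        denom = float(nh)
    running = np.cumsum(hit_w / denom - (~hits) / (n - nh))
    idx = int(np.argmax(np.abs(running)))
    es = float(running[idx])
    if es >= 0:
        leading = [g for g, h in zip(ranked_genes[: idx + 1], hits[: idx + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked_genes[idx + 1 :], hits[idx + 1 :]) if h]
    return es, leading


def preranked_gsea(
    ranked_stats: pd.Series,
    gene_sets: dict,
    n_permutations: int = 1000,
    seed: int = 0,
    min_size: int = 3,
) -> pd.DataFrame:
    """Preranked GSEA over a dict of gene sets.

    ``ranked_stats`` maps gene to its ranking metric (e.g. a per-window log2
    fold change); genes are sorted by decreasing value.  The null is formed
    by permuting gene labels (drawing random same-size sets), NES is ES
    divided by the mean |null ES| of matching sign, p-values use the
    matching-sign null with a +1 correction, and BH adjusts across sets.
    Sets with fewer than ``min_size`` members in the universe are skipped
    with a warning.  Results are sorted by adjusted p.
    """
    stats = ranked_stats.dropna().sort_values(ascending=False)
    if not np.isfinite(stats.to_numpy()).all():
        raise ValueError("ranking metric must be finite for all genes")
    genes = list(stats.index)
    values = stats.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & set(genes)
        if len(inset) < min_size:
            warnings.warn(f"gene set {name!r} has fewer than {min_size} members in the ranked universe; skipped", stacklevel=2)
            continue
        es, leading = enrichment_score(genes, values, inset)
        null_es = np.empty(n_permutations)
        k = len(inset)
        for i in range(n_permutations):
            perm = set(rng.choice(len(genes), size=k, replace=False))
            null_es[i], _ = enrichment_score(genes, values, {genes[j] for j in perm})
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        pool = np.abs(null_es[same_sign])
        if len(pool) == 0:
            p = 1.0 / (n_permutations + 1)
            nes = np.nan
        else:
            p = (np.sum(pool >= abs(es)) + 1) / (len(pool) + 1)
            mean_pool = pool.mean()
            nes = abs(es) / mean_pool * np.sign(es) if mean_pool > 0 else np.nan
        rows.append(
            {"set": name, "size": len(inset), "es": es, "nes": nes, "p": float(p), "leading_edge": leading}
        )
    res = pd.DataFrame(rows)
    if len(res):
        res["padj"] = bh_adjust(res["p"])
        res = res.sort_values("padj", kind="stable").reset_index(drop=True)
    return res


def time_to_peak_ordering(mean_expression: pd.DataFrame, pseudocount: float = 1.0) -> tuple[pd.Series, pd.DataFrame]:
    """Order genes by time of peak expression; return row-centered log2 values.

    ``mean_expression`` is genes x time points (columns sortable as times).
    Values are log2(x + pseudocount) centered by row mean; time-to-peak is
    the column (time) of the maximum; genes sort ascending by it with ties
    broken by gene id.
    """
    cols = sorted(mean_expression.columns, key=float)
    expr = mean_expression[cols]
    logged = np.log2(expr + pseudocount)
    centered = logged.sub(logged.mean(axis=1), axis=0)
    peak_time = logged.idxmax(axis=1).astype(float).rename("time_to_peak")
    order = peak_time.to_frame().sort_index().sort_values("time_to_peak", kind="stable").index
    return peak_time.loc[order], centered.loc[order]


def contraction_frequency(
    intensity_trace,
    fps: float,
    min_distance_s: float = 0.3,
    prominence_sd: float = 0.5,
) -> float | None:
    """Contraction frequency (Hz) from a mean frame-intensity trace.

    Peaks are detected with a minimum spacing of ``min_distance_s`` seconds
    and a prominence of ``prominence_sd`` times the trace standard
    deviation; the frequency is (n_peaks - 1) divided by the time between
    the first and last peak.  Returns None (undefined) when fewer than 2
    peaks are found.
    """
    trace = np.asarray(intensity_trace, dtype=float)
    if len(trace) < 2 * fps:
        raise ValueError("trace must cover at least 2 seconds of frames")
    sd = trace.std()
    if sd == 0:
        return None
    distance = max(int(round(min_distance_s * fps)), 1)
    peaks, _ = find_peaks(trace, distance=distance, prominence=prominence_sd * sd)
    if len(peaks) < 2:
        return None
    span_s = (peaks[-1] - peaks[0]) / fps
    return float((len(peaks) - 1) / span_s)
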