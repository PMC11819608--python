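"""Downstream calling and evaluation.

Covers: thresholding posterior differential probabilities (strict
``P(d=1) > 0.75`` by default), gene-level aggregation (a gene is
differential iff at least one of its isoforms is), the median relative
abundance filter (strict ``> 10%``), confusion-matrix evaluation against
simulation truth with optional SNR-band breakdown, abundance-correlation
assessment, a permutation enrichment statistic over time-course fold
changes, and a naive two-sample t-test baseline caller used only as a
comparison arm in power experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import snr_db
from .sampler import PosteriorSummary

DEFAULT_PROBABILITY_THRESHOLD = 0.75
DEFAULT_ABUNDANCE_CUTOFF = 0.10
DEFAULT_SNR_BANDS = (-3.0, -1.0)


@dataclass
class DetectionResult:
    """Per-isoform call with the statistics behind it."""

    gene_id: str
    transcript_id: str
    prob_differential: float
    call: bool
    mean_group1: float
    mean_group2: float
    snr_db: float
    median_relative_abundance: float


@dataclass
class EvaluationSummary:
    """Confusion counts with precision/recall/F and per-SNR-band recall."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f_score: float
    band_recall: dict[str, float] | None = None


def call_differential(
    summary: PosteriorSummary,
    threshold: float = DEFAULT_PROBABILITY_THRESHOLD,
) -> list[DetectionResult]:
    """Call isoforms differential when P(d=1) strictly exceeds the threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    g1, g2 = summary.design.group1_idx, summary.design.group2_idx
    results = []
    for gid in summary.gene_ids:
        B = summary.beta_hat[gid]
        rel = B / B.sum(axis=0, keepdims=True)  # relative abundance per sample
        for t, tid in enumerate(summary.transcript_ids[gid]):
            prob = float(summary.p[gid][t])
            b1, b2 = B[t, g1], B[t, g2]
            try:
                snr = snr_db(b1, b2)
            except ValueError:
                snr = float("nan")
            results.append(DetectionResult(
                gene_id=gid, transcript_id=tid, prob_differential=prob,
                call=prob > threshold,
                mean_group1=float(b1.mean()), mean_group2=float(b2.mean()),
                snr_db=snr,
                median_relative_abundance=float(np.median(rel[t])),
            ))
    return results


def results_table(results: list[DetectionResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def gene_level_aggregate(results: list[DetectionResult]) -> set[str]:
    """Genes with at least one differentially expressed isoform."""
    return {r.gene_id for r in results if r.call}


def relative_abundance_filter(
    results: list[DetectionResult],
    cutoff: float = DEFAULT_ABUNDANCE_CUTOFF,
) -> list[DetectionResult]:
    """Keep isoforms whose median relative abundance strictly exceeds cutoff.

    Relative abundance of isoform t in a sample is its estimated abundance
    divided by the summed abundance of all isoforms of the same gene; the
    median is taken across samples.
    """
    return [r for r in results if r.median_relative_abundance > cutoff]


def evaluate_detection(
    results: list[DetectionResult],
    truth: pd.DataFrame,
    snr_bands: tuple[float, float] | None = DEFAULT_SNR_BANDS,
) -> EvaluationSummary:
    """Confusion counts of calls against simulation truth.

    ``truth`` needs columns ``transcript_id`` and ``d_true`` (and ``snr_db``
    for the per-band recall over truly differential isoforms; bands are
    split at the given breakpoints, by default -3 and -1 dB).
    """
    calls = {r.transcript_id: r.call for r in results}
    truth_ids = set(truth["transcript_id"])
    if truth_ids != set(calls):
        raise ValueError("transcript ids in calls and truth do not match")
    d_true = dict(zip(truth["transcript_id"], truth["d_true"]))
    tp = sum(1 for tid, c in calls.items() if c and d_true[tid])
    fp = sum(1 for tid, c in calls.items() if c and not d_true[tid])
    fn = sum(1 for tid, c in calls.items() if not c and d_true[tid])
    tn = len(calls) - tp - fp - fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f_score = (2 * precision * recall / (precision + recall)
               if precision + recall else 0.0)

    band_recall = None
    if snr_bands is not None and "snr_db" in truth.columns:
        lo, hi = snr_bands
        edges = [(-np.inf, lo), (lo, hi), (hi, np.inf)]
        labels = [f"<{lo}dB", f"{lo}..{hi}dB", f">={hi}dB"]
        band_recall = {}
        pos = truth[truth["d_true"] == 1]
        for (a, b), lab in zip(edges, labels):
            sub = pos[(pos["snr_db"] >= a) & (pos["snr_db"] < b)]
            if len(sub) == 0:
                band_recall[lab] = float("nan")
            else:
                band_recall[lab] = float(
                    np.mean([calls[tid] for tid in sub["transcript_id"]]))
    return EvaluationSummary(tp, fp, fn, tn, precision, recall, f_score,
                             band_recall)


def abundance_correlation(
    beta_hat: dict[str, np.ndarray],
    beta_true: dict[str, np.ndarray],
) -> float:
    """Mean per-isoform Pearson correlation of estimated vs true abundances.

    Correlation is computed per isoform across samples and averaged;
    isoforms with zero variance in either vector are skipped with a warning.
    """
    import warnings

    cors = []
    for gid, true in beta_true.items():
        est = beta_hat[gid]
        if est.shape != true.shape:
            raise ValueError(f"{gid}: shape mismatch")
        for t in range(true.shape[0]):
            if true.shape[1] < 3:
                raise ValueError("need at least 3 samples per isoform")
            if np.std(est[t]) == 0 or np.std(true[t]) == 0:
                warnings.warn(f"{gid} isoform {t}: zero variance, skipped")
                continue
            cors.append(stats.pearsonr(est[t], true[t]).statistic)
    if not cors:
        raise ValueError("no isoform with non-degenerate abundances")
    return float(np.mean(cors))


def permutation_enrichment(
    expr: pd.DataFrame,
    gene_set: list[str],
    iterations: int = 100_000,
    rng: np.random.Generator | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Permutation test of a gene set's mean log2 fold change per time point.

    ``expr`` is a transcripts-by-time-points matrix of log2 fold changes
    against the first time point.  The observed statistic per time point is
    the mean over the set; the null is built from ``iterations`` random
    same-size sets drawn without replacement from the matrix rows, the
    p-value uses the add-one convention p = (1 + #{null >= obs}) /
    (iterations + 1) (two-sided on |statistic| with ``alternative='two-sided'``),
    and the enrichment score is -log10 p.
    """
    if rng is None:
        rng = np.random.default_rng()
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    missing = set(gene_set) - set(expr.index)
    if missing:
        raise ValueError(f"gene set members absent from matrix: {sorted(missing)}")
    m = len(gene_set)
    n = len(expr)
    if m > n:
        raise ValueError("gene set larger than the expression universe")
    values = expr.to_numpy(dtype=float)
    set_idx = np.sort(expr.index.get_indexer(gene_set))
    observed = values[set_idx].mean(axis=0)

    exceed = np.zeros(values.shape[1], dtype=np.int64)
    batch = max(1, min(iterations, int(2e7) // max(n, 1)))
    done = 0
    while done < iterations:
        k = min(batch, iterations - done)
        # row-wise random subsets without replacement via partial argsort
        u = rng.random((k, n))
        # sorted so null and observed statistics share a summation order
        idx = np.sort(np.argpartition(u, m - 1, axis=1)[:, :m], axis=1)
        null = values[idx].mean(axis=1)  # (k, P)
        if alternative == "greater":
            exceed += (null >= observed).sum(axis=0)
        elif alternative == "two-sided":
            exceed += (np.abs(null) >= np.abs(observed)).sum(axis=0)
        else:
            raise ValueError("alternative must be 'greater' or 'two-sided'")
        done += k
    p = (1.0 + exceed) / (iterations + 1.0)
    return pd.DataFrame({
        "time_point": list(expr.columns),
        "statistic": observed,
        "p_value": p,
        "enrichment_score": -np.log10(p),
    })


def baseline_ttest_calls(
    summary: PosteriorSummary,
    alpha: float = 0.05,
) -> list[DetectionResult]:
    """Naive comparison arm: per-isoform Welch t-test on estimated FPKM.

    Benjamini-Hochberg adjusted across isoforms; a call is an adjusted
    p-value below ``alpha``.  This is a generic baseline, not a re-creation
    of any published tool.
    """
    g1, g2 = summary.design.group1_idx, summary.design.group2_idx
    rows = []
    for gid in summary.gene_ids:
        B = summary.beta_hat[gid]
        rel = B / B.sum(axis=0, keepdims=True)
        for t, tid in enumerate(summary.transcript_ids[gid]):
            rows.append((gid, tid, B[t, g1], B[t, g2],
                         float(np.median(rel[t]))))
    pvals = np.array([
        stats.ttest_ind(b1, b2, equal_var=False).pvalue
        for _, _, b1, b2, _ in rows
    ])
    pvals = np.nan_to_num(pvals, nan=1.0)
    padj = multipletests(pvals, method="fdr_bh")[1]

    results = []
    for (gid, tid, b1, b2, med_rel), q in zip(rows, padj):
        try:
            snr = snr_db(b1, b2)
        except ValueError:
            snr = float("nan")
        results.append(DetectionResult(
            gene_id=gid, transcript_id=tid,
            prob_differential=float(1.0 - q), call=bool(q < alpha),
            mean_group1=float(b1.mean()), mean_group2=float(b2.mean()),
            snr_db=snr, median_relative_abundance=med_rel,
        ))
    return results
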