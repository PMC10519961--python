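"""Diagnostic-concordance and stain-quality statistics for reader studies.

A panel of pathologists reads paired virtual and true H&E images, calling
each image benign or malignant.  The consensus over true-image readings
defines the gold standard; per-rater sensitivity, specificity, PPV, NPV
and accuracy are computed against it (malignant = positive), summarized as
unweighted means over raters and as consensus-call metrics.  Agreement is
chance-corrected: Cohen's kappa per rater (their virtual vs true readings,
intra-observer) and Fleiss' kappa over the true-image call matrix
(inter-observer).  Stain-quality scores (1-4 scale) are compared between
virtual staining and frozen sections with a right-tailed exact Wilcoxon
rank-sum test computed by combinatorial enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "RaterTable", "ConfusionCounts", "ConcordanceReport",
    "confusion", "rate_metrics", "mean_over_raters", "consensus_calls",
    "cohen_kappa", "fleiss_kappa", "wilcoxon_right_exact",
    "concordance_report", "stain_quality_summary",
    "example_breast_table", "example_prostate_table",
]


@dataclass
class RaterTable:
    """Per-rater binary calls on virtual and true images, plus gold labels.

    ``virtual_calls`` and ``true_calls`` are (n_raters, n_items) boolean
    matrices (True = malignant).  ``quality`` optionally holds a tidy frame
    of 1-4 stain-quality scores with columns (method, metric, image, rater,
    score).
    """

    item_ids: np.ndarray
    gold: np.ndarray
    virtual_calls: np.ndarray
    true_calls: np.ndarray
    quality: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.gold = np.asarray(self.gold, dtype=bool)
        self.virtual_calls = np.atleast_2d(np.asarray(self.virtual_calls, dtype=bool))
        self.true_calls = np.atleast_2d(np.asarray(self.true_calls, dtype=bool))
        n = len(self.gold)
        if self.virtual_calls.shape[1] != n or self.true_calls.shape[1] != n:
            raise ValueError("call matrices must have one column per item")
        if self.virtual_calls.shape[0] != self.true_calls.shape[0]:
            raise ValueError("virtual and true call matrices need equal rater counts")
        if self.quality is not None:
            scores = self.quality["score"]
            if not scores.isin([1, 2, 3, 4]).all():
                raise ValueError("quality scores must be in {1, 2, 3, 4}")

    @property
    def n_items(self) -> int:
        return len(self.gold)

    @property
    def n_raters(self) -> int:
        return self.virtual_calls.shape[0]

    @property
    def prevalence(self) -> float:
        return float(np.mean(self.gold))


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_binary(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("calls must be binary (bool or 0/1)")
        arr = arr.astype(bool)
    return arr


def confusion(calls, gold) -> ConfusionCounts:
    """2x2 confusion counts with malignant as the positive class."""
    calls = _as_binary(calls)
    gold = _as_binary(gold)
    if calls.shape != gold.shape:
        raise ValueError("calls and gold must have equal length")
    return ConfusionCounts(
        tp=int(np.sum(calls & gold)),
        fp=int(np.sum(calls & ~gold)),
        tn=int(np.sum(~calls & ~gold)),
        fn=int(np.sum(~calls & gold)),
    )


def rate_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV and accuracy from 2x2 counts.

    Rates with a zero denominator are reported as None (missing).
    """

    def _safe(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "sensitivity": _safe(c.tp, c.tp + c.fn),
        "specificity": _safe(c.tn, c.tn + c.fp),
        "ppv": _safe(c.tp, c.tp + c.fp),
        "npv": _safe(c.tn, c.tn + c.fn),
        "accuracy": _safe(c.tp + c.tn, c.n),
    }


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (table-formatting rule)."""
    factor = 10 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def mean_over_raters(per_rater_rates: list[dict]) -> dict[str, float | None]:
    """Unweighted arithmetic mean of unrounded per-rater rates.

    Missing (None) rates are excluded from that metric's mean.  Means are
    computed on unrounded values; rounding to two decimals is applied only
    at reporting time.
    """
    if not per_rater_rates:
        raise ValueError("need at least one rater")
    out: dict[str, float | None] = {}
    for key in per_rater_rates[0]:
        vals = [r[key] for r in per_rater_rates if r.get(key) is not None]
        out[key] = float(np.mean(vals)) if vals else None
    return out


def consensus_calls(call_matrix: np.ndarray, tie_break: bool = True) -> np.ndarray:
    """Per-item majority vote across raters.

    Ties (possible with an even rater count) break toward malignant when
    ``tie_break`` is True -- the conservative choice for margin assessment.
    """
    m = _as_binary(call_matrix)
    if m.ndim != 2:
        raise ValueError("call matrix must be 2-D (raters x items)")
    pos = m.sum(axis=0)
    n = m.shape[0]
    out = pos * 2 > n
    ties = pos * 2 == n
    if tie_break:
        out = out | ties
    return out


def cohen_kappa(calls_a, calls_b) -> float:
    """Cohen's kappa between two equal-length binary call vectors.

    Chance agreement uses the product of marginals.  If both raters are
    constant and identical (p_e = 1), kappa is defined as 1; constant but
    different raters raise an error.
    """
    a = _as_binary(calls_a)
    b = _as_binary(calls_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("call vectors must be 1-D and equal length")
    n = len(a)
    if n == 0:
        raise ValueError("empty call vectors")
    po = float(np.mean(a == b))
    pa, pb = float(np.mean(a)), float(np.mean(b))
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe >= 1.0 - 1e-12:
        if po == 1.0:
            return 1.0
        raise ValueError("kappa undefined: both raters constant but unequal")
    return (po - pe) / (1.0 - pe)


def fleiss_kappa(call_matrix: np.ndarray) -> float:
    """Fleiss' kappa of a (raters x items) binary call matrix.

    All items must be rated by every rater.  If a single category is used
    throughout, agreement is perfect and kappa is defined as 1.
    """
    m = _as_binary(call_matrix)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 raters and >= 2 items")
    r, n = m.shape
    counts = np.stack([(~m).sum(axis=0), m.sum(axis=0)], axis=1).astype(float)
    p_cat = counts.sum(axis=0) / (n * r)
    if np.max(p_cat) >= 1.0 - 1e-12:
        return 1.0
    p_i = ((counts ** 2).sum(axis=1) - r) / (r * (r - 1))
    p_bar = float(np.mean(p_i))
    p_e = float(np.sum(p_cat ** 2))
    return (p_bar - p_e) / (1.0 - p_e)


def wilcoxon_right_exact(sample_x, sample_y) -> float:
    """Exact right-tailed Wilcoxon rank-sum p value (H1: x > y).

    Enumerates the null distribution of the x rank-sum combinatorially:
    p = (# of rank assignments with rank-sum >= observed) / C(m+n, m).
    Ties across the pooled sample are refused -- pre-average tied scores
    (e.g. use per-image inter-rater means) before testing.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if len(np.unique(pooled)) != len(pooled):
        raise ValueError(
            "ties present; average tied scores (e.g. over raters) before the exact test"
        )
    ranks = pooled.argsort().argsort() + 1
    m = len(x)
    w_obs = int(ranks[:m].sum())
    total = math.comb(len(pooled), m)
    # distribution of rank-sums of m-subsets of ranks 1..N by subset-sum DP
    n_all = len(pooled)
    max_sum = n_all * (n_all + 1) // 2
    dp = np.zeros((m + 1, max_sum + 1), dtype=object)
    dp[0, 0] = 1
    for rank in range(1, n_all + 1):
        for k in range(min(rank, m), 0, -1):
            dp[k, rank:] = dp[k, rank:] + dp[k - 1, :-rank if rank else None]
    count_ge = int(sum(dp[m, w_obs:]))
    return count_ge / total


def concordance_report(table: RaterTable, tie_break: bool = True) -> "ConcordanceReport":
    """Full diagnostic-concordance summary of a reader study.

    Per-rater rates are computed from virtual-image calls against the gold
    standard; the mean row averages unrounded per-rater rates; the
    consensus row uses the majority vote over virtual calls.  Cohen's kappa
    compares each rater's virtual and true readings (intra-observer);
    Fleiss' kappa measures inter-observer agreement on the true images.
    """
    per_rater = []
    kappas = []
    for r in range(table.n_raters):
        per_rater.append(rate_metrics(confusion(table.virtual_calls[r], table.gold)))
        kappas.append(cohen_kappa(table.virtual_calls[r], table.true_calls[r]))
    means = mean_over_raters(per_rater)
    cons = consensus_calls(table.virtual_calls, tie_break=tie_break)
    consensus = rate_metrics(confusion(cons, table.gold))
    fk = fleiss_kappa(table.true_calls)
    return ConcordanceReport(
        per_rater=per_rater,
        means=means,
        consensus=consensus,
        cohen_kappa_per_rater=kappas,
        fleiss_kappa_true=fk,
        prevalence=table.prevalence,
    )


@dataclass
class ConcordanceReport:
    per_rater: list[dict]
    means: dict
    consensus: dict
    cohen_kappa_per_rater: list[float]
    fleiss_kappa_true: float
    prevalence: float

    def rounded(self, decimals: int = 2) -> dict:
        """Reporting view with half-up rounding (table formatting)."""

        def _r(d):
            return {k: (round_half_up(v, decimals) if v is not None else None)
                    for k, v in d.items()}

        return {
            "per_rater": [_r(d) for d in self.per_rater],
            "mean": _r(self.means),
            "consensus": _r(self.consensus),
            "cohen_kappa": [round_half_up(k, decimals)
                            for k in self.cohen_kappa_per_rater],
            "fleiss_kappa": round_half_up(self.fleiss_kappa_true, decimals),
            "prevalence": round_half_up(self.prevalence, decimals),
        }


def stain_quality_summary(quality: pd.DataFrame) -> dict:
    """Stain-quality reader statistics with exact Wilcoxon comparisons.

    ``quality`` columns: method ('virtual'/'frozen'), metric, image, rater,
    score (1-4).  Reports per-rater mean and SEM per method and metric, the
    per-image inter-rater average score, and a right-tailed exact Wilcoxon
    p value per metric for virtual > frozen computed on the per-image
    inter-rater averages (which also removes integer-score ties).  Missing
    scores are handled pairwise-complete and flagged.
    """
    required = {"method", "metric", "image", "rater", "score"}
    if not required.issubset(quality.columns):
        raise ValueError(f"quality table needs columns {sorted(required)}")
    flagged = bool(quality["score"].isna().any())
    q = quality.dropna(subset=["score"])

    per_rater = (
        q.groupby(["method", "metric", "rater"])["score"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    per_image = (
        q.groupby(["method", "metric", "image"])["score"]
        .mean()
        .reset_index(name="inter_rater_mean")
    )
    tests = {}
    for metric in q["metric"].unique():
        sub = per_image[per_image["metric"] == metric]
        xv = sub.loc[sub["method"] == "virtual", "inter_rater_mean"].to_numpy()
        yf = sub.loc[sub["method"] == "frozen", "inter_rater_mean"].to_numpy()
        if xv.size and yf.size:
            try:
                tests[metric] = wilcoxon_right_exact(xv, yf)
            except ValueError:
                tests[metric] = None
    return {
        "per_rater": per_rater,
        "per_image": per_image,
        "p_values": tests,
        "flagged_missing": flagged,
    }


# ---------------------------------------------------------------------------
# reference reader-study tables
# ---------------------------------------------------------------------------

def _calls_from_errors(gold: np.ndarray, fn_items, fp_items) -> np.ndarray:
    calls = gold.copy()
    calls[list(fn_items)] = False
    calls[list(fp_items)] = True
    return calls


def example_breast_table() -> RaterTable:
    """Reference breast reader study: 24 items (10 malignant), 5 raters.

    Calls are reconstructed from the published per-rater confusion counts
    (P1: 1 FN, 1 FP; P2: 1 FN, 2 FP; P3: perfect; P4: 2 FP; P5: 1 FP); the
    error items are assigned so that the majority vote reproduces the
    published consensus row (one benign item flagged by three raters).
    True-image readings are unanimous (inter-observer Fleiss kappa 1).
    """
    gold = np.array([True] * 10 + [False] * 14)
    # malignant items 0..9; benign items 10..23
    virtual = np.stack([
        _calls_from_errors(gold, fn_items=[0], fp_items=[10]),       # P1
        _calls_from_errors(gold, fn_items=[1], fp_items=[10, 11]),   # P2
        _calls_from_errors(gold, fn_items=[], fp_items=[]),          # P3
        _calls_from_errors(gold, fn_items=[], fp_items=[10, 12]),    # P4
        _calls_from_errors(gold, fn_items=[], fp_items=[13]),        # P5
    ])
    true_calls = np.tile(gold, (5, 1))
    return RaterTable(np.arange(24), gold, virtual, true_calls)


def example_prostate_table() -> RaterTable:
    """Reference prostate reader study: 32 items (20 malignant), 3 raters.

    Reconstructed per-rater confusion counts: P1 4 FN, P2 1 FN + 2 FP,
    P3 3 FN; three malignant items are missed by a majority, reproducing
    the published consensus row (sensitivity 0.85, specificity 1.00).
    True-image readings are taken as the gold standard itself; this is an
    approximation here (inter-observer agreement on true prostate images
    was below unanimity), but it leaves all virtual-call statistics exact.
    """
    gold = np.array([True] * 20 + [False] * 12)
    virtual = np.stack([
        _calls_from_errors(gold, fn_items=[0, 1, 2, 3], fp_items=[]),   # P1
        _calls_from_errors(gold, fn_items=[0], fp_items=[20, 21]),      # P2
        _calls_from_errors(gold, fn_items=[0, 1, 2], fp_items=[]),      # P3
    ])
    true_calls = np.tile(gold, (3, 1))
    return RaterTable(np.arange(32), gold, virtual, true_calls)
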