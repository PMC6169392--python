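"""Benchmark machinery: ROC curves, stratified bootstrap, agreement analyses.

Sensitivity is the proportion of phenotype-altering (positive) variants called
deleterious; specificity is the proportion of putatively neutral (negative)
variants called neutral.  AUC summarises the whole tradeoff and is compared
across approaches with stratified bootstrap intervals, where every replicate
resamples positives and negatives separately so class counts are preserved.

Approaches disagree: the call matrix at each approach's 95%-specificity
threshold supports enrichment-by-frequency-class summaries, cumulative
agreement counts, a pairwise disagreement distance, and hierarchical
clustering of approaches with bootstrap support over variants.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn import metrics as _skm

logger = logging.getLogger(__name__)

__all__ = [
    "ROCCurve",
    "CallMatrix",
    "roc_curve",
    "rank_auc",
    "threshold_at_specificity",
    "calls_at_threshold",
    "bootstrap_auc_ci",
    "auc_difference_test",
    "proportion_deleterious_by_class",
    "call_agreement_summary",
    "disagreement_distance",
    "cluster_approaches",
    "DEFAULT_FREQUENCY_CLASSES",
]


@dataclasses.dataclass
class ROCCurve:
    """Thresholds with sensitivity/specificity pairs plus AUC.

    ``higher_is_deleterious`` records the score orientation so thresholds can
    be applied to raw scores later.  A call is "deleterious" when the oriented
    score is >= the threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    higher_is_deleterious: bool = True
    ci: tuple[float, float, float] | None = None  # (low, high, level)


def _orient(scores: np.ndarray, higher_is_deleterious: bool) -> np.ndarray:
    return scores if higher_is_deleterious else -scores


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic (midrank tie handling)."""
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    r = rankdata(scores)
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[float],
    higher_is_deleterious: bool = True,
) -> ROCCurve:
    """ROC curve over all distinct-score thresholds, AUC by trapezoid rule.

    With the midrank tie convention the trapezoidal AUC equals the
    Mann-Whitney statistic (#concordant + 0.5 #tied) / (n_pos * n_neg).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.isnan(s).any():
        raise ValueError("scores contain missing values")
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    oriented = _orient(s, higher_is_deleterious)
    fpr, tpr, thr = _skm.roc_curve(y, oriented, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    thresholds = thr if higher_is_deleterious else -thr
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        higher_is_deleterious=higher_is_deleterious,
    )


@dataclasses.dataclass
class ThresholdResult:
    threshold: float
    sensitivity: float
    specificity: float
    target_met: bool


def threshold_at_specificity(curve: ROCCurve, target: float = 0.95) -> ThresholdResult:
    """Most permissive calling threshold whose specificity still meets the target.

    Among thresholds with specificity >= target the one maximising sensitivity
    is returned.  If no threshold reaches the target (pathological scores),
    the strictest threshold is returned with ``target_met=False``.
    """
    ok = curve.specificity >= target
    if ok.any():
        idx = np.flatnonzero(ok)
        best = idx[np.argmax(curve.sensitivity[idx])]
        return ThresholdResult(
            threshold=float(curve.thresholds[best]),
            sensitivity=float(curve.sensitivity[best]),
            specificity=float(curve.specificity[best]),
            target_met=True,
        )
    strict = int(np.argmax(curve.specificity))
    logger.warning("specificity target %.3f unreachable; returning strictest threshold", target)
    return ThresholdResult(
        threshold=float(curve.thresholds[strict]),
        sensitivity=float(curve.sensitivity[strict]),
        specificity=float(curve.specificity[strict]),
        target_met=False,
    )


def calls_at_threshold(
    scores: np.ndarray, threshold: float, higher_is_deleterious: bool = True
) -> np.ndarray:
    """Binary deleterious calls (NaN scores stay NaN: missing calls)."""
    s = np.asarray(scores, dtype=float)
    oriented = _orient(s, higher_is_deleterious)
    t = threshold if higher_is_deleterious else -threshold
    calls = np.where(oriented >= t, 1.0, 0.0)
    calls[np.isnan(s)] = np.nan
    return calls


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _stratified_resample_auc(
    scores: np.ndarray, labels: np.ndarray, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """AUCs over stratified bootstrap replicates (class counts preserved)."""
    y = np.asarray(labels, dtype=bool)
    pos, neg = scores[y], scores[~y]
    n_pos, n_neg = len(pos), len(neg)
    aucs = np.empty(n_reps)
    i = 0
    redrawn = 0
    while i < n_reps:
        ps = pos[rng.integers(0, n_pos, n_pos)]
        ns = neg[rng.integers(0, n_neg, n_neg)]
        r = rankdata(np.concatenate([ps, ns]))
        auc = (r[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        if np.isnan(auc):  # degenerate replicate: redraw
            redrawn += 1
            continue
        aucs[i] = auc
        i += 1
    if redrawn:
        logger.info("bootstrap: %d degenerate replicates redrawn", redrawn)
    return aucs


def bootstrap_auc_ci(
    scores: Sequence[float],
    labels: Sequence[float],
    n_reps: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile CI for the AUC from stratified bootstrap resampling.

    Each replicate draws positives and negatives separately with replacement,
    preserving the original class counts.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need >= 2 members of each class")
    rng = np.random.default_rng(seed)
    aucs = _stratified_resample_auc(s, y, n_reps, rng)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def auc_difference_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[float],
    n_reps: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Paired stratified bootstrap of the AUC difference (a minus b).

    The same resampled variants feed both score sets in each replicate;
    'significant' means the percentile interval excludes 0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("score vectors and labels must align on the same variants")
    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.flatnonzero(y), np.flatnonzero(~y)
    n_pos, n_neg = len(pos_idx), len(neg_idx)
    deltas = np.empty(n_reps)
    for i in range(n_reps):
        idx = np.concatenate(
            [
                pos_idx[rng.integers(0, n_pos, n_pos)],
                neg_idx[rng.integers(0, n_neg, n_neg)],
            ]
        )
        yy = y[idx]
        deltas[i] = rank_auc(a[idx], yy) - rank_auc(b[idx], yy)
    delta_obs = rank_auc(a, y) - rank_auc(b, y)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(deltas, [alpha, 1.0 - alpha])
    return float(delta_obs), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Call matrices: frequency classes, agreement, disagreement clustering
# ---------------------------------------------------------------------------

class CallMatrix:
    """Variants x approaches matrix of binary deleterious calls.

    Entries are 1 (deleterious), 0 (neutral) or NaN (missing call).
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        values = frame.to_numpy(dtype=float)
        valid = np.isnan(values) | (values == 0) | (values == 1)
        if not valid.all():
            raise ValueError("call entries must be 0, 1 or missing")
        self.frame = frame.astype(float)

    @property
    def approaches(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)


#: minor-allele-count classes: (1), (2), (3-4), (5-8), (>8)
DEFAULT_FREQUENCY_CLASSES: tuple[tuple[int, float], ...] = (
    (1, 1), (2, 2), (3, 4), (5, 8), (9, np.inf),
)


def _class_name(lo: int, hi: float) -> str:
    if np.isinf(hi):
        return f">{lo - 1}"
    return str(lo) if lo == hi else f"{lo}-{int(hi)}"


def proportion_deleterious_by_class(
    calls: CallMatrix,
    minor_allele_counts: Sequence[int],
    class_edges: Sequence[tuple[int, float]] = DEFAULT_FREQUENCY_CLASSES,
) -> pd.DataFrame:
    """Per-approach proportion of variants called deleterious per frequency class.

    Class membership is by minor allele count; missing calls are excluded from
    both numerator and denominator.  A count of 0 is not a variant and is a
    validation error.
    """
    macs = np.asarray(minor_allele_counts)
    if len(macs) != len(calls):
        raise ValueError("need a minor allele count for every variant")
    if (macs <= 0).any():
        raise ValueError("minor allele count must be >= 1 (0 is not a variant)")
    out = {}
    for lo, hi in class_edges:
        in_class = (macs >= lo) & (macs <= hi)
        sub = calls.frame.loc[in_class]
        out[_class_name(lo, hi)] = sub.mean(axis=0, skipna=True)
    return pd.DataFrame(out)


def call_agreement_summary(calls: CallMatrix) -> pd.Series:
    """Proportion of variants called deleterious by >= k approaches, k=1..m.

    Rows with any missing call are excluded (listwise) and the exclusion count
    logged; the proportions are over the complete rows.
    """
    values = calls.frame.to_numpy(dtype=float)
    complete = ~np.isnan(values).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("agreement summary: %d rows with missing calls excluded", n_dropped)
    sub = values[complete]
    if len(sub) == 0:
        raise ValueError("no complete rows")
    m = sub.shape[1]
    n_called = sub.sum(axis=1)
    return pd.Series(
        {k: float((n_called >= k).mean()) for k in range(1, m + 1)},
        name="proportion_called_by_at_least_k",
    )


def disagreement_distance(calls: CallMatrix) -> pd.DataFrame:
    """Pairwise number of variants where two approaches' calls differ.

    Rows where either call is missing are excluded pairwise.
    """
    cols = calls.approaches
    if len(cols) < 2:
        raise ValueError("need >= 2 approaches")
    values = calls.frame.to_numpy(dtype=float)
    m = len(cols)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            both = ~np.isnan(values[:, i]) & ~np.isnan(values[:, j])
            d = float(np.sum(values[both, i] != values[both, j]))
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=cols, columns=cols)


@dataclasses.dataclass
class ClusterResult:
    linkage: np.ndarray
    approaches: list[str]
    support: dict[frozenset, float]  # clade (set of approach names) -> support
    newick: str


def _clades_from_linkage(Z: np.ndarray, names: list[str]) -> list[frozenset]:
    """Leaf sets of every internal node of a scipy linkage tree."""
    n = len(names)
    members: dict[int, frozenset] = {i: frozenset([names[i]]) for i in range(n)}
    clades = []
    for k, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        clades.append(merged)
    return clades


def _linkage_to_newick(Z: np.ndarray, names: list[str], support: Mapping[frozenset, float]) -> str:
    n = len(names)
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: names[i] for i in range(n)}
    members: dict[int, frozenset] = {i: frozenset([names[i]]) for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la, lb = h - height[a], h - height[b]
        merged = members[a] | members[b]
        sup = support.get(merged)
        label = f"{sup:.3f}" if sup is not None else ""
        node[n + k] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g}){label}"
        members[n + k] = merged
        height[n + k] = h
    return node[n + len(Z) - 1] + ";"


def cluster_approaches(
    calls: CallMatrix, n_boot: int = 2000, seed: int = 0
) -> ClusterResult:
    """Average-linkage clustering of approaches by call disagreement.

    Support at each internal node is the fraction of bootstrap trees — each
    built from a resampling of variants with replacement — whose clustering
    contains the same set of approaches as a clade.
    """
    names = calls.approaches
    if len(names) < 3:
        raise ValueError("need >= 3 approaches for internal structure")
    D = disagreement_distance(calls).to_numpy()
    Z = linkage(squareform(D, checks=False), method="average")
    observed = _clades_from_linkage(Z, names)

    rng = np.random.default_rng(seed)
    values = calls.frame
    hits = {c: 0 for c in observed}
    n = len(values)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        Db = disagreement_distance(CallMatrix(values.iloc[idx])).to_numpy()
        Zb = linkage(squareform(Db, checks=False), method="average")
        boot_clades = set(_clades_from_linkage(Zb, names))
        for c in observed:
            if c in boot_clades:
                hits[c] += 1
    support = {c: hits[c] / n_boot for c in observed}
    newick = _linkage_to_newick(Z, names, support)
    return ClusterResult(linkage=Z, approaches=names, support=support, newick=newick)
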