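"""Correlation-map (longest same-sign run) similarity statistics.

Two scattering curves measured on the same grid are compared through the
longest run of same-sign differences: under the null hypothesis that the
curves differ only by symmetric noise, each difference is an independent
fair sign, and the probability that the longest run of equal signs among
``n`` points reaches the observed length is computed exactly from the
run-length recursion.  The resulting P value needs no error estimates,
which makes it the work-horse similarity test throughout the pipeline
(frame-vs-frame maps, fit diagnostics, steady-state detection).

Pairwise maps over a frame set are summarised by a three-colour
classification (green P ≥ 0.05, yellow 0.01 ≤ P < 0.05, red P < 0.01 for
the unadjusted test) and by red-cluster statistics: maximal 4-connected
groups of red cells in the square map.  A Holm–Bonferroni step-down
adjustment is available for the multiple-testing problem inherent in the
n(n−1)/2 simultaneous comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage

__all__ = [
    "PairwiseOptions",
    "PValueMap",
    "ClusterStats",
    "longest_same_sign_run",
    "run_pvalue",
    "cormap_pvalue",
    "pairwise_pvalue_map",
    "holm_bonferroni",
    "red_cluster_stats",
]

GREEN, YELLOW, RED = 0, 1, 2
RED_THRESHOLD = 0.01
YELLOW_THRESHOLD = 0.05


@dataclass(frozen=True)
class PairwiseOptions:
    """Options shared by every pairwise comparison of an analysis.

    q_max_cutoff restricts the comparison to the information-rich low-q
    region (default 0.05 Å⁻¹); stride subsamples the remaining grid
    (stride 2 = every other point) to decorrelate adjacent detector
    pixels; adjust selects the multiple-testing treatment.
    """

    q_max_cutoff: float = 0.05
    stride: int = 1
    adjust: str = "none"  # "none" | "holm_bonferroni"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.adjust not in ("none", "holm_bonferroni"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")

    def restrict(self, q: np.ndarray) -> np.ndarray:
        """Index array selecting q ≤ cutoff, then subsampled by stride."""
        idx = np.flatnonzero(np.asarray(q) <= self.q_max_cutoff)
        return idx[:: self.stride]


def longest_same_sign_run(delta) -> int:
    """Length of the longest run of strictly-positive or strictly-negative
    consecutive entries.  Exact zeros break runs and belong to none."""
    delta = np.asarray(delta, dtype=float)
    if delta.size == 0:
        raise ValueError("empty difference vector")
    if not np.all(np.isfinite(delta)):
        raise ValueError("non-finite values in difference vector")
    signs = np.sign(delta).astype(int)
    best = run = 0
    prev = 0
    for s in signs:
        if s != 0 and s == prev:
            run += 1
        elif s != 0:
            run = 1
        else:
            run = 0
        prev = s
        if run > best:
            best = run
    return best


@lru_cache(maxsize=None)
def _n_bounded(n: int, k: int) -> int:
    """Number of binary sequences of length n whose longest run is <= k.

    Counted exactly in integer arithmetic: a sequence is 2 (first symbol)
    times a composition of n into parts of size <= k.
    """
    if k <= 0:
        return 0 if n > 0 else 1
    if n == 0:
        return 1
    # compositions of n with parts <= k
    comp = [0] * (n + 1)
    comp[0] = 1
    for i in range(1, n + 1):
        comp[i] = sum(comp[i - j] for j in range(1, min(i, k) + 1))
    return 2 * comp[n]


def run_pvalue(n: int, C: int) -> float:
    """P(longest run of equal signs among n independent fair signs >= C).

    Exact (integer recursion, then one float division); C = 0 or 1
    returns 1, C = n returns 2^(1-n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if C > n:
        raise ValueError(f"observed run C={C} exceeds n={n}")
    if C <= 1:
        return 1.0
    # exact integer complement before the single float division
    num = (1 << n) - _n_bounded(n, C - 1)
    p = num / (1 << n)
    return min(max(p, 0.0), 1.0)


def cormap_pvalue(a, b, q=None, opts: PairwiseOptions | None = None) -> float:
    """P value for the similarity of two curves on a shared grid.

    The grid is restricted to q ≤ q_max_cutoff and subsampled by stride
    before the run statistic is formed; the null sample size is the
    number of points actually compared.
    """
    opts = opts or PairwiseOptions()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must share the abscissa grid")
    if q is not None:
        idx = opts.restrict(np.asarray(q))
        a, b = a[idx], b[idx]
    else:
        a, b = a[:: opts.stride], b[:: opts.stride]
    if a.size < 2:
        raise ValueError("fewer than 2 points after q restriction")
    delta = a - b
    C = longest_same_sign_run(delta)
    return run_pvalue(a.size, C)


def _classify(p: float) -> int:
    if p < RED_THRESHOLD:
        return RED
    if p < YELLOW_THRESHOLD:
        return YELLOW
    return GREEN


@dataclass
class PValueMap:
    """Square matrix of pairwise P values with three-class labels."""

    P: np.ndarray
    classes: np.ndarray
    opts: PairwiseOptions

    @property
    def n_curves(self) -> int:
        return self.P.shape[0]

    @property
    def m(self) -> int:
        """Number of pairwise comparisons n(n−1)/2."""
        n = self.n_curves
        return n * (n - 1) // 2

    def upper_pvals(self) -> np.ndarray:
        iu = np.triu_indices(self.n_curves, k=1)
        return self.P[iu]


def holm_bonferroni(pvals, alpha: float = 0.05):
    """Holm step-down procedure.

    Sorts the m P values ascending and rejects while
    p_(i) <= alpha/(m - i + 1) (1-based), stopping at the first failure.
    Returns (reject: bool array in input order, step thresholds in input
    order).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one P value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds_sorted = alpha / (m - np.arange(m))
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if p[order[i]] <= thresholds_sorted[i]:
            reject_sorted[i] = True
        else:
            break
    reject = np.zeros(m, dtype=bool)
    thresholds = np.zeros(m)
    reject[order] = reject_sorted
    thresholds[order] = thresholds_sorted
    return reject, thresholds


def pairwise_pvalue_map(curves, q=None, opts: PairwiseOptions | None = None) -> PValueMap:
    """All-pairs CorMap P values with three-class colouring.

    With ``adjust="holm_bonferroni"`` the classes use the step-down
    acceptance thresholds: red = rejected by the Holm procedure at level
    0.01, yellow = rejected at 0.05 but not at 0.01, green otherwise.
    """
    opts = opts or PairwiseOptions()
    curves = [np.asarray(c, dtype=float) for c in curves]
    n = len(curves)
    if n < 2:
        raise ValueError("need at least two curves")
    P = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = cormap_pvalue(curves[i], curves[j], q=q, opts=opts)
            P[i, j] = P[j, i] = p
    classes = np.full((n, n), GREEN, dtype=int)
    iu = np.triu_indices(n, k=1)
    pvec = P[iu]
    if opts.adjust == "holm_bonferroni":
        rej_red, _ = holm_bonferroni(pvec, alpha=RED_THRESHOLD)
        rej_yel, _ = holm_bonferroni(pvec, alpha=YELLOW_THRESHOLD)
        cvec = np.where(rej_red, RED, np.where(rej_yel, YELLOW, GREEN))
    else:
        cvec = np.array([_classify(p) for p in pvec])
    classes[iu] = cvec
    classes[(iu[1], iu[0])] = cvec
    return PValueMap(P=P, classes=classes, opts=opts)


@dataclass
class ClusterStats:
    cluster_sizes: list
    average_red_cluster_size: float
    percent_red: float
    percent_yellow: float
    percent_green: float


def red_cluster_stats(pmap: PValueMap) -> ClusterStats:
    """Red-cluster and class-percentage summary of a P-value map.

    Clusters are maximal 4-connected components of red cells in the full
    (symmetric) map with the diagonal excluded; class percentages are
    fractions of the m off-diagonal pairs.
    """
    n = pmap.n_curves
    classes = pmap.classes.copy()
    np.fill_diagonal(classes, -1)
    red = classes == RED
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n_clusters = ndimage.label(red, structure=structure)
    sizes = (
        ndimage.sum_labels(red, labels, index=np.arange(1, n_clusters + 1))
        .astype(int)
        .tolist()
        if n_clusters
        else []
    )
    avg = float(np.mean(sizes)) if sizes else 0.0
    iu = np.triu_indices(n, k=1)
    cvec = pmap.classes[iu]
    m = cvec.size
    return ClusterStats(
        cluster_sizes=sizes,
        average_red_cluster_size=avg,
        percent_red=100.0 * np.count_nonzero(cvec == RED) / m,
        percent_yellow=100.0 * np.count_nonzero(cvec == YELLOW) / m,
        percent_green=100.0 * np.count_nonzero(cvec == GREEN) / m,
    )
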