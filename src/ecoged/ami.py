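"""Adjusted mutual information between two real-valued similarity vectors.

Two continuous vectors are discretized into equal-frequency bins; the
mutual information I(U,V) of the resulting labelings measures how much
knowing one similarity index tells you about the other.  Plug-in MI is
positively biased for finite samples, so it is adjusted for chance: the
expectation E{I} of MI over all contingency tables with the observed
margins (the hypergeometric/permutation model) is subtracted and the result
normalised by the larger marginal entropy,

    AMI_max = (I − E{I}) / (max{H(U), H(V)} − E{I}).

AMI is ≈ 0 for independent vectors, 1 for informationally identical ones.
All information quantities use natural logarithms (nats); AMI itself is
scale-free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "Labeling",
    "ContingencyTable",
    "AMIResult",
    "discretize_equal_frequency",
    "entropy",
    "mutual_information",
    "contingency",
    "expected_mi",
    "ami",
    "ami_from_labelings",
    "default_nbins",
]


@dataclass(frozen=True)
class Labeling:
    """Integer bin labels 1..k for a vector of n observations."""

    labels: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def k(self) -> int:
        return len(set(self.labels))

    def counts(self) -> np.ndarray:
        return np.bincount(np.asarray(self.labels))[1:]


@dataclass(frozen=True)
class ContingencyTable:
    counts: tuple[tuple[int, ...], ...]

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def row_margins(self) -> np.ndarray:
        return self.array.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.array.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.array.sum())


@dataclass(frozen=True)
class AMIResult:
    mi: float
    h_u: float
    h_v: float
    emi: float
    ami: float


def default_nbins(n: int) -> int:
    """Cube-root rule of the discretization literature: round(n^(1/3))."""
    return max(1, round(n ** (1.0 / 3.0)))


def discretize_equal_frequency(x, nbins: int) -> Labeling:
    """Equal-frequency (quantile) binning into ``nbins`` bins.

    Observations are split, in stable (value, original index) order, into
    contiguous chunks of ⌊n/nbins⌋ or ⌈n/nbins⌉ points.  Ties straddling a
    boundary stay split by stable order, but bins that consist of a single
    repeated value identical to their neighbour's are merged (a constant
    vector collapses to one bin, which is logged).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    if nbins > n:
        raise ValueError(f"nbins ({nbins}) exceeds the number of observations ({n})")
    order = np.argsort(x, kind="stable")
    base, rem = divmod(n, nbins)
    labels = np.empty(n, dtype=np.int64)
    bounds: list[tuple[float, float]] = []
    start = 0
    for b in range(nbins):
        size = base + (1 if b < rem else 0)
        chunk = order[start:start + size]
        labels[chunk] = b + 1
        bounds.append((float(x[chunk[0]]), float(x[chunk[-1]])))
        start += size
    # merge degenerate single-valued bins that repeat the neighbour's value
    relabel = list(range(nbins + 1))
    for b in range(1, nbins):
        lo_prev, hi_prev = bounds[b - 1]
        lo, hi = bounds[b]
        if lo_prev == hi_prev == lo == hi:
            relabel[b + 1] = relabel[b]
    labels = np.array([relabel[l] for l in labels])
    uniq = {v: i + 1 for i, v in enumerate(sorted(set(labels)))}
    labels = np.array([uniq[l] for l in labels])
    k = len(uniq)
    if k < nbins:
        logger.info("equal-frequency binning collapsed %d bins to %d (tied values)", nbins, k)
    return Labeling(tuple(int(l) for l in labels))


def entropy(l: Labeling) -> float:
    """Plug-in Shannon entropy in nats, with 0·log 0 := 0."""
    p = l.counts() / l.n
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def contingency(lu: Labeling, lv: Labeling) -> ContingencyTable:
    if lu.n != lv.n:
        raise ValueError("labelings must have equal length")
    ku, kv = max(lu.labels), max(lv.labels)
    t = np.zeros((ku, kv), dtype=np.int64)
    for a, b in zip(lu.labels, lv.labels):
        t[a - 1, b - 1] += 1
    return ContingencyTable(tuple(tuple(int(v) for v in row) for row in t))


def mutual_information(lu: Labeling, lv: Labeling) -> float:
    """Plug-in mutual information I(U,V) in nats from the joint counts."""
    t = contingency(lu, lv).array.astype(float)
    n = t.sum()
    pij = t / n
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    mask = pij > 0
    mi = float((pij[mask] * np.log(pij[mask] / (pi @ pj)[mask])).sum())
    return max(0.0, mi)


def expected_mi(t: ContingencyTable) -> float:
    """Expected plug-in MI over all tables with the observed margins.

    Under the permutation (hypergeometric) null, each cell count n_ij
    follows a hypergeometric law given margins (a_i, b_j, N); E{I} sums the
    MI contribution of every feasible n_ij weighted by its probability.
    Evaluated in log-factorial space for stability; exact, not sampled.
    """
    a = t.row_margins.astype(np.int64)
    b = t.col_margins.astype(np.int64)
    N = t.total
    if N == 0:
        return 0.0
    gln = gammaln
    log_n_fact_terms = gln(N + 1)
    emi = 0.0
    for ai in a:
        if ai == 0:
            continue
        for bj in b:
            if bj == 0:
                continue
            lo = max(1, ai + bj - N)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1, dtype=np.int64)
            log_p = (
                gln(ai + 1) + gln(bj + 1) + gln(N - ai + 1) + gln(N - bj + 1)
                - log_n_fact_terms - gln(nij + 1) - gln(ai - nij + 1)
                - gln(bj - nij + 1) - gln(N - ai - bj + nij + 1)
            )
            contrib = (nij / N) * (np.log(N * nij) - math.log(ai * bj))
            emi += float((contrib * np.exp(log_p)).sum())
    return emi


def ami_from_labelings(lu: Labeling, lv: Labeling) -> AMIResult:
    """Max-normalised adjusted mutual information of two labelings."""
    mi = mutual_information(lu, lv)
    h_u, h_v = entropy(lu), entropy(lv)
    emi = expected_mi(contingency(lu, lv))
    denom = max(h_u, h_v) - emi
    if abs(denom) < 1e-12:
        # both labelings single-bin: no information either way
        value = 1.0 if lu.labels == lv.labels else 0.0
    else:
        value = (mi - emi) / denom
    return AMIResult(mi=mi, h_u=h_u, h_v=h_v, emi=emi, ami=value)


def ami(x, y, nbins: int | None = None) -> AMIResult:
    """AMI between two real vectors after equal-frequency discretization.

    ``nbins`` defaults to the cube-root rule round(n^(1/3)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if nbins is None:
        nbins = default_nbins(x.size)
    return ami_from_labelings(
        discretize_equal_frequency(x, nbins),
        discretize_equal_frequency(y, nbins),
    )
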