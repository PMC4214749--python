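"""Density thresholding and Dice similarity against the chance expectation.

A weighted network is binarised by retaining its k highest-ranked
connections, giving a binary network of density d = k/T with
T = N(N-1)/2.  Connections of equal weight — predominantly the mass of
exact zeros that probabilistic tractography leaves between unconnected
parcels — are assigned a random rank.  One complete tie-broken ranking
is drawn per (network, seed) and reused across every k, so the
thresholded edge sets are nested as the density grows.

The Dice coefficient of two equal-density binary networks is the
fraction of their k edges that coincide; for two independent random
networks its expectation equals the density itself, which is the chance
null every similarity is judged against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .netio import BinaryNetwork, NetworkError, WeightedNetwork


@dataclass(frozen=True)
class DCRecord:
    """Dice coefficient of one subject's pipeline pair at one density."""

    subject: str
    k: int
    density: float
    dc: float
    expected: float  # chance-level DC = density
    normalized: float  # dc - expected

    def __post_init__(self) -> None:
        if not 0.0 <= self.dc <= 1.0:
            raise NetworkError(f"DC out of [0, 1]: {self.dc}")


def rank_edges(net: WeightedNetwork, seed: int) -> np.ndarray:
    """Full tie-broken ranking of the T node pairs, best first.

    Returns upper-triangle pair indices ordered by decreasing weight;
    within tied weights the order is uniform-random from the seeded
    stream.  Thresholding at k is the first k entries, hence edge sets
    are nested across k by construction.
    """
    w = net.upper_triangle()
    rng = np.random.default_rng(seed)
    tiebreak = rng.random(w.size)
    # lexsort: last key is primary; ascending on -w puts largest weights first
    return np.lexsort((tiebreak, -w))


def _pairs_to_adjacency(pair_idx: np.ndarray, n: int) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[0][pair_idx], iu[1][pair_idx]] = 1
    return a | a.T


def threshold_by_rank(net: WeightedNetwork, k: int, seed: int) -> BinaryNetwork:
    """Retain the k highest-ranked connections (random rank within ties)."""
    t = net.scheme.n_pairs
    if not 0 <= k <= t:
        raise NetworkError(f"k={k} out of range [0, {t}]")
    order = rank_edges(net, seed)
    a = _pairs_to_adjacency(order[:k], net.scheme.n_nodes)
    return BinaryNetwork(scheme=net.scheme, adjacency=a)


def dice(a: BinaryNetwork, b: BinaryNetwork) -> float:
    """Dice coefficient: shared edges as a proportion of the edge count.

    Defined for equal-density networks only.  Two empty networks (k=0)
    are identical, so the coefficient is 1 by convention.
    """
    if a.scheme.labels != b.scheme.labels:
        raise NetworkError("Dice coefficient requires a common scheme")
    if a.k != b.k:
        raise NetworkError(
            f"Dice coefficient requires equal density (k={a.k} vs k={b.k})"
        )
    if a.k == 0:
        return 1.0
    shared = int(np.sum((a.adjacency & b.adjacency)[np.triu_indices(a.scheme.n_nodes, 1)]))
    return shared / a.k


def dc_curve(
    p1: WeightedNetwork,
    p2: WeightedNetwork,
    seed: int,
    subject: str = "",
    ks: np.ndarray | None = None,
) -> list[DCRecord]:
    """Dice coefficient of a pipeline pair at every density k = 0..T.

    Each network gets an independent tie-breaking stream derived from
    the seed.  The sweep is O(T): with nested rankings, an edge is
    present in both networks at density k iff the later of its two rank
    positions is below k, so the intersection sizes are a cumulative
    histogram of the pairwise rank maxima.
    """
    if p1.scheme.labels != p2.scheme.labels:
        raise NetworkError("dc_curve requires a common scheme")
    t = p1.scheme.n_pairs
    seq = np.random.SeedSequence(entropy=seed)
    s1, s2 = (int(s.generate_state(1)[0]) for s in seq.spawn(2))
    pos1 = np.empty(t, dtype=np.int64)
    pos1[rank_edges(p1, s1)] = np.arange(t)
    pos2 = np.empty(t, dtype=np.int64)
    pos2[rank_edges(p2, s2)] = np.arange(t)
    later = np.maximum(pos1, pos2)
    # intersection size at k = #{pairs with later-rank < k}
    inter = np.cumsum(np.bincount(later, minlength=t))
    if ks is None:
        ks = np.arange(t + 1)
    records = []
    for k in np.asarray(ks, dtype=int):
        dc = 1.0 if k == 0 else float(inter[k - 1]) / k
        d = k / t
        records.append(
            DCRecord(
                subject=subject, k=int(k), density=d, dc=dc,
                expected=d, normalized=dc - d,
            )
        )
    return records


def weight_correlations(
    p1: WeightedNetwork, p2: WeightedNetwork
) -> tuple[float, float]:
    """Spearman and Pearson correlation of the T upper-triangle weights.

    Spearman uses mid-ranks for ties.  If either weight vector has zero
    variance both correlations are undefined and returned as NaN.
    """
    if p1.scheme.labels != p2.scheme.labels:
        raise NetworkError("weight_correlations requires a common scheme")
    x, y = p1.upper_triangle(), p2.upper_triangle()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        import warnings

        warnings.warn("zero-variance weight vector: correlations undefined", stacklevel=2)
        return float("nan"), float("nan")
    spearman = float(stats.spearmanr(x, y).statistic)
    pearson = float(stats.pearsonr(x, y).statistic)
    return spearman, pearson


def subject_pipeline_seed(master_seed: int, subject: str, pipeline: str) -> int:
    """Deterministic tie-breaking seed for one subject x pipeline stream."""
    digest = np.random.SeedSequence(
        entropy=master_seed,
        spawn_key=(hash_label(subject), hash_label(pipeline)),
    ).generate_state(1)[0]
    return int(digest)


def hash_label(label: str) -> int:
    """Stable (process-independent) 32-bit hash of a text label."""
    h = 2166136261
    for byte in label.encode():
        h = ((h ^ byte) * 16777619) & 0xFFFFFFFF
    return h
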