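"""Consensus-network extraction and binary graph-theoretic characterisation.

At the peak-convergence density, each subject's convergent edges are the
intersection of the two pipelines' binary networks; per-edge prevalence
is the fraction of subjects whose convergent set contains the edge, and
the group consensus network keeps the edges present in every subject.

The five binary metrics follow the Brain Connectivity Toolbox
conventions: characteristic path length averages shortest paths over
reachable ordered pairs (disconnected pairs are counted and reported,
not averaged as infinities); clustering and local efficiency assign 0
to nodes of degree < 2; assortativity is the Pearson correlation of
endpoint degrees with each undirected edge contributing both
orientations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .netio import BinaryNetwork, NetworkError, ParcellationScheme

METRIC_NAMES = ("PL", "CC", "Geff", "Leff", "AS")


@dataclass(frozen=True)
class PathLengthResult:
    value: float
    n_unreachable_pairs: int  # ordered pairs with no connecting path


@dataclass(frozen=True)
class ConsensusResult:
    """Group consensus at a fixed density: intersection and prevalence."""

    scheme: ParcellationScheme
    k: int
    intersection: BinaryNetwork  # edges convergent in every subject
    prevalence: np.ndarray  # fraction of subjects per edge, N x N
    subject_convergent: list[BinaryNetwork]

    def __post_init__(self) -> None:
        p = self.prevalence
        if (p < 0).any() or (p > 1).any():
            raise NetworkError("prevalence entries must lie in [0, 1]")
        if (p != p.T).any() or np.diag(p).any():
            raise NetworkError("prevalence must be symmetric with zero diagonal")


def consensus_edges(
    pipeline1: list[BinaryNetwork], pipeline2: list[BinaryNetwork]
) -> ConsensusResult:
    """Convergent edges per subject, their prevalence, and the intersection.

    Both lists are per-subject binary networks thresholded at the same
    edge count k on a common scheme.
    """
    if len(pipeline1) != len(pipeline2) or not pipeline1:
        raise NetworkError("need matched, non-empty per-subject network lists")
    scheme = pipeline1[0].scheme
    k = pipeline1[0].k
    for net in (*pipeline1, *pipeline2):
        if net.scheme.labels != scheme.labels:
            raise NetworkError("all networks must share one scheme")
        if net.k != k:
            raise NetworkError(f"all networks must share k (got {net.k} != {k})")
    n_sub = len(pipeline1)
    prevalence = np.zeros((scheme.n_nodes, scheme.n_nodes), dtype=float)
    convergent = []
    for a, b in zip(pipeline1, pipeline2):
        conv = a.adjacency & b.adjacency
        prevalence += conv
        convergent.append(BinaryNetwork(scheme=scheme, adjacency=conv))
    prevalence /= n_sub
    intersection = BinaryNetwork(
        scheme=scheme, adjacency=(prevalence == 1.0).astype(np.int8)
    )
    return ConsensusResult(
        scheme=scheme,
        k=k,
        intersection=intersection,
        prevalence=prevalence,
        subject_convergent=convergent,
    )


def _distances(adjacency: np.ndarray) -> np.ndarray:
    return shortest_path(adjacency.astype(float), method="D", unweighted=True)


def characteristic_pathlength(net: BinaryNetwork) -> PathLengthResult:
    """Mean shortest-path length over reachable ordered node pairs."""
    d = _distances(net.adjacency)
    off = ~np.eye(net.scheme.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    n_unreachable = int(off.sum() - finite.sum())
    if not finite.any():
        warnings.warn("no reachable node pairs: path length undefined", stacklevel=2)
        return PathLengthResult(value=float("nan"), n_unreachable_pairs=n_unreachable)
    return PathLengthResult(
        value=float(d[finite].mean()), n_unreachable_pairs=n_unreachable
    )


def clustering_coefficient(net: BinaryNetwork) -> float:
    """Mean local clustering: 2*triangles / (deg*(deg-1)); deg<2 nodes count 0."""
    a = net.adjacency.astype(np.int64)
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2
    denom = deg * (deg - 1)
    local = np.zeros(net.scheme.n_nodes)
    ok = denom > 0
    local[ok] = 2.0 * triangles[ok] / denom[ok]
    return float(local.mean())


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean inverse shortest-path length over ordered pairs (1/inf = 0)."""
    n = net.scheme.n_nodes
    d = _distances(net.adjacency)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(off & np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def local_efficiency(net: BinaryNetwork) -> float:
    """Mean over nodes of the global efficiency of the neighbour subgraph.

    Nodes with fewer than two neighbours contribute 0.
    """
    a = net.adjacency
    n = net.scheme.n_nodes
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        d = _distances(sub)
        off = ~np.eye(nbrs.size, dtype=bool)
        with np.errstate(divide="ignore"):
            inv = np.where(off & np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        eff[i] = inv[off].mean()
    return float(eff.mean())


def assortativity(net: BinaryNetwork) -> float:
    """Degree assortativity: Pearson correlation of endpoint degrees.

    Every undirected edge contributes both (deg_i, deg_j) orientations.
    Undefined (NaN, with a warning) when all endpoint degrees are equal.
    """
    a = net.adjacency
    if a.sum() == 0:
        warnings.warn("assortativity undefined for an empty graph", stacklevel=2)
        return float("nan")
    deg = a.sum(axis=1)
    i, j = np.nonzero(np.triu(a, k=1))
    x = np.concatenate([deg[i], deg[j]]).astype(float)
    y = np.concatenate([deg[j], deg[i]]).astype(float)
    if x.std() == 0.0:
        warnings.warn(
            "assortativity undefined: zero variance in endpoint degrees",
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def network_metrics(net: BinaryNetwork) -> dict[str, float]:
    """The five Table-style binary metrics of one network."""
    return {
        "PL": characteristic_pathlength(net).value,
        "CC": clustering_coefficient(net),
        "Geff": global_efficiency(net),
        "Leff": local_efficiency(net),
        "AS": assortativity(net),
    }


def metrics_table(
    networks_by_pipeline: dict[str, list[BinaryNetwork]]
) -> dict[str, dict[str, dict[str, float]]]:
    """Per-pipeline mean +/- sample sd of the five metrics across subjects.

    Undefined metric values (NaN) are dropped from the summary; their
    count is reported per cell so missingness is visible, not silent.
    """
    table: dict[str, dict[str, dict[str, float]]] = {}
    for pipeline, nets in networks_by_pipeline.items():
        per_metric = {name: [] for name in METRIC_NAMES}
        for net in nets:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = network_metrics(net)
            for name in METRIC_NAMES:
                per_metric[name].append(m[name])
        table[pipeline] = {}
        for name, values in per_metric.items():
            arr = np.asarray(values, dtype=float)
            ok = arr[~np.isnan(arr)]
            table[pipeline][name] = {
                "mean": float(ok.mean()) if ok.size else float("nan"),
                "sd": float(ok.std(ddof=1)) if ok.size > 1 else 0.0,
                "n": int(ok.size),
                "n_undefined": int(arr.size - ok.size),
            }
    return table
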