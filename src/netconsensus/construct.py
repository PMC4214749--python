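"""Weighted-network construction: fiber tallies, scan averaging, node merging.

The connection weight between two parcels is the density of connecting
fibers: the number of fibers with one endpoint in each parcel, divided by
the mean of the two parcels' total boundary-voxel volumes, (V_i + V_j)/2.
Fibers whose two endpoints fall in the same parcel carry no inter-parcel
information and are discarded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .netio import (
    CorrespondenceTable,
    FiberEndpoints,
    NetworkError,
    ParcellationScheme,
    WeightedNetwork,
)


@dataclass(frozen=True)
class ConstructionReport:
    """Bookkeeping from network construction: what was kept and dropped."""

    n_fibers: int
    n_connecting: int
    n_intra_parcel: int
    n_unknown_label: int


def tally_fiber_counts(
    ep: FiberEndpoints,
    scheme: ParcellationScheme,
    permissive: bool = False,
) -> tuple[np.ndarray, ConstructionReport]:
    """Count connecting fibers per unordered parcel pair.

    Returns the symmetric N-by-N count matrix (zero diagonal) and a
    report.  Records naming a label outside the scheme raise an error
    unless ``permissive``, in which case they are tallied as discarded.
    """
    known = set(scheme.labels)
    index = {label: i for i, label in enumerate(scheme.labels)}
    counts = np.zeros((scheme.n_nodes, scheme.n_nodes), dtype=float)
    n_intra = n_unknown = n_connecting = 0
    for fiber_id, a, b in ep.records:
        if a not in known or b not in known:
            if permissive:
                n_unknown += 1
                continue
            offender = a if a not in known else b
            raise NetworkError(
                f"fiber {fiber_id!r} endpoint label {offender!r} not in scheme {scheme.name!r}"
            )
        if a == b:
            n_intra += 1
            continue
        i, j = index[a], index[b]
        counts[i, j] += 1
        counts[j, i] += 1
        n_connecting += 1
    report = ConstructionReport(
        n_fibers=len(ep.records),
        n_connecting=n_connecting,
        n_intra_parcel=n_intra,
        n_unknown_label=n_unknown,
    )
    return counts, report


def counts_to_weights(
    counts: np.ndarray, volumes: np.ndarray
) -> np.ndarray:
    """Apply the fiber-density formula W[i,j] = C[i,j] / ((V[i] + V[j]) / 2)."""
    if (volumes <= 0).any():
        raise NetworkError("boundary-voxel volumes must be strictly positive")
    mean_vol = (volumes[:, None] + volumes[None, :]) / 2.0
    w = counts / mean_vol
    np.fill_diagonal(w, 0.0)
    return w


def build_weighted_network(
    ep: FiberEndpoints,
    scheme: ParcellationScheme,
    permissive: bool = False,
) -> tuple[WeightedNetwork, ConstructionReport]:
    """Build the fiber-density weighted network from endpoint records."""
    counts, report = tally_fiber_counts(ep, scheme, permissive=permissive)
    missing = sorted(set(scheme.labels) - set(ep.volumes))
    if missing:
        raise NetworkError(f"missing boundary-voxel volumes for: {missing}")
    volumes = np.array([ep.volumes[l] for l in scheme.labels], dtype=float)
    w = counts_to_weights(counts, volumes)
    return WeightedNetwork(scheme=scheme, weights=w), report


def average_scans(nets: list[WeightedNetwork]) -> WeightedNetwork:
    """Elementwise mean of repeat-scan networks on a common scheme."""
    if not nets:
        raise NetworkError("average_scans needs at least one network")
    scheme = nets[0].scheme
    for net in nets[1:]:
        if net.scheme.labels != scheme.labels:
            raise NetworkError(
                f"scheme mismatch: {net.scheme.name!r} vs {scheme.name!r}"
            )
    mean = np.mean([net.weights for net in nets], axis=0)
    return WeightedNetwork(scheme=scheme, weights=mean)


def merged_scheme(
    scheme: ParcellationScheme, table: CorrespondenceTable
) -> tuple[ParcellationScheme, list[list[int]]]:
    """Derive the target scheme and source-node groups for a merge.

    Target nodes are ordered by first appearance of their group in the
    source scheme; hemisphere is inherited (all members of a group must
    share it), lobe is taken from the group's first member.
    """
    groups: dict[str, list[int]] = {}
    order: list[str] = []
    for i, label in enumerate(scheme.labels):
        target = table.target_of(label)
        if target not in groups:
            groups[target] = []
            order.append(target)
        groups[target].append(i)
    labels, hemis, lobes, members = [], [], [], []
    for target in order:
        idx = groups[target]
        hemi_set = {scheme.hemispheres[i] for i in idx}
        if len(hemi_set) > 1:
            raise NetworkError(
                f"merge group {target!r} spans both hemispheres: "
                f"{[scheme.labels[i] for i in idx]}"
            )
        labels.append(target)
        hemis.append(hemi_set.pop())
        lobes.append(scheme.lobes[idx[0]])
        members.append(idx)
    out = ParcellationScheme(
        name=table.target_scheme or f"{scheme.name}_merged",
        labels=tuple(labels),
        hemispheres=tuple(hemis),
        lobes=tuple(lobes),
    )
    return out, members


def merge_nodes(
    net: WeightedNetwork,
    table: CorrespondenceTable,
    volumes: dict[str, float] | None = None,
) -> WeightedNetwork:
    """Aggregate nodes to a coarser scale through a correspondence table.

    With per-parcel boundary-voxel ``volumes``, fiber counts are
    recovered from the density weights, pooled across merge groups,
    group volumes summed, and the density formula re-applied — this
    commutes exactly with network construction.  Without volumes the
    group weights are plainly summed, a documented approximation.
    Connections internal to a merge group become self-connections and
    are dropped.
    """
    target, members = merged_scheme(net.scheme, table)
    n_src = net.scheme.n_nodes
    m = np.zeros((n_src, target.n_nodes))
    for g, idx in enumerate(members):
        m[idx, g] = 1.0

    if volumes is not None:
        missing = sorted(set(net.scheme.labels) - set(volumes))
        if missing:
            raise NetworkError(f"missing volumes for labels: {missing}")
        v_src = np.array([volumes[l] for l in net.scheme.labels], dtype=float)
        if (v_src <= 0).any():
            raise NetworkError("volumes must be strictly positive")
        # invert the density formula to recover pooled fiber counts
        counts = net.weights * (v_src[:, None] + v_src[None, :]) / 2.0
        pooled_counts = m.T @ counts @ m
        v_tgt = m.T @ v_src
        w = counts_to_weights(pooled_counts, v_tgt)
    else:
        w = m.T @ net.weights @ m
        np.fill_diagonal(w, 0.0)
    return WeightedNetwork(scheme=target, weights=w)


def merge_endpoints(
    ep: FiberEndpoints, table: CorrespondenceTable
) -> FiberEndpoints:
    """Relabel endpoint records and pool volumes to the target scale."""
    records = tuple(
        (fid, table.target_of(a), table.target_of(b)) for fid, a, b in ep.records
    )
    pooled: Counter[str] = Counter()
    for label, vol in ep.volumes.items():
        pooled[table.target_of(label)] += vol
    return FiberEndpoints(records=records, volumes=dict(pooled))
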