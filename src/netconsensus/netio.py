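"""Domain types and file I/O for connectome matrices, label tables and results.

The on-disk dialect is deliberately plain: tab-separated text with node
labels carried in both the header row and the index column, decimal
points, no thousands separators.  Scheme order is canonical — matrices
stored in any node order are permuted to scheme order on read.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

HEMISPHERES = ("L", "R")
LOBES = ("temporal", "frontal", "parietal", "occipital", "insula", "limbic/cingulate")

#: symmetry is enforced within this tolerance, then the matrix is exactly
#: symmetrised as (W + W.T) / 2; larger asymmetries are an error, not a fix
SYMMETRY_TOL = 1e-9


class NetworkError(ValueError):
    """Invariant violation in a connectome object or file."""


@dataclass(frozen=True)
class ParcellationScheme:
    """An ordered cortical parcellation: node labels with hemisphere and lobe.

    The node order of a scheme is canonical: every matrix bound to the
    scheme uses this order on both axes.
    """

    name: str
    labels: tuple[str, ...]
    hemispheres: tuple[str, ...]
    lobes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise NetworkError("a parcellation needs at least 2 nodes")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise NetworkError(f"duplicate node labels: {dupes}")
        if len(self.hemispheres) != len(self.labels) or len(self.lobes) != len(self.labels):
            raise NetworkError("labels, hemispheres and lobes must have equal length")
        bad_hemi = sorted({h for h in self.hemispheres if h not in HEMISPHERES})
        if bad_hemi:
            raise NetworkError(f"unknown hemisphere codes: {bad_hemi}")
        bad_lobe = sorted({l for l in self.lobes if l not in LOBES})
        if bad_lobe:
            raise NetworkError(f"unknown lobes: {bad_lobe}")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_pairs(self) -> int:
        """Total possible undirected connections T = N(N-1)/2."""
        n = self.n_nodes
        return n * (n - 1) // 2

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise NetworkError(f"label {label!r} not in scheme {self.name!r}") from None

    def subset_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels, "hemisphere": self.hemispheres, "lobe": self.lobes}
        )


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric non-negative fiber-density matrix bound to a scheme.

    Weights are connecting-fiber densities (fibers per mm^3 of boundary
    voxels); the diagonal is structurally zero (self-connections are
    meaningless for inter-parcel connectivity).
    """

    scheme: ParcellationScheme
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = self.scheme.n_nodes
        if w.shape != (n, n):
            raise NetworkError(f"weight matrix shape {w.shape} != ({n}, {n})")
        if not np.isfinite(w).all():
            raise NetworkError("weight matrix contains non-finite entries")
        asym = np.abs(w - w.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise NetworkError(f"weight matrix asymmetric (max |W - W.T| = {asym:g})")
        if (w < 0).any():
            i, j = np.argwhere(w < 0)[0]
            raise NetworkError(f"negative weight at ({self.scheme.labels[i]}, {self.scheme.labels[j]})")
        if np.abs(np.diag(w)).max() > 0:
            raise NetworkError("weight matrix diagonal must be zero")
        object.__setattr__(self, "weights", (w + w.T) / 2.0)
        self.weights.flags.writeable = False

    def upper_triangle(self) -> np.ndarray:
        """Weights of the T node pairs, in row-major upper-triangle order."""
        iu = np.triu_indices(self.scheme.n_nodes, k=1)
        return self.weights[iu]


@dataclass(frozen=True)
class BinaryNetwork:
    """0/1 adjacency retaining k edges, i.e. network density k/T."""

    scheme: ParcellationScheme
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = self.scheme.n_nodes
        if a.shape != (n, n):
            raise NetworkError(f"adjacency shape {a.shape} != ({n}, {n})")
        if not np.isin(a, (0, 1)).all():
            raise NetworkError("adjacency entries must be 0 or 1")
        if (a != a.T).any():
            raise NetworkError("adjacency must be symmetric")
        if np.diag(a).any():
            raise NetworkError("adjacency diagonal must be zero")
        object.__setattr__(self, "adjacency", a.astype(np.int8))
        self.adjacency.flags.writeable = False

    @property
    def k(self) -> int:
        """Number of retained edges."""
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        return self.k / self.scheme.n_pairs

    def edge_set(self) -> frozenset[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return frozenset(zip(i.tolist(), j.tolist()))


@dataclass(frozen=True)
class FiberEndpoints:
    """Tabular fiber-endpoint records plus per-parcel boundary-voxel volumes.

    Each record names the two parcels a reconstructed fiber terminates
    in; volumes are total boundary-voxel volumes in mm^3 and must be
    strictly positive.
    """

    records: tuple[tuple[str, str, str], ...]  # (fiber_id, parcel_a, parcel_b)
    volumes: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = sorted({l for l, v in self.volumes.items() if not v > 0})
        if bad:
            raise NetworkError(f"non-positive boundary-voxel volumes for: {bad}")


@dataclass(frozen=True)
class CorrespondenceTable:
    """Atlas-correspondence (merge) table: source parcel label -> target label.

    The mapping must be surjective onto its targets and, for cortical
    atlases, identical in the two hemispheres (labels prefixed ``lh_`` /
    ``rh_``); asymmetry is reported as a warning by default.
    """

    source_scheme: str
    target_scheme: str
    mapping: Mapping[str, str]

    @property
    def n_targets(self) -> int:
        return len(set(self.mapping.values()))

    def target_of(self, label: str) -> str:
        try:
            return self.mapping[label]
        except KeyError:
            raise NetworkError(
                f"label {label!r} has no entry in correspondence "
                f"{self.source_scheme!r} -> {self.target_scheme!r}"
            ) from None

    def check_hemisphere_symmetry(self, strict: bool = False) -> list[str]:
        """Return base labels whose L/R merge patterns differ.

        Labels are paired by stripping ``lh_``/``rh_`` prefixes; unpaired
        labels are ignored.
        """
        left = {
            l[3:]: t[3:] if t.startswith(("lh_", "rh_")) else t
            for l, t in self.mapping.items()
            if l.startswith("lh_")
        }
        right = {
            l[3:]: t[3:] if t.startswith(("lh_", "rh_")) else t
            for l, t in self.mapping.items()
            if l.startswith("rh_")
        }
        offenders = sorted(
            base
            for base in set(left) & set(right)
            if left[base] != right[base]
        )
        if offenders:
            msg = f"hemisphere-asymmetric merge pattern for: {offenders}"
            if strict:
                raise NetworkError(msg)
            warnings.warn(msg, stacklevel=2)
        return offenders


# ---------------------------------------------------------------------------
# readers / writers


def read_scheme(path: str | Path, name: str | None = None) -> ParcellationScheme:
    """Read a parcellation label table (TSV: label, hemisphere, lobe)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"label", "hemisphere", "lobe"}
    if not required.issubset(df.columns):
        raise NetworkError(f"label table {path} missing columns {sorted(required - set(df.columns))}")
    return ParcellationScheme(
        name=name or Path(path).stem,
        labels=tuple(df["label"]),
        hemispheres=tuple(df["hemisphere"]),
        lobes=tuple(df["lobe"]),
    )


def write_scheme(scheme: ParcellationScheme, path: str | Path) -> None:
    scheme.subset_table().to_csv(path, sep="\t", index=False)


def read_weight_matrix(path: str | Path, scheme: ParcellationScheme) -> WeightedNetwork:
    """Read a TSV weight matrix and bind it to ``scheme``.

    The file carries node labels in its header row and index column; rows
    and columns are permuted to scheme order.  Asymmetry beyond
    ``SYMMETRY_TOL`` and negative entries are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    file_labels = [str(c) for c in df.columns]
    if list(map(str, df.index)) != file_labels:
        raise NetworkError(f"{path}: row labels differ from column labels")
    missing = sorted(set(scheme.labels) - set(file_labels))
    extra = sorted(set(file_labels) - set(scheme.labels))
    if missing or extra:
        raise NetworkError(
            f"{path}: label mismatch vs scheme {scheme.name!r}"
            f" (missing {missing}, unexpected {extra})"
        )
    df = df.loc[list(scheme.labels), list(scheme.labels)]
    w = df.to_numpy(dtype=float)
    asym = np.abs(w - w.T).max()
    if asym > SYMMETRY_TOL:
        raise NetworkError(f"{path}: asymmetric matrix (max |W - W.T| = {asym:g})")
    if (w < 0).any():
        raise NetworkError(f"{path}: negative weight entries")
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(scheme=scheme, weights=w)


def write_weight_matrix(net: WeightedNetwork, path: str | Path) -> None:
    labels = list(net.scheme.labels)
    pd.DataFrame(net.weights, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_correspondence(
    path: str | Path,
    source_scheme: str = "",
    target_scheme: str = "",
    strict_symmetry: bool = False,
) -> CorrespondenceTable:
    """Read a two-column TSV correspondence table (source, target)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise NetworkError(f"{path}: correspondence table needs two columns")
    src_col, tgt_col = df.columns[:2]
    if df[src_col].duplicated().any():
        dupes = sorted(df.loc[df[src_col].duplicated(), src_col])
        raise NetworkError(f"{path}: duplicate source labels {dupes}")
    table = CorrespondenceTable(
        source_scheme=source_scheme or str(src_col),
        target_scheme=target_scheme or str(tgt_col),
        mapping=dict(zip(df[src_col], df[tgt_col])),
    )
    table.check_hemisphere_symmetry(strict=strict_symmetry)
    return table


def write_correspondence(table: CorrespondenceTable, path: str | Path) -> None:
    pd.DataFrame(
        {table.source_scheme or "source": list(table.mapping.keys()),
         table.target_scheme or "target": list(table.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def packaged_data_path(name: str) -> Path:
    """Path of a label/correspondence table shipped with the package."""
    return Path(resources.files("netconsensus") / "data" / name)


def to_graph(
    net: BinaryNetwork, prevalence: np.ndarray | None = None
) -> nx.Graph:
    """Convert a binary network to a networkx graph with anatomical attributes."""
    g = nx.Graph()
    s = net.scheme
    for idx, (label, hemi, lobe) in enumerate(zip(s.labels, s.hemispheres, s.lobes)):
        g.add_node(label, hemisphere=hemi, lobe=lobe, index=idx)
    for i, j in sorted(net.edge_set()):
        attrs = {}
        if prevalence is not None:
            attrs["prevalence"] = float(prevalence[i, j])
        g.add_edge(s.labels[i], s.labels[j], **attrs)
    return g


def write_graphml(
    net: BinaryNetwork,
    path: str | Path,
    prevalence: np.ndarray | None = None,
) -> None:
    """Write a binary network as GraphML with node anatomy and optional
    per-edge prevalence."""
    nx.write_graphml(to_graph(net, prevalence), str(path))


def read_graphml(path: str | Path, scheme: ParcellationScheme) -> BinaryNetwork:
    g = nx.read_graphml(str(path))
    n = scheme.n_nodes
    a = np.zeros((n, n), dtype=np.int8)
    for u, v in g.edges():
        i, j = scheme.index_of(str(u)), scheme.index_of(str(v))
        a[i, j] = a[j, i] = 1
    return BinaryNetwork(scheme=scheme, adjacency=a)


def read_endpoints(endpoints_path: str | Path, volumes_path: str | Path) -> FiberEndpoints:
    """Read fiber endpoints (fiber_id, parcel_a, parcel_b) and volumes (label, mm3)."""
    ep = pd.read_csv(endpoints_path, sep="\t", dtype=str)
    need = {"fiber_id", "parcel_a", "parcel_b"}
    if not need.issubset(ep.columns):
        raise NetworkError(f"{endpoints_path}: missing columns {sorted(need - set(ep.columns))}")
    vol = pd.read_csv(volumes_path, sep="\t")
    if not {"label", "mm3"}.issubset(vol.columns):
        raise NetworkError(f"{volumes_path}: expected columns label, mm3")
    return FiberEndpoints(
        records=tuple(zip(ep["fiber_id"], ep["parcel_a"], ep["parcel_b"])),
        volumes=dict(zip(vol["label"].astype(str), vol["mm3"].astype(float))),
    )


def write_endpoints(ep: FiberEndpoints, endpoints_path: str | Path, volumes_path: str | Path) -> None:
    pd.DataFrame(ep.records, columns=["fiber_id", "parcel_a", "parcel_b"]).to_csv(
        endpoints_path, sep="\t", index=False
    )
    pd.DataFrame(
        {"label": list(ep.volumes.keys()), "mm3": list(ep.volumes.values())}
    ).to_csv(volumes_path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
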