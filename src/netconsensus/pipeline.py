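"""End-to-end orchestration: inputs -> networks -> similarity -> consensus.

One run executes the full analysis under a single master seed: obtain
per-subject, per-pipeline weighted networks (synthetic, from fiber
endpoints, or from precomputed matrices), average repeat scans, sweep
the Dice-similarity curve over all densities, locate the peak
convergence, and extract the consensus network with its graph metrics.
Every stage artifact is written under the output directory and entered
into a manifest with content checksums, so a run is reproducible and
verifiable file by file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import construct, convergence, netio, similarity, synthgen
from .consensus import consensus_edges, metrics_table
from .netio import NetworkError

logger = logging.getLogger("netconsensus")

INPUT_MODES = ("synthetic", "endpoints", "matrices")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (one input mode, one seed)."""

    mode: str
    out_dir: str
    seed: int
    n_boot: int = 1000
    neglog_base: float = 10.0
    density_stride: int = 1
    # synthetic mode
    synth: dict = field(default_factory=dict)
    # endpoints / matrices modes
    pipeline1_dir: str | None = None
    pipeline2_dir: str | None = None
    scheme_path: str | None = None
    merge_table_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in INPUT_MODES:
            raise NetworkError(f"input mode must be one of {INPUT_MODES}")
        if self.mode != "synthetic" and not (
            self.pipeline1_dir and self.pipeline2_dir and self.scheme_path
        ):
            raise NetworkError(f"{self.mode} mode needs pipeline dirs and a scheme path")
        if self.density_stride < 1:
            raise NetworkError("density_stride must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_matrix_pipelines(cfg: RunConfig):
    scheme = netio.read_scheme(cfg.scheme_path)
    p1_files = sorted(Path(cfg.pipeline1_dir).glob("*.tsv"))
    p2_files = sorted(Path(cfg.pipeline2_dir).glob("*.tsv"))
    if [f.name for f in p1_files] != [f.name for f in p2_files]:
        raise NetworkError("pipeline directories must contain matching file names")
    if not p1_files:
        raise NetworkError("no matrix files found")
    subjects = [f.stem for f in p1_files]
    means1, means2 = [], []
    for f1, f2 in zip(p1_files, p2_files):
        try:
            means1.append(netio.read_weight_matrix(f1, scheme))
        except NetworkError as err:
            raise NetworkError(f"stage=load subject={f1.stem}: {err}") from err
        try:
            means2.append(netio.read_weight_matrix(f2, scheme))
        except NetworkError as err:
            raise NetworkError(f"stage=load subject={f2.stem}: {err}") from err
    return scheme, subjects, means1, means2


def _load_endpoint_pipelines(cfg: RunConfig):
    scheme = netio.read_scheme(cfg.scheme_path)
    table = (
        netio.read_correspondence(cfg.merge_table_path)
        if cfg.merge_table_path
        else None
    )
    means = []
    subjects = None
    for pdir in (cfg.pipeline1_dir, cfg.pipeline2_dir):
        ep_files = sorted(Path(pdir).glob("*_endpoints.tsv"))
        if not ep_files:
            raise NetworkError(f"no *_endpoints.tsv files under {pdir}")
        subs, nets = [], []
        for ep_file in ep_files:
            sid = ep_file.name[: -len("_endpoints.tsv")]
            vol_file = ep_file.with_name(f"{sid}_volumes.tsv")
            ep = netio.read_endpoints(ep_file, vol_file)
            if table is not None:
                ep = construct.merge_endpoints(ep, table)
            net, _ = construct.build_weighted_network(ep, scheme)
            subs.append(sid)
            nets.append(net)
        if subjects is None:
            subjects = subs
        elif subjects != subs:
            raise NetworkError("pipeline directories must contain the same subjects")
        means.append(nets)
    return scheme, subjects, means[0], means[1]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return the run manifest."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.__dict__ | {"synth": dict(cfg.synth)},
                      "checksums": {}, "stages": {}}

    def _record(stage: str, path: Path) -> None:
        manifest["checksums"][path.name] = _sha256(path)
        manifest["stages"].setdefault(stage, []).append(path.name)

    # --- stage 1: obtain per-subject, per-pipeline subject-mean networks
    truth = None
    if cfg.mode == "synthetic":
        synth_cfg = synthgen.SynthConfig(**({"seed": cfg.seed} | dict(cfg.synth)))
        p1_scans, p2_scans, truth = synthgen.generate_cohort(synth_cfg)
        scheme = truth.scheme
        subjects = [f"subject{i:03d}" for i in range(synth_cfg.n_subjects)]
        means1 = synthgen.subject_means(p1_scans)
        means2 = synthgen.subject_means(p2_scans)
        path = out / "truth.graphml"
        netio.write_graphml(truth, path)
        _record("synthetic", path)
    elif cfg.mode == "matrices":
        scheme, subjects, means1, means2 = _load_matrix_pipelines(cfg)
    else:
        scheme, subjects, means1, means2 = _load_endpoint_pipelines(cfg)
    logger.info("stage=input mode=%s subjects=%d nodes=%d", cfg.mode, len(subjects), scheme.n_nodes)

    # --- stage 2: Dice curves across all densities
    t = scheme.n_pairs
    ks = np.arange(0, t + 1, cfg.density_stride)
    if cfg.density_stride > 1:
        logger.warning("density stride %d coarsens peak resolution", cfg.density_stride)
    if ks[-1] != t:
        ks = np.append(ks, t)
    curves = {}
    for sid, m1, m2 in zip(subjects, means1, means2):
        seed = similarity.subject_pipeline_seed(cfg.seed, sid, "pair")
        curves[sid] = similarity.dc_curve(m1, m2, seed=seed, subject=sid, ks=ks)
        logger.info("stage=similarity subject=%s", sid)
    path = out / "dc_curves.json"
    netio.write_json(
        {
            sid: [rec.__dict__ for rec in recs]
            for sid, recs in curves.items()
        },
        path,
    )
    _record("similarity", path)

    # --- stage 3: significance curve, bootstrap, peak
    interior = (ks > 0) & (ks < t)
    dc_table = np.array([[r.dc for r, keep in zip(curves[sid], interior) if keep] for sid in subjects])
    densities = ks[interior] / t
    curve = convergence.bootstrap_curve(
        dc_table, densities, n_boot=cfg.n_boot, seed=cfg.seed, ks=ks[interior]
    )
    peak_k, peak_density = curve.peak()
    path = out / "convergence.json"
    netio.write_json(curve.to_dict(), path)
    _record("convergence", path)
    logger.info("stage=convergence peak_k=%d peak_density=%.4f", peak_k, peak_density)

    # --- stage 4: consensus network at the peak density
    bin1, bin2 = [], []
    for sid, m1, m2 in zip(subjects, means1, means2):
        s1 = similarity.subject_pipeline_seed(cfg.seed, sid, "p1")
        s2 = similarity.subject_pipeline_seed(cfg.seed, sid, "p2")
        bin1.append(similarity.threshold_by_rank(m1, peak_k, seed=s1))
        bin2.append(similarity.threshold_by_rank(m2, peak_k, seed=s2))
    result = consensus_edges(bin1, bin2)
    path = out / "consensus.graphml"
    netio.write_graphml(result.intersection, path, prevalence=result.prevalence)
    _record("consensus", path)
    path = out / "prevalence.tsv"
    pd.DataFrame(result.prevalence, index=scheme.labels, columns=scheme.labels).to_csv(
        path, sep="\t", float_format="%.17g"
    )
    _record("consensus", path)

    # --- stage 5: graph metrics of the thresholded subject networks
    table = metrics_table({"P1": bin1, "P2": bin2})
    rows = []
    for pipeline, metrics in table.items():
        for name, cell in metrics.items():
            rows.append({"pipeline": pipeline, "metric": name, **cell})
    path = out / "metrics.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    _record("metrics", path)

    manifest["peak_k"] = peak_k
    manifest["peak_density"] = peak_density
    manifest["elapsed_s"] = round(time.time() - t0, 3)
    netio.write_json(manifest, out / "manifest.json")
    return manifest
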