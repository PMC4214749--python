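"""Synthetic paired-pipeline connectome cohorts with a planted core network.

Emulates, at matrix level, what two independent probabilistic-tractography
pipelines produce from the same scans: dense non-negative symmetric
fiber-density matrices per subject and scan that share a latent "true"
core of strong connections, agree only partially elsewhere, and carry a
mass of exact-zero entries among weak pairs.

Generative model, per subject:

* a hemisphere-symmetric planted core adjacency shared by the whole
  cohort — the ground truth downstream analysis should recover;
* core pair log-weights drawn from the signal distribution, shared by
  both pipelines (both reconstruct the same anatomy);
* non-core ("spurious") pair log-weights drawn from the weaker noise
  distribution and split into a shared and a pipeline-specific
  component: spurious connections arise from fiber dispersal and each
  algorithm disperses differently, so they reproduce across pipelines
  only partially.  The pipeline-specific share varies by subject and
  grows with the pipeline noise level, vanishing in the zero-noise
  limit (identical pipelines);
* independent pipeline-level multiplicative log-noise on every pair —
  the knob the Spearman calibration turns;
* scan-level multiplicative log-noise shared by both pipelines (a
  repeat scan is one acquisition fed to both reconstructions);
* per subject and pipeline, the weakest-observed non-core pairs are
  forced to exactly zero — real tractography zeros are the connections
  a pipeline failed to find, so the two pipelines' zero sets overlap
  without coinciding.  The subject-level zero fraction is
  Beta-distributed: cohorts genuinely differ in matrix sparsity.

All randomness derives from one seed through keyed substreams, so
enlarging the cohort never perturbs already-generated subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .construct import average_scans
from .netio import BinaryNetwork, NetworkError, ParcellationScheme, WeightedNetwork, LOBES
from .similarity import weight_correlations

#: pipeline log-noise calibrated once (bisection against the Monte-Carlo
#: Spearman estimate) to give ~0.7 inter-pipeline rank correlation at the
#: default cohort settings, and frozen as the package default
DEFAULT_PIPELINE_NOISE_SD = 0.35

#: pipeline noise level at which the pipeline-specific share of spurious
#: weight variance saturates at its subject-drawn value
_SPURIOUS_REF_SD = 0.35


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-generation settings.

    Defaults mirror the study conditions of a repeat-scan adult cohort
    analysed at the common 34-node scale: 28 subjects, 3 scans each,
    core density 0.196, inter-pipeline rank correlation ~0.7.
    """

    n_nodes: int = 34
    n_subjects: int = 28
    n_scans: int = 3
    core_density: float = 0.196
    signal_lognormal: tuple[float, float] = (0.0, 0.25)  # (mu, sigma) of core log weight
    noise_lognormal: tuple[float, float] = (-2.5, 0.8)  # non-core log weight
    pipeline_noise_sd: float = DEFAULT_PIPELINE_NOISE_SD
    scan_noise_sd: float = 0.2
    zero_fraction: float = 0.4  # cohort-mean fraction of non-core pairs zeroed
    zero_fraction_spread: float = 0.12  # between-subject sd of the zero fraction
    spurious_specific: tuple[float, float] = (0.5, 0.22)  # Beta(mean, sd) of the
    # pipeline-specific share of spurious log-weight variance, per subject
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.core_density < 1.0:
            raise NetworkError("core_density must lie in (0, 1)")
        if self.n_scans < 1:
            raise NetworkError("n_scans must be >= 1")
        if not 0.0 <= self.zero_fraction < 1.0:
            raise NetworkError("zero_fraction must lie in [0, 1)")
        if self.n_nodes < 4 or self.n_nodes % 2:
            raise NetworkError("n_nodes must be an even number >= 4")
        t = self.n_nodes * (self.n_nodes - 1) // 2
        if self.core_density * t < 1:
            raise NetworkError("degenerate config: core_density * T < 1")

    @property
    def n_pairs(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    @property
    def core_k(self) -> int:
        return int(round(self.core_density * self.n_pairs))


def synthetic_scheme(n_nodes: int, name: str = "synthetic") -> ParcellationScheme:
    """Hemisphere-interleaved synthetic parcellation of ``n_nodes`` parcels."""
    if n_nodes % 2:
        raise NetworkError("a bilateral scheme needs an even node count")
    labels, hemis, lobes = [], [], []
    for r in range(n_nodes // 2):
        lobe = LOBES[r % len(LOBES)]
        for prefix, hemi in (("lh_", "L"), ("rh_", "R")):
            labels.append(f"{prefix}region{r:02d}")
            hemis.append(hemi)
            lobes.append(lobe)
    return ParcellationScheme(
        name=name, labels=tuple(labels), hemispheres=tuple(hemis), lobes=tuple(lobes)
    )


def _rng(cfg: SynthConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=key))


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    if sd <= 0:
        raise NetworkError("Beta spread must be positive")
    conc = mean * (1 - mean) / (sd * sd) - 1
    if conc <= 0:
        raise NetworkError(f"Beta spread {sd} too large for mean {mean}")
    return mean * conc, (1 - mean) * conc


def _mirror_orbits(n_nodes: int) -> list[list[int]]:
    """Unordered node pairs grouped into left/right mirror orbits.

    Nodes are hemisphere-interleaved, so the mirror of node i is i XOR 1.
    Homotopic pairs (a region with its own mirror) are their own orbit;
    every other pair belongs to a two-pair orbit.
    """
    iu = np.triu_indices(n_nodes, k=1)
    pair_index = {(int(i), int(j)): p for p, (i, j) in enumerate(zip(*iu))}
    seen: set[int] = set()
    orbits = []
    for (i, j), p in pair_index.items():
        if p in seen:
            continue
        mi, mj = sorted((i ^ 1, j ^ 1))
        q = pair_index[(mi, mj)]
        orbit = [p] if q == p else [p, q]
        seen.update(orbit)
        orbits.append(orbit)
    return orbits


def planted_core(cfg: SynthConfig) -> BinaryNetwork:
    """Hemisphere-symmetric random core adjacency with exactly core_k edges."""
    scheme = synthetic_scheme(cfg.n_nodes)
    orbits = _mirror_orbits(cfg.n_nodes)
    rng = _rng(cfg, 0)
    order = rng.permutation(len(orbits))
    chosen: list[int] = []
    deficit = cfg.core_k
    skipped_singles: list[list[int]] = []
    for o in order:
        orbit = orbits[o]
        if len(orbit) <= deficit:
            chosen.extend(orbit)
            deficit -= len(orbit)
        elif len(orbit) == 1:
            skipped_singles.append(orbit)
        if deficit == 0:
            break
    if deficit == 1:
        # parity fix: a homotopic (size-1) orbit keeps the core symmetric
        singles = skipped_singles or [
            o for o in orbits if len(o) == 1 and o[0] not in chosen
        ]
        if singles:
            chosen.extend(singles[0])
            deficit = 0
    if deficit:
        raise NetworkError("could not realise a symmetric core at the requested density")
    iu = np.triu_indices(cfg.n_nodes, k=1)
    a = np.zeros((cfg.n_nodes, cfg.n_nodes), dtype=np.int8)
    sel = np.asarray(chosen, dtype=int)
    a[iu[0][sel], iu[1][sel]] = 1
    return BinaryNetwork(scheme=scheme, adjacency=(a | a.T))


def _pairs_to_matrix(values: np.ndarray, n: int) -> np.ndarray:
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = values
    return m + m.T


def generate_cohort(
    cfg: SynthConfig, shared_latent: bool = True
) -> tuple[list[list[WeightedNetwork]], list[list[WeightedNetwork]], BinaryNetwork]:
    """Generate the paired-pipeline cohort.

    Returns (pipeline1, pipeline2, truth) where each pipeline is a list
    of subjects, each subject a list of per-scan weighted networks, and
    truth is the planted core.  With ``shared_latent=False`` nothing is
    shared between the pipelines and no contrast is planted (all pairs
    draw from the background distribution) — the null cohort under which
    thresholded networks agree only by chance.
    """
    truth = planted_core(cfg)
    scheme = truth.scheme
    iu = np.triu_indices(cfg.n_nodes, k=1)
    core_mask = truth.adjacency[iu].astype(bool)
    t = cfg.n_pairs
    mu_s, sd_s = cfg.signal_lognormal
    mu_n, sd_n = cfg.noise_lognormal
    za, zb = _beta_params(cfg.zero_fraction, cfg.zero_fraction_spread) \
        if cfg.zero_fraction > 0 else (None, None)
    wa, wb = _beta_params(*cfg.spurious_specific)
    noncore_idx = np.flatnonzero(~core_mask)

    pipeline_nets: tuple[list[list[WeightedNetwork]], ...] = ([], [])
    for s in range(cfg.n_subjects):
        rng = _rng(cfg, 1, s)
        core_lat = rng.normal(mu_s, sd_s, size=t)
        shared_spurious = rng.normal(0.0, 1.0, size=t)
        z_s = _rng(cfg, 5, s).beta(za, zb) if cfg.zero_fraction > 0 else 0.0
        # pipeline-specific share of spurious variance: subject-drawn,
        # scaled down with the pipeline noise level so the zero-noise
        # limit gives identical pipelines
        w_s = _rng(cfg, 6, s).beta(wa, wb)
        w_s *= min(1.0, cfg.pipeline_noise_sd / _SPURIOUS_REF_SD)
        scan_shift = [
            _rng(cfg, 4, s, scan).normal(0.0, cfg.scan_noise_sd, size=t)
            for scan in range(cfg.n_scans)
        ]
        for p in range(2):
            if shared_latent:
                own_spurious = _rng(cfg, 7, s, p).normal(0.0, 1.0, size=t)
                spurious = mu_n + sd_n * (
                    np.sqrt(1.0 - w_s) * shared_spurious + np.sqrt(w_s) * own_spurious
                )
                latent = np.where(core_mask, core_lat, spurious)
            else:
                # null cohort: no planted contrast, nothing shared — every
                # pair draws from the background distribution, independently
                # per pipeline
                latent = _rng(cfg, 8, s, p).normal(mu_n, sd_n, size=t)
            pipe_shift = _rng(cfg, 2, s, p).normal(0.0, cfg.pipeline_noise_sd, size=t)
            observed = latent + pipe_shift
            if cfg.zero_fraction > 0:
                if shared_latent:
                    eligible = noncore_idx
                    rate = z_s
                else:
                    # no core exists under the null: every pair is
                    # zero-eligible, at a rate preserving the zero mass
                    eligible = np.arange(t)
                    rate = z_s * noncore_idx.size / t
                n_zero = _rng(cfg, 3, s, p).binomial(eligible.size, rate)
                order = np.argsort(observed[eligible])
                zero_idx = eligible[order[:n_zero]]
            else:
                zero_idx = np.empty(0, dtype=int)
            scans = []
            for scan in range(cfg.n_scans):
                if shared_latent:
                    shift = scan_shift[scan]
                else:
                    # a true null shares nothing, not even scan noise
                    shift = _rng(cfg, 9, s, p, scan).normal(
                        0.0, cfg.scan_noise_sd, size=t
                    )
                w = np.exp(observed + shift)
                w[zero_idx] = 0.0
                scans.append(
                    WeightedNetwork(
                        scheme=scheme, weights=_pairs_to_matrix(w, cfg.n_nodes)
                    )
                )
            pipeline_nets[p].append(scans)
    return pipeline_nets[0], pipeline_nets[1], truth


def generate_null_cohort(
    cfg: SynthConfig,
) -> tuple[list[list[WeightedNetwork]], list[list[WeightedNetwork]], BinaryNetwork]:
    """Cohort whose two pipelines share nothing: latents drawn independently.

    Under this null the pipelines' thresholded networks are independent
    random graphs at every density, so the Dice coefficient sits at its
    chance expectation.
    """
    return generate_cohort(cfg, shared_latent=False)


def subject_means(pipeline: list[list[WeightedNetwork]]) -> list[WeightedNetwork]:
    """Per-subject scan-average networks."""
    return [average_scans(scans) for scans in pipeline]


def simulated_spearman(cfg: SynthConfig, n_reps: int = 50) -> float:
    """Monte-Carlo mean inter-pipeline Spearman of subject-mean networks.

    Each rep simulates one fresh single-subject cohort (distinct seeds
    derived from cfg.seed) and correlates the two pipelines' scan means.
    """
    rhos = []
    for rep in range(n_reps):
        rep_cfg = replace(cfg, n_subjects=1, seed=cfg.seed + 100_003 * (rep + 1))
        p1, p2, _ = generate_cohort(rep_cfg)
        rho, _ = weight_correlations(subject_means(p1)[0], subject_means(p2)[0])
        rhos.append(rho)
    return float(np.mean(rhos))


def calibrate_noise(
    target_spearman: float,
    cfg: SynthConfig,
    n_reps: int = 50,
    tol: float = 0.05,
    max_iter: int = 30,
) -> SynthConfig:
    """Bisect pipeline_noise_sd until the simulated Spearman hits the target.

    Mean inter-pipeline rank correlation decreases monotonically in the
    pipeline noise; the achievable range is bounded by the zero-noise
    limit (identical pipelines, rho = 1 up to zero-tie placement) and
    the high-noise floor (the shared latent never fully washes out), so
    unattainable targets raise with the achieved range.
    """
    if not 0.0 < target_spearman < 1.0:
        raise NetworkError("target Spearman must lie in (0, 1)")
    lo, hi = 0.0, 4.0
    rho_lo = simulated_spearman(replace(cfg, pipeline_noise_sd=lo), n_reps)
    rho_hi = simulated_spearman(replace(cfg, pipeline_noise_sd=hi), n_reps)
    if target_spearman > rho_lo + tol or target_spearman < rho_hi - tol:
        raise NetworkError(
            f"target Spearman {target_spearman} outside achievable range "
            f"[{rho_hi:.3f}, {rho_lo:.3f}] for this configuration"
        )
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        rho_mid = simulated_spearman(replace(cfg, pipeline_noise_sd=mid), n_reps)
        if abs(rho_mid - target_spearman) <= tol:
            return replace(cfg, pipeline_noise_sd=mid)
        if rho_mid > target_spearman:
            lo = mid
        else:
            hi = mid
    raise NetworkError("noise calibration did not converge")
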