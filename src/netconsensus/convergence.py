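"""Significance-vs-chance curves across densities and peak-convergence detection.

At each density d = k/T the observed per-subject Dice coefficients are
compared with the chance expectation (equal to d) by a one-sample
two-tailed t-test.  Peak significances in real cohorts reach p below
1e-40, far past what naive CDF subtraction can represent, so p-values
are carried in log space throughout via the Student-t log survival
function.  Subject resampling with replacement gives a standard error
on the -log10 p curve; the peak-convergence density is the global
maximum of the curve away from the degenerate boundary densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .netio import NetworkError

#: -log10 p reported when a zero-variance sample sits away from the null
#: mean (t is infinite); chosen beyond any representable p-value so the
#: flag, not the number, is the signal
NEGLOGP_FLOOR = 350.0

LOG10_2 = np.log10(2.0)
LN10 = np.log(10.0)

#: a sample standard deviation below this is treated as exactly zero:
#: identical DC values can leave an O(1e-17) residual sd through
#: floating-point averaging, which would otherwise masquerade as a
#: t-statistic of ~1e12
SD_TOL = 1e-12


@dataclass(frozen=True)
class SignificanceResult:
    t: float
    p: float
    neglogp: float
    degenerate: bool = False  # zero-variance sample off the null mean


@dataclass(frozen=True)
class ConvergenceCurve:
    """Per-density significance of pipeline similarity versus chance."""

    densities: np.ndarray  # k/T per evaluated threshold
    ks: np.ndarray
    t_stats: np.ndarray
    neglogp: np.ndarray  # point estimate, -log10 p
    neglogp_boot_mean: np.ndarray | None = None
    neglogp_se: np.ndarray | None = None  # bootstrap SE of the mean
    degenerate: np.ndarray | None = None  # per-density zero-variance flag
    n_boot: int = 0
    seed: int | None = None
    #: fraction of bootstrap resamples per density that were degenerate
    #: (all-identical subjects off the null mean) and excluded from the
    #: bootstrap mean and SE
    boot_degenerate_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        lengths = {len(self.densities), len(self.ks), len(self.t_stats), len(self.neglogp)}
        for arr in (self.neglogp_boot_mean, self.neglogp_se, self.degenerate,
                    self.boot_degenerate_fraction):
            if arr is not None:
                lengths.add(len(arr))
        if len(lengths) != 1:
            raise NetworkError("curve arrays must have equal length")
        if (self.neglogp < 0).any():
            raise NetworkError("-log10 p cannot be negative")

    def peak(self, exclude_boundaries: bool = True) -> tuple[int, float]:
        return find_peak(self, exclude_boundaries=exclude_boundaries)

    def to_dict(self) -> dict:
        out = {
            "densities": self.densities.tolist(),
            "ks": self.ks.tolist(),
            "t_stats": self.t_stats.tolist(),
            "neglogp": self.neglogp.tolist(),
            "n_boot": self.n_boot,
            "seed": self.seed,
        }
        for name in ("neglogp_boot_mean", "neglogp_se", "degenerate",
                     "boot_degenerate_fraction"):
            arr = getattr(self, name)
            out[name] = None if arr is None else np.asarray(arr).tolist()
        peak_k, peak_density = self.peak()
        out["peak_k"] = peak_k
        out["peak_density"] = peak_density
        return out


def _neglogp_from_t(t: np.ndarray, df: int) -> np.ndarray:
    """Two-tailed -log10 p of Student-t statistics, computed in log space."""
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        logsf = stats.t.logsf(np.abs(t), df)
    neglogp = -(LOG10_2 + logsf / LN10)
    # t = +/-inf (zero-variance sample off the mean) maps past any
    # representable p; report the documented floor
    neglogp = np.where(np.isinf(t), NEGLOGP_FLOOR, neglogp)
    return np.maximum(neglogp, 0.0)


def significance_at_density(
    dcs: np.ndarray, expected: float
) -> SignificanceResult:
    """One-sample two-tailed t-test of observed DCs against the chance DC.

    t = (mean - expected) / (sd / sqrt(n)) with the n-1 sample standard
    deviation.  A zero-variance sample at the null mean gives t = 0 and
    p = 1; off the null mean the p-value underflows to the log-space
    floor and the result is flagged degenerate.
    """
    dcs = np.asarray(dcs, dtype=float)
    n = dcs.size
    if n < 2:
        raise NetworkError("significance test needs at least 2 subjects")
    mean = dcs.mean()
    sd = dcs.std(ddof=1)
    if sd <= SD_TOL:
        if abs(mean - expected) <= SD_TOL:
            return SignificanceResult(t=0.0, p=1.0, neglogp=0.0)
        t = np.inf if mean > expected else -np.inf
        return SignificanceResult(
            t=t, p=0.0, neglogp=NEGLOGP_FLOOR, degenerate=True
        )
    t = (mean - expected) / (sd / np.sqrt(n))
    neglogp = float(_neglogp_from_t(np.array([t]), n - 1)[0])
    return SignificanceResult(t=float(t), p=float(10.0 ** (-neglogp)), neglogp=neglogp)


def significance_curve(
    dc_table: np.ndarray,
    densities: np.ndarray,
    ks: np.ndarray | None = None,
) -> ConvergenceCurve:
    """Point-estimate significance curve from a subjects-by-densities DC table."""
    dc_table = np.asarray(dc_table, dtype=float)
    densities = np.asarray(densities, dtype=float)
    n_sub, n_d = dc_table.shape
    if n_sub < 2:
        raise NetworkError("significance curve needs at least 2 subjects")
    if densities.shape != (n_d,):
        raise NetworkError("densities length must match DC table columns")
    if ks is None:
        ks = np.full(n_d, -1, dtype=int)
    mean = dc_table.mean(axis=0)
    sd = dc_table.std(axis=0, ddof=1)
    zero_sd = sd <= SD_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - densities) / (sd / np.sqrt(n_sub))
    degenerate = zero_sd & (np.abs(mean - densities) > SD_TOL)
    t = np.where(zero_sd & ~degenerate, 0.0, t)
    t = np.where(degenerate, np.sign(mean - densities) * np.inf, t)
    neglogp = _neglogp_from_t(t, n_sub - 1)
    return ConvergenceCurve(
        densities=densities,
        ks=np.asarray(ks, dtype=int),
        t_stats=t,
        neglogp=neglogp,
        degenerate=degenerate,
    )


def bootstrap_curve(
    dc_table: np.ndarray,
    densities: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    ks: np.ndarray | None = None,
) -> ConvergenceCurve:
    """Subject bootstrap of the significance curve.

    Subjects are resampled with replacement ``n_boot`` times; the
    -log10 p recomputed on every resample gives the bootstrap mean and
    the standard error of the curve.  The point estimate on the full
    sample is retained alongside.
    """
    if n_boot < 1:
        raise NetworkError("n_boot must be >= 1")
    point = significance_curve(dc_table, densities, ks=ks)
    dc_table = np.asarray(dc_table, dtype=float)
    densities = np.asarray(densities, dtype=float)
    n_sub = dc_table.shape[0]
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, dc_table.shape[1]))
    boot_degenerate = np.zeros((n_boot, dc_table.shape[1]), dtype=bool)
    for b in range(n_boot):
        idx = rng.integers(0, n_sub, size=n_sub)
        sample = dc_table[idx]
        mean = sample.mean(axis=0)
        sd = sample.std(axis=0, ddof=1)
        zero_sd = sd <= SD_TOL
        off = np.abs(mean - densities) > SD_TOL
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (mean - densities) / (sd / np.sqrt(n_sub))
        t = np.where(zero_sd & ~off, 0.0, t)
        t = np.where(zero_sd & off, np.sign(mean - densities) * np.inf, t)
        boot[b] = _neglogp_from_t(t, n_sub - 1)
        boot_degenerate[b] = zero_sd & off
    # degenerate resamples (all-identical subjects off the null mean) carry
    # the sentinel floor, not a p-value; they are excluded from the
    # bootstrap moments and reported as a fraction instead
    ok = ~boot_degenerate
    n_ok = ok.sum(axis=0)
    masked = np.ma.masked_array(boot, mask=boot_degenerate)
    boot_mean = np.where(n_ok > 0, masked.mean(axis=0).filled(np.nan), np.nan)
    boot_se = np.where(n_ok > 1, masked.std(axis=0, ddof=1).filled(np.nan), 0.0)
    return ConvergenceCurve(
        densities=point.densities,
        ks=point.ks,
        t_stats=point.t_stats,
        neglogp=point.neglogp,
        neglogp_boot_mean=boot_mean,
        neglogp_se=boot_se,
        degenerate=point.degenerate,
        n_boot=n_boot,
        seed=seed,
        boot_degenerate_fraction=boot_degenerate.mean(axis=0),
    )


def find_peak(
    curve: ConvergenceCurve, exclude_boundaries: bool = True
) -> tuple[int, float]:
    """Global maximum of the -log10 p curve and its density.

    Boundary densities (k = 0 and k = T, where the chance DC is exactly
    0 or 1 and the null is degenerate) are excluded by default, as are
    densities flagged degenerate (zero variance across subjects: the
    t-statistic is undefined there and the reported floor value would
    otherwise always win).  Ties break toward the sparser network — the
    more specific consensus.  Uses the point-estimate curve; the
    bootstrap mean tracks it closely and both are stored.
    """
    if len(curve.densities) == 0:
        raise NetworkError("cannot find the peak of an empty curve")
    eligible = np.ones(len(curve.densities), dtype=bool)
    if exclude_boundaries:
        eligible &= (curve.densities > 0.0) & (curve.densities < 1.0)
    if curve.degenerate is not None and not np.asarray(curve.degenerate).all():
        eligible &= ~np.asarray(curve.degenerate, dtype=bool)
    if not eligible.any():
        raise NetworkError("no eligible densities for peak detection")
    values = np.where(eligible, curve.neglogp, -np.inf)
    best = float(values.max())
    candidates = np.flatnonzero(values == best)
    if len(candidates) > 1:
        warnings.warn(
            f"{len(candidates)} densities tie at the peak; "
            "taking the sparsest", stacklevel=2,
        )
    # densities are ordered by k, so the first candidate is the sparsest
    idx = int(candidates[0])
    return int(curve.ks[idx]), float(curve.densities[idx])
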