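"""Hierarchical-bootstrap statistics for nested (mouse -> neuron) data.

Neurons recorded in the same animal are not independent; comparisons
between areas therefore resample at both levels: draw M animals with
replacement, then N cells with replacement within each drawn animal,
repeated L times.  Two areas are compared by computing the two-sample
Kolmogorov-Smirnov statistic D on each of the L paired resamples; the
percentile confidence interval of D is compared against the asymptotic
critical values

    D_alpha = c(alpha) sqrt((n1 + n2) / (n1 n2)),
    c(alpha) = 1.36, 1.63, 1.95 for alpha = 0.05, 0.01, 0.001.

If the lower CI bound exceeds a critical value the most stringent such
level is reported.  The module also provides the bootstrap effect size
(Cohen's d on bootstrap distributions) and fixed-bandwidth Gaussian
kernel density estimates for distribution summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

__all__ = [
    "HBConfig",
    "HBKSResult",
    "EffectSize",
    "KS_COEFFICIENTS",
    "hierarchical_resample",
    "ks_statistic",
    "ks_critical_value",
    "hb_ks_test",
    "cohens_d",
    "kde",
]

KS_COEFFICIENTS = {0.05: 1.36, 0.01: 1.63, 0.001: 1.95}
ALPHA_LEVELS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class HBConfig:
    """Hierarchical resampling scheme: N cells x M animals x L resamples."""

    n_cells: int = 150
    n_animals: int = 5
    n_resamples: int = 1000
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cells, self.n_animals, self.n_resamples) < 1:
            raise ValueError("N, M and L must all be >= 1")

    @property
    def sample_size(self) -> int:
        return self.n_cells * self.n_animals


@dataclass
class HBKSResult:
    """Outcome of a hierarchical-bootstrap two-sample KS test."""

    d_distribution: np.ndarray
    ci_low: float
    ci_high: float
    significance: str  # "ns", "0.05", "0.01" or "0.001"
    d_critical: dict
    n1: int
    n2: int


@dataclass
class EffectSize:
    """Cohen's d between two bootstrap distributions."""

    d: float
    category: str  # small (<0.2), median ([0.2, 2]), large (>2)


def hierarchical_resample(groups: dict, config: HBConfig,
                          rng: np.random.Generator | None = None,
                          ) -> list[np.ndarray]:
    """Draw L nested resamples from values keyed by animal.

    Each resample draws ``n_animals`` animals with replacement, then
    ``n_cells`` values with replacement within each drawn animal,
    yielding arrays of length N*M.
    """
    keys = [k for k, v in groups.items() if len(v) > 0]
    if not keys:
        raise ValueError("no animal contributes any value")
    arrays = {k: np.asarray(groups[k], dtype=float) for k in keys}
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out = []
    for _ in range(config.n_resamples):
        animals = rng.choice(len(keys), size=config.n_animals, replace=True)
        parts = [rng.choice(arrays[keys[a]], size=config.n_cells,
                            replace=True) for a in animals]
        out.append(np.concatenate(parts))
    return out


def ks_statistic(x, y) -> float:
    """Two-sample KS statistic: sup distance between empirical CDFs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(ks_2samp(x, y, method="asymp").statistic)


def ks_critical_value(n1: int, n2: int, alpha: float) -> float:
    """Asymptotic KS critical value D_alpha for sample sizes n1, n2."""
    if alpha not in KS_COEFFICIENTS:
        raise ValueError(f"unsupported alpha {alpha}; "
                         f"choose from {sorted(KS_COEFFICIENTS)}")
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    return KS_COEFFICIENTS[alpha] * np.sqrt((n1 + n2) / (n1 * n2))


def hb_ks_test(group_a: dict, group_b: dict,
               config: HBConfig | None = None,
               alpha_levels=ALPHA_LEVELS) -> HBKSResult:
    """Hierarchical-bootstrap two-sample KS test between two groups.

    ``group_a`` and ``group_b`` map animal id -> values.  For each of L
    paired resamples the KS statistic D is computed; the percentile CI
    of D at each alpha is compared with the critical value for the
    resampled sizes n1 = n2 = N*M, and the most stringent alpha whose
    critical value lies below the lower CI bound is reported.
    """
    config = config or HBConfig()
    rng = np.random.default_rng(config.seed)
    res_a = hierarchical_resample(group_a, config, rng)
    res_b = hierarchical_resample(group_b, config, rng)
    d = np.array([ks_statistic(a, b) for a, b in zip(res_a, res_b)])

    n = config.sample_size
    d_crit = {a: ks_critical_value(n, n, a) for a in alpha_levels}
    significance = "ns"
    ci_low = ci_high = float(d[0])
    for alpha in sorted(alpha_levels, reverse=True):  # lenient -> stringent
        lo = float(np.percentile(d, alpha / 2.0 * 100.0))
        hi = float(np.percentile(d, 100.0 - alpha / 2.0 * 100.0))
        if alpha == max(alpha_levels):
            ci_low, ci_high = lo, hi
        if lo > d_crit[alpha]:
            significance = str(alpha)
    return HBKSResult(d_distribution=d, ci_low=ci_low, ci_high=ci_high,
                      significance=significance, d_critical=d_crit,
                      n1=n, n2=n)


def cohens_d(boot_a, boot_b) -> EffectSize:
    """Cohen's d = |mean_a - mean_b| / sqrt((sd_a^2 + sd_b^2)/2).

    Categories: small below 0.2, median from 0.2 through 2 inclusive,
    large above 2.
    """
    a = np.asarray(boot_a, dtype=float)
    b = np.asarray(boot_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("bootstrap distributions need length >= 2")
    va, vb = a.std(ddof=1) ** 2, b.std(ddof=1) ** 2
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return EffectSize(d=0.0, category="small")
        raise ValueError("zero variance in both distributions")
    d = float(np.abs(a.mean() - b.mean()) / np.sqrt((va + vb) / 2.0))
    if d < 0.2:
        cat = "small"
    elif d <= 2.0:
        cat = "median"
    else:
        cat = "large"
    return EffectSize(d=d, category=cat)


def kde(values, bandwidth: float, grid: np.ndarray | None = None,
        pad_bw: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-bandwidth Gaussian kernel density estimate.

    ``bandwidth`` is the absolute kernel SD in data units (not a factor
    of the sample SD).  Returns ``(grid, density)``; with the default
    grid (512 points spanning the data +- 4 bandwidths) the density
    integrates to 1 up to truncation error.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(x.min() - pad_bw * bandwidth,
                           x.max() + pad_bw * bandwidth, 512)
    z = (grid[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) \
        / (x.size * bandwidth * np.sqrt(2.0 * np.pi))
    return grid, dens
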