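"""Pairwise population decoding of stimulus speed with linear SVMs.

Speed pairs are neighbouring dataset-1 conditions lying orthogonally to
the iso-speed lines — (sf, tf) vs (2 sf, tf/2), a 4-fold difference in
speed tf/sf.  Swapping the frequency combination yields the matched
iso-speed pair, (sf, tf/2) vs (2 sf, tf), with identical speeds.
Classifiers are trained on the trial-mean epoch amplitudes of a random
pool of neurons: 2 of the 4 trials per condition train, the other 2
test, repeated over random trial splits (iterations) and random neuron
pools (resamples).  Accuracies are averaged over iterations within a
resample, and means with 95% confidence intervals are taken over the
resamples.  Chance is 50%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from sklearn.svm import SVC

from .stimuli import SF_CENTERS_SFTF, TF_CENTERS_SFTF

__all__ = [
    "StimulusPair",
    "DecodingResult",
    "build_pairs",
    "decode_pair",
    "pool_curve",
    "delta_accuracy",
    "default_pool_sizes",
]


@dataclass(frozen=True)
class StimulusPair:
    """Two dataset-1 conditions to discriminate."""

    kind: str  # "speed" or "iso-speed"
    cond_a: int  # canonical condition index (sf-major, tf-minor)
    cond_b: int
    speed_a: float  # deg/s
    speed_b: float
    pair_id: int  # shared between a speed pair and its iso-speed partner

    @property
    def speed_ratio(self) -> float:
        hi, lo = max(self.speed_a, self.speed_b), min(self.speed_a,
                                                      self.speed_b)
        return hi / lo


def build_pairs() -> tuple[list[StimulusPair], list[StimulusPair]]:
    """Enumerate all speed pairs and their matched iso-speed partners.

    On the 5 x 6 dataset-1 grid this yields 20 pairs of each kind.
    """
    sfs, tfs = list(SF_CENTERS_SFTF), list(TF_CENTERS_SFTF)
    n_tf = len(tfs)

    def idx(i_sf, j_tf):
        return i_sf * n_tf + j_tf

    speed, iso = [], []
    pid = 0
    for i in range(len(sfs) - 1):
        for j in range(1, n_tf):
            sf, tf = sfs[i], tfs[j]
            # speed pair: (sf, tf) vs (2 sf, tf/2) -> speeds differ 4-fold
            speed.append(StimulusPair(
                "speed", idx(i, j), idx(i + 1, j - 1),
                tf / sf, (tf / 2.0) / (2.0 * sf), pid))
            # iso-speed partner: swap the frequency combination
            iso.append(StimulusPair(
                "iso-speed", idx(i, j - 1), idx(i + 1, j),
                (tf / 2.0) / sf, tf / (2.0 * sf), pid))
            pid += 1
    return speed, iso


@dataclass
class DecodingResult:
    """Accuracy of one (pair, pool size) decoding protocol."""

    pair: StimulusPair
    pool_size: int
    accuracies: np.ndarray  # per-resample mean accuracy, %
    area: str | None = None

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.percentile(self.accuracies, 2.5)),
                float(np.percentile(self.accuracies, 97.5)))


def _train_test_split_trials(n_trials: int, rng) -> tuple[np.ndarray,
                                                          np.ndarray]:
    perm = rng.permutation(n_trials)
    half = n_trials // 2
    return perm[:half], perm[half:]


def decode_pair(amplitudes: np.ndarray, pair: StimulusPair,
                pool: np.ndarray, n_iter: int = 100,
                rng: np.random.Generator | int = 0) -> np.ndarray:
    """Train/test accuracies of a linear SVM on one stimulus pair.

    ``amplitudes`` has shape (n_neurons, n_conditions, n_trials); the
    feature vector of a presentation is the pooled neurons' amplitudes.
    Per iteration, 2 of the 4 trials (drawn without replacement) train
    and the remaining 2 test, for both conditions; features are z-scored
    with training-split statistics.  Returns accuracy (%) per iteration.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) \
        else rng
    pool = np.asarray(pool, dtype=int)
    if pool.size == 0:
        raise ValueError("empty neuron pool")
    xa = amplitudes[pool, pair.cond_a, :].T  # (n_trials, n_pool)
    xb = amplitudes[pool, pair.cond_b, :].T
    n_trials = xa.shape[0]
    accs = np.empty(n_iter)
    for it in range(n_iter):
        tr, te = _train_test_split_trials(n_trials, rng)
        x_train = np.vstack([xa[tr], xb[tr]])
        y_train = np.repeat([0, 1], len(tr))
        x_test = np.vstack([xa[te], xb[te]])
        y_test = np.repeat([0, 1], len(te))
        mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=1.0)
        clf.fit((x_train - mu) / sd, y_train)
        accs[it] = (clf.predict((x_test - mu) / sd) == y_test).mean() * 100.0
    return accs


def default_pool_sizes(max_size: int = 512) -> list[int]:
    """Logarithmic pool-size ladder 2, 4, ..., up to ``max_size``."""
    return [2 ** k for k in range(1, int(np.log2(max_size)) + 1)]


def pool_curve(amplitudes: np.ndarray, pair: StimulusPair,
               sizes=None, n_resamples: int = 50, n_iter: int = 100,
               seed: int = 0, neuron_indices=None,
               area: str | None = None) -> list[DecodingResult]:
    """Decoding accuracy as a function of neuron pool size.

    For each size, ``n_resamples`` random pools are drawn without
    replacement from the available neurons; each pool's accuracy is the
    mean over ``n_iter`` random trial splits.  Sizes exceeding the
    population are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    if neuron_indices is None:
        neuron_indices = np.arange(amplitudes.shape[0])
    neuron_indices = np.asarray(neuron_indices, dtype=int)
    sizes = list(sizes) if sizes is not None else default_pool_sizes()
    usable = [s for s in sizes if s <= neuron_indices.size]
    if len(usable) < len(sizes):
        warnings.warn(
            f"pool sizes above population ({neuron_indices.size}) truncated",
            stacklevel=2)
    results = []
    for size in usable:
        accs = np.empty(n_resamples)
        for r in range(n_resamples):
            pool = rng.choice(neuron_indices, size=size, replace=False)
            accs[r] = decode_pair(amplitudes, pair, pool, n_iter, rng).mean()
        results.append(DecodingResult(pair=pair, pool_size=size,
                                      accuracies=accs, area=area))
    return results


def delta_accuracy(result_a: DecodingResult, result_b: DecodingResult,
                   ) -> dict:
    """Difference in mean accuracy between two matched decoding results.

    Returns the difference (percentage points), its 95% CI from the
    resample distributions, and a two-sample t-test over the per-
    resample accuracies.
    """
    if result_a.pool_size != result_b.pool_size:
        raise ValueError("pool sizes differ between results")
    if result_a.pair.pair_id != result_b.pair.pair_id:
        raise ValueError("results belong to different stimulus pairs")
    a, b = result_a.accuracies, result_b.accuracies
    delta = float(a.mean() - b.mean())
    se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    if a.size == b.size and np.allclose(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(a, b)
    return {
        "delta": delta,
        "ci_low": delta - 1.96 * float(se),
        "ci_high": delta + 1.96 * float(se),
        "t": float(t),
        "p": float(p),
        "significant": bool(p < 0.05),
    }
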