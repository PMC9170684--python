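"""Trace preprocessing and selection of visually responsive cells.

Trials present the stimulus battery in randomised order; analysis
starts by de-randomising each trial into canonical condition order.
Every de-randomised epoch window spans 12 s: the 4-s gray preceding the
stimulus (the baseline), the 4-s stimulus, and the 4-s gray that
follows (needed for offset and wrap-around analyses).  A cell is
*responsive* if, for at least one condition, its across-trial median
time course exceeds 3 standard deviations of the pre-stimulus baseline
continuously for more than 1 s during the stimulus epoch; cells whose
responses meet the criterion only after stimulus offset are flagged and
excluded.  The *reliability index* r is the 75th percentile of the six
pairwise Pearson correlations between concatenated de-randomised trial
time courses; cells with r > 0.3 are selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter

from .stimuli import EPOCH_DURATION_S, GRAY_DURATION_S

__all__ = [
    "EpochMatrix",
    "DegenerateBaselineError",
    "derandomize",
    "preprocess_trace",
    "is_responsive",
    "reliability_index",
    "reliability_null",
    "qc_filter",
]

R_THRESHOLD = 0.3  # default reliability selection threshold
RESPONSE_SD_FACTOR = 3.0  # response must exceed 3x baseline SD
MIN_RESPONSE_DURATION_S = 1.0  # ... continuously for more than this
OFFSET_WINDOW_S = 2.0  # post-offset window for offset-only detection


class DegenerateBaselineError(ValueError):
    """Raised when the pre-stimulus baseline has zero variance."""


@dataclass
class EpochMatrix:
    """De-randomised responses of one neuron.

    ``windows`` has shape (n_conditions, n_trials, n_window) where each
    window is [preceding gray | stimulus | following gray];
    ``amplitudes`` is the time-mean dF/F over the stimulus segment,
    shape (n_conditions, n_trials).
    """

    windows: np.ndarray
    amplitudes: np.ndarray
    frame_rate: float
    n_gray: int  # frames of gray before the stimulus
    n_stim: int  # frames of stimulus

    @property
    def stim_slice(self) -> slice:
        return slice(self.n_gray, self.n_gray + self.n_stim)

    @property
    def post_slice(self) -> slice:
        return slice(self.n_gray + self.n_stim, None)


def derandomize(trial_traces: np.ndarray, schedule: pd.DataFrame,
                n_conditions: int, frame_rate: float) -> EpochMatrix:
    """Reorder a trial's epoch blocks into canonical condition order.

    ``trial_traces`` has shape (n_trials, n_frames) with each trial laid
    out as consecutive 8-s blocks (4 s gray then 4 s stimulus).  The
    window following the last block's stimulus wraps to the start of the
    trial trace (the only 4-s gray not adjacent to a next block).
    """
    traces = np.asarray(trial_traces, dtype=float)
    n_trials, n_frames = traces.shape
    n_gray = int(round(GRAY_DURATION_S * frame_rate))
    n_stim = int(round(EPOCH_DURATION_S * frame_rate))
    block = n_gray + n_stim
    if n_frames != n_conditions * block:
        raise ValueError(
            f"trace length {n_frames} does not match {n_conditions} "
            f"conditions x {block} frames")
    n_win = block + n_gray
    windows = np.empty((n_conditions, n_trials, n_win))
    for trial in range(1, n_trials + 1):
        tr = schedule[schedule["trial"] == trial]
        if len(tr) != n_conditions:
            raise ValueError(f"schedule of trial {trial} covers {len(tr)} "
                             f"epochs, expected {n_conditions}")
        order = tr.sort_values("epoch_index")["condition_id"].to_numpy()
        for epoch, cid in enumerate(order):
            idx = np.arange(epoch * block, epoch * block + n_win) % n_frames
            windows[cid, trial - 1] = traces[trial - 1, idx]
    amplitudes = windows[:, :, n_gray:n_gray + n_stim].mean(axis=2)
    return EpochMatrix(windows=windows, amplitudes=amplitudes,
                       frame_rate=frame_rate, n_gray=n_gray, n_stim=n_stim)


def preprocess_trace(trace: np.ndarray, frame_rate: float,
                     window_s: float = 40.0,
                     percentile: float = 10.0) -> np.ndarray:
    """Correct slow baseline drift with a running low-percentile filter.

    The running ``percentile`` of the trace over a ``window_s`` window
    estimates the stimulus-free baseline (gray epochs dominate the lower
    tail) and is subtracted, leaving gray-screen activity near zero.  On
    a drift-free noiseless trace the estimate is identically the
    baseline, making the correction a no-op.
    """
    trace = np.asarray(trace, dtype=float)
    if np.all(np.isnan(trace)):
        raise ValueError("all-NaN trace")
    size = max(3, int(round(window_s * frame_rate)))
    baseline = percentile_filter(trace, percentile, size=size,
                                 mode="reflect")
    return trace - baseline


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[0], mask.astype(int), [0]])
    edges = np.flatnonzero(np.diff(padded))
    return int(np.max(edges[1::2] - edges[::2]))


def is_responsive(epochs: EpochMatrix) -> tuple[bool, bool]:
    """Apply the 3-SD / >1-s responsiveness criterion.

    Returns ``(responsive, offset_only)``.  ``offset_only`` is True when
    the criterion is met only within the 2-s post-offset window of some
    condition (the cell responds to stimulus offset, not the stimulus).
    """
    fs = epochs.frame_rate
    min_frames = int(np.floor(MIN_RESPONSE_DURATION_S * fs)) + 1
    n_offset = int(round(OFFSET_WINDOW_S * fs))
    med = np.median(epochs.windows, axis=1)  # (n_cond, n_win)
    baseline = med[:, :epochs.n_gray]
    sd = baseline.std(axis=1)
    if np.all(sd == 0):
        raise DegenerateBaselineError("zero-variance pre-stimulus baseline")
    mean = baseline.mean(axis=1)
    thresh = mean + RESPONSE_SD_FACTOR * sd
    stim_hit = offset_hit = False
    for c in range(med.shape[0]):
        if sd[c] == 0:
            continue
        above_stim = med[c, epochs.stim_slice] > thresh[c]
        above_off = med[c, epochs.post_slice][:n_offset] > thresh[c]
        if _longest_run(above_stim) >= min_frames:
            stim_hit = True
        if _longest_run(above_off) >= min_frames:
            offset_hit = True
    return stim_hit, (offset_hit and not stim_hit)


def _trial_courses(epochs: EpochMatrix) -> np.ndarray:
    """Concatenated stimulus + following-gray time course per trial."""
    seg = epochs.windows[:, :, epochs.n_gray:]  # (cond, trial, stim+gray)
    return np.transpose(seg, (1, 0, 2)).reshape(seg.shape[1], -1)


def _pairwise_r(courses: np.ndarray) -> np.ndarray:
    rs = []
    for i, j in combinations(range(courses.shape[0]), 2):
        a, b = courses[i], courses[j]
        if a.std() == 0 or b.std() == 0:
            rs.append(0.0)  # silent trials count as unreliable, not NaN
        else:
            rs.append(float(np.corrcoef(a, b)[0, 1]))
    return np.array(rs)


def reliability_index(epochs: EpochMatrix,
                      mode: str = "concatenate") -> float:
    """75th percentile of pairwise cross-trial Pearson correlations.

    ``mode="concatenate"`` (default) correlates whole concatenated
    trial time courses; ``mode="per-condition"`` computes the pairwise
    correlations within each condition's epoch and pools them before
    taking the percentile.
    """
    if epochs.windows.shape[1] < 2:
        raise ValueError("need at least 2 trials")
    if mode == "concatenate":
        rs = _pairwise_r(_trial_courses(epochs))
    elif mode == "per-condition":
        seg = epochs.windows[:, :, epochs.n_gray:]
        rs = np.concatenate([_pairwise_r(seg[c])
                             for c in range(seg.shape[0])])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.percentile(rs, 75))


def reliability_null(epochs: EpochMatrix, n_shuffles: int = 1000,
                     seed: int = 0) -> tuple[np.ndarray, dict]:
    """Null distribution of r under epoch-identity shuffling.

    Condition identity is permuted independently within each trial
    before recomputing the reliability index.  Returns the null values
    and their 97.5 / 99.75 percentiles.
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles")
    rng = np.random.default_rng(seed)
    n_cond, n_trials = epochs.windows.shape[:2]
    seg = epochs.windows[:, :, epochs.n_gray:]
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        courses = np.empty((n_trials, n_cond * seg.shape[2]))
        for t in range(n_trials):
            perm = rng.permutation(n_cond)
            courses[t] = seg[perm, t].ravel()
        null[s] = np.percentile(_pairwise_r(courses), 75)
    thresholds = {97.5: float(np.percentile(null, 97.5)),
                  99.75: float(np.percentile(null, 99.75))}
    return null, thresholds


def qc_filter(sim, dataset_id: int = 1, r_threshold: float = R_THRESHOLD,
              detrend: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run QC over a simulated (or loaded) dataset.

    Returns ``(table, summary)``: a per-neuron table with columns
    neuron_id, mouse_id, area, responsive, offset_only, r, selected, and
    per-area summary counts (all / responsive / reliable).  Selection
    requires responsive AND not offset-only AND r above threshold;
    neurons with a degenerate (zero-variance) baseline are skipped and
    marked unselected.
    """
    traces = sim.traces[dataset_id]
    schedule = sim.schedules[dataset_id]
    n_cond = len(sim.grid(dataset_id))
    rows = []
    for i, (_, neuron) in enumerate(sim.population.iterrows()):
        tr = traces[i]
        if detrend:
            tr = np.stack([preprocess_trace(t, sim.frame_rate) for t in tr])
        epochs = derandomize(tr, schedule, n_cond, sim.frame_rate)
        try:
            responsive, offset_only = is_responsive(epochs)
        except DegenerateBaselineError:
            rows.append((neuron["neuron_id"], neuron["mouse_id"],
                         neuron["area"], False, False, np.nan, False))
            continue
        r = reliability_index(epochs)
        selected = responsive and not offset_only and r > r_threshold
        rows.append((neuron["neuron_id"], neuron["mouse_id"],
                     neuron["area"], responsive, offset_only, r, selected))
    table = pd.DataFrame(rows, columns=["neuron_id", "mouse_id", "area",
                                        "responsive", "offset_only", "r",
                                        "selected"])
    summary = table.groupby("area").agg(
        n_all=("neuron_id", "size"),
        n_responsive=("responsive", "sum"),
        n_selected=("selected", "sum"),
    ).reset_index()
    return table, summary
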