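"""Retinotopic phase maps and smoothed cortical parameter maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhaseMap", "phase_map", "parameter_map"]


@dataclass
class PhaseMap:
    """Per-pixel phase of peak response to a cyclic retinotopy stimulus.

    Phase is in radians, 2 pi = one stimulus cycle; ``amplitude`` is
    the cycle-averaged peak-to-trough response, near zero for pixels
    without stimulus-locked modulation (their phase is unreliable).
    """

    phase: np.ndarray  # (ny, nx), [0, 2 pi)
    amplitude: np.ndarray  # (ny, nx)
    period_s: float

    def preferred_time(self) -> np.ndarray:
        """Preferred cycle time in seconds."""
        return self.phase / (2.0 * np.pi) * self.period_s


def phase_map(movie: np.ndarray, period_s: float, frame_rate: float,
              method: str = "argmax") -> PhaseMap:
    """Compute the retinotopic phase map of a widefield movie.

    The movie is averaged across the repeated stimulus cycles; each
    pixel's phase is the cycle time of its maximal response (``argmax``,
    the default) or the phase of the first Fourier harmonic of the
    cycle-averaged time course (``fourier``, more robust to noise).
    """
    movie = np.asarray(movie, dtype=float)
    n_per_cycle = int(round(period_s * frame_rate))
    n_frames = movie.shape[0]
    if n_frames % n_per_cycle:
        raise ValueError("movie length is not an integer number of cycles")
    cycles = movie.reshape(n_frames // n_per_cycle, n_per_cycle,
                           *movie.shape[1:])
    avg = cycles.mean(axis=0)  # (n_per_cycle, ny, nx)
    amplitude = avg.max(axis=0) - avg.min(axis=0)
    if method == "argmax":
        phase = np.argmax(avg, axis=0) / n_per_cycle * 2.0 * np.pi
    elif method == "fourier":
        harmonic = np.exp(-2j * np.pi * np.arange(n_per_cycle)
                          / n_per_cycle)
        phase = np.angle(np.tensordot(harmonic, avg, axes=(0, 0)))
        phase = -phase % (2.0 * np.pi)  # peak time, not cosine phase lead
    else:
        raise ValueError(f"unknown method {method!r}")
    return PhaseMap(phase=phase, amplitude=amplitude, period_s=period_s)


def parameter_map(positions_um: np.ndarray, values: np.ndarray,
                  smoothing_um: float = 400.0, grid_step_um: float = 100.0,
                  extent=None, min_weight: float = 1e-3):
    """Gaussian-smoothed cortical map of a per-neuron tuning parameter.

    Values are averaged on a regular grid with Gaussian weights of
    sigma ``smoothing_um`` around each neuron (a Nadaraya-Watson
    estimate, linear in the value vector); grid cells whose total
    weight falls below ``min_weight`` are masked as NaN.  Returns
    ``(x_grid, y_grid, map)``.
    """
    pos = np.asarray(positions_um, dtype=float)
    vals = np.asarray(values, dtype=float)
    if extent is None:
        pad = 2.0 * smoothing_um
        extent = (pos[:, 0].min() - pad, pos[:, 0].max() + pad,
                  pos[:, 1].min() - pad, pos[:, 1].max() + pad)
    x = np.arange(extent[0], extent[1] + grid_step_um, grid_step_um)
    y = np.arange(extent[2], extent[3] + grid_step_um, grid_step_um)
    gx, gy = np.meshgrid(x, y)
    if smoothing_um <= 0:
        # limit case: nearest-neuron value
        d2 = ((gx[..., None] - pos[:, 0]) ** 2
              + (gy[..., None] - pos[:, 1]) ** 2)
        return x, y, vals[np.argmin(d2, axis=-1)]
    d2 = ((gx[..., None] - pos[:, 0]) ** 2
          + (gy[..., None] - pos[:, 1]) ** 2)
    w = np.exp(-d2 / (2.0 * smoothing_um**2))
    wsum = w.sum(axis=-1)
    out = np.where(wsum > min_weight, (w * vals).sum(axis=-1)
                   / np.maximum(wsum, 1e-300), np.nan)
    return x, y, out
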