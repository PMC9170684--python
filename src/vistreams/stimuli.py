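"""Stimulus batteries and bandpass-filtered noise movie synthesis.

Three stimulus batteries are defined:

* dataset 1 — isotropic noise, 5 spatial frequencies x 6 temporal
  frequencies (30 conditions), infinite orientation bandwidth;
* dataset 2 — the same 30 SF x TF conditions with anisotropic noise of
  15 deg FWHM orientation bandwidth whose centre orientation rotates at
  45 deg/s;
* dataset 3 — 4 spatial frequencies x 4 orientation bandwidths
  (infinite, 60, 30, 15 deg FWHM) at a fixed 2 Hz temporal frequency.

Movies are synthesised by shaping white Gaussian noise to a 1/f
amplitude spectrum, applying a Gaussian bandpass (1 octave FWHM in
log2-SF and log2-TF) and, for anisotropic conditions, a per-frame
rotating orientation mask, then normalising to 50% RMS contrast around
a mean luminance of 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusCondition",
    "StimulusMovie",
    "NyquistWarning",
    "ROTATION_RATE_DEG_S",
    "EPOCH_DURATION_S",
    "GRAY_DURATION_S",
    "RMS_CONTRAST",
    "build_condition_grid",
    "orientation_trajectory",
    "bandpass_amplitude",
    "make_bandpass_filter",
    "synthesize_noise_movie",
    "normalize_contrast",
    "measure_fwhm",
    "build_schedule",
]

# stimulus battery constants
SF_CENTERS_SFTF = (0.02, 0.04, 0.08, 0.16, 0.32)  # cpd, datasets 1-2
TF_CENTERS_SFTF = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)  # Hz, datasets 1-2
SF_CENTERS_ELONG = (0.04, 0.08, 0.16, 0.32)  # cpd, dataset 3
ORI_BANDWIDTHS_ELONG = (np.inf, 60.0, 30.0, 15.0)  # deg FWHM, dataset 3
TF_CENTER_ELONG = 2.0  # Hz, dataset 3
ANISO_BANDWIDTH = 15.0  # deg FWHM, dataset 2

ROTATION_RATE_DEG_S = 45.0  # deg/s, centre-orientation rotation
EPOCH_DURATION_S = 4.0  # s of filtered noise per stimulus epoch
GRAY_DURATION_S = 4.0  # s of gray screen between epochs
RMS_CONTRAST = 0.5  # target RMS contrast relative to mean luminance

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class NyquistWarning(UserWarning):
    """A centre frequency's 1-octave upper band exceeds the Nyquist limit."""


@dataclass(frozen=True)
class StimulusCondition:
    """One cell of a stimulus battery.

    ``ori_bandwidth`` is the FWHM of the orientation band in degrees;
    ``numpy.inf`` denotes an isotropic (non-oriented) texture.
    """

    dataset_id: int
    sf_center: float  # cpd
    tf_center: float  # Hz
    ori_bandwidth: float = np.inf  # deg FWHM
    sf_bandwidth: float = 1.0  # octaves FWHM
    tf_bandwidth: float = 1.0  # octaves FWHM

    @property
    def is_anisotropic(self) -> bool:
        return np.isfinite(self.ori_bandwidth)


@dataclass
class StimulusMovie:
    """A synthesised noise movie in normalised luminance units (mean 1)."""

    frames: np.ndarray  # (n_frames, ny, nx)
    frame_rate: float  # Hz
    pixel_pitch: tuple[float, float]  # (deg/px along y, deg/px along x)
    condition: StimulusCondition | None = None
    seed: int | None = None

    @property
    def rms_contrast(self) -> float:
        """Pixel SD over mean luminance, pooled over all frames."""
        return float(self.frames.std() / self.frames.mean())


def build_condition_grid(dataset_id: int) -> list[StimulusCondition]:
    """Enumerate the full stimulus battery for one dataset.

    Conditions are returned in canonical order: spatial frequency is the
    major (slow) axis; temporal frequency (datasets 1-2) or orientation
    bandwidth (dataset 3) is the minor axis.
    """
    if dataset_id in (1, 2):
        bw = np.inf if dataset_id == 1 else ANISO_BANDWIDTH
        return [
            StimulusCondition(dataset_id, sf, tf, bw)
            for sf in SF_CENTERS_SFTF
            for tf in TF_CENTERS_SFTF
        ]
    if dataset_id == 3:
        return [
            StimulusCondition(3, sf, TF_CENTER_ELONG, bw)
            for sf in SF_CENTERS_ELONG
            for bw in ORI_BANDWIDTHS_ELONG
        ]
    raise ValueError(f"unknown dataset_id: {dataset_id!r}")


def orientation_trajectory(t):
    """Centre orientation (deg) of the rotating anisotropic band at time ``t``.

    The orientation rotates clockwise at 45 deg/s and is 180-periodic,
    so one 4-s epoch sweeps [0, 180) exactly once.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return (ROTATION_RATE_DEG_S * t) % 180.0


def _log_gaussian(f, f0, fwhm_oct):
    """Gaussian amplitude in log2-frequency, peak 1 at f0, FWHM in octaves."""
    f = np.asarray(f, dtype=float)
    sigma = fwhm_oct * _FWHM_TO_SIGMA
    out = np.zeros_like(f)
    pos = f > 0
    with np.errstate(divide="ignore"):
        out[pos] = np.exp(-((np.log2(f[pos] / f0)) ** 2) / (2.0 * sigma**2))
    return out


def _ori_gaussian(angle_deg, center_deg, fwhm_deg):
    """Gaussian amplitude over 180-periodic orientation angle, peak 1."""
    sigma = fwhm_deg * _FWHM_TO_SIGMA
    d = (np.asarray(angle_deg, dtype=float) - center_deg + 90.0) % 180.0 - 90.0
    return np.exp(-(d**2) / (2.0 * sigma**2))


def bandpass_amplitude(condition: StimulusCondition, sf, tf, ori_deg=None,
                       ori_center: float = 0.0):
    """Analytic filter amplitude at (sf, tf[, orientation]).

    This is the continuous profile that :func:`make_bandpass_filter`
    samples onto the discrete FFT grid; evaluating it on dense axes is
    how bandwidths are validated for conditions whose band exceeds the
    Nyquist limit of a given rendering resolution.
    """
    amp = _log_gaussian(sf, condition.sf_center, condition.sf_bandwidth) * \
        _log_gaussian(tf, condition.tf_center, condition.tf_bandwidth)
    if ori_deg is not None and condition.is_anisotropic:
        amp = amp * _ori_gaussian(ori_deg, ori_center, condition.ori_bandwidth)
    return amp


def _evenize(mask: np.ndarray) -> np.ndarray:
    """Force M(-f) = M(f) on the FFT grid (exact conjugate symmetry).

    The orientation mask is even in frequency analytically, but at the
    Nyquist bins (their own negatives) the sampled angle picks one sign
    arbitrarily; averaging with the negated-frequency view restores
    evenness so filtered movies are exactly real.
    """
    neg = np.ix_(*[(-np.arange(n)) % n for n in mask.shape])
    return 0.5 * (mask + mask[neg])


def _check_nyquist(condition, nyq_sf, nyq_tf):
    if condition.sf_center * 2.0 ** (condition.sf_bandwidth / 2.0) > nyq_sf:
        warnings.warn(
            f"SF band of {condition.sf_center} cpd exceeds Nyquist "
            f"{nyq_sf:.3f} cpd; validate spectra on the analytic mask",
            NyquistWarning,
            stacklevel=3,
        )
    if condition.tf_center * 2.0 ** (condition.tf_bandwidth / 2.0) > nyq_tf:
        warnings.warn(
            f"TF band of {condition.tf_center} Hz exceeds Nyquist "
            f"{nyq_tf:.3f} Hz; validate spectra on the analytic mask",
            NyquistWarning,
            stacklevel=3,
        )


def make_bandpass_filter(
    condition: StimulusCondition,
    shape: tuple[int, int] = (64, 64),
    n_frames: int = 120,
    frame_rate: float = 30.0,
    fov_deg: tuple[float, float] = (80.0, 100.0),
    ori_center: float | None = None,
) -> np.ndarray:
    """Spectral amplitude mask on the FFT grid of a movie.

    Returns an array of shape ``(n_frames, ny, nx)`` indexed by FFT
    frequencies (``numpy.fft.fftfreq`` layout).  The mask is an even
    function of frequency, hence conjugate-symmetric as the spectrum of
    a real movie.  If ``ori_center`` is None the orientation mask is
    omitted (use per-frame masks for the rotating stimulus).
    """
    ny, nx = shape
    pitch_y = fov_deg[0] / ny
    pitch_x = fov_deg[1] / nx
    _check_nyquist(condition, 0.5 / max(pitch_x, pitch_y), frame_rate / 2.0)

    fy = np.fft.fftfreq(ny, d=pitch_y)[:, None]
    fx = np.fft.fftfreq(nx, d=pitch_x)[None, :]
    ft = np.fft.fftfreq(n_frames, d=1.0 / frame_rate)
    sf_r = np.hypot(fy, fx)

    sf_mask = _log_gaussian(sf_r, condition.sf_center, condition.sf_bandwidth)
    tf_mask = _log_gaussian(np.abs(ft), condition.tf_center,
                            condition.tf_bandwidth)
    mask = tf_mask[:, None, None] * sf_mask[None, :, :]
    if ori_center is not None and condition.is_anisotropic:
        # a band oriented at theta has spectral energy at theta + 90 deg
        spec_angle = np.degrees(np.arctan2(fy, fx)) % 180.0
        mask = mask * _evenize(_ori_gaussian(
            spec_angle, ori_center + 90.0,
            condition.ori_bandwidth))[None, :, :]
    return mask


def _one_over_f(shape, pitch, frame_rate):
    """1/f amplitude envelope over the joint spatiotemporal frequency."""
    nt, ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pitch[0])[None, :, None]
    fx = np.fft.fftfreq(nx, d=pitch[1])[None, None, :]
    ft = np.fft.fftfreq(nt, d=1.0 / frame_rate)[:, None, None]
    f = np.sqrt(fy**2 + fx**2 + (ft / frame_rate * max(1.0 / pitch[0], 1.0 / pitch[1])) ** 2)
    f[0, 0, 0] = np.inf  # kill DC; mean luminance is added back later
    fmin = np.min(f[f > 0])
    return 1.0 / np.maximum(f, fmin)


def normalize_contrast(frames: np.ndarray, rms: float = RMS_CONTRAST,
                       mean_luminance: float = 1.0) -> np.ndarray:
    """Rescale a movie to the target RMS contrast around ``mean_luminance``.

    Idempotent: renormalising an already-normalised movie is a no-op up
    to floating-point rounding.
    """
    frames = np.asarray(frames, dtype=float)
    centered = frames - frames.mean()
    sd = centered.std()
    if sd == 0:
        raise ValueError("cannot normalise a constant movie")
    return mean_luminance + centered * (rms * mean_luminance / sd)


def synthesize_noise_movie(
    condition: StimulusCondition,
    seed: int,
    shape: tuple[int, int] = (64, 64),
    frame_rate: float = 30.0,
    duration_s: float = EPOCH_DURATION_S,
    fov_deg: tuple[float, float] = (80.0, 100.0),
) -> StimulusMovie:
    """Synthesise one bandpass-filtered noise epoch.

    White Gaussian noise is shaped to a 1/f amplitude spectrum, band-
    passed around the condition's centre SF and TF, and — for
    anisotropic conditions — filtered per frame by an orientation mask
    whose centre follows :func:`orientation_trajectory`.  The result is
    normalised to 50% RMS contrast with mean luminance 1.
    """
    ny, nx = shape
    n_frames = int(round(duration_s * frame_rate))
    pitch = (fov_deg[0] / ny, fov_deg[1] / nx)

    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_frames, ny, nx))
    spectrum = np.fft.fftn(white)
    spectrum *= _one_over_f((n_frames, ny, nx), pitch, frame_rate)
    spectrum *= make_bandpass_filter(condition, shape, n_frames, frame_rate,
                                     fov_deg)
    frames = np.fft.ifftn(spectrum).real

    if condition.is_anisotropic:
        fy = np.fft.fftfreq(ny, d=pitch[0])[:, None]
        fx = np.fft.fftfreq(nx, d=pitch[1])[None, :]
        spec_angle = np.degrees(np.arctan2(fy, fx)) % 180.0
        t = np.arange(n_frames) / frame_rate
        centers = orientation_trajectory(t)
        for i, theta in enumerate(centers):
            ori_mask = _evenize(_ori_gaussian(spec_angle, theta + 90.0,
                                              condition.ori_bandwidth))
            frames[i] = np.fft.ifft2(np.fft.fft2(frames[i]) * ori_mask).real

    frames = normalize_contrast(frames)
    return StimulusMovie(frames=frames, frame_rate=frame_rate,
                         pixel_pitch=pitch, condition=condition, seed=seed)


def measure_fwhm(x: np.ndarray, amp: np.ndarray) -> float:
    """Full width at half maximum of a sampled single-peaked profile.

    Half-maximum crossings are located by linear interpolation between
    samples; ``x`` must be monotonically increasing.
    """
    x = np.asarray(x, dtype=float)
    amp = np.asarray(amp, dtype=float)
    half = amp.max() / 2.0
    above = amp >= half
    if not above.any():
        raise ValueError("profile has no half-maximum region")
    idx = np.flatnonzero(above)
    lo, hi = idx[0], idx[-1]

    def _cross(i, j):
        if i < 0 or j >= len(x):
            raise ValueError("half-maximum crossing outside sampled range")
        return x[i] + (half - amp[i]) * (x[j] - x[i]) / (amp[j] - amp[i])

    left = x[0] if lo == 0 else _cross(lo - 1, lo)
    right = x[-1] if hi == len(x) - 1 else _cross(hi, hi + 1)
    return float(right - left)


def build_schedule(
    grid: list[StimulusCondition],
    n_trials: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomised presentation schedule for one stimulus battery.

    Each trial presents every condition exactly once in an independent
    random order; each (trial, epoch) pair carries its own noise seed so
    that phases differ across trials while the frequency content is
    condition-determined.

    Returns a DataFrame with columns ``trial``, ``epoch_index``,
    ``condition_id``, ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = len(grid)
    rows = []
    for trial in range(1, n_trials + 1):
        order = rng.permutation(n)
        seeds = rng.integers(0, 2**31, size=n)
        for epoch, (cid, s) in enumerate(zip(order, seeds)):
            rows.append((trial, epoch, int(cid), int(s)))
    return pd.DataFrame(rows,
                        columns=["trial", "epoch_index", "condition_id",
                                 "seed"])
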