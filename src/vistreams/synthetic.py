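"""Hierarchical synthetic populations and simulated calcium responses.

Ground-truth neurons are organised as mice -> visual areas -> cells.
Each neuron carries the parameters of the spatiotemporal tuning model
(peak amplitude A, peak SF/TF, tuning widths, speed-tuning index xi),
an orientation preference and tuning width, a cell type with an
elongation-gain profile over orientation bandwidths, and a noise model.
Area-level parameter distributions are configurable; per-mouse offsets
(shared by all cells of a mouse) generate the nested variability the
hierarchical-bootstrap statistics are designed for.

Simulated dF/F traces mirror the recording layout: each condition of a
battery is presented once per trial in randomised order as a 4-s
stimulus epoch preceded by 4 s of gray, for four trials.  The
underlying response rate is convolved with a double-exponential
GCaMP6s-like kernel, then corrupted with per-epoch multiplicative gain
noise and per-frame additive Gaussian noise.

The generator emulates the statistical structure of the recordings
(tuning diversity, hierarchy, calcium dynamics, trial noise), not raw
fluorescence movies: traces are emitted directly as dF/F.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from . import stimuli
from .stimuli import (
    EPOCH_DURATION_S,
    GRAY_DURATION_S,
    StimulusCondition,
    build_condition_grid,
    build_schedule,
    orientation_trajectory,
)
from .tuning import spatiotemporal_response

__all__ = [
    "CalciumKernel",
    "AreaParams",
    "PopulationConfig",
    "SimulatedDataset",
    "WidefieldSimulation",
    "AREAS",
    "DEFAULT_AREA_PARAMS",
    "orientation_gain",
    "sample_population",
    "expected_response",
    "expected_amplitudes",
    "simulate_trial_traces",
    "simulate_osi_pair",
    "simulate_widefield_movie",
    "smoke_config",
]

AREAS = ("V1", "LM", "AL", "RL", "AM", "PM", "LI", "POR")
CELL_TYPES = ("non-OS", "sharp-OS", "broad-OS")
DEFAULT_FRAME_RATE = 10.0  # Hz, typical multi-plane 2p acquisition

# nominal area centres on the cortical surface (um), for parameter maps
AREA_CENTERS_UM = {
    "V1": (0.0, 0.0), "LM": (1200.0, -600.0), "AL": (1500.0, 300.0),
    "RL": (1100.0, 900.0), "AM": (300.0, 1300.0), "PM": (-500.0, 1000.0),
    "LI": (1800.0, -300.0), "POR": (1700.0, -1100.0),
}


@dataclass(frozen=True)
class CalciumKernel:
    """Double-exponential calcium-indicator impulse response.

    Defaults follow typical GCaMP6s transients: 200 ms rise, 560 ms
    decay.  ``sample`` returns a discrete kernel normalised to unit sum
    so that convolution preserves the mean of a sustained response.
    """

    rise_ms: float = 200.0
    decay_ms: float = 560.0
    amplitude: float = 1.0

    def __post_init__(self):
        if not 0 < self.rise_ms < self.decay_ms:
            raise ValueError("require 0 < rise < decay")

    def sample(self, frame_rate: float, duration_s: float = 5.0,
               normalize: str = "sum") -> np.ndarray:
        t = np.arange(int(round(duration_s * frame_rate))) / frame_rate
        k = np.exp(-t / (self.decay_ms / 1000.0)) \
            - np.exp(-t / (self.rise_ms / 1000.0))
        if normalize == "sum":
            k = k / k.sum()
        elif normalize == "peak":
            k = k / k.max()
        return self.amplitude * k


def orientation_gain(theta_deg, theta_pref_deg: float, fwhm_deg: float):
    """Peak-normalised Gaussian orientation tuning curve, 180-periodic.

    A wrapped Gaussian parameterised by its FWHM: value 1 at the
    preferred orientation, 1/2 at +-FWHM/2.  Wrapping (rather than a
    von Mises approximation) keeps very broad curves genuinely flat, so
    a 170-deg-FWHM cell is essentially untuned.
    """
    sigma = fwhm_deg / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    d = (np.asarray(theta_deg, dtype=float) - theta_pref_deg + 90.0) \
        % 180.0 - 90.0
    wraps = range(-2, 3)  # +-2 wraps cover sigma up to ~72 deg
    out = sum(np.exp(-((d + 180.0 * k) ** 2) / (2.0 * sigma**2))
              for k in wraps)
    peak = sum(np.exp(-((180.0 * k) ** 2) / (2.0 * sigma**2))
               for k in wraps)
    return out / peak


@dataclass(frozen=True)
class AreaParams:
    """Ground-truth parameter distributions for one visual area.

    Centre frequencies are parameterised in log2 units (log2 cpd and
    log2 Hz); draws are Gaussian in that space.
    """

    sf0_log2_mean: float
    tf0_log2_mean: float
    xi_mean: float
    sf0_log2_sd: float = 1.0
    tf0_log2_sd: float = 1.0
    xi_sd: float = 0.3
    cell_type_mix: tuple[float, float, float] = (0.45, 0.25, 0.30)
    responsive_frac: float = 0.85


# qualitative area biases: V1 slow/coarse, anterior (AL/RL/AM) fast and
# speed-tuned, posterior-ventral (PM/LI/POR) slow and fine
DEFAULT_AREA_PARAMS: dict[str, AreaParams] = {
    "V1": AreaParams(np.log2(0.04), np.log2(1.0), 0.10,
                     cell_type_mix=(0.40, 0.30, 0.30)),
    "LM": AreaParams(np.log2(0.08), np.log2(2.0), 0.30,
                     cell_type_mix=(0.35, 0.35, 0.30)),
    "AL": AreaParams(np.log2(0.04), np.log2(8.0), 0.60,
                     cell_type_mix=(0.55, 0.15, 0.30)),
    "RL": AreaParams(np.log2(0.04), np.log2(8.0), 0.55,
                     cell_type_mix=(0.55, 0.15, 0.30)),
    "AM": AreaParams(np.log2(0.06), np.log2(6.0), 0.50,
                     cell_type_mix=(0.50, 0.20, 0.30)),
    "PM": AreaParams(np.log2(0.16), np.log2(1.0), 0.20,
                     cell_type_mix=(0.30, 0.40, 0.30)),
    "LI": AreaParams(np.log2(0.16), np.log2(1.0), 0.25,
                     cell_type_mix=(0.30, 0.40, 0.30)),
    "POR": AreaParams(np.log2(0.12), np.log2(0.8), 0.20,
                      cell_type_mix=(0.30, 0.40, 0.30)),
}

# epoch-mean elongation gains over orientation bandwidths (inf, 60, 30, 15)
_ELONGATION_BASE = {
    "non-OS": np.array([1.00, 0.75, 0.50, 0.30]),
    "sharp-OS": np.array([0.25, 0.50, 0.75, 1.00]),
    "broad-OS": np.array([0.85, 0.90, 0.88, 0.85]),
}
_ORI_FWHM = {  # (mean, sd, lo, hi) of orientation-tuning FWHM per type
    "non-OS": (150.0, 10.0, 120.0, 170.0),
    "sharp-OS": (35.0, 8.0, 15.0, 60.0),
    "broad-OS": (85.0, 15.0, 50.0, 120.0),
}


@dataclass(frozen=True)
class PopulationConfig:
    """Scale, area composition and noise of a synthetic population."""

    n_mice: int = 10
    n_per_area_mouse: int = 150
    areas: dict = field(default_factory=lambda: dict(DEFAULT_AREA_PARAMS))
    mouse_sd_log2sf: float = 0.30  # per-mouse offset SD, octaves
    mouse_sd_log2tf: float = 0.30
    mouse_sd_xi: float = 0.10
    amp_median: float = 0.5  # dF/F, log-normal amplitude distribution
    amp_sigma_ln: float = 0.4
    sigma_freq_mean: float = 1.5  # octaves, SF/TF tuning widths
    sigma_freq_sd: float = 0.4
    noise_sigma: float = 0.05  # additive dF/F noise SD per frame
    gain_cv: float = 0.15  # multiplicative per-epoch gain CV
    position_scatter_um: float = 300.0

    def __post_init__(self):
        for name, p in self.areas.items():
            mix = np.asarray(p.cell_type_mix, dtype=float)
            if np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
                raise ValueError(f"cell-type mixture of {name} must be a "
                                 "probability vector")
            if min(p.sf0_log2_sd, p.tf0_log2_sd, p.xi_sd) < 0:
                raise ValueError(f"negative SD in area {name}")


def smoke_config(n_mice: int = 2, n_per_area_mouse: int = 20,
                 areas: tuple[str, ...] = ("V1", "AL"),
                 **kw) -> PopulationConfig:
    """A small configuration for quick end-to-end runs."""
    return PopulationConfig(
        n_mice=n_mice, n_per_area_mouse=n_per_area_mouse,
        areas={a: DEFAULT_AREA_PARAMS[a] for a in areas}, **kw)


def sample_population(config: PopulationConfig | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Draw a ground-truth neuron table.

    One row per neuron with tuning parameters, cell type, elongation
    gains (columns e_inf, e_60, e_30, e_15), orientation preference,
    cortical position and noise parameters.  Per-mouse offsets on
    log2 sf0, log2 tf0 and xi are shared across all neurons of a mouse.
    """
    cfg = config or PopulationConfig()
    rng = np.random.default_rng(seed)
    rows = []
    nid = 0
    for m in range(cfg.n_mice):
        mouse = f"mouse{m:02d}"
        off_sf = rng.normal(0.0, cfg.mouse_sd_log2sf)
        off_tf = rng.normal(0.0, cfg.mouse_sd_log2tf)
        off_xi = rng.normal(0.0, cfg.mouse_sd_xi)
        for area, p in cfg.areas.items():
            n = cfg.n_per_area_mouse
            lsf0 = rng.normal(p.sf0_log2_mean + off_sf, p.sf0_log2_sd, n)
            ltf0 = rng.normal(p.tf0_log2_mean + off_tf, p.tf0_log2_sd, n)
            xi = rng.normal(p.xi_mean + off_xi, p.xi_sd, n)
            A = np.clip(cfg.amp_median
                        * np.exp(rng.normal(0.0, cfg.amp_sigma_ln, n)),
                        0.05, 3.0)
            ssf = np.clip(rng.normal(cfg.sigma_freq_mean,
                                     cfg.sigma_freq_sd, n), 0.6, 3.5)
            stf = np.clip(rng.normal(cfg.sigma_freq_mean,
                                     cfg.sigma_freq_sd, n), 0.6, 3.5)
            ctype = rng.choice(CELL_TYPES, size=n, p=p.cell_type_mix)
            theta_pref = rng.uniform(0.0, 180.0, n)
            cx, cy = AREA_CENTERS_UM.get(area, (0.0, 0.0))
            x = rng.normal(cx, cfg.position_scatter_um, n)
            y = rng.normal(cy, cfg.position_scatter_um, n)
            responsive = rng.random(n) < p.responsive_frac
            for i in range(n):
                mu, sd, lo, hi = _ORI_FWHM[ctype[i]]
                fwhm = float(np.clip(rng.normal(mu, sd), lo, hi))
                e = _ELONGATION_BASE[ctype[i]] \
                    * np.exp(rng.normal(0.0, 0.03, 4))
                if ctype[i] == "non-OS":
                    e = np.sort(e)[::-1]
                elif ctype[i] == "sharp-OS":
                    e = np.sort(e)
                rows.append({
                    "neuron_id": nid, "mouse_id": mouse, "area": area,
                    "x_um": x[i], "y_um": y[i],
                    "A": A[i], "sf0": 2.0 ** lsf0[i], "tf0": 2.0 ** ltf0[i],
                    "sigma_sf": ssf[i], "sigma_tf": stf[i], "xi": xi[i],
                    "theta_pref": theta_pref[i], "ori_fwhm": fwhm,
                    "cell_type": ctype[i],
                    "e_inf": e[0], "e_60": e[1], "e_30": e[2], "e_15": e[3],
                    "noise_sigma": cfg.noise_sigma, "gain_cv": cfg.gain_cv,
                    "responsive": bool(responsive[i]),
                })
                nid += 1
    return pd.DataFrame(rows)


_E_COLUMN = {np.inf: "e_inf", 60.0: "e_60", 30.0: "e_30", 15.0: "e_15"}


def _elongation_gain(neuron, ori_bandwidth: float) -> float:
    return float(neuron[_E_COLUMN[ori_bandwidth]])


def expected_response(neuron, condition: StimulusCondition) -> float:
    """Noise-free epoch-mean dF/F of a neuron to one condition.

    The spatiotemporal model response is scaled by the neuron's
    elongation gain at the condition's orientation bandwidth.  The
    elongation gains are defined as epoch means: for rotating
    anisotropic stimuli the within-epoch orientation modulation is
    normalised to mean 1 over the sweep, so the epoch-mean amplitude
    does not depend on the preferred orientation.
    """
    base = spatiotemporal_response(
        condition.sf_center, condition.tf_center,
        neuron["A"], neuron["sf0"], neuron["tf0"],
        neuron["sigma_sf"], neuron["sigma_tf"], neuron["xi"])
    return float(base) * _elongation_gain(neuron, condition.ori_bandwidth)


def expected_amplitudes(population: pd.DataFrame,
                        grid: list[StimulusCondition]) -> np.ndarray:
    """Vectorised :func:`expected_response`: (n_neurons, n_conditions)."""
    sf = np.array([c.sf_center for c in grid])
    tf = np.array([c.tf_center for c in grid])
    base = spatiotemporal_response(
        sf[None, :], tf[None, :],
        population["A"].to_numpy()[:, None],
        population["sf0"].to_numpy()[:, None],
        population["tf0"].to_numpy()[:, None],
        population["sigma_sf"].to_numpy()[:, None],
        population["sigma_tf"].to_numpy()[:, None],
        population["xi"].to_numpy()[:, None])
    gains = np.stack([population[_E_COLUMN[c.ori_bandwidth]].to_numpy()
                      for c in grid], axis=1)
    return base * gains


@dataclass
class SimulatedDataset:
    """A synthetic recording: population table, schedules and traces.

    ``traces[dataset_id]`` has shape (n_neurons, n_trials, n_frames);
    each trial is a sequence of 8-s blocks, 4 s gray then 4 s stimulus,
    one block per condition in the schedule's randomised order.
    """

    population: pd.DataFrame
    schedules: dict
    traces: dict
    frame_rate: float
    kernel: CalciumKernel

    def grid(self, dataset_id: int) -> list[StimulusCondition]:
        return build_condition_grid(dataset_id)


def simulate_trial_traces(
    population: pd.DataFrame,
    schedules: dict | None = None,
    datasets: tuple[int, ...] = (1, 2, 3),
    frame_rate: float = DEFAULT_FRAME_RATE,
    kernel: CalciumKernel | None = None,
    noise_sigma: float | None = None,
    gain_cv: float | None = None,
    drift_amp: float = 0.0,
    n_trials: int = 4,
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate dF/F trial traces for a population over stimulus batteries.

    Per epoch the underlying rate equals the neuron's expected response
    (modulated within anisotropic epochs by its orientation tuning along
    the 45 deg/s sweep, normalised to epoch mean 1), scaled by a
    log-normal per-epoch gain, convolved with the calcium kernel, with
    additive Gaussian noise and an optional linear drift added.
    ``noise_sigma``/``gain_cv`` override the per-neuron table values.
    """
    kernel = kernel or CalciumKernel()
    rng = np.random.default_rng(seed)
    k = kernel.sample(frame_rate)
    n_neurons = len(population)
    n_gray = int(round(GRAY_DURATION_S * frame_rate))
    n_stim = int(round(EPOCH_DURATION_S * frame_rate))
    block = n_gray + n_stim

    sig = (np.full(n_neurons, noise_sigma) if noise_sigma is not None
           else population["noise_sigma"].to_numpy())
    cv = (np.full(n_neurons, gain_cv) if gain_cv is not None
          else population["gain_cv"].to_numpy())
    responsive = population["responsive"].to_numpy()

    # within-epoch orientation modulation (epoch mean 1) per neuron
    t_stim = np.arange(n_stim) / frame_rate
    theta_t = orientation_trajectory(t_stim)
    mod = np.empty((n_neurons, n_stim))
    for i, (tp, fw) in enumerate(zip(population["theta_pref"],
                                     population["ori_fwhm"])):
        v = orientation_gain(theta_t, tp, fw)
        mod[i] = v / v.mean()

    schedules = schedules or {}
    out_sched = {}
    traces = {}
    for ds in datasets:
        grid = build_condition_grid(ds)
        sched = schedules.get(ds)
        if sched is None:
            sched = build_schedule(grid, n_trials=n_trials,
                                   seed=int(rng.integers(0, 2**31)))
        out_sched[ds] = sched
        amps = expected_amplitudes(population, grid)
        amps = np.where(responsive[:, None], amps, 0.0)
        n_epochs = len(grid)
        n_frames = n_epochs * block
        ds_traces = np.empty((n_neurons, n_trials, n_frames))
        aniso = np.array([c.is_anisotropic for c in grid])
        for trial in range(1, n_trials + 1):
            tr = sched[sched["trial"] == trial].sort_values("epoch_index")
            rate = np.zeros((n_neurons, n_frames))
            ln_sd = np.sqrt(np.log1p(cv**2))
            gains = np.exp(rng.normal(0.0, 1.0, (n_neurons, n_epochs))
                           * ln_sd[:, None] - 0.5 * ln_sd[:, None] ** 2)
            for e, cid in enumerate(tr["condition_id"].to_numpy()):
                sl = slice(e * block + n_gray, (e + 1) * block)
                a = amps[:, cid] * gains[:, e]
                if aniso[cid]:
                    rate[:, sl] = a[:, None] * mod
                else:
                    rate[:, sl] = a[:, None]
            clean = fftconvolve(rate, k[None, :], axes=1)[:, :n_frames]
            noise = rng.standard_normal((n_neurons, n_frames)) * sig[:, None]
            trace = clean + noise
            if drift_amp:
                trace += drift_amp * np.linspace(0.0, 1.0, n_frames)[None, :]
            ds_traces[:, trial - 1] = trace
        traces[ds] = ds_traces
    return SimulatedDataset(population=population, schedules=out_sched,
                            traces=traces, frame_rate=frame_rate,
                            kernel=kernel)


def simulate_osi_pair(
    fwhm_deg: float,
    theta_pref: float,
    rate_scale: float,
    kernel: CalciumKernel | None = None,
    seed: int = 0,
    dt: float = 0.01,
    stim_duration_s: float = EPOCH_DURATION_S,
    tail_s: float = GRAY_DURATION_S,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Poisson spikes and calcium of a model cell under the rotating sweep.

    The firing rate is ``rate_scale`` (spikes/s at the preferred
    orientation) times the peak-normalised orientation tuning curve
    evaluated along the 45 deg/s trajectory, zero during the post-
    stimulus tail (zero spontaneous rate).  Returns (spike counts per
    bin, calcium trace, dt).
    """
    if rate_scale <= 0:
        raise ValueError("rate_scale must be positive")
    if not 10.0 <= fwhm_deg <= 170.0:
        raise ValueError("tuning FWHM must lie in [10, 170] deg")
    kernel = kernel or CalciumKernel()
    rng = np.random.default_rng(seed)
    n_stim = int(round(stim_duration_s / dt))
    n_tail = int(round(tail_s / dt))
    t = np.arange(n_stim) * dt
    rate = rate_scale * orientation_gain(orientation_trajectory(t),
                                         theta_pref, fwhm_deg)
    rate = np.concatenate([rate, np.zeros(n_tail)])
    spikes = rng.poisson(rate * dt).astype(float)
    k = kernel.sample(1.0 / dt, normalize="peak")
    calcium = fftconvolve(spikes, k)[:spikes.size]
    return spikes, calcium, dt


@dataclass
class WidefieldSimulation:
    """Synthetic widefield retinotopy movie plus its ground truth."""

    movie: np.ndarray  # (n_frames, ny, nx)
    truth_time_s: np.ndarray  # (ny, nx) preferred cycle time
    period_s: float
    frame_rate: float
    n_cycles: int


def simulate_widefield_movie(
    shape: tuple[int, int] = (32, 32),
    period_s: float = 20.0,
    n_cycles: int = 20,
    frame_rate: float = 5.0,
    bump_sigma_s: float = 1.0,
    noise_sigma: float = 0.2,
    kernel: CalciumKernel | None = None,
    seed: int = 0,
) -> WidefieldSimulation:
    """Simulate a retinotopic-mapping movie with a phase reversal.

    Each pixel responds with a circular-Gaussian bump centred at its
    preferred cycle time; the preferred-time map is smooth and folds
    back along x (a phase reversal, as at an area border), convolved
    with the calcium kernel and corrupted with Gaussian noise.
    """
    ny, nx = shape
    kernel = kernel or CalciumKernel()
    rng = np.random.default_rng(seed)
    u = np.linspace(0.0, 1.0, nx)[None, :].repeat(ny, axis=0)
    tri = np.where(u < 0.5, 2.0 * u, 2.0 * (1.0 - u))
    v = np.linspace(0.0, 1.0, ny)[:, None].repeat(nx, axis=1)
    truth = period_s * ((0.75 * tri + 0.15 * v) % 1.0)

    n_per_cycle = int(round(period_s * frame_rate))
    t_cycle = np.arange(n_per_cycle) / frame_rate
    d = (t_cycle[:, None, None] - truth[None, :, :]
         + period_s / 2.0) % period_s - period_s / 2.0
    cycle = np.exp(-(d**2) / (2.0 * bump_sigma_s**2))
    movie = np.tile(cycle, (n_cycles, 1, 1))
    k = kernel.sample(frame_rate)
    movie = fftconvolve(movie, k[:, None, None], axes=0)[:movie.shape[0]]
    movie += rng.standard_normal(movie.shape) * noise_sigma
    return WidefieldSimulation(movie=movie, truth_time_s=truth,
                               period_s=period_s, frame_rate=frame_rate,
                               n_cycles=n_cycles)
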