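"""Synthetic cohort generator with planted natural-frequency structure.

Real inputs to the pipeline are source-reconstructed resting-state
recordings (voxel x time per participant and session).  This module
emulates their statistical structure so every downstream stage can be
exercised and scored without any recording:

* a *base field* of natural frequencies that increases along two grid
  axes, mimicking the medial-to-lateral and posterior-to-anterior
  gradients of cortical oscillation frequency;
* *subject deviations* — spatially smooth, subject-specific frequency
  offsets that are stable across sessions (the fingerprint);
* *session jitter* — small per-session frequency drift;
* bursty amplitude-modulated oscillations riding on a 1/f^chi aperiodic
  background at a configurable oscillation-to-background RMS ratio.

The generator is a stand-in: the underlying study is empirical and
specifies no generative model.  See docs/methods.md for what the
simulation does and does not emulate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

from .grid import VoxelGrid, make_voxel_grid

__all__ = [
    "CohortConfig",
    "SourceTimeSeries",
    "plant_frequency_fields",
    "simulate_session",
    "simulate_cohort",
]

logger = logging.getLogger(__name__)

#: analysis band used for clipping planted frequencies and for the
#: minimum-duration check; matches the default spectral axis.
DEFAULT_BAND = (1.7, 34.5)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a small resting-state-like cohort: a 6x6x6 grid at
    1 cm, 150 s sessions at 200 Hz, an 8-16 Hz planted gradient with
    0.5 Hz subject-specific deviations, 0.1 Hz session drift, and
    oscillations as strong as the 1/f background (snr = 1).
    """

    n_subjects: int = 12
    grid_shape: tuple[int, int, int] = (6, 6, 6)
    spacing_cm: float = 1.0
    duration_s: float = 150.0
    fs: float = 200.0
    base_freq_range: tuple[float, float] = (8.0, 16.0)
    subject_sd: float = 0.5
    session_jitter_sd: float = 0.1
    snr: float = 1.0
    aperiodic_exponent: float = 1.0
    burst_rate: float = 1.0
    elapsed_days_range: tuple[float, float] = (0.0, 1700.0)
    analysis_band: tuple[float, float] = DEFAULT_BAND
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        f_lo, f_hi = self.base_freq_range
        band_lo, band_hi = self.analysis_band
        if f_lo < band_lo or f_hi > band_hi:
            raise ValueError(
                f"base_freq_range {self.base_freq_range} must lie inside the "
                f"analysis band {self.analysis_band}"
            )
        if f_lo > f_hi:
            raise ValueError("base_freq_range must be (low, high)")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        if self.session_jitter_sd < 0:
            raise ValueError("session_jitter_sd must be >= 0")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.burst_rate <= 0:
            raise ValueError("burst_rate must be positive")

    def make_grid(self) -> VoxelGrid:
        return make_voxel_grid(self.grid_shape, self.spacing_cm)


@dataclass
class SourceTimeSeries:
    """One subject-session of source-level data: a (V, samples) matrix.

    ``segments`` lists artifact-free intervals in seconds; by default one
    segment spans the whole recording.  ``elapsed_days`` is the number of
    days since the subject's first session (0 for session 1).
    """

    subject_id: str
    session_id: int
    data: np.ndarray  # (V, n_samples)
    fs: float
    segments: list[tuple[float, float]] = field(default_factory=list)
    elapsed_days: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a (V, samples) matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite samples")
        dur = self.duration_s
        if not self.segments:
            self.segments = [(0.0, dur)]
        prev_end = 0.0
        for start, end in self.segments:
            if start < prev_end - 1e-12 or end > dur + 1e-9 or end <= start:
                raise ValueError(f"invalid segment ({start}, {end})")
            prev_end = end

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


def plant_frequency_fields(grid: VoxelGrid, config: CohortConfig) -> np.ndarray:
    """True natural-frequency maps, one length-V row per subject.

    The shared base field ramps linearly from ``base_freq_range[0]`` to
    ``base_freq_range[1]`` along the mean of the (normalised) x and y
    coordinates — two orthogonal increasing-frequency gradients.  Each
    subject adds a spatially smoothed Gaussian deviation field rescaled
    to standard deviation ``subject_sd`` (Gaussian kernel FWHM = 3 x grid
    spacing).  Maps are clipped to the analysis band.
    """
    if config.subject_sd < 0:
        raise ValueError("subject_sd must be >= 0")
    if grid.shape is None:
        raise ValueError("plant_frequency_fields requires a rectangular grid")
    f_lo, f_hi = config.base_freq_range
    coords = grid.coords
    base = np.zeros(grid.n_voxels) + f_lo
    ramp = np.zeros(grid.n_voxels)
    for axis in (0, 1):  # medial->lateral (x) and posterior->anterior (y)
        span = coords[:, axis].max() - coords[:, axis].min()
        if span > 0:
            ramp += (coords[:, axis] - coords[:, axis].min()) / span
        else:
            ramp += 0.5
    base = f_lo + (f_hi - f_lo) * ramp / 2.0

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xF1E1D]))
    nx, ny, nz = grid.shape
    sigma_vox = 3.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM = 3 x spacing
    maps = np.empty((config.n_subjects, grid.n_voxels))
    for s in range(config.n_subjects):
        if config.subject_sd == 0:
            dev = np.zeros(grid.n_voxels)
        else:
            white = rng.standard_normal((nz, ny, nx))
            smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
            sd = smooth.std(ddof=1)
            dev = (smooth / sd * config.subject_sd).ravel() if sd > 0 else smooth.ravel()
        maps[s] = np.clip(base + dev, *config.analysis_band)
    return maps


def _burst_envelope(n: int, fs: float, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Rectified low-pass-filtered noise, normalised to unit mean."""
    white = rng.standard_normal(n)
    b, a = signal.butter(2, min(cutoff_hz / (fs / 2.0), 0.99), btype="low")
    env = np.abs(signal.filtfilt(b, a, white))
    mean = env.mean()
    return env / mean if mean > 0 else np.ones(n)


def _aperiodic_noise(
    shape: tuple[int, int], fs: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f^chi Gaussian noise rows via spectral shaping of white noise."""
    n = shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal(shape)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * gain, n=n, axis=1)
    rms = shaped.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return shaped / rms


def min_session_duration_s(
    config: CohortConfig, cycles: float = 5.0, trim_cycles: float = 10.0
) -> float:
    """Shortest session the analysis can digest: two edge trims plus one
    window at the lowest analysis frequency."""
    f_min = config.analysis_band[0]
    return (2.0 * trim_cycles + cycles) / f_min


def simulate_session(
    grid: VoxelGrid,
    true_map: np.ndarray,
    config: CohortConfig,
    session_id: int,
    seed: int,
    subject_id: str = "S00",
    elapsed_days: float = 0.0,
) -> SourceTimeSeries:
    """Simulate one subject-session of source-level data.

    Each voxel carries an amplitude-modulated sinusoid at its planted
    frequency (plus per-voxel session jitter) over an independent
    1/f^chi background.  With ``snr = s`` the oscillation RMS is ``s``
    times the background RMS; ``snr = inf`` yields a pure oscillation and
    ``snr = 0`` pure background.
    """
    true_map = np.asarray(true_map, dtype=float)
    if true_map.shape != (grid.n_voxels,):
        raise ValueError("true_map length must equal the number of grid voxels")
    min_dur = min_session_duration_s(config)
    if config.duration_s < min_dur:
        raise ValueError(
            f"duration_s={config.duration_s} too short for spectral analysis: "
            f"need at least {min_dur:.2f} s (edge trims plus one window at "
            f"{config.analysis_band[0]} Hz)"
        )
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    rng = np.random.default_rng(seed)
    V = grid.n_voxels

    jitter = (
        rng.normal(0.0, config.session_jitter_sd, size=V)
        if config.session_jitter_sd > 0
        else np.zeros(V)
    )
    freqs = np.clip(true_map + jitter, *config.analysis_band)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=V)

    data = np.empty((V, n))
    for v in range(V):
        env = _burst_envelope(n, config.fs, config.burst_rate, rng)
        osc = env * np.sin(2.0 * np.pi * freqs[v] * t + phases[v])
        osc_rms = osc.std()
        if osc_rms > 0:
            osc = osc / osc_rms
        if np.isinf(config.snr):
            data[v] = osc
        else:
            bg = _aperiodic_noise((1, n), config.fs, config.aperiodic_exponent, rng)[0]
            data[v] = config.snr * osc + bg
    return SourceTimeSeries(
        subject_id=subject_id,
        session_id=session_id,
        data=data,
        fs=config.fs,
        segments=[(0.0, n / config.fs)],
        elapsed_days=elapsed_days,
    )


def simulate_cohort(
    config: CohortConfig, n_sessions: int = 2
) -> tuple[VoxelGrid, np.ndarray, list[SourceTimeSeries]]:
    """Simulate a full cohort: grid, true maps, and all subject-sessions.

    Session 1 of each subject has ``elapsed_days = 0``; later sessions
    draw elapsed days uniformly from ``config.elapsed_days_range``.
    Per-session RNG streams are spawned deterministically from
    ``config.seed``, so identical configs reproduce bit-identical data.
    """
    grid = config.make_grid()
    true_maps = plant_frequency_fields(grid, config)
    root = np.random.SeedSequence([int(config.seed), 0x5E55])
    children = root.spawn(config.n_subjects * n_sessions + 1)
    day_rng = np.random.default_rng(children[-1])
    recordings: list[SourceTimeSeries] = []
    for s in range(config.n_subjects):
        days = 0.0
        for sess in range(1, n_sessions + 1):
            if sess > 1:
                days = float(
                    np.floor(day_rng.uniform(*config.elapsed_days_range))
                )
            child = children[s * n_sessions + (sess - 1)]
            rec = simulate_session(
                grid,
                true_maps[s],
                config,
                session_id=sess,
                seed=child,
                subject_id=f"S{s:02d}",
                elapsed_days=days,
            )
            recordings.append(rec)
    return grid, true_maps, recordings
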