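"""Single-window power spectra on a shared log-frequency axis.

The analysis converts each voxel's time series into a large set of
short-window power spectra.  Window length adapts to frequency (a fixed
number of cycles per bin), the taper is a Hanning window, and window
centres slide in fixed steps through every artifact-free segment after
trimming the segment edges.  Power is scaled FieldTrip-style — unit-energy
taper and a 2/L factor — so a unit sinusoid yields the same peak power at
every frequency while the noise floor of 1/f background is flattened.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy.signal.windows import hann

from .cohort import SourceTimeSeries

__all__ = [
    "FrequencyAxis",
    "SpectrumSet",
    "make_frequency_axis",
    "normalize_voxel_signal",
    "sliding_spectra",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyAxis:
    """Logarithmically spaced frequency bin centres (Hz)."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.ndim != 1 or freqs.size < 2:
            raise ValueError("axis needs at least two bins")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("bin centres must be strictly increasing")
        object.__setattr__(self, "freqs", freqs)

    @property
    def n_bins(self) -> int:
        return self.freqs.size

    @property
    def f_min(self) -> float:
        return float(self.freqs[0])

    @property
    def f_max(self) -> float:
        return float(self.freqs[-1])

    def upsample(self, factor: int = 10) -> "FrequencyAxis":
        """Log-spaced axis with ``(n_bins - 1) * factor + 1`` points and
        the same endpoints; every native bin lies on the fine axis."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        n_fine = (self.n_bins - 1) * factor + 1
        return make_frequency_axis(self.f_min, self.f_max, n_fine)

    def nearest_bin(self, f: float) -> int:
        return int(np.argmin(np.abs(self.freqs - f)))


def make_frequency_axis(
    f_min: float = 1.7, f_max: float = 34.5, n_bins: int = 61
) -> FrequencyAxis:
    """Geometric (log-spaced) axis: bin i = f_min * (f_max/f_min)^(i/(n-1))."""
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    freqs = np.geomspace(f_min, f_max, n_bins)
    # pin the endpoints exactly
    freqs[0], freqs[-1] = f_min, f_max
    return FrequencyAxis(freqs=freqs)


@dataclass
class SpectrumSet:
    """All single-window power spectra of one subject-session.

    ``spectra`` has shape (V, n_windows, n_bins); every voxel of a
    recording shares the axis and the window-centre times.
    """

    subject_id: str
    session_id: int
    axis: FrequencyAxis
    spectra: np.ndarray
    window_times: np.ndarray

    def __post_init__(self) -> None:
        if self.spectra.ndim != 3:
            raise ValueError("spectra must be (V, n_windows, n_bins)")
        if self.spectra.shape[2] != self.axis.n_bins:
            raise ValueError("spectra bin count does not match the axis")
        if self.spectra.shape[1] != len(self.window_times):
            raise ValueError("window_times length does not match spectra")

    @property
    def n_voxels(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_windows(self) -> int:
        return self.spectra.shape[1]


def normalize_voxel_signal(x: np.ndarray) -> np.ndarray:
    """Divide a time series by its standard deviation across time.

    Counteracts depth bias of beamformer source estimates, where signal
    amplitude depends on voxel location rather than physiology.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D series of length >= 2")
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance (degenerate) voxel signal")
    return x / sd


def _window_length(fs: float, cycles: float, f: float) -> int:
    """Window length in samples: round(fs * cycles / f), forced odd."""
    n = int(round(fs * cycles / f))
    if n % 2 == 0:
        n += 1
    return max(n, 3)


def _segment_centers(
    start_s: float, end_s: float, trim_s: float, step_s: float
) -> np.ndarray:
    """Window-centre times: first at start + trim, every step, last at or
    before end - trim."""
    usable = (end_s - start_s) - 2.0 * trim_s
    n = int(np.floor(usable / step_s + 1e-9)) + 1
    if n < 1:
        return np.empty(0)
    return start_s + trim_s + step_s * np.arange(n)


def _project_bin(
    data: np.ndarray, centers: np.ndarray, fs: float, f: float, cycles: float
) -> np.ndarray:
    """Power of all voxels at all window centres for one frequency bin."""
    V, T = data.shape
    L = _window_length(fs, cycles, f)
    half = (L - 1) // 2
    starts = centers - half
    if starts.min() < 0 or (starts.max() + L) > T:
        raise ValueError("window extends past the segment boundary")
    n = np.arange(L)
    taper = hann(L, sym=True)
    taper = taper / np.sqrt(np.sum(taper**2))
    phase = 2.0 * np.pi * f * n / fs
    kern = np.stack([taper * np.cos(phase), taper * np.sin(phase)], axis=1)  # (L, 2)

    step = np.diff(starts)
    if starts.size > 1 and np.all(step == step[0]) and step[0] > 0:
        itemsize = data.itemsize
        offset_view = as_strided(
            data[:, int(starts[0]):],
            shape=(V, starts.size, L),
            strides=(data.strides[0], int(step[0]) * itemsize, itemsize),
        )
        proj = offset_view @ kern  # (V, n_win, 2)
    else:
        proj = np.empty((V, starts.size, 2))
        chunk = max(1, int(2e7 // (L * V)))
        for i in range(0, starts.size, chunk):
            idx = starts[i : i + chunk, None] + n[None, :]
            proj[:, i : i + chunk] = data[:, idx] @ kern
    return (2.0 / L) * (proj[..., 0] ** 2 + proj[..., 1] ** 2)


def sliding_spectra(
    ts: SourceTimeSeries,
    axis: FrequencyAxis | None = None,
    step_s: float = 0.2,
    cycles: float = 5.0,
    trim_cycles: float = 10.0,
    normalize: bool = True,
    dtype: np.dtype = np.float32,
) -> SpectrumSet:
    """Sliding-window Hanning-tapered spectra of one recording.

    Per artifact-free segment, ``trim_cycles / f_min`` seconds are
    discarded at both ends (edge effects), window centres are placed
    every ``step_s`` within the trimmed span, and at each centre the
    power at every bin ``f`` is the squared magnitude of the tapered
    Fourier coefficient over a window of ``cycles / f`` seconds.  The
    coefficient is computed by direct complex-exponential projection at
    exactly ``f`` (bin frequencies are not DFT-aligned).  Segments whose
    trimmed span is shorter than one window at ``f_min`` are skipped.
    """
    if axis is None:
        axis = make_frequency_axis()
    f_min = axis.f_min
    trim_s = trim_cycles / f_min
    data = ts.data
    if normalize:
        sds = data.std(axis=1, keepdims=True)
        if np.any(sds == 0):
            bad = np.nonzero(sds.ravel() == 0)[0]
            raise ValueError(f"zero-variance voxel signal at voxels {bad.tolist()}")
        data = data / sds

    all_powers: list[np.ndarray] = []
    all_times: list[np.ndarray] = []
    for start_s, end_s in ts.segments:
        if (end_s - start_s) - 2.0 * trim_s < cycles / f_min:
            logger.warning(
                "segment (%.1f, %.1f) too short after %.2f-s edge trims; skipped",
                start_s,
                end_s,
                trim_s,
            )
            continue
        times = _segment_centers(start_s, end_s, trim_s, step_s)
        centers = np.round(times * ts.fs).astype(np.intp)
        powers = np.empty((ts.n_voxels, times.size, axis.n_bins), dtype=dtype)
        for j, f in enumerate(axis.freqs):
            powers[:, :, j] = _project_bin(data, centers, ts.fs, f, cycles)
        all_powers.append(powers)
        all_times.append(times)
    if not all_powers:
        raise ValueError("all segments were too short for spectral analysis")
    return SpectrumSet(
        subject_id=ts.subject_id,
        session_id=ts.session_id,
        axis=axis,
        spectra=np.concatenate(all_powers, axis=1),
        window_times=np.concatenate(all_times),
    )
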