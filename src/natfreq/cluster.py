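"""Whole-group clustering of power spectra and centroid peak annotation.

Spectral shapes are grouped with spherical k-means: rows are
unit-normalised, distance is cosine (one minus the cosine of the angle
between spectra, so amplitude is ignored), and the centroid update is
the unit-normalised mean of the assigned rows — the minimiser of summed
cosine distance.  The model is trained once on spectra sampled from the
first part/session of every participant and then applied to all data.

Each centroid is annotated with its spectral peak(s).  Centroids with no
local maximum carry no genuine oscillatory activity and are disregarded
downstream; when a centroid has two peaks, a harmonic pair (e.g. 10 and
20 Hz, within a +/-1 Hz tolerance) keeps only the fundamental, while
non-harmonic peaks each receive a 50% weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectral import FrequencyAxis, SpectrumSet

__all__ = [
    "ClusterConfig",
    "ClusterModel",
    "cosine_distance",
    "sample_training_spectra",
    "kmeans_cosine",
    "detect_centroid_peaks",
    "resolve_harmonics",
    "assign_labels",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterConfig:
    k: int = 25
    replicates: int = 5
    max_iter: int = 200
    spectra_per_voxel: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.spectra_per_voxel < 1:
            raise ValueError("spectra_per_voxel must be >= 1")


@dataclass
class ClusterModel:
    """Trained spherical k-means model with per-centroid peak annotations.

    ``peaks[c]`` is a list of ``(frequency_hz, weight)`` tuples, empty for
    peakless centroids; weights per centroid sum to 1 when non-empty.
    """

    centroids: np.ndarray  # (k, n_bins), unit-norm rows
    total_distance: float
    axis: FrequencyAxis
    peaks: list[list[tuple[float, float]]] = field(default_factory=list)
    trained_on: list[str] = field(default_factory=list)
    config: ClusterConfig | None = None
    objective_history: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def annotate_peaks(self, tolerance_hz: float = 1.0) -> "ClusterModel":
        """Detect local maxima of every centroid and resolve harmonics."""
        peaks = []
        for c in range(self.k):
            raw = detect_centroid_peaks(self.centroids[c], self.axis)
            amps = [self.centroids[c][self.axis.nearest_bin(f)] for f in raw]
            peaks.append(resolve_harmonics(raw, tolerance_hz, amplitudes=amps))
        self.peaks = peaks
        n_peakless = sum(1 for p in peaks if not p)
        if n_peakless:
            logger.info("%d of %d centroids have no spectral peak", n_peakless, self.k)
        return self


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """One minus the cosine of the angle between two spectra.

    Amplitude-invariant: scaling either vector leaves the distance
    unchanged.  In [0, 1] for non-negative spectra, [0, 2] in general.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - (a @ b) / (na * nb))


def sample_training_spectra(
    spectrum_sets: list[SpectrumSet],
    config: ClusterConfig,
    seed: int | None = None,
) -> np.ndarray:
    """Sample ``spectra_per_voxel`` windows per voxel and participant.

    Only first-part/first-session data may enter training (to avoid
    biasing the identification of second-instance data).  Sampling is
    uniform without replacement; a voxel with fewer windows than
    requested is resampled with replacement (logged).
    """
    if not spectrum_sets:
        raise ValueError("no spectrum sets supplied")
    for ss in spectrum_sets:
        if ss.session_id != 1:
            raise ValueError(
                f"training accepts only session 1 data; got session "
                f"{ss.session_id} for subject {ss.subject_id}"
            )
    rng = np.random.default_rng(
        config.seed if seed is None else seed
    )
    rows = []
    for ss in spectrum_sets:
        n_win = ss.n_windows
        if n_win < config.spectra_per_voxel:
            logger.warning(
                "subject %s: only %d windows available; sampling %d with "
                "replacement",
                ss.subject_id,
                n_win,
                config.spectra_per_voxel,
            )
        for v in range(ss.n_voxels):
            if n_win >= config.spectra_per_voxel:
                idx = rng.choice(n_win, size=config.spectra_per_voxel, replace=False)
            else:
                idx = rng.choice(n_win, size=config.spectra_per_voxel, replace=True)
            rows.append(np.asarray(ss.spectra[v, idx], dtype=float))
    return np.concatenate(rows, axis=0)


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero rows cannot be clustered under cosine distance")
    return X / norms


def _kmeans_once(
    Xn: np.ndarray, k: int, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    n = Xn.shape[0]
    centroids = Xn[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1, dtype=np.intp)
    history: list[float] = []
    for _ in range(max_iter):
        sim = Xn @ centroids.T
        new_labels = np.argmax(sim, axis=1)  # tie -> lowest centroid index
        history.append(float(np.sum(1.0 - sim[np.arange(n), new_labels])))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = labels == c
            if not members.any():
                # re-seed with the point farthest from its current centroid
                far = int(np.argmin(sim[np.arange(n), labels]))
                logger.info("empty cluster %d re-seeded with row %d", c, far)
                centroids[c] = Xn[far]
                labels[far] = c
                members = labels == c
            mean = Xn[members].mean(axis=0)
            norm = np.linalg.norm(mean)
            centroids[c] = mean / norm if norm > 0 else Xn[members][0]
    sim = Xn @ centroids.T
    labels = np.argmax(sim, axis=1)
    total = float(np.sum(1.0 - sim[np.arange(n), labels]))
    history.append(total)
    return centroids, labels, total, history


def kmeans_cosine(
    X: np.ndarray,
    config: ClusterConfig,
    axis: FrequencyAxis | None = None,
    trained_on: list[str] | None = None,
) -> ClusterModel:
    """Spherical k-means over spectra; best of ``replicates`` seeded runs.

    Each replicate starts from ``k`` distinct random rows, alternates
    nearest-centroid assignment (cosine) with normalised-mean updates
    until assignments stabilise or ``max_iter``, and the replicate with
    the lowest sum of distances wins.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < config.k:
        raise ValueError("need at least k rows of spectra")
    Xn = _normalize_rows(X)
    seeds = np.random.SeedSequence(config.seed).spawn(config.replicates)
    best: tuple[np.ndarray, float, list[float]] | None = None
    scores = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        centroids, _, total, history = _kmeans_once(Xn, config.k, config.max_iter, rng)
        scores.append(total)
        if best is None or total < best[1]:
            best = (centroids, total, history)
    logger.info("replicate scores: %s", [f"{s:.3f}" for s in scores])
    assert best is not None
    model = ClusterModel(
        centroids=best[0],
        total_distance=best[1],
        objective_history=best[2],
        axis=axis if axis is not None else FrequencyAxis(np.arange(1, X.shape[1] + 1, dtype=float)),
        trained_on=list(trained_on or []),
        config=config,
    )
    if axis is not None:
        model.annotate_peaks()
    return model


def assign_labels(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid (cosine) label per row; tie -> lowest index."""
    Xn = _normalize_rows(np.asarray(X, dtype=float))
    return np.argmax(Xn @ centroids.T, axis=1)


def detect_centroid_peaks(
    centroid: np.ndarray,
    axis: FrequencyAxis,
    min_prominence_frac: float = 0.05,
) -> list[float]:
    """Local maxima of a centroid spectrum, as bin-centre frequencies.

    A peak must be strictly above its flanking values (a run of equal
    values counts once, located at its first bin; endpoint bins cannot
    be peaks) and must rise by at least ``min_prominence_frac`` times
    the centroid's maximum above its surroundings.  The prominence
    requirement separates genuine oscillatory bumps from roundoff-scale
    ripple on the aperiodic background — without it, a near-flat
    centroid sprouts spurious "peaks" wherever the noise wiggles.
    Monotone or background-only centroids return an empty list.
    """
    from scipy.signal import find_peaks

    c = np.asarray(centroid, dtype=float)
    if c.shape != (axis.n_bins,):
        raise ValueError("centroid length does not match the axis")
    if not np.all(np.isfinite(c)):
        raise ValueError("centroid must be finite")
    if c.max() <= 0:
        return []
    idx, props = find_peaks(
        c,
        prominence=min_prominence_frac * c.max(),
        plateau_size=(1, None),
    )
    return [float(axis.freqs[i]) for i in props["left_edges"]]


def _is_harmonic(f1: float, f2: float, tol: float) -> bool:
    """Whether f2 is an integer multiple (m >= 2) of f1 within tol Hz.

    The comparison is strict (< tol): a pair exactly at the tolerance,
    such as 7 and 22 Hz against 3 x 7 = 21 Hz, counts as non-harmonic.
    """
    for m in {int(np.floor(f2 / f1)), int(np.ceil(f2 / f1))}:
        if m >= 2 and abs(f2 - m * f1) < tol:
            return True
    return False


def resolve_harmonics(
    peak_freqs: list[float],
    tolerance_hz: float = 1.0,
    amplitudes: list[float] | None = None,
) -> list[tuple[float, float]]:
    """Collapse harmonically related peaks and assign weights.

    One peak keeps weight 1.  For two peaks, a harmonic pair (higher peak
    within ``tolerance_hz`` of an integer multiple >= 2 of the lower)
    retains only the fundamental at weight 1; otherwise both peaks get
    weight 0.5.  With more than two peaks, harmonics of the lowest peak
    are dropped first and the two largest-amplitude survivors are kept at
    weight 0.5 each (logged — this case is beyond the two-peak rule).
    """
    freqs = sorted(float(f) for f in peak_freqs)
    if not freqs:
        return []
    if len(freqs) == 1:
        return [(freqs[0], 1.0)]
    if len(freqs) == 2:
        if _is_harmonic(freqs[0], freqs[1], tolerance_hz):
            return [(freqs[0], 1.0)]
        return [(freqs[0], 0.5), (freqs[1], 0.5)]
    logger.info("centroid with %d peaks: pairwise harmonic resolution", len(freqs))
    fundamental = freqs[0]
    survivors = [fundamental] + [
        f for f in freqs[1:] if not _is_harmonic(fundamental, f, tolerance_hz)
    ]
    if len(survivors) == 1:
        return [(survivors[0], 1.0)]
    if amplitudes is not None:
        amp = dict(zip(sorted(float(f) for f in peak_freqs), [float(a) for a in amplitudes]))
        survivors = sorted(
            sorted(survivors, key=lambda f: -amp.get(f, 0.0))[:2]
        )
    else:
        survivors = survivors[:2]
    return [(survivors[0], 0.5), (survivors[1], 0.5)]
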