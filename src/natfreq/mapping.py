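"""Single-subject natural-frequency brain maps.

A participant's map assigns one natural frequency per voxel, in four
steps: (1) classify every available single-window spectrum of each voxel
into the whole-group clusters; (2) z-score the per-cluster assignment
proportions across voxels, giving the relative presence of each
cluster's peak frequency; (3) spread those presence z-scores onto a 10x
upsampled log-frequency axis through the peaked centroids; (4) smooth
across each voxel's 1.5-cm neighbourhood with per-bin one-sample t-tests
against zero and select the bin with the highest t.  Voxels where no
frequency is reliably expressed (one-sided p above alpha at the best
bin) receive a missing value (NaN).

Smoothing by t-test rather than by averaging respects abrupt spatial
transitions between natural frequencies of adjacent regions: it asks
which frequency is *consistently* present in the neighbourhood, not what
the mean frequency is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cluster import ClusterModel, assign_labels
from .grid import VoxelGrid
from .spectral import FrequencyAxis, SpectrumSet

__all__ = [
    "PresenceProfile",
    "NaturalFrequencyMap",
    "assign_all_spectra",
    "zscore_presence",
    "presence_to_frequency_profile",
    "smooth_and_select",
    "single_subject_map",
]

logger = logging.getLogger(__name__)


@dataclass
class PresenceProfile:
    """Per-voxel presence z-scores mapped onto the fine frequency axis."""

    subject_id: str
    session_id: int
    z: np.ndarray  # (V, n_fine_bins)
    fine_axis: FrequencyAxis

    def __post_init__(self) -> None:
        if self.z.shape[1] != self.fine_axis.n_bins:
            raise ValueError("profile width does not match the fine axis")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("presence profile must be finite")


@dataclass
class NaturalFrequencyMap:
    """One participant-session map: a natural frequency per voxel (Hz).

    Missing entries (no reliably expressed frequency) are NaN.
    ``selection_t`` holds the winning t-statistic per voxel (NaN where
    the voxel is missing for lack of neighbours).
    """

    subject_id: str
    session_id: int
    freq_hz: np.ndarray  # (V,), NaN = missing
    selection_t: np.ndarray  # (V,)
    elapsed_days: float = 0.0

    @property
    def n_voxels(self) -> int:
        return self.freq_hz.size

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.freq_hz).sum())


def assign_all_spectra(spectrum_set: SpectrumSet, model: ClusterModel) -> np.ndarray:
    """Fraction of each voxel's spectra assigned to each cluster.

    Returns a (V, k) matrix whose rows sum to 1.  Unlike training, which
    samples a subset, *all* available windows are classified here — the
    assignment step is cheap and sharpens the presence estimates.
    """
    if not np.allclose(spectrum_set.axis.freqs, model.axis.freqs):
        raise ValueError("spectrum set and cluster model use different axes")
    if spectrum_set.n_windows == 0:
        raise ValueError("voxels have zero spectra")
    V, k = spectrum_set.n_voxels, model.k
    props = np.empty((V, k))
    for v in range(V):
        labels = assign_labels(
            np.asarray(spectrum_set.spectra[v], dtype=float), model.centroids
        )
        props[v] = np.bincount(labels, minlength=k) / labels.size
    return props


def zscore_presence(proportions: np.ndarray) -> np.ndarray:
    """Standardise each cluster's presence across voxels (ddof = 1).

    Columns with zero variance carry no spatial information and are set
    to zero (logged).
    """
    P = np.asarray(proportions, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need a (V, k) matrix with V >= 2")
    mean = P.mean(axis=0)
    sd = P.std(axis=0, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.info("%d cluster column(s) constant across voxels; zeroed", flat.sum())
    sd_safe = np.where(flat, 1.0, sd)
    Z = (P - mean) / sd_safe
    Z[:, flat] = 0.0
    return Z


def presence_to_frequency_profile(
    z: np.ndarray, model: ClusterModel, fine_axis: FrequencyAxis
) -> np.ndarray:
    """Map cluster-presence z-scores onto the fine frequency axis.

    Each peaked cluster deposits ``weight * z`` at its peak frequency
    (dual-peak centroids split their presence 50/50); clusters sharing a
    peak frequency accumulate.  The sparse per-voxel profile is then
    interpolated linearly in log-frequency through the populated peak
    frequencies and evaluated on ``fine_axis``, with constant
    extrapolation beyond the outermost peaks.  Peakless clusters are
    disregarded.
    """
    z = np.asarray(z, dtype=float)
    if not model.peaks or all(not p for p in model.peaks):
        raise ValueError("cluster model has no peaked centroids")
    if z.shape[1] != model.k:
        raise ValueError("z width does not match the number of clusters")
    # weight matrix: cluster -> populated peak frequencies
    freq_set = sorted({f for plist in model.peaks for f, _ in plist})
    col = {f: j for j, f in enumerate(freq_set)}
    W = np.zeros((model.k, len(freq_set)))
    for c, plist in enumerate(model.peaks):
        for f, w in plist:
            W[c, col[f]] += w
    native = z @ W  # (V, n_populated_freqs)

    xs = np.log(np.asarray(freq_set))
    xf = np.log(fine_axis.freqs)
    if len(freq_set) == 1:
        return np.repeat(native, fine_axis.n_bins, axis=1)
    seg = np.clip(np.searchsorted(xs, xf, side="right") - 1, 0, len(xs) - 2)
    t = (xf - xs[seg]) / (xs[seg + 1] - xs[seg])
    t = np.clip(t, 0.0, 1.0)  # constant extrapolation outside the span
    return native[:, seg] * (1.0 - t) + native[:, seg + 1] * t


def _one_sided_t(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column one-sample t vs 0 and one-sided p (H1: mean > 0).

    Zero-variance columns get t = +/-inf by the sign of the mean (p of 0
    or 1), t = 0 when the column is identically zero.
    """
    n = rows.shape[0]
    mean = rows.mean(axis=0)
    sd = rows.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd == 0
    t[zero_sd & (mean > 0)] = np.inf
    t[zero_sd & (mean < 0)] = -np.inf
    t[zero_sd & (mean == 0)] = 0.0
    p = stats.t.sf(t, df=n - 1)
    return t, p


def smooth_and_select(
    profile: PresenceProfile,
    grid: VoxelGrid,
    radius_cm: float = 1.5,
    alpha: float = 0.05,
) -> NaturalFrequencyMap:
    """Neighbourhood t-test smoothing and natural-frequency selection.

    For each voxel, the presence profiles of the voxel and its
    neighbours within ``radius_cm`` are tested bin-by-bin against zero
    (one-sided: the null is that the mean presence z-score is <= 0).
    The bin with the highest t becomes the voxel's natural frequency;
    if even that bin's p exceeds ``alpha``, the voxel is missing.
    """
    if profile.z.shape[0] != grid.n_voxels:
        raise ValueError("profile and grid voxel counts differ")
    V = grid.n_voxels
    fine = profile.fine_axis.freqs
    freq = np.full(V, np.nan)
    tstat = np.full(V, np.nan)
    neighbor_lists = grid.all_neighbors(radius_cm)
    for v in range(V):
        nbrs = neighbor_lists[v]
        if nbrs.size < 2:
            logger.warning("voxel %d has no neighbours within %.2f cm", v, radius_cm)
            continue
        t, p = _one_sided_t(profile.z[nbrs])
        best = int(np.argmax(t))  # tie -> lowest frequency
        tstat[v] = t[best]
        if p[best] <= alpha:
            freq[v] = fine[best]
    return NaturalFrequencyMap(
        subject_id=profile.subject_id,
        session_id=profile.session_id,
        freq_hz=freq,
        selection_t=tstat,
    )


def single_subject_map(
    spectrum_set: SpectrumSet,
    model: ClusterModel,
    grid: VoxelGrid,
    radius_cm: float = 1.5,
    alpha: float = 0.05,
    upsample: int = 10,
    elapsed_days: float = 0.0,
) -> NaturalFrequencyMap:
    """Full mapping chain for one participant-session."""
    props = assign_all_spectra(spectrum_set, model)
    z = zscore_presence(props)
    fine_axis = model.axis.upsample(upsample)
    zf = presence_to_frequency_profile(z, model, fine_axis)
    profile = PresenceProfile(
        subject_id=spectrum_set.subject_id,
        session_id=spectrum_set.session_id,
        z=zf,
        fine_axis=fine_axis,
    )
    out = smooth_and_select(profile, grid, radius_cm=radius_cm, alpha=alpha)
    out.elapsed_days = elapsed_days
    return out
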