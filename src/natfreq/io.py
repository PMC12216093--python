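"""On-disk formats for every pipeline stage.

Small, human-diffable artifacts (grids, maps, metrics) are TSV; large
per-window spectra and raw time series are chunked HDF5; cluster models
are a single ``.npz`` archive with a JSON metadata blob; run summaries
are JSON.  Natural-frequency maps can additionally be rasterised to a
3-D volume (NIfTI) when the grid is a full rectangular lattice.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cluster import ClusterConfig, ClusterModel
from .cohort import SourceTimeSeries
from .grid import VoxelGrid
from .mapping import NaturalFrequencyMap
from .spectral import FrequencyAxis, SpectrumSet

__all__ = [
    "write_grid",
    "read_grid",
    "write_true_maps",
    "read_true_maps",
    "write_timeseries",
    "read_timeseries",
    "write_spectra",
    "read_spectra",
    "save_cluster_model",
    "load_cluster_model",
    "write_map",
    "read_map",
    "map_to_volume",
    "write_nifti",
]


# -- grid and map TSVs -------------------------------------------------------

def write_grid(grid: VoxelGrid, path: str | Path) -> None:
    df = grid.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_grid(path: str | Path) -> VoxelGrid:
    df = pd.read_csv(path, sep="\t")
    coords = df[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float)
    # recover lattice shape if the grid is a full rectangular lattice
    shape = None
    uniq = [np.unique(coords[:, a]) for a in range(3)]
    if np.prod([u.size for u in uniq]) == coords.shape[0]:
        shape = (uniq[0].size, uniq[1].size, uniq[2].size)
    spacing = float(np.diff(uniq[0]).min()) if uniq[0].size > 1 else 1.0
    return VoxelGrid(coords=coords, spacing=spacing, shape=shape)


def write_true_maps(true_maps: np.ndarray, path: str | Path) -> None:
    """Planted per-subject frequency maps (`voxel_id` + one column per subject)."""
    n_subj, V = true_maps.shape
    df = pd.DataFrame({"voxel_id": np.arange(V)})
    for s in range(n_subj):
        df[f"S{s:02d}_freq_hz"] = true_maps[s]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_true_maps(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.endswith("_freq_hz")]
    return df[cols].to_numpy(dtype=float).T


def write_map(nf_map: NaturalFrequencyMap, grid: VoxelGrid, path: str | Path) -> None:
    df = grid.to_frame()
    df["natural_freq_hz"] = nf_map.freq_hz
    df["t_stat"] = nf_map.selection_t
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="")


def read_map(path: str | Path, subject_id: str = "", session_id: int = 0) -> NaturalFrequencyMap:
    df = pd.read_csv(path, sep="\t")
    return NaturalFrequencyMap(
        subject_id=subject_id,
        session_id=session_id,
        freq_hz=df["natural_freq_hz"].to_numpy(dtype=float),
        selection_t=df["t_stat"].to_numpy(dtype=float),
    )


# -- time series and spectra (HDF5) ------------------------------------------

def write_timeseries(ts: SourceTimeSeries, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data, chunks=True, compression="gzip")
        f.attrs["fs"] = ts.fs
        f.attrs["subject_id"] = ts.subject_id
        f.attrs["session_id"] = ts.session_id
    meta = {
        "subject_id": ts.subject_id,
        "session_id": int(ts.session_id),
        "fs": float(ts.fs),
        "segments": [[float(a), float(b)] for a, b in ts.segments],
        "elapsed_days": float(ts.elapsed_days),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_timeseries(path: str | Path) -> SourceTimeSeries:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with h5py.File(path, "r") as f:
        data = f["data"][()]
    return SourceTimeSeries(
        subject_id=meta["subject_id"],
        session_id=meta["session_id"],
        data=data,
        fs=meta["fs"],
        segments=[tuple(seg) for seg in meta["segments"]],
        elapsed_days=meta["elapsed_days"],
    )


def write_spectra(ss: SpectrumSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("spectra", data=ss.spectra, chunks=True, compression="gzip")
        f.create_dataset("freqs", data=ss.axis.freqs)
        f.create_dataset("window_times", data=ss.window_times)
        f.attrs["subject_id"] = ss.subject_id
        f.attrs["session_id"] = ss.session_id


def read_spectra(path: str | Path) -> SpectrumSet:
    with h5py.File(path, "r") as f:
        return SpectrumSet(
            subject_id=str(f.attrs["subject_id"]),
            session_id=int(f.attrs["session_id"]),
            axis=FrequencyAxis(f["freqs"][()]),
            spectra=f["spectra"][()],
            window_times=f["window_times"][()],
        )


# -- cluster model (npz + JSON metadata) -------------------------------------

def save_cluster_model(model: ClusterModel, path: str | Path) -> None:
    meta = {
        "trained_on": model.trained_on,
        "total_distance": model.total_distance,
        "peaks": model.peaks,
        "config": (
            {
                "k": model.config.k,
                "replicates": model.config.replicates,
                "max_iter": model.config.max_iter,
                "spectra_per_voxel": model.config.spectra_per_voxel,
                "seed": model.config.seed,
            }
            if model.config is not None
            else None
        ),
    }
    np.savez(
        path,
        centroids=model.centroids,
        freqs=model.axis.freqs,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_cluster_model(path: str | Path) -> ClusterModel:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        cfg = meta.get("config")
        model = ClusterModel(
            centroids=npz["centroids"],
            total_distance=float(meta["total_distance"]),
            axis=FrequencyAxis(npz["freqs"]),
            peaks=[[(float(f), float(w)) for f, w in plist] for plist in meta["peaks"]],
            trained_on=list(meta.get("trained_on", [])),
            config=ClusterConfig(**cfg) if cfg else None,
        )
    return model


# -- raster / NIfTI export ---------------------------------------------------

def map_to_volume(values: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Rasterise a length-V vector onto the grid's (nx, ny, nz) lattice."""
    if grid.shape is None:
        raise ValueError("raster export requires a rectangular grid")
    nx, ny, nz = grid.shape
    vol = np.asarray(values, dtype=float).reshape(nz, ny, nx)  # x fastest
    return np.transpose(vol, (2, 1, 0))


def write_nifti(values: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    import nibabel as nib

    vol = map_to_volume(values, grid)
    affine = np.diag([grid.spacing * 10, grid.spacing * 10, grid.spacing * 10, 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))
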