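"""Shared fixtures.

The expensive fixtures run the full pipeline in memory on a 12-subject
synthetic cohort (6x6x6 grid, 150-s sessions at 200 Hz, snr 1) and are
session-scoped so the end-to-end property and acceptance tests share
one computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import natfreq as nf

COHORT_KW = dict(
    n_subjects=12,
    grid_shape=(6, 6, 6),
    duration_s=150.0,
    fs=200.0,
    snr=1.0,
    burst_rate=1.0,
    aperiodic_exponent=1.0,
)


@dataclass
class PipelineProducts:
    config: nf.CohortConfig
    grid: nf.VoxelGrid
    true_maps: np.ndarray
    model: nf.ClusterModel
    maps1: list
    maps2: list
    tau: np.ndarray


def run_cohort_pipeline(config: nf.CohortConfig) -> PipelineProducts:
    """simulate -> spectra -> cluster -> maps -> tau, all in memory."""
    axis = nf.make_frequency_axis()
    grid, true_maps, recordings = nf.simulate_cohort(config)
    cluster_cfg = nf.ClusterConfig(seed=config.seed)
    spectrum_sets = [nf.sliding_spectra(rec, axis) for rec in recordings]
    training = nf.sample_training_spectra(
        [ss for ss in spectrum_sets if ss.session_id == 1],
        cluster_cfg,
        seed=config.seed + 1,
    )
    model = nf.kmeans_cosine(training, cluster_cfg, axis=axis)
    maps = {1: [], 2: []}
    for rec, ss in zip(recordings, spectrum_sets):
        maps[ss.session_id].append(
            nf.single_subject_map(ss, model, grid, elapsed_days=rec.elapsed_days)
        )
    tau = nf.build_tau_matrix(maps[1], maps[2])
    return PipelineProducts(
        config=config,
        grid=grid,
        true_maps=true_maps,
        model=model,
        maps1=maps[1],
        maps2=maps[2],
        tau=tau,
    )


@pytest.fixture(scope="session")
def pipeline_identical_subjects() -> PipelineProducts:
    """Cohort with no subject-specific structure (subject_sd = 0)."""
    cfg = nf.CohortConfig(subject_sd=0.0, seed=42, **COHORT_KW)
    return run_cohort_pipeline(cfg)


@pytest.fixture(scope="session")
def pipeline_individual_subjects() -> PipelineProducts:
    """Cohort with stable 0.5-Hz subject deviations (fingerprintable)."""
    cfg = nf.CohortConfig(subject_sd=0.5, session_jitter_sd=0.1, seed=42, **COHORT_KW)
    return run_cohort_pipeline(cfg)


@pytest.fixture()
def small_axis() -> nf.FrequencyAxis:
    return nf.make_frequency_axis(2.0, 32.0, 5)  # bins 2, 4, 8, 16, 32


@pytest.fixture()
def default_axis() -> nf.FrequencyAxis:
    return nf.make_frequency_axis()
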