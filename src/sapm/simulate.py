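"""Synthetic data generators: paradigm regressors, forward-simulated
network datasets with known ground truth, Gaussian null datasets, and
voxel-level region data for clustering.

Every generator is a pure function of its seed and parameters, so any
dataset can be regenerated bit-for-bit from its :class:`GroundTruth` (or
shape + seed).  Signals are produced directly in percent-signal-change
units around zero; scanner physics, physiological noise structure, and
motion are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .engine import BoldDataset, forward_signals, latent_basis
from .network import NetworkModel, build_matrices
from .paradigm import Paradigm, canonical_hrf, make_paradigm_regressor

__all__ = [
    "Paradigm",
    "canonical_hrf",
    "make_paradigm_regressor",
    "GroundTruth",
    "simulate_network_dataset",
    "simulate_null_dataset",
    "simulate_region_voxels",
]


@dataclass
class GroundTruth:
    """Everything needed to regenerate a forward-simulated dataset.

    Variable-latent time courses are smoothed Gaussian processes
    (``latent_smooth_sd`` in volumes, standardized to unit variance) plus
    optional paradigm-locked components (``epoch_coefficients`` per latent
    name); fixed latents contribute amplitude x template.  Observation
    noise is i.i.d. Gaussian with standard deviation ``noise_sd``.
    """

    model: NetworkModel
    d_values: dict
    db_values: dict
    fixed_amplitudes: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    latent_smooth_sd: float = 2.0
    epoch_coefficients: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def simulate_network_dataset(
    truth: GroundTruth, paradigm: Paradigm | None = None
) -> tuple[BoldDataset, GroundTruth]:
    """Forward-simulate BOLD data from a network with known parameters.

    ``S_BOLD = M_input M_eigv L + noise``; raises before emitting any data
    if the generating parameter point is unstable (latent propagation
    undefined).
    """
    p = paradigm or Paradigm()
    matrices = build_matrices(truth.model, truth.d_values, truth.db_values)
    basis = latent_basis(matrices)  # raises UnstableNetworkError if unstable

    t_total = p.total_volumes
    rng = np.random.default_rng(truth.seed)
    regressor = make_paradigm_regressor(p)
    latents = np.zeros((truth.model.n_latents, t_total))
    for k, lat in enumerate(truth.model.latents):
        if lat.is_fixed:
            template = np.asarray(lat.template, dtype=float)
            if template.size == p.volumes_per_run:
                template = np.tile(template, p.n_runs)
            if template.size != t_total:
                raise ValueError(
                    f"fixed latent {lat.name!r}: template length {template.size} does not "
                    f"match the paradigm ({t_total} volumes)"
                )
            latents[k] = truth.fixed_amplitudes.get(lat.name, 1.0) * template
        else:
            smooth = gaussian_filter1d(
                rng.standard_normal(t_total), truth.latent_smooth_sd, mode="wrap"
            )
            sd = smooth.std()
            if sd > 0:
                smooth = smooth / sd
            coef = truth.epoch_coefficients.get(lat.name, 0.0)
            latents[k] = smooth + coef * regressor

    _, s_input = forward_signals(matrices, basis, latents)
    noise = truth.noise_sd * rng.standard_normal(s_input.shape) if truth.noise_sd else 0.0
    data = BoldDataset(
        data=s_input + noise,
        runs=p.runs,
        regions=list(truth.model.regions),
    )
    return data, truth


def simulate_null_dataset(
    n_regions: int = 10,
    n_runs: int = 5,
    volumes_per_run: int = 40,
    seed: int = 0,
    regions: list[str] | None = None,
) -> BoldDataset:
    """Gaussian null data: i.i.d. standard-normal values per region per
    volume, organized as repeated runs.  Contains no network structure, so
    any fit to it reflects what the model can absorb from pure noise."""
    if n_regions < 1 or n_runs < 1 or volumes_per_run < 1:
        raise ValueError("null dataset shape must be positive")
    if regions is None:
        regions = [f"region{i}" for i in range(n_regions)]
    if len(regions) != n_regions:
        raise ValueError("regions list does not match n_regions")
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_regions, n_runs * volumes_per_run))
    runs = [(r * volumes_per_run, volumes_per_run) for r in range(n_runs)]
    return BoldDataset(data=data, runs=runs, regions=list(regions))


def simulate_region_voxels(
    n_voxels: int,
    cluster_profiles: np.ndarray,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel time series drawn around known cluster profiles.

    Voxels are assigned round-robin to the rows of ``cluster_profiles``
    (n_profiles x T); each voxel is its profile plus Gaussian noise.
    Returns (voxel matrix, generating labels) for recovery scoring.
    """
    profiles = np.atleast_2d(np.asarray(cluster_profiles, dtype=float))
    if profiles.shape[0] < 1:
        raise ValueError("at least one cluster profile is required")
    if n_voxels < profiles.shape[0]:
        raise ValueError("n_voxels must be >= the number of profiles")
    labels = np.arange(n_voxels) % profiles.shape[0]
    rng = np.random.default_rng(seed)
    voxels = profiles[labels] + noise_sd * rng.standard_normal((n_voxels, profiles.shape[1]))
    return voxels, labels
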