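"""Canonical synthetic study conditions.

This module pins down, in one place, the simulated datasets that the
analysis scripts, the test suite, and the acceptance script all share:

* the planted-topography dataset — a 20^3 grid at 3.5 mm, 16 runs,
  8 subjects, with three informative regions (familiarity, subcategory,
  identity) either spatially offset or deliberately co-located;
* the four-zone connectivity network driven by four seed time-courses;
* well-separated 3-D point clusters for the mixture-model comparison.

Amplitudes are in units of the beta noise SD (noise_sd = 1): familiarity
1.5, subcategory 0.3, identity 0.6 — chosen once so that searchlight
localization succeeds (the premise of the topography analysis) while the
rank-based model-correlation maps stay below the tau-a ceiling, which
would otherwise flatten the map top into a plateau.
Region radius is 14 mm (4 voxels), larger than the ~2.9-voxel radius of a
100-voxel searchlight sphere, so map maxima decay strictly away from the
region centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import VoxelTimeSeries, default_affine, derive_rng, voxel_to_mm
from .synth import ExperimentDesign, Region, SignalSpec, generate_design, generate_patterns
from .topography import TopographyDataset

TOPO_GRID: tuple[int, int, int] = (20, 20, 20)
TOPO_VOXEL_SIZE = 3.5
TOPO_NOISE_SD = 1.0
TOPO_RADIUS_MM = 14.0
#: voxel-index centers of the three informative regions (offset layout);
#: separations exceed region radius + searchlight radius, so no
#: neighborhood at one region's center samples another region's signal
TOPO_CENTERS_VOX = {
    "familiarity": (4, 9, 9),
    "subcategory": (15, 9, 9),
    "identity": (9, 14, 10),
}
#: single shared center for the co-located (null-topography) layout
COLOCATED_CENTER_VOX = (9, 9, 9)
TOPO_AMPLITUDES = {"familiarity": 1.5, "subcategory": 0.3, "identity": 0.6}
#: analysis mask: central box, index ranges inclusive
TOPO_MASK_BOX = ((2, 17), (2, 17), (4, 15))


def topography_mask() -> np.ndarray:
    """Grid-flat voxel indices of the central analysis box."""
    (x0, x1), (y0, y1), (z0, z1) = TOPO_MASK_BOX
    grid = np.zeros(TOPO_GRID, dtype=bool)
    grid[x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1] = True
    return np.flatnonzero(grid.reshape(-1))


def planted_signal_spec(colocated: bool = False, amplitude_scale: float = 1.0) -> SignalSpec:
    """The three-region signal specification (offset or co-located)."""
    affine = default_affine(TOPO_VOXEL_SIZE)
    regions = []
    for level in ("familiarity", "subcategory", "identity"):
        vox = COLOCATED_CENTER_VOX if colocated else TOPO_CENTERS_VOX[level]
        center = tuple(voxel_to_mm(np.array(vox, dtype=float), affine))
        regions.append(
            Region(
                center_mm=center,
                radius_mm=TOPO_RADIUS_MM,
                level=level,
                amplitude=TOPO_AMPLITUDES[level] * amplitude_scale,
            )
        )
    return SignalSpec(grid_shape=TOPO_GRID, affine=affine, regions=regions)


def planted_centers_mm(colocated: bool = False) -> dict[str, np.ndarray]:
    affine = default_affine(TOPO_VOXEL_SIZE)
    out = {}
    for level, vox in TOPO_CENTERS_VOX.items():
        v = COLOCATED_CENTER_VOX if colocated else vox
        out[level] = voxel_to_mm(np.array(v, dtype=float), affine)
    return out


def simulate_topography_dataset(
    seed: int,
    n_subjects: int = 8,
    n_runs: int = 16,
    colocated: bool = False,
    amplitude_scale: float = 1.0,
    design: ExperimentDesign | None = None,
) -> TopographyDataset:
    """Multi-subject beta patterns on the analysis mask.

    Each subject gets an independent template draw and noise stream
    (seeded from ``seed``); the planted region geometry is shared.
    """
    spec = planted_signal_spec(colocated=colocated, amplitude_scale=amplitude_scale)
    mask = topography_mask()
    if design is None:
        design = generate_design(n_runs, seed)
    cat, ident = [], []
    for s in range(n_subjects):
        subj_seed = int(derive_rng(seed, 800, s).integers(2**31))
        cat.append(
            generate_patterns(design, spec, TOPO_NOISE_SD, subj_seed,
                              level="categories", mask=mask)
        )
        ident.append(
            generate_patterns(design, spec, TOPO_NOISE_SD, subj_seed,
                              level="identities", mask=mask)
        )
    return TopographyDataset(category_patterns=cat, identity_patterns=ident, mask=mask)


@dataclass
class ConnectivityNetwork:
    """Synthetic four-zone network: each zone's voxels follow one seed's
    latent series plus independent noise."""

    runs: list[VoxelTimeSeries]
    stimulus: list[np.ndarray]  # per-run stimulus regressor (to be removed)
    seed_masks: list[np.ndarray]  # flat voxel indices, one per seed
    zone_labels: np.ndarray  # per-voxel ground truth (-1 = background)


def generate_connectivity_network(
    seed: int,
    n_zones: int = 4,
    zone_voxels: int = 150,
    seed_voxels: int = 10,
    background_voxels: int = 60,
    n_runs: int = 4,
    timepoints_per_run: int = 150,
    snr: float = 1.0,
    tr: float = 2.0,
) -> ConnectivityNetwork:
    """Latent-driven network at a given SNR (signal amplitude / noise SD).

    Voxel layout (flat, C order): seeds first, then zones, then
    background.  Seed voxels carry their latent at low noise so the seed
    mean series is a clean reference; zone voxels are latent * snr +
    unit noise; a shared stimulus regressor with random per-voxel gain is
    added everywhere and must be regressed out downstream.
    """
    n_vox = n_zones * (seed_voxels + zone_voxels) + background_voxels
    grid_shape = (n_vox, 1, 1)
    affine = default_affine(1.0)
    rng = derive_rng(seed, 900)

    seed_masks = [
        np.arange(z * seed_voxels, (z + 1) * seed_voxels) for z in range(n_zones)
    ]
    zone_labels = np.full(n_vox, -1, dtype=int)
    zone_start = n_zones * seed_voxels
    for z in range(n_zones):
        zone_labels[zone_start + z * zone_voxels : zone_start + (z + 1) * zone_voxels] = z

    runs, stimulus = [], []
    for r in range(n_runs):
        latents = rng.standard_normal((timepoints_per_run, n_zones))
        stim = np.sin(2 * np.pi * np.arange(timepoints_per_run) / 20.0)
        gain = rng.normal(0, 1.0, n_vox)
        data = rng.standard_normal((timepoints_per_run, n_vox))  # unit noise floor
        for z in range(n_zones):
            data[:, seed_masks[z]] = (
                latents[:, [z]] + 0.3 * rng.standard_normal((timepoints_per_run, seed_voxels))
            )
            zone = zone_labels == z
            data[:, zone] += snr * latents[:, [z]]
        data += np.outer(stim, gain)
        runs.append(VoxelTimeSeries(data=data, tr=tr, grid_shape=grid_shape,
                                    affine=affine, run_id=r))
        stimulus.append(stim)
    return ConnectivityNetwork(runs, stimulus, seed_masks, zone_labels)


def sample_cluster_points(
    seed: int,
    n_per_group: int = 20,
    n_groups: int = 3,
    separation: float = 10.0,
    spread: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic 3-D Gaussian clusters with pairwise-separated means."""
    rng = derive_rng(seed, 1000)
    means = np.array(
        [[0, 0, 0], [separation, 0, 0], [0, separation, 0], [0, 0, separation]]
    )[:n_groups]
    points = np.vstack(
        [rng.normal(mu, spread, size=(n_per_group, 3)) for mu in means]
    )
    labels = np.repeat(np.arange(n_groups), n_per_group)
    return points, labels
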