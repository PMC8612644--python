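"""Shared containers and grid geometry for the face-MVPA pipeline.

All spatial analyses run on a regular voxel grid.  Voxel indices are
0-based (i, j, k); metric coordinates are obtained through a NIfTI-style
4x4 affine and are interpreted as right-anterior-superior (RAS)
millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Category conditions in canonical order (four familiar + one unfamiliar).
CATEGORIES: tuple[str, ...] = ("cinema", "music", "politics", "sport", "unfamiliar")
FAMILIAR_CATEGORIES: tuple[str, ...] = CATEGORIES[:4]
N_IDENTITIES_PER_CATEGORY = 8

#: 40 stimulus identities: "<category>_<1..8>".
IDENTITIES: tuple[str, ...] = tuple(
    f"{cat}_{i + 1}" for cat in CATEGORIES for i in range(N_IDENTITIES_PER_CATEGORY)
)
FAMILIAR_IDENTITIES: tuple[str, ...] = tuple(
    lab for lab in IDENTITIES if not lab.startswith("unfamiliar")
)


def default_affine(voxel_size: float = 3.5) -> np.ndarray:
    """Isotropic RAS affine with the given voxel size in mm."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


def voxel_to_mm(ijk: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map voxel indices (..., 3) to metric mm coordinates."""
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def grid_coordinates(grid_shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """(n_voxels, 3) mm coordinates of every voxel in C order."""
    idx = np.indices(grid_shape).reshape(3, -1).T
    return voxel_to_mm(idx, affine)


@dataclass
class VoxelTimeSeries:
    """One run of voxel data: time x voxel, flattened C-order grid."""

    data: np.ndarray  # (n_timepoints, n_voxels)
    tr: float
    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    run_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time-series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class BetaPatternSet:
    """Per-run condition response amplitudes (GLM betas).

    ``betas`` has shape (n_runs, n_conditions, n_voxels) where the voxel
    axis is either the full flattened grid or the voxels selected by
    ``mask`` (flat indices into the grid, C order).
    """

    betas: np.ndarray
    condition_labels: tuple[str, ...]
    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    mask: np.ndarray | None = None  # flat voxel indices, or None = full grid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 3:
            raise ValueError("betas must be (runs, conditions, voxels)")
        if self.betas.shape[1] != len(self.condition_labels):
            raise ValueError("condition axis does not match labels")
        n_grid = int(np.prod(self.grid_shape))
        n_vox = self.betas.shape[2]
        if self.mask is None:
            if n_vox != n_grid:
                raise ValueError(
                    f"unmasked betas must cover the grid ({n_grid} voxels), got {n_vox}"
                )
        else:
            self.mask = np.asarray(self.mask, dtype=int)
            if self.mask.shape[0] != n_vox:
                raise ValueError("mask length does not match voxel axis")

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.betas.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[2]

    def voxel_coordinates(self) -> np.ndarray:
        """(n_voxels, 3) mm coordinates of the voxel axis."""
        coords = grid_coordinates(self.grid_shape, self.affine)
        if self.mask is not None:
            coords = coords[self.mask]
        return coords

    def restrict(self, flat_indices: np.ndarray) -> "BetaPatternSet":
        """Restrict the voxel axis to ``flat_indices`` (grid-flat indices)."""
        flat_indices = np.asarray(flat_indices, dtype=int)
        if self.mask is None:
            cols = flat_indices
        else:
            pos = {int(v): i for i, v in enumerate(self.mask)}
            cols = np.array([pos[int(v)] for v in flat_indices], dtype=int)
        return replace(self, betas=self.betas[:, :, cols], mask=flat_indices)

    def select_conditions(self, labels: tuple[str, ...]) -> "BetaPatternSet":
        idx = [self.condition_labels.index(lab) for lab in labels]
        return replace(self, betas=self.betas[:, idx, :], condition_labels=tuple(labels))


def derive_rng(seed: int, *streams: int) -> np.random.Generator:
    """Deterministic substream generator: one root seed, labelled branches.

    All randomness in the package flows from a single integer seed; each
    component derives its own independent stream by entropy-list seeding.
    """
    return np.random.default_rng([int(seed), *map(int, streams)])
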