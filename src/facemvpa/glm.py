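"""Design matrices and per-run OLS beta estimation.

Task regressors are event trains convolved with a canonical double-gamma
hemodynamic response (response peak 6 s, undershoot 16 s, ratio 1/6 —
nilearn's SPM variant), sampled at the repetition time.  Nuisance
regressors follow the event-related fMRI convention: linear trend,
quadratic trend, mean confound, and optional motion columns.  Betas are
estimated separately for each run by ordinary least squares after
discarding the first few frames of the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from nilearn.glm.first_level import spm_hrf

from .core import (
    BetaPatternSet,
    CATEGORIES,
    IDENTITIES,
    VoxelTimeSeries,
)

HRF_OVERSAMPLING = 16  # HRF sampled at tr / HRF_OVERSAMPLING internally


@dataclass
class NuisanceSpec:
    """Which nuisance columns to include in a design matrix."""

    linear_trend: bool = True
    quadratic_trend: bool = True
    mean: bool = True
    motion: np.ndarray | None = None  # (n_timepoints, n_params) or None

    @classmethod
    def none(cls) -> "NuisanceSpec":
        return cls(linear_trend=False, quadratic_trend=False, mean=False, motion=None)


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_timepoints, n_regressors)
    regressor_names: tuple[str, ...]
    task_names: tuple[str, ...]

    @property
    def task_indices(self) -> np.ndarray:
        return np.array([self.regressor_names.index(n) for n in self.task_names])

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]


class SingularDesignError(ValueError):
    """Raised when the design matrix is rank deficient."""


def hrf_kernel(tr: float, oversampling: int = HRF_OVERSAMPLING) -> np.ndarray:
    """Canonical double-gamma HRF sampled at dt = tr / oversampling."""
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr}")
    return spm_hrf(tr, oversampling=oversampling)


def hrf_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_scans: int,
    tr: float,
    oversampling: int = HRF_OVERSAMPLING,
) -> np.ndarray:
    """Boxcar event train convolved with the canonical HRF, sampled at TR."""
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if np.any(durations < 0):
        raise ValueError("event durations must be non-negative")
    dt = tr / oversampling
    n_fine = n_scans * oversampling
    train = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        a = int(np.round(onset / dt))
        b = int(np.round((onset + dur) / dt))
        b = max(b, a + 1)  # zero-duration events act as impulses
        if a >= n_fine:
            continue
        train[a : min(b, n_fine)] = 1.0
    kernel = hrf_kernel(tr, oversampling)
    conv = np.convolve(train, kernel)[:n_fine]
    return conv[::oversampling]


def _task_events(events: pd.DataFrame, model: str) -> dict[str, pd.DataFrame]:
    """Group face/letter events into task regressor sources."""
    face = events[events["event_kind"] == "face"]
    letter = events[events["event_kind"] == "letter"]
    if model == "categories":
        groups = {cat: face[face["category"] == cat] for cat in CATEGORIES}
    elif model == "identities":
        groups = {ident: face[face["identity"] == ident] for ident in IDENTITIES}
    else:
        raise ValueError(f"unknown model {model!r}; expected 'categories' or 'identities'")
    groups["letter"] = letter
    return groups


def build_design_matrix(
    events: pd.DataFrame,
    n_scans: int,
    tr: float,
    model: str = "categories",
    nuisance: NuisanceSpec | None = None,
) -> DesignMatrix:
    """Task + nuisance design matrix for one run.

    ``events`` is the run's event table with columns onset, duration,
    event_kind (face | letter), category, identity.  The categories model
    yields 5 face regressors + 1 letter regressor; the identities model
    yields 40 face regressors + 1 letter regressor.
    """
    nuisance = NuisanceSpec() if nuisance is None else nuisance
    groups = _task_events(events, model)
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name, ev in groups.items():
        reg = hrf_regressor(ev["onset"].to_numpy(), ev["duration"].to_numpy(), n_scans, tr)
        if not np.any(reg):
            raise ValueError(f"task regressor {name!r} is all zero (no events)")
        cols.append(reg)
        names.append(name)
    task_names = tuple(names)

    t = np.arange(n_scans, dtype=float)
    if nuisance.linear_trend:
        cols.append(t - t.mean())
        names.append("trend_linear")
    if nuisance.quadratic_trend:
        q = (t - t.mean()) ** 2
        cols.append(q - q.mean())
        names.append("trend_quadratic")
    if nuisance.motion is not None:
        motion = np.asarray(nuisance.motion, dtype=float)
        if motion.shape[0] != n_scans:
            raise ValueError("motion regressors do not match the number of scans")
        for i in range(motion.shape[1]):
            cols.append(motion[:, i])
            names.append(f"motion_{i}")
    if nuisance.mean:
        cols.append(np.ones(n_scans))
        names.append("mean")

    return DesignMatrix(np.column_stack(cols), tuple(names), task_names)


def _check_rank(matrix: np.ndarray, names: tuple[str, ...]) -> None:
    rank = np.linalg.matrix_rank(matrix)
    if rank < matrix.shape[1]:
        # name columns implicated in the deficiency via tiny R diagonal
        _, r = np.linalg.qr(matrix)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {matrix.shape[1]}); "
            f"offending columns: {bad or 'collinear set not isolable'}"
        )


def fit_glm(
    ts: VoxelTimeSeries,
    dm: DesignMatrix,
    discard_initial: int = 4,
    run_id: int | None = None,
) -> BetaPatternSet:
    """Per-run OLS; returns task betas only (one 'run' in the output).

    The first ``discard_initial`` frames of both the data and the design
    matrix are dropped before fitting.
    """
    if dm.n_timepoints != ts.n_timepoints:
        raise ValueError(
            f"design matrix rows ({dm.n_timepoints}) do not match "
            f"time-series length ({ts.n_timepoints})"
        )
    y = ts.data[discard_initial:]
    x = dm.matrix[discard_initial:]
    _check_rank(x, dm.regressor_names)
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    task = coef[dm.task_indices]
    return BetaPatternSet(
        betas=task[None, :, :],
        condition_labels=dm.task_names,
        grid_shape=ts.grid_shape,
        affine=ts.affine,
        meta={"run_ids": [ts.run_id if run_id is None else run_id]},
    )


def fit_glm_runs(
    runs: list[VoxelTimeSeries],
    dms: list[DesignMatrix],
    discard_initial: int = 4,
) -> BetaPatternSet:
    """Fit each run separately and stack the task betas."""
    fits = [fit_glm(ts, dm, discard_initial) for ts, dm in zip(runs, dms)]
    labels = fits[0].condition_labels
    for f in fits[1:]:
        if f.condition_labels != labels:
            raise ValueError("runs have inconsistent condition labels")
    return BetaPatternSet(
        betas=np.concatenate([f.betas for f in fits], axis=0),
        condition_labels=labels,
        grid_shape=fits[0].grid_shape,
        affine=fits[0].affine,
        meta={"run_ids": [f.meta["run_ids"][0] for f in fits]},
    )


def normalize_intensity(ts: VoxelTimeSeries, brain_mask: np.ndarray) -> VoxelTimeSeries:
    """Scale to a standard intensity: grand in-mask mean becomes 100."""
    brain_mask = np.asarray(brain_mask)
    if brain_mask.dtype == bool:
        idx = np.flatnonzero(brain_mask.reshape(-1))
    else:
        idx = brain_mask.reshape(-1).astype(int)
    if idx.size == 0:
        raise ValueError("brain mask is empty")
    grand_mean = ts.data[:, idx].mean()
    if grand_mean <= 0:
        raise ValueError(f"grand mean intensity must be positive, got {grand_mean}")
    return VoxelTimeSeries(
        data=ts.data * (100.0 / grand_mean),
        tr=ts.tr,
        grid_shape=ts.grid_shape,
        affine=ts.affine,
        run_id=ts.run_id,
    )


def smooth_volume(values: np.ndarray, grid_shape: tuple[int, int, int],
                  voxel_size: float, fwhm_mm: float) -> np.ndarray:
    """Gaussian smoothing on the voxel grid (univariate/connectivity paths only)."""
    from scipy.ndimage import gaussian_filter

    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size
    return gaussian_filter(values.reshape(grid_shape), sigma_vox).reshape(-1)
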