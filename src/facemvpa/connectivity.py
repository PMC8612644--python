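"""Seed-based functional connectivity on nuisance-cleaned residuals.

Per run, the voxel time-series are residualized against a stimulus
regressor, motion parameters, and the top five principal components of
the white-matter and ventricle/CSF voxel sets; residuals are z-scored per
voxel within each run and then concatenated across runs.  Seed maps are
Pearson correlations between the mean seed series and every voxel,
Fisher r-to-z transformed and thresholded; the winner-take-all step
assigns every voxel in the union of thresholded masks to the seed with
the largest multiple-regression coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import VoxelTimeSeries


@dataclass
class ResidualSeries:
    data: np.ndarray  # (total_timepoints, n_voxels), z-scored per run then concatenated
    run_boundaries: np.ndarray  # start index of each run in ``data``
    grid_shape: tuple[int, int, int]
    affine: np.ndarray


@dataclass
class ConnectivityMap:
    r: np.ndarray  # per-voxel Pearson r with the seed mean series (NaN = undefined)
    z: np.ndarray  # Fisher transform; +/-inf where |r| = 1 (excluded from averages)
    mask: np.ndarray  # r >= threshold
    threshold: float
    seed_label: int | None = None


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing r-to-z transform z = 0.5 ln((1+r)/(1-r))."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        return 0.5 * np.log((1.0 + r) / (1.0 - r))


def top_principal_components(series: np.ndarray, n_components: int = 5) -> np.ndarray:
    """Top PCA component time-courses of a (time, voxel) block.

    Columns are the left singular vectors of the column-demeaned series,
    i.e. the orthonormal time-courses of the leading variance directions.
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :n_components]


def _as_indices(mask: np.ndarray) -> np.ndarray:
    """Boolean mask or index array -> sorted flat voxel indices."""
    mask = np.asarray(mask).reshape(-1)
    return np.flatnonzero(mask) if mask.dtype == bool else np.sort(mask.astype(int))


def _zscore_runs(data: np.ndarray) -> np.ndarray:
    mu = data.mean(axis=0)
    sd = data.std(axis=0)
    # voxels whose series were fully absorbed by the regressors carry only
    # numerical noise: return zeros rather than amplifying it
    dead = sd <= 1e-10 * max(np.abs(data).max(), 1.0)
    sd[dead] = np.inf
    sd[sd == 0] = 1.0
    return (data - mu) / sd


def nuisance_residualize(
    runs: list[VoxelTimeSeries],
    stimulus_regressor: list[np.ndarray],
    motion: list[np.ndarray] | None = None,
    wm_voxels: np.ndarray | None = None,
    vcsf_voxels: np.ndarray | None = None,
    n_components: int = 5,
) -> ResidualSeries:
    """OLS residuals after removing stimulus, motion, and WM/VCSF PCs.

    ``wm_voxels`` / ``vcsf_voxels`` are flat voxel indices of the tissue
    masks; their top ``n_components`` PCA time-courses per run join the
    nuisance set.  Residuals are z-scored per run, then concatenated.
    """
    blocks, boundaries, offset = [], [], 0
    for i, ts in enumerate(runs):
        cols = [np.ones(ts.n_timepoints)]
        cols.append(np.asarray(stimulus_regressor[i], dtype=float))
        if motion is not None:
            cols.extend(np.asarray(motion[i], dtype=float).T)
        for vox in (wm_voxels, vcsf_voxels):
            if vox is not None:
                pcs = top_principal_components(ts.data[:, vox], n_components)
                cols.extend(pcs.T)
        x = np.column_stack(cols)
        if x.shape[1] >= x.shape[0]:
            raise ValueError(
                f"run {i}: {x.shape[1]} nuisance regressors for {x.shape[0]} time points"
            )
        coef, *_ = np.linalg.lstsq(x, ts.data, rcond=None)
        resid = ts.data - x @ coef
        blocks.append(_zscore_runs(resid))
        boundaries.append(offset)
        offset += ts.n_timepoints
    return ResidualSeries(
        data=np.vstack(blocks),
        run_boundaries=np.array(boundaries),
        grid_shape=runs[0].grid_shape,
        affine=runs[0].affine,
    )


def seed_map(
    res: ResidualSeries,
    seed_mask: np.ndarray,
    r_threshold: float = 0.12,
    seed_label: int | None = None,
) -> ConnectivityMap:
    """Pearson correlation of every voxel with the mean seed series.

    The default threshold r = 0.12 follows the convention of keeping
    voxels above the average whole-volume correlation level.
    """
    seed_mask = np.asarray(seed_mask).reshape(-1)
    idx = np.flatnonzero(seed_mask) if seed_mask.dtype == bool else seed_mask.astype(int)
    if idx.size == 0:
        raise ValueError("seed mask is empty")
    seed_series = res.data[:, idx].mean(axis=1)
    s = seed_series - seed_series.mean()
    ns = np.linalg.norm(s)
    if ns == 0:
        raise ValueError("seed series has zero variance")
    x = res.data - res.data.mean(axis=0)
    nx = np.linalg.norm(x, axis=0)
    undefined = nx == 0
    nx[undefined] = 1.0
    r = (s @ x) / (ns * nx)
    r = np.clip(r, -1.0, 1.0)
    r[np.abs(r) >= 1.0 - 1e-12] = np.sign(r[np.abs(r) >= 1.0 - 1e-12])  # exact limit
    r[undefined] = np.nan
    with np.errstate(invalid="ignore"):
        mask = r >= r_threshold
    return ConnectivityMap(r=r, z=fisher_z(r), mask=mask, threshold=r_threshold,
                           seed_label=seed_label)


def winner_take_all(
    res_by_subject: list[ResidualSeries],
    seed_masks: list[np.ndarray],
    analysis_mask: np.ndarray,
    collinearity_limit: float = 0.999,
) -> np.ndarray:
    """Assign each in-mask voxel to the seed with the largest regression beta.

    Per subject, every voxel's series is regressed jointly on all seed
    mean series (plus an intercept); betas are averaged across subjects
    before assignment.  Exact ties go to the lowest seed index.  Returns
    a per-voxel label array (-1 outside ``analysis_mask``).
    """
    seed_idx = [_as_indices(sm) for sm in seed_masks]
    for i in range(len(seed_idx)):
        for j in range(i + 1, len(seed_idx)):
            if np.intersect1d(seed_idx[i], seed_idx[j]).size:
                raise ValueError(f"seed masks {i} and {j} overlap")
    in_mask = _as_indices(analysis_mask)
    beta_sum = None
    for res in res_by_subject:
        s = np.column_stack([res.data[:, idx].mean(axis=1) for idx in seed_idx])
        sc = s - s.mean(axis=0)
        norms = np.linalg.norm(sc, axis=0)
        corr = (sc.T @ sc) / np.outer(norms, norms)
        np.fill_diagonal(corr, 0.0)
        if np.abs(corr).max() > collinearity_limit:
            i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
            raise ValueError(f"seed series {i} and {j} are collinear "
                             f"(|r| = {np.abs(corr).max():.4f})")
        x = np.column_stack([np.ones(s.shape[0]), s])
        coef, *_ = np.linalg.lstsq(x, res.data[:, in_mask], rcond=None)
        betas = coef[1:]  # (n_seeds, n_mask_voxels)
        beta_sum = betas if beta_sum is None else beta_sum + betas
    mean_betas = beta_sum / len(res_by_subject)
    winners = np.argmax(mean_betas, axis=0)  # argmax takes the lowest index on ties
    labels = np.full(res_by_subject[0].data.shape[1], -1, dtype=int)
    labels[in_mask] = winners
    return labels


def repeated_measures_anova(table: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures F for a subjects x conditions coupling
    table (reporting utility for seed-to-ROI coupling comparisons).

    Returns (F, p) with df = (c-1, (c-1)(s-1)).
    """
    from scipy import stats as ss

    x = np.asarray(table, dtype=float)
    s, c = x.shape
    if s < 2 or c < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    ss_subj = c * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cond = s * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_cond
    df_cond, df_err = c - 1, (c - 1) * (s - 1)
    f = (ss_cond / df_cond) / (ss_err / df_err)
    return float(f), float(ss.f.sf(f, df_cond, df_err))


def wta_analysis_mask(maps: list[ConnectivityMap]) -> np.ndarray:
    """Winner-take-all domain: union of the thresholded seed maps."""
    out = np.zeros_like(maps[0].mask, dtype=bool)
    for m in maps:
        out |= m.mask
    return out
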