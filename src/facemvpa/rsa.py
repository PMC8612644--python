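"""Correlation-method MVPA: split-data RSMs, CDI, and model correlation.

The split-data representational similarity matrix (sdRSM) is built by
splitting the runs into two equal halves, averaging each condition's
pattern within each half, and computing the Pearson correlation between
every condition pair across the halves.  Averaging over many random run
splits removes the arbitrariness of any single split.  The category
discriminability index (CDI) is the mean diagonal minus the mean
off-diagonal of the sdRSM; model correlation is Kendall's tau-a between
the sdRSM entries (diagonal plus upper triangle of the symmetrized
matrix) and the same entries of an ideal categorical model (an identity
matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import BetaPatternSet, derive_rng


@dataclass
class SplitRSM:
    matrix: np.ndarray  # (N, N), rows = half A, columns = half B
    condition_labels: tuple[str, ...]
    n_permutations_averaged: int
    symmetrized: bool = False
    seed: int | None = None

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[0]

    def symmetrize(self) -> "SplitRSM":
        """Average corresponding upper- and lower-triangular elements."""
        if self.symmetrized:
            return self
        return replace(self, matrix=(self.matrix + self.matrix.T) / 2.0, symmetrized=True)


@dataclass
class ModelMatrix:
    """Ideal categorical model: identity matrix (1 on-diagonal, 0 off)."""

    matrix: np.ndarray
    label: str

    @classmethod
    def categorical(cls, n_conditions: int, label: str = "") -> "ModelMatrix":
        return cls(np.eye(n_conditions), label or f"categorical_{n_conditions}")


def subcategory_model() -> ModelMatrix:
    """4x4 model for the familiar face subcategories."""
    return ModelMatrix.categorical(4, "subcategories")


def identity_model() -> ModelMatrix:
    """32x32 model for the familiar face identities."""
    return ModelMatrix.categorical(32, "identities")


def mean_subtract(patterns: BetaPatternSet) -> BetaPatternSet:
    """Remove the common response pattern: per run and voxel, subtract the
    mean across conditions."""
    if patterns.n_conditions < 2:
        raise ValueError("mean subtraction needs at least 2 conditions")
    betas = patterns.betas - patterns.betas.mean(axis=1, keepdims=True)
    return replace(patterns, betas=betas)


def half_partitions(
    n_runs: int,
    n_permutations: int | None,
    seed: int | None = None,
    exhaustive: bool = False,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Distinct unordered balanced run partitions (half A contains run 0).

    With ``exhaustive=True`` every possible partition is returned;
    otherwise ``n_permutations`` distinct partitions are sampled without
    replacement (all of them if fewer exist).
    """
    if n_runs < 2 or n_runs % 2:
        raise ValueError(f"run splitting needs an even run count >= 2, got {n_runs}")
    h = n_runs // 2
    others = list(range(1, n_runs))
    all_parts = [(0, *c) for c in combinations(others, h - 1)]
    if exhaustive:
        chosen = all_parts
    else:
        if n_permutations is None or n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if n_permutations >= len(all_parts):
            chosen = all_parts
        else:
            rng = derive_rng(0 if seed is None else seed, 500)
            idx = rng.choice(len(all_parts), size=n_permutations, replace=False)
            chosen = [all_parts[i] for i in idx]
    out = []
    for part in chosen:
        a = np.array(part)
        b = np.setdiff1d(np.arange(n_runs), a)
        out.append((a, b))
    return out


def _cross_half_corr(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """Pearson r between every row of mean_a and every row of mean_b."""
    a = mean_a - mean_a.mean(axis=1, keepdims=True)
    b = mean_b - mean_b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    bad_a, bad_b = na == 0, nb == 0
    if np.any(bad_a) or np.any(bad_b):
        warnings.warn("zero-variance pattern: undefined correlations set to NaN")
    na[bad_a] = 1.0
    nb[bad_b] = 1.0
    r = (a @ b.T) / np.outer(na, nb)
    r[bad_a, :] = np.nan
    r[:, bad_b] = np.nan
    return np.clip(r, -1.0, 1.0)  # clip propagates NaN for flagged rows/cols


def split_rsm(
    patterns: BetaPatternSet,
    n_permutations: int = 100,
    seed: int | None = None,
    symmetrize: bool = False,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> SplitRSM:
    """sdRSM averaged over random run-split permutations.

    ``splits`` overrides the random sampling with explicit
    (half_a, half_b) run-index pairs (used by oracles and by the peak
    harvesting, which needs one matrix per split).
    """
    if patterns.n_voxels < 2:
        raise ValueError("need at least 2 voxels to correlate patterns")
    if splits is None:
        splits = half_partitions(patterns.n_runs, n_permutations, seed)
    mats = []
    for half_a, half_b in splits:
        mean_a = patterns.betas[half_a].mean(axis=0)
        mean_b = patterns.betas[half_b].mean(axis=0)
        mats.append(_cross_half_corr(mean_a, mean_b))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        matrix = np.nanmean(np.stack(mats), axis=0)
    rsm = SplitRSM(
        matrix=matrix,
        condition_labels=patterns.condition_labels,
        n_permutations_averaged=len(splits),
        seed=seed,
    )
    return rsm.symmetrize() if symmetrize else rsm


def cdi(rsm: SplitRSM | np.ndarray) -> float:
    """Category discriminability index: mean diagonal minus mean
    off-diagonal of the sdRSM.  Missing entries are excluded."""
    m = rsm.matrix if isinstance(rsm, SplitRSM) else np.asarray(rsm, dtype=float)
    if m.shape[0] < 2 or m.shape[0] != m.shape[1]:
        raise ValueError("sdRSM must be square with N >= 2")
    diag = np.diag(m)
    off = m[~np.eye(m.shape[0], dtype=bool)]
    if np.isnan(diag).any() or np.isnan(off).any():
        warnings.warn("missing sdRSM entries excluded from CDI means")
    return float(np.nanmean(diag) - np.nanmean(off))


def kendall_tau_a(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's tau-a: (concordant - discordant) / all pairs.

    Pairs tied in either variable count in the denominator but not the
    numerator — the variant recommended for model matrices whose entries
    are mostly tied.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("tau-a needs two equal-length vectors of size >= 2")
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(x.size, k=1)
    s = dx[iu] * dy[iu]
    return float(s.sum() / iu[0].size)


def rsm_model_vector(matrix: np.ndarray) -> np.ndarray:
    """Diagonal + upper-triangle entries of a (symmetrized) square matrix."""
    iu = np.triu_indices(matrix.shape[0])
    return matrix[iu]


def model_correlation(rsm: SplitRSM, model: ModelMatrix) -> float:
    """Kendall tau-a between the symmetrized sdRSM and the model matrix,
    over the diagonal plus upper-triangle entries."""
    if rsm.matrix.shape != model.matrix.shape:
        raise ValueError(
            f"sdRSM shape {rsm.matrix.shape} does not match model {model.matrix.shape}"
        )
    x = rsm_model_vector(rsm.symmetrize().matrix)
    if np.isnan(x).any():
        raise ValueError("sdRSM has missing entries; model correlation undefined")
    if np.allclose(x, x[0]):
        raise ValueError("constant sdRSM vector: Kendall tau undefined")
    y = rsm_model_vector(model.matrix)
    return kendall_tau_a(x, y)


@dataclass
class GroupInferenceResult:
    t_values: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray  # BH-FDR flags
    alpha: float
    degenerate: np.ndarray  # zero-variance tests (p set to NaN -> not significant)


def group_inference(
    per_subject_values: np.ndarray,
    null_value: float = 0.0,
    alpha: float = 0.05,
) -> GroupInferenceResult:
    """Random-effects group inference: one-sample t-test of each column
    against ``null_value``, Benjamini-Hochberg FDR across columns."""
    vals = np.atleast_2d(np.asarray(per_subject_values, dtype=float))
    if vals.shape[0] < 2:
        raise ValueError("group inference needs >= 2 subjects")
    t = np.empty(vals.shape[1])
    p = np.empty(vals.shape[1])
    degenerate = np.zeros(vals.shape[1], dtype=bool)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        if np.allclose(col, col[0]):
            degenerate[j] = True
            t[j], p[j] = np.nan, np.nan
            continue
        t[j], p[j] = stats.ttest_1samp(col, null_value)
    ok = ~degenerate
    sig = np.zeros(vals.shape[1], dtype=bool)
    if ok.any():
        sig[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
    return GroupInferenceResult(t, p, sig, alpha, degenerate)
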