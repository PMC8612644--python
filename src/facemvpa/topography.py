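"""Spatial separation of peak-activation distributions.

Three families of face information (familiarity, subcategory, identity)
are mapped repeatedly over random run splits; the location of the map
maximum is recorded per split, giving one cloud of peak coordinates per
family in a right-anterior-superior (RAS) metric frame.  Separation of
the clouds is then quantified four ways: per-axis rank tests
(Kruskal-Wallis, pairwise Mann-Whitney with Bonferroni correction),
ANOSIM on the full Euclidean dissimilarity matrix with a permutation
test, AIC comparison of explicit-parameter 3-D Gaussian mixtures with one
component versus one component per family, and Dice overlap of
thresholded maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import ceil

import numpy as np
from scipy import stats

from .core import BetaPatternSet, FAMILIAR_CATEGORIES, FAMILIAR_IDENTITIES, grid_coordinates
from .rsa import half_partitions
from .searchlight import Neighborhoods, build_neighborhoods, model_tau_maps_group

PEAK_LABELS = ("familiarity", "subcategory", "identity")


@dataclass
class PeakSet:
    label: str
    points: np.ndarray  # (n_points, 3) RAS mm

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class TopographyDataset:
    """Per-subject beta patterns feeding the three peak-harvest analyses."""

    category_patterns: list[BetaPatternSet]  # 5 category conditions per subject
    identity_patterns: list[BetaPatternSet]  # 40 identity conditions per subject
    mask: np.ndarray  # grid-flat voxel indices of the analysis mask

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=int)
        if self.mask.size == 0:
            raise ValueError("analysis mask is empty")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.category_patterns[0].grid_shape

    @property
    def affine(self) -> np.ndarray:
        return self.category_patterns[0].affine


def familiarity_tmap(patterns: BetaPatternSet, runs: np.ndarray) -> np.ndarray:
    """Per-voxel t of the familiar-vs-unfamiliar contrast across ``runs``.

    The contrast per run is mean(familiar category betas) - unfamiliar
    beta; computed on raw (non-mean-subtracted) category betas.
    """
    fam_idx = [patterns.condition_labels.index(c) for c in FAMILIAR_CATEGORIES]
    unf_idx = patterns.condition_labels.index("unfamiliar")
    b = patterns.betas[runs]
    contrast = b[:, fam_idx, :].mean(axis=1) - b[:, unf_idx, :]  # (runs, voxels)
    mean = contrast.mean(axis=0)
    sd = contrast.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    return mean / (sd / np.sqrt(len(runs)))


def _on_mask(values: np.ndarray, patterns: BetaPatternSet, mask: np.ndarray) -> np.ndarray:
    """Reindex a per-voxel map from the pattern's voxel axis onto ``mask``."""
    if patterns.mask is None:
        return values[mask]
    pos = np.full(int(np.prod(patterns.grid_shape)), -1, dtype=int)
    pos[patterns.mask] = np.arange(patterns.mask.size)
    cols = pos[mask]
    if (cols < 0).any():
        raise ValueError("analysis mask extends outside the pattern mask")
    return values[cols]


def harvest_peaks(
    dataset: TopographyDataset,
    analysis: str,
    n_perm: int = 500,
    seed: int = 0,
    k: int = 100,
    searchlight_cache: Neighborhoods | None = None,
    subcategory_pair: tuple[str, str] | None = None,
) -> PeakSet:
    """Peak coordinates over run-split permutations.

    ``analysis`` is one of ``univariate_contrast`` (familiar-vs-unfamiliar
    t-map on each half of every split, two peaks per split),
    ``subcategory_searchlight`` (4x4 model-correlation map, one split per
    permutation), or ``identity_searchlight`` (32x32 model).  Maps are
    averaged across subjects before the in-mask argmax; coordinates are
    returned in metric mm.
    """
    subjects_cat = dataset.category_patterns
    subjects_id = dataset.identity_patterns
    n_runs = subjects_cat[0].n_runs
    coords = grid_coordinates(dataset.grid_shape, dataset.affine)[dataset.mask]

    if analysis == "univariate_contrast":
        n_splits = ceil(n_perm / 2)
        splits = half_partitions(n_runs, n_splits, seed)
        points = []
        for half_a, half_b in splits:
            for half in (half_a, half_b):
                tmap = np.mean(
                    [_on_mask(familiarity_tmap(p, half), p, dataset.mask)
                     for p in subjects_cat],
                    axis=0,
                )
                if np.isnan(tmap).all():
                    raise ValueError("all-missing contrast map; cannot harvest peak")
                points.append(coords[np.nanargmax(tmap)])
        return PeakSet("familiarity", np.array(points[:n_perm]))

    if analysis == "subcategory_searchlight":
        label, conds, pats = "subcategory", FAMILIAR_CATEGORIES, subjects_cat
        if subcategory_pair is not None:
            label = "subcategory_" + "+".join(subcategory_pair)
            conds = tuple(subcategory_pair)
    elif analysis == "identity_searchlight":
        label, conds, pats = "identity", FAMILIAR_IDENTITIES, subjects_id
    else:
        raise ValueError(f"unknown analysis {analysis!r}")

    nb = searchlight_cache
    if nb is None:
        nb = build_neighborhoods(dataset.mask, dataset.grid_shape, dataset.affine, k=k)
    splits = half_partitions(n_runs, n_perm, seed)
    maps = model_tau_maps_group(pats, nb, conds, splits=splits, average=False)
    points = []
    for m in maps:
        if np.isnan(m.values).all():
            raise ValueError("all-missing searchlight map; cannot harvest peak")
        points.append(coords[np.nanargmax(m.values)])
    return PeakSet(label, np.array(points[:n_perm]))


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int


def anosim(
    dissimilarity: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities on a full pairwise dissimilarity matrix.

    R = (mean rank of between-group dissimilarities - mean rank of
    within-group dissimilarities) / (M/2) with M = n(n-1)/2 pairs and
    mid-ranks for ties.  The permutation p-value uses the add-one
    convention p = (1 + #{permuted R >= observed}) / (1 + n_perm).
    """
    d = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(labels)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T) or (d < 0).any():
        raise ValueError("dissimilarity must be symmetric and non-negative")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"group(s) {list(small)} have a single member: "
                         "within-group mean rank undefined")
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(d[iu])  # mid-ranks for ties
    m = ranks.size
    denom = m / 2.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    labels_w = labels[iu[0]] == labels[iu[1]]
    if labels_w.all() or not labels_w.any():  # cannot happen with >=2 groups of >=2
        raise ValueError("degenerate grouping")
    observed = r_stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if r_stat(lab) >= observed:
            count += 1
    return AnosimResult(float(observed), (1 + count) / (1 + n_perm), n_perm)


def euclidean_dissimilarity(points: np.ndarray) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    return np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2)


def peaksets_anosim(peaksets: list[PeakSet], n_perm: int = 1000, seed: int = 0) -> AnosimResult:
    """ANOSIM over the pooled peak coordinates of several peak sets."""
    points = np.vstack([ps.points for ps in peaksets])
    labels = np.concatenate([[ps.label] * ps.n_points for ps in peaksets])
    return anosim(euclidean_dissimilarity(points), labels, n_perm=n_perm, seed=seed)


@dataclass
class PeakLocationTests:
    kruskal_p: dict[str, float]  # per axis (R, A, S), uncorrected
    kruskal_p_corrected: dict[str, float]  # Bonferroni across axes
    pairwise_p: dict[tuple[str, str, str], float]  # (group_i, group_j, axis), uncorrected
    pairwise_p_corrected: dict[tuple[str, str, str], float]
    skipped_axes: list[str] = field(default_factory=list)

    @property
    def joint_significant(self) -> bool:
        return any(p <= 0.05 for p in self.kruskal_p_corrected.values())


AXES = ("R", "A", "S")


def peak_location_tests(peaksets: list[PeakSet]) -> PeakLocationTests:
    """Kruskal-Wallis per coordinate axis plus pairwise two-tailed
    Mann-Whitney U, both Bonferroni-corrected."""
    if len(peaksets) < 2 or any(ps.n_points < 2 for ps in peaksets):
        raise ValueError("need >= 2 groups with >= 2 points each")
    kw_p: dict[str, float] = {}
    skipped: list[str] = []
    for ai, axis in enumerate(AXES):
        cols = [ps.points[:, ai] for ps in peaksets]
        if np.ptp(np.concatenate(cols)) == 0:
            skipped.append(axis)
            continue
        kw_p[axis] = float(stats.kruskal(*cols).pvalue)
    m_axes = len(kw_p)
    kw_corr = {a: min(1.0, p * m_axes) for a, p in kw_p.items()}

    pw_p: dict[tuple[str, str, str], float] = {}
    for ps_i, ps_j in combinations(peaksets, 2):
        for ai, axis in enumerate(AXES):
            if axis in skipped:
                continue
            x, y = ps_i.points[:, ai], ps_j.points[:, ai]
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            pw_p[(ps_i.label, ps_j.label, axis)] = float(res.pvalue)
    m_pw = len(pw_p)
    pw_corr = {key: min(1.0, p * m_pw) for key, p in pw_p.items()}
    return PeakLocationTests(kw_p, kw_corr, pw_p, pw_corr, skipped)


def bonferroni(p: float | np.ndarray, m: int) -> np.ndarray:
    """Bonferroni correction: multiply by m, capped at 1."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


@dataclass
class MixtureFit:
    k: int
    log_likelihood: float
    n_params: int
    aic: float
    relative_likelihood: float | None = None  # vs the best model, filled by compare


def _regularized_cov(points: np.ndarray) -> np.ndarray:
    cov = np.cov(points.T)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance regularized")
        cov = cov + np.eye(3) * (1e-6 * np.trace(cov) / 3.0 + 1e-12)
    return cov


def mixture_aic(points: np.ndarray, group_labels: np.ndarray, k: int) -> MixtureFit:
    """Explicit-parameter 3-D Gaussian mixture and its AIC.

    No iterative fitting: component means are the group sample means,
    covariances the group sample covariances, mixing proportions the group
    sizes over the total.  k = 1 uses pooled statistics.  The free
    parameter count is k*(3 + 6 + 1) - 1 (means + symmetric covariances +
    proportions minus the sum-to-one constraint); AIC = 2*params - 2*LL.
    """
    points = np.asarray(points, dtype=float)
    group_labels = np.asarray(group_labels)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if k == 1:
        comps = [np.ones(points.shape[0], dtype=bool)]
    else:
        uniq = list(dict.fromkeys(group_labels))  # order of appearance
        if len(uniq) != k:
            raise ValueError(f"k={k} but labels define {len(uniq)} groups")
        comps = [group_labels == u for u in uniq]
    log_parts = []
    for sel in comps:
        sub = points[sel]
        if sub.shape[0] < 4:
            raise ValueError("each component needs >= 4 points for a covariance")
        weight = sub.shape[0] / points.shape[0]
        mvn = stats.multivariate_normal(mean=sub.mean(axis=0), cov=_regularized_cov(sub))
        log_parts.append(np.log(weight) + mvn.logpdf(points))
    ll = float(np.logaddexp.reduce(np.stack(log_parts), axis=0).sum())
    n_params = k * (3 + 6 + 1) - 1
    return MixtureFit(k=k, log_likelihood=ll, n_params=n_params,
                      aic=2.0 * n_params - 2.0 * ll)


def compare_mixtures(fits: list[MixtureFit]) -> list[MixtureFit]:
    """Fill relative likelihoods exp((AIC_min - AIC)/2) against the best fit."""
    best = min(f.aic for f in fits)
    for f in fits:
        f.relative_likelihood = float(np.exp((best - f.aic) / 2.0))
    return fits


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|); 0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = a.sum() + b.sum()
    if total == 0:
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / total)
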