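"""Synthetic event-related designs, beta patterns, and voxel time-series.

The generator emulates the study conditions the downstream analyses
assume: 16 event-related runs, 5 face categories x 8 identities, 40
stimulus trials per run interleaved with 35-39 variable-duration null
trials, HRF-convolved responses, i.i.d. Gaussian noise, and three
spatially offset informative regions carrying familiarity, subcategory,
and identity signals respectively.

Signal model
------------
Each informative region is a ball of radius ``radius_mm`` around a metric
center, tapered by a Gaussian radial profile w(d) = exp(-d^2 / (2 sigma^2))
with sigma = radius/2 (zero outside the ball).  Templates are drawn once
per dataset from a seeded stream and are identical across runs; only the
additive Gaussian noise varies from run to run.

* familiarity region: a non-negative bump ``amplitude * w`` added to every
  familiar condition (nothing for unfamiliar faces), so the
  familiar-vs-unfamiliar contrast peaks at the region center.
* subcategory region: one zero-mean spatial pattern per familiar category,
  constrained to sum to zero across the four categories at every voxel;
  the unfamiliar category carries no pattern there.  The zero-sum
  constraint makes the familiarity contrast vanish in expectation inside
  this region.
* identity region: per familiar identity, ``amplitude * w * (gamma * z_cat
  + z_id)`` where z_cat is a nested category component (shared by the
  eight identities of a category, zero-sum across categories) and z_id is
  an identity perturbation, zero-sum across the identities of a category.
  The nesting makes both subcategory and identity information decodable
  from one dataset, with the category signal in this region scaled down by
  ``gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm
from .core import (
    BetaPatternSet,
    CATEGORIES,
    FAMILIAR_CATEGORIES,
    IDENTITIES,
    N_IDENTITIES_PER_CATEGORY,
    VoxelTimeSeries,
    default_affine,
    derive_rng,
    grid_coordinates,
)

NESTED_CATEGORY_SCALE = 0.2  # gamma: category component inside the identity region


@dataclass
class TrialParams:
    """Timing constants of the event-related design (seconds)."""

    trial_duration: float = 4.0  # face event (1 s + 1 s blank) + letter event (1 s + 1 s)
    event_duration: float = 1.0
    first_null: float = 10.0
    last_null: float = 4.0
    null_range: tuple[int, int] = (0, 10)  # null durations, whole seconds
    n_null_range: tuple[int, int] = (35, 39)
    tr: float = 2.0

    def validate(self) -> None:
        if min(self.trial_duration, self.event_duration, self.first_null,
               self.last_null, self.tr) < 0 or self.tr == 0:
            raise ValueError("trial parameters must be non-negative (tr positive)")
        if self.null_range[0] < 0 or self.null_range[1] < self.null_range[0]:
            raise ValueError(f"invalid null duration range {self.null_range}")
        if self.event_duration * 4 > self.trial_duration:
            raise ValueError("events do not fit inside the stimulus trial")


@dataclass
class RunDesign:
    events: pd.DataFrame  # onset, duration, trial_type, event_kind, category, identity
    nulls: pd.DataFrame  # onset, duration
    run_duration: float
    tr: float

    @property
    def n_scans(self) -> int:
        return int(round(self.run_duration / self.tr))

    @property
    def n_stimulus_trials(self) -> int:
        return int((self.events["event_kind"] == "face").sum())


@dataclass
class ExperimentDesign:
    runs: list[RunDesign]
    trial_params: TrialParams
    seed: int

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def generate_design(
    n_runs: int,
    seed: int,
    trial_params: TrialParams | None = None,
) -> ExperimentDesign:
    """Randomized event-related designs: 40 stimulus trials per run (8 per
    category, every identity exactly once) interleaved with 35-39 null
    trials of 0-10 s; the first 10 s and last 4 s of every run are null."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    tp = TrialParams() if trial_params is None else trial_params
    tp.validate()
    runs = []
    for r in range(n_runs):
        rng = derive_rng(seed, 100, r)
        runs.append(_generate_run(rng, tp))
    return ExperimentDesign(runs=runs, trial_params=tp, seed=seed)


def _generate_run(rng: np.random.Generator, tp: TrialParams) -> RunDesign:
    order = rng.permutation(len(IDENTITIES))  # each identity once: 8 per category
    n_null = int(rng.integers(tp.n_null_range[0], tp.n_null_range[1] + 1))
    n_middle = n_null - 2  # first and last nulls are fixed-duration
    durs = rng.integers(tp.null_range[0], tp.null_range[1] + 1, size=n_middle).astype(float)
    # keep the run length a whole number of TRs (integer null durations; fix parity)
    total = tp.first_null + tp.last_null + 40 * tp.trial_duration + durs.sum()
    rem = total % tp.tr
    if rem:
        grow = np.flatnonzero(durs <= tp.null_range[1] - (tp.tr - rem))
        if grow.size:
            durs[rng.choice(grow)] += tp.tr - rem
        else:
            durs[rng.choice(np.flatnonzero(durs >= rem))] -= rem

    # slot sequence: 40 trials and n_middle nulls in random order
    slots = np.array([0] * 40 + [1] * n_middle)
    rng.shuffle(slots)

    face_rows, null_rows = [], [(0.0, tp.first_null)]
    t = tp.first_null
    trial_i, null_i = 0, 0
    for s in slots:
        if s == 0:
            ident = IDENTITIES[order[trial_i]]
            cat = ident.rsplit("_", 1)[0]
            face_rows.append((t, tp.event_duration, f"face_{ident}", "face", cat, ident))
            face_rows.append(
                (t + 2 * tp.event_duration, tp.event_duration, "letter", "letter", "", "")
            )
            t += tp.trial_duration
            trial_i += 1
        else:
            d = durs[null_i]
            null_rows.append((t, d))  # zero-duration nulls stay in the schedule
            t += d
            null_i += 1
    null_rows.append((t, tp.last_null))
    t += tp.last_null

    events = pd.DataFrame(
        face_rows,
        columns=["onset", "duration", "trial_type", "event_kind", "category", "identity"],
    ).sort_values("onset", ignore_index=True)
    nulls = pd.DataFrame(null_rows, columns=["onset", "duration"])
    return RunDesign(events=events, nulls=nulls, run_duration=t, tr=tp.tr)


@dataclass
class Region:
    center_mm: tuple[float, float, float]
    radius_mm: float
    level: str  # familiarity | subcategory | identity
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("region amplitude must be >= 0")
        if self.level not in ("familiarity", "subcategory", "identity"):
            raise ValueError(f"unknown region level {self.level!r}")


@dataclass
class SignalSpec:
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    affine: np.ndarray = field(default_factory=default_affine)
    regions: list[Region] = field(default_factory=list)
    nested_category_scale: float = NESTED_CATEGORY_SCALE

    def __post_init__(self) -> None:
        coords = grid_coordinates(self.grid_shape, self.affine)
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        for reg in self.regions:
            c = np.asarray(reg.center_mm, dtype=float)
            if np.any(c < lo) or np.any(c > hi):
                raise ValueError(f"region center {reg.center_mm} lies outside the grid")

    def radial_weight(self, region: Region) -> np.ndarray:
        """Gaussian taper w(d) over the full grid, zero outside the ball."""
        coords = grid_coordinates(self.grid_shape, self.affine)
        d = np.linalg.norm(coords - np.asarray(region.center_mm), axis=1)
        sigma = region.radius_mm / 2.0
        w = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
        w[d > region.radius_mm] = 0.0
        return w

    def informative_voxels(self, level: str | None = None) -> np.ndarray:
        """Boolean grid-flat mask of voxels within any (matching) region."""
        out = np.zeros(int(np.prod(self.grid_shape)), dtype=bool)
        for reg in self.regions:
            if level is not None and reg.level != level:
                continue
            out |= self.radial_weight(reg) > 0
        return out


def _signal_tables(spec: SignalSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free signal for category conditions (5 x V) and identity
    conditions (40 x V) on the full grid, from the per-dataset template
    stream.  Drawn once per dataset: independent of run and of any mask."""
    n_grid = int(np.prod(spec.grid_shape))
    sig_cat = np.zeros((len(CATEGORIES), n_grid))
    sig_id = np.zeros((len(IDENTITIES), n_grid))
    fam_slice = slice(0, len(FAMILIAR_CATEGORIES))
    rng = derive_rng(seed, 200)  # template stream
    gamma = spec.nested_category_scale

    for reg in spec.regions:
        w = spec.radial_weight(reg)
        vox = np.flatnonzero(w > 0)
        wv = w[vox] * reg.amplitude
        if reg.level == "familiarity":
            for ci, cat in enumerate(CATEGORIES):
                if cat in FAMILIAR_CATEGORIES:
                    sig_cat[ci, vox] += wv
            for ii, ident in enumerate(IDENTITIES):
                if not ident.startswith("unfamiliar"):
                    sig_id[ii, vox] += wv
        elif reg.level == "subcategory":
            z = rng.standard_normal((len(FAMILIAR_CATEGORIES), vox.size))
            z -= z.mean(axis=0)  # zero-sum across the four familiar categories
            sig_cat[fam_slice, vox] += wv * z
            for ii, ident in enumerate(IDENTITIES):
                cat = ident.rsplit("_", 1)[0]
                if cat in FAMILIAR_CATEGORIES:
                    sig_id[ii, vox] += wv * z[FAMILIAR_CATEGORIES.index(cat)]
        else:  # identity
            zc = rng.standard_normal((len(FAMILIAR_CATEGORIES), vox.size))
            zc -= zc.mean(axis=0)
            zid = rng.standard_normal(
                (len(FAMILIAR_CATEGORIES), N_IDENTITIES_PER_CATEGORY, vox.size)
            )
            zid -= zid.mean(axis=1, keepdims=True)  # zero-sum within category
            # category-level view: identity perturbations average out
            sig_cat[fam_slice, vox] += wv * gamma * zc
            for ci, cat in enumerate(FAMILIAR_CATEGORIES):
                for k in range(N_IDENTITIES_PER_CATEGORY):
                    ii = IDENTITIES.index(f"{cat}_{k + 1}")
                    sig_id[ii, vox] += wv * (gamma * zc[ci] + zid[ci, k])
    return sig_cat, sig_id


def generate_patterns(
    design: ExperimentDesign,
    spec: SignalSpec,
    noise_sd: float,
    seed: int,
    level: str = "categories",
    mask: np.ndarray | None = None,
) -> BetaPatternSet:
    """Per-run condition betas: run-stable planted signal + i.i.d. noise.

    ``level`` selects the condition set: "categories" (5 conditions) or
    "identities" (40 conditions).  ``mask`` (grid-flat voxel indices)
    restricts the voxel axis; the signal templates do not depend on it.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    sig_cat, sig_id = _signal_tables(spec, seed)
    if level == "categories":
        signal, labels = sig_cat, CATEGORIES
    elif level == "identities":
        signal, labels = sig_id, IDENTITIES
    else:
        raise ValueError(f"unknown level {level!r}")
    if mask is not None:
        mask = np.asarray(mask, dtype=int)
        signal = signal[:, mask]
    rng = derive_rng(seed, 300, 0 if level == "categories" else 1)  # noise stream
    n_runs = design.n_runs
    betas = signal[None, :, :] + rng.normal(
        0.0, noise_sd, size=(n_runs, *signal.shape)
    )
    return BetaPatternSet(
        betas=betas,
        condition_labels=labels,
        grid_shape=spec.grid_shape,
        affine=spec.affine,
        mask=mask,
        meta={"level": level, "seed": seed, "noise_sd": noise_sd},
    )


def generate_timeseries(
    design: ExperimentDesign,
    patterns: BetaPatternSet,
    noise_sd: float,
    seed: int,
    letter_amplitude: float = 0.5,
    drift_sd: float = 0.0,
    nuisance: glm.NuisanceSpec | None = None,
) -> list[VoxelTimeSeries]:
    """HRF-convolved voxel time-series, one per run.

    data = design-matrix(events (x) HRF) . B + drift + Gaussian noise, with
    the letter event as a separate regressor source (uniform response of
    ``letter_amplitude``) and optional random per-voxel drift coefficients
    on the nuisance columns (SD ``drift_sd``).
    """
    if patterns.mask is not None:
        raise ValueError("time-series generation requires full-grid patterns")
    if patterns.n_runs != design.n_runs:
        raise ValueError("patterns and design disagree on the number of runs")
    model = "categories" if patterns.n_conditions == len(CATEGORIES) else "identities"
    nuisance = glm.NuisanceSpec() if nuisance is None else nuisance
    out = []
    tp = design.trial_params
    for r, run in enumerate(design.runs):
        dm = glm.build_design_matrix(run.events, run.n_scans, tp.tr, model, nuisance)
        n_vox = patterns.n_voxels
        coefs = np.zeros((len(dm.regressor_names), n_vox))
        coefs[dm.task_indices[:-1]] = patterns.betas[r]  # face conditions
        coefs[dm.task_indices[-1]] = letter_amplitude  # letter regressor
        rng = derive_rng(seed, 400, r)
        n_nuis = len(dm.regressor_names) - len(dm.task_names)
        if drift_sd > 0 and n_nuis:
            coefs[len(dm.task_names):] = rng.normal(0, drift_sd, (n_nuis, n_vox))
        data = dm.matrix @ coefs
        if noise_sd > 0:
            data = data + rng.normal(0, noise_sd, data.shape)
        out.append(
            VoxelTimeSeries(
                data=data,
                tr=tp.tr,
                grid_shape=patterns.grid_shape,
                affine=patterns.affine,
                run_id=r,
            )
        )
    return out
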