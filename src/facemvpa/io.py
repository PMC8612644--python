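"""File interfaces: BIDS-dialect event tables, NIfTI volumes, CSV/JSON
result tables, and the declarative simulation config."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import BetaPatternSet, VoxelTimeSeries, default_affine
from .rsa import SplitRSM
from .synth import Region, SignalSpec
from .topography import PeakSet


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated event table with the BIDS columns onset, duration,
    trial_type."""
    events[["onset", "duration", "trial_type"]].to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    """Read a BIDS-dialect events table and reconstruct the event_kind /
    category / identity columns from trial_type."""
    ev = pd.read_csv(path, sep="\t")
    kind, cat, ident = [], [], []
    for tt in ev["trial_type"]:
        if tt.startswith("face_"):
            name = tt[len("face_"):]
            kind.append("face")
            cat.append(name.rsplit("_", 1)[0])
            ident.append(name)
        else:
            kind.append("letter")
            cat.append("")
            ident.append("")
    ev["event_kind"], ev["category"], ev["identity"] = kind, cat, ident
    return ev


def timeseries_to_nifti(ts: VoxelTimeSeries, path: str | Path) -> None:
    vol = ts.data.T.reshape(*ts.grid_shape, ts.n_timepoints)
    img = nib.Nifti1Image(vol.astype(np.float32), ts.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], ts.tr))
    nib.save(img, str(path))


def timeseries_from_nifti(path: str | Path, run_id: int = 0) -> VoxelTimeSeries:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    grid_shape = vol.shape[:3]
    data = vol.reshape(-1, vol.shape[3]).T
    tr = float(img.header.get_zooms()[3])
    return VoxelTimeSeries(data=data, tr=tr, grid_shape=grid_shape,
                           affine=img.affine, run_id=run_id)


def betas_to_nifti(patterns: BetaPatternSet, path: str | Path) -> None:
    """Beta volumes as a 4-D NIfTI (runs x conditions stacked along t)
    with a JSON sidecar naming the condition order."""
    if patterns.mask is not None:
        raise ValueError("masked patterns cannot be written as full volumes")
    path = Path(path)
    stacked = patterns.betas.reshape(-1, patterns.n_voxels)  # (runs*conds, vox)
    vol = stacked.T.reshape(*patterns.grid_shape, stacked.shape[0])
    nib.save(nib.Nifti1Image(vol.astype(np.float32), patterns.affine), str(path))
    sidecar = {
        "condition_labels": list(patterns.condition_labels),
        "n_runs": patterns.n_runs,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def mask_to_nifti(mask_flat: np.ndarray, grid_shape, affine, path: str | Path) -> None:
    vol = np.zeros(int(np.prod(grid_shape)), dtype=np.int16)
    vol[np.asarray(mask_flat, dtype=int)] = 1
    nib.save(nib.Nifti1Image(vol.reshape(grid_shape), affine), str(path))


def statmap_to_nifti(values_vol: np.ndarray, affine, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.nan_to_num(values_vol).astype(np.float32), affine),
             str(path))


def save_rsm(rsm: SplitRSM, path: str | Path) -> None:
    """sdRSM as CSV plus a JSON metadata sidecar (condition order,
    permutation count, seed)."""
    path = Path(path)
    pd.DataFrame(rsm.matrix, index=rsm.condition_labels,
                 columns=rsm.condition_labels).to_csv(path)
    meta = {
        "condition_labels": list(rsm.condition_labels),
        "n_permutations_averaged": rsm.n_permutations_averaged,
        "symmetrized": rsm.symmetrized,
        "seed": rsm.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_rsm(path: str | Path) -> SplitRSM:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = json.loads(path.with_suffix(".json").read_text())
    return SplitRSM(
        matrix=df.to_numpy(),
        condition_labels=tuple(meta["condition_labels"]),
        n_permutations_averaged=meta["n_permutations_averaged"],
        symmetrized=meta["symmetrized"],
        seed=meta["seed"],
    )


def save_peaksets(peaksets: list[PeakSet], path: str | Path) -> None:
    rows = []
    for ps in peaksets:
        for p in ps.points:
            rows.append((ps.label, *p))
    pd.DataFrame(rows, columns=["label", "R", "A", "S"]).to_csv(path, index=False)


def load_peaksets(path: str | Path) -> list[PeakSet]:
    df = pd.read_csv(path)
    return [
        PeakSet(label, grp[["R", "A", "S"]].to_numpy())
        for label, grp in df.groupby("label", sort=False)
    ]


def load_signal_config(path: str | Path) -> dict:
    """Declarative simulation config (YAML key-value) -> SignalSpec plus
    simulation parameters.

    Keys: grid_shape, voxel_size_mm, regions (center_mm/center_vox,
    radius_mm, level, amplitude), noise_sd, seed, n_runs.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    affine = default_affine(float(cfg.get("voxel_size_mm", 3.5)))
    regions = []
    for reg in cfg.get("regions", []):
        if "center_vox" in reg:
            center = tuple(affine[i, i] * v for i, v in enumerate(reg["center_vox"]))
        else:
            center = tuple(reg["center_mm"])
        regions.append(Region(center_mm=center, radius_mm=float(reg["radius_mm"]),
                              level=reg["level"], amplitude=float(reg["amplitude"])))
    spec = SignalSpec(
        grid_shape=tuple(cfg.get("grid_shape", (20, 20, 20))),
        affine=affine,
        regions=regions,
    )
    return {
        "signal_spec": spec,
        "noise_sd": float(cfg.get("noise_sd", 1.0)),
        "seed": int(cfg.get("seed", 0)),
        "n_runs": int(cfg.get("n_runs", 16)),
    }
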