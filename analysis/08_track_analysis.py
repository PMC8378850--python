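#!/usr/bin/env python
"""Track-based estimators: effective diffusion and radial bias recovery.

Generates synthetic cell trajectories with known ground truth and applies
the study's estimators: the end-to-end displacement diffusion constant
D = |x(T)-x(0)|^2/(4T) on unbiased walks (hypoxic-activity level
D = 28.2 um^2/min), and the radially projected velocity bias on walks with
a known outward drift. Also documents the estimator's drift sensitivity.

Writes results/track_estimators.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from aeroring.rings import diffusion_constant, radial_bias
from aeroring.synth import gen_tracks, radial_drift

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
args = ap.parse_args()

rows = []

D_true = 28.2
tracks, _ = gen_tracks(n_tracks=2000, duration=30.0, frame_interval=0.25,
                       D=D_true, seed=args.seed)
D_est = float(np.mean([diffusion_constant(t) for t in tracks]))
rows.append(("diffusion_unbiased", D_true, D_est, abs(D_est - D_true) / D_true))

v_true = 1.0
tracks, _ = gen_tracks(n_tracks=2000, duration=30.0, frame_interval=0.25,
                       D=D_true, drift=radial_drift(v_true),
                       start_box=2000.0, seed=args.seed + 1)
centers, bias, sem, n = radial_bias(tracks, (0.0, 0.0), lag=5.0, bin_width=500.0)
ok = n > 200
v_est = float(np.nansum(bias[ok] * n[ok]) / n[ok].sum())
rows.append(("radial_bias", v_true, v_est, abs(v_est - v_true) / v_true))

# drift sensitivity of the end-to-end estimator (documented caveat)
tracks, _ = gen_tracks(n_tracks=500, duration=30.0, frame_interval=0.25,
                       D=0.0, drift=(1.0, 0.0), seed=args.seed + 2)
D_drift = float(np.mean([diffusion_constant(t) for t in tracks]))
rows.append(("diffusion_pure_drift", 1.0**2 * 30.0 / 4.0, D_drift,
             abs(D_drift - 7.5) / 7.5))

df = pd.DataFrame(rows, columns=["estimator", "truth", "estimate", "rel_dev"])
df.to_csv(OUT / "track_estimators.csv", index=False)
print(df.to_string(index=False))
print("\nnote: the end-to-end estimator reports v^2*T/4 for pure drift -- it "
      "conflates directed motion with diffusion, as used in the study.")
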