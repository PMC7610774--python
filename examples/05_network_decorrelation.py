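"""Simulate a scaled DG network and quantify channel decorrelation.

Builds a 20 GC / 3 BC network from the shipped valid populations
(intrinsic + synaptic heterogeneity, identical afferents), simulates a
60 s traversal for the base circuit and for a BK knockout applied to
every granule cell, and prints firing rates, pairwise output
correlations and the knockout-induced percentage changes.

Takes a couple of minutes on one CPU.
"""

import numpy as np

from dgnet import load_valid_population
from dgnet.afferents import generate_trajectory
from dgnet.analysis import delta_correlation_matrix, lower_triangle
from dgnet.experiment import ExperimentConfig, run_experiment

gc_pop = load_valid_population("GC")
bc_pop = load_valid_population("BC")
traj = generate_trajectory(60.0, seed=3)

results = {}
for ko in (None, ("BK", "GC")):
    cfg = ExperimentConfig(preset="mature-identical", knockout=ko,
                           n_gc=20, n_bc=3, duration_s=60.0)
    results[ko] = run_experiment(cfg, gc_pop, bc_pop, trajectory=traj)
    label = "base" if ko is None else "BK knockout"
    r = results[ko]
    out = lower_triangle(r.bundle.output)
    print(f"{label:12s}: mean GC rate {r.gc_rates_hz.mean():.2f} Hz, "
          f"median output correlation {np.median(out):.3f} "
          f"({out.size} pairs)")

dr, excluded = delta_correlation_matrix(results[None].bundle.output,
                                        results[("BK", "GC")].bundle.output)
vals = lower_triangle(dr)
print(f"\nknockout impact on decorrelation: median dR = "
      f"{np.median(vals):+.2f}% (IQR {np.percentile(vals, 25):+.2f} to "
      f"{np.percentile(vals, 75):+.2f}%), {excluded} near-zero pairs excluded")

# Removing BK from every GC raises firing rates (less after-spike brake)
# and shifts the pairwise rate correlations; the dR distribution is the
# per-pair quantification of how the knockout degrades or enhances the
# network's channel decorrelation.
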