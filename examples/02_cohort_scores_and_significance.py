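"""Score a synthetic tumor cohort and test marker significance.

Simulates 20 samples over four chromosomes with planted broad and focal
amplifications/deletions plus Gaussian marker noise, computes per-marker
G-scores, builds the permutation null by histogram convolution, and reports
how many markers clear the q < 0.25 significance bar in each direction.
"""

import numpy as np

import cnapeel as cp
from cnapeel.significance import build_null, pvalues, qvalues

spec = cp.random_cohort_spec(seed=0)
matrix, truth = cp.simulate(spec)
arms = cp.arm_table_for(spec)

print(f"cohort: {matrix.n_markers} markers x {matrix.n_samples} samples, "
      f"{len(truth)} planted events")
for direction in ("amp", "del"):
    params = cp.ScoreParams(direction=direction)
    track = cp.compute_gscore(matrix, params)
    null = build_null(track.contributions)
    q = qvalues(pvalues(track.scores, null))
    n_sig = int((q < 0.25).sum())
    print(f"{direction}: max G = {track.scores.max():.3f}, "
          f"{n_sig} markers with q < 0.25")
    result = cp.run_variant(matrix, arms, params, variant="limited", seed=0)
    print(f"  limited peel-off reports {len(result.peaks)} peaks "
          f"(G_thres = {result.g_thres:.3f})")
print("Significant markers cluster on the chromosomes carrying planted "
      "events; peaks localize the focal drivers inside them.")
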