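# Methods

## Model and procedure

The input is a markers × samples matrix of segmented log2 copy-number
ratios centered at 0 (the package assumes this scale throughout; absolute
copy numbers must be converted first). Amplifications and deletions are
analyzed as fully independent, sign-mirrored pipelines.

**Scoring.** The contribution of sample *i* at marker *m* is CN(m, i) when
it clears the aberration threshold (inclusive boundary: a value exactly at
Θ counts) and 0 otherwise; the G-score is the sum of contributions across
samples, so it grows with both the frequency and the magnitude of the
aberration. Missing entries contribute 0 to every sum and are excluded from
arm medians. The focal variant replaces the fixed Θ by a per-sample
threshold Θ + max(0, largest arm median of that sample) (deletions use the
most negative arm median), floored at Θ so it is never laxer; a sample's
arm-wide gain therefore cannot contribute to focal scores at its own broad
level.

**Significance.** The null model treats each sample's contribution vector
as exchangeable across the genome: a null G-score is a sum of one
independent draw per sample from that sample's empirical contribution
distribution. The default construction bins each sample's contributions
(right-closed binning) and convolves the per-sample histograms — the exact
permutation null up to binning resolution, and deterministic. An explicit
Monte-Carlo permutation (independent per-sample shuffles, mandatory seed)
is retained behind a flag and must agree with the convolution within
sampling error; the tests check this. Score lookups round down, so binning
error always inflates p-values (conservative). p-values are corrected to
q-values by Benjamini–Hochberg step-up across all markers of one direction
genome-wide; markers with q below the threshold (default 0.25) are
significant. The inversion `gscore_for_q` returns the smallest binned
score whose null tail is at most the q-target; it is exact at the most
favorable BH rank (all markers at the threshold score).

**Peak discovery.** Each iteration recomputes G-scores from the working
contribution grid but evaluates them against the null *frozen* from the
initial grid: the null models the chance aberration background, and
rebuilding it after deleting signal would bias it downward. The most
significant marker (ties: larger G, then smaller genomic coordinate) seeds
a peak; its region is the contiguous q-plateau around it, widened by the
union of leave-one-out plateaus (each sample removed in turn, q
recomputed). Leave-outs under which the peak is no longer significant
carry no boundary information and are skipped — without this guard a
left-out track that is flat at q = 1 would sweep the whole chromosome into
the region. The loop ends when no marker clears the q-threshold; an
iteration-count guard (> marker count) would flag a peel step that failed
to remove the peak.

**Limited peel-off.** Walking outward from each region edge, each carrier
sample's contribution is split into G_r (still attributable to the peak)
and G_n = max(0, G − G_r). G_r is the running minimum of the
forward-looking windowed maximum over max(s, 1) markers: a reduction is
accepted only when sustained for at least *s* consecutive markers, so
transient segmentation noise does not open false sub-peaks; s = 0 and
s = 1 both accept instantaneous dips. Samples not carrying the peak have
G_r = 0, so their whole contribution counts as independent signal in the
abort sum. At the first marker where Σ_i G_n(m, i) ≥ G_thres the peel
aborts on that side.

Peel semantics: the default removes contributions the way the standard
variant does — zeroing each carrier's contiguous run — but truncated at
the abort marker; the peak region itself is always cleared. An alternative
mode (`peel_mode="subtract"`) removes only G_r, leaving G_n in place. The
zero-up-to-abort default is the semantics under which the limiting
behavior is exact: with G_thres = +∞ the abort never fires and the result
is identical to the standard variant peak-for-peak, which the subtract
mode cannot guarantee (it can leave significant residual G_n behind with
no abort to protect it). For finite G_thres the two modes report the same
peak sets, because any residual the subtract mode leaves before the abort
marker is below G_thres — i.e. below the significance bar — by definition
of the first crossing.

G_thres defaults to `gscore_for_q(q_threshold)` on the focal-variant null,
applying one evidence bar to baseline peaks and sub-peaks alike. When the
focal null is degenerate (no focal aberration anywhere) G_thres becomes
+∞ with a log message and limited peel-off coincides with standard.

## Parameters

| parameter | units | default | role |
|---|---|---|---|
| Θ_amp, Θ_del | log2 ratio | 0.1 | aberration thresholds; small symmetric values are the conventional operating point for log2-ratio input |
| q threshold | — | 0.25 | FDR bar for significance and for G_thres |
| s | markers | 10 | persistence of an accepted reduction in G_r |
| n_bins | — | 10,000 | null resolution; binning error ≤ range/10⁴ and conservative |
| n_perm | — | 10,000 | Monte-Carlo permutations (flagged method only) |
| G_thres | score | from focal null | abort bar for limited peel-off |

## Synthetic cohorts

The generator emulates segmented log2-ratio cohorts: baseline 0, iid
Gaussian marker noise (default SD 0.1), and planted events added to a
seeded random carrier subset of ⌈fraction·N⌉ samples. Broad events span at
least half a chromosome arm; focal events are short and high-amplitude.
The segment-noise mode draws one noise value per random segment (geometric
lengths) to emulate spurious segmentation steps — the failure mode the
persistence parameter exists for. The generator does not model platform-
specific noise spectra, tumor purity/ploidy shifts, marker-density
variation, or evolutionary clonal structure, so passing tests demonstrate
algorithmic correctness on the stated conditions, not calibrated
performance on any particular platform's data.

The two-sub-peak demonstration cohort is noiseless by construction
(5 samples, one 100-marker chromosome; broad gain 0.5 over 41 q-arm
markers in four samples, sub-peaks +0.85 and +0.8 in two samples each),
with amplitudes chosen so the global q-minimum is unique; planting is
deterministic so the standard/limited contrast is exact.

Problem sizes used in the test suite and acceptance script (cohorts of
roughly 1,000–2,000 markers × 15–20 samples, 20–50 seeded replicates,
10,000 permutations/iterations for Monte-Carlo checks) were chosen as the
smallest scales at which every property is non-vacuous — e.g. nulls
resolve p ≪ 0.25/M and planted events are unambiguous against noise.

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive everywhere; only BED export converts
  to 0-based half-open. Chromosome names are normalized by stripping a
  leading `chr`; mitochondrial markers are dropped by default.
* Markers in neither arm interval (centromere gaps) are dropped at arm
  assignment with a logged count so arm medians stay well defined; a
  chromosome with no arm definition is an error.
* Arm medians use all non-missing markers of the arm (not only
  non-aberrant ones); a sample with no data at all is an error naming it.
* Right-closed binning plus floor lookups make all binning error
  conservative; scores beyond the null support get the smallest
  representable tail mass and are logged.
* BH q-values are computed by vectorized step-up; the test suite checks
  them against an independent implementation to 1e-12.
* The enrichment p-value uses the +1 pseudo-count estimator
  (1 + #{perm ≥ obs}) / (1 + n_iter), which never reports 0; at 10,000
  iterations the difference from the plain ratio is below 1e-4.
* Shifted peaks in the enrichment test may overlap each other (placements
  are independent); chromosome choice is length-weighted to avoid
  small-chromosome bias.
* Tie-breaks are deterministic everywhere (q, then G, then coordinate), so
  a rerun with the same config and seed is byte-identical.

## Known limitations

* The permutation unit is the single marker: autocorrelation of segmented
  profiles is not preserved by the null, which therefore understates the
  chance of long noise runs (the standard trade-off for this class of
  null; the persistence parameter mitigates the peel-off-side symptom).
* LOH analysis is out of scope; so are raw-array normalization and
  segmentation, probe remapping between genome builds, per-gene scores,
  and weighted G-score schemes.
* The leave-one-out boundary extension takes the union of regions; an
  intersection rule would be tighter but less robust to single outlier
  samples.
* Reported q-values after the first iteration are conditional on earlier
  peels and should be read as discovery-order diagnostics, not marginal
  FDR statements.
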