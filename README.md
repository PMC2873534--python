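# cnapeel

Tumor genomes carry many copy-number aberrations, but only a few *drive*
the cancer; the rest are passengers with no selective advantage. `cnapeel`
analyzes cohorts of segmented copy-number profiles (log2 ratios over a
shared marker grid) and reports the genomic regions that are aberrant more
often — and more strongly — than chance allows, for amplifications and
deletions independently. It is aimed at cancer-genomics analysts working
with array or sequencing copy-number calls in SEG or marker-matrix form.

## The statistic and the algorithm

For marker *m* and sample *i* with copy number CN(m, i), the per-marker
**G-score** sums supra-threshold values across samples:

    G_amp(m) = Σ_i CN(m, i) · I[CN(m, i) ≥ Θ_amp]

(deletions mirror the sign), combining the magnitude and frequency of the
aberration. Significance comes from a genome-wide permutation null — each
sample's contributions shuffled independently — computed either exactly by
histogram convolution (default, deterministic) or by explicit seeded
permutation, and is corrected by Benjamini–Hochberg FDR; markers with
q < 0.25 are significant.

Peaks are discovered iteratively: report the minimal-q marker, extend its
boundaries by leave-one-out over samples, then **peel off** the peak's
influence and repeat. Four peel variants are provided:

* **standard** — zero every included sample's whole contiguous aberration;
* **focal** — the same, on sample-specific high-level thresholds (standard
  threshold plus the sample's largest chromosome-arm median);
* **arm** — zero the whole chromosome arm;
* **limited** — walk outward from the peak decomposing each contribution
  into a peak-attributable component G_r (a monotone envelope that accepts
  only reductions sustained for ≥ *s* consecutive markers) and an
  independent remainder G_n; abort the peel at the first marker where
  Σ_i G_n(m, i) ≥ G_thres, leaving everything beyond untouched so a later
  iteration can report it.

G_thres is the G-score equivalent of the q-threshold under the focal-variant
null, so a sub-peak inside a broad aberration faces the same evidence bar
as a peak on baseline copy number. With G_thres = +∞ the limited variant
reproduces the standard variant exactly; at the operating threshold it
additionally recovers independent sub-peaks that standard peel-off erases.

A peak-shift permutation test (relocate every peak to a random
length-preserving genome position, count peaks containing a driver-list
gene) checks that reported peaks are enriched for plausible drivers.

## Worked example

`examples/01_two_subpeaks_in_a_broad_gain.py` builds a 5-sample toy
chromosome with a broad gain (log2 ratio 0.5) containing two stronger
sub-regions, and runs both variants:

```
planted sub-peak marker spans: [(59, 63), (74, 78)]
standard variant: 1 peak(s)
  chr1:590001-630001 (markers 59-63), q=0.01611
limited variant (s=2, G_thres=0.00053): 2 peak(s)
  chr1:590001-630001 (markers 59-63), q=0.01611
  chr1:740001-780001 (markers 74-78), q=0.0485
```

The standard variant finds the stronger sub-peak, then peels the entire
aberration — including the second driver. The limited variant aborts the
peel where the peak-independent signal Σ G_n clears G_thres and reports
both planted spans, each with its q-value at discovery. The other examples
cover cohort simulation and scoring, the two null constructions and the
q → G-score inversion, and the driver-enrichment test.

The same analysis is available from the shell:

```
cnapeel run --matrix matrix.tsv --arms arms.tsv --genes genes.tsv \
    --variant limited --s 10 --q 0.25 --seed 1 -o out/
```

writing a peak report (`peaks.tsv`), per-marker G/p/q tracks, IGV `.igv`
and BED tracks, and diagnostics; `cnapeel simulate` generates synthetic
cohorts and `cnapeel enrich` runs the peak-shift test on a peak report.

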