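# Methods

## Scope and model

`tumorfrac` estimates the tumor cellular fraction (TCF) of a marked region
of an H&E image by counting classified nuclei, gates the result with the
molecular-adequacy rule, propagates cellularity into purity-corrected
copy-number calls, and quantifies observer agreement on ordinal TCF
scores. Every stage is exercised against a synthetic scene generator that
carries per-object ground truth, so all claims made by the test suite are
claims about recovery of known parameters.

## Synthetic H&E scenes

A scene is a flat eosin-tinted stromal field with three object
populations placed by rejection sampling inside a rectangular ROI (the
analogue of the pen-marked microdissection region):

| parameter | default | meaning |
|---|---|---|
| tile | 1024 × 1024 px | field size at desk scale |
| mpp | 0.4416 µm/px | 20× scan resolution |
| n_tumor / n_nonneo / n_artifact | 45 / 105 / 10 | true fraction 0.30 |
| tumor mean nuclear area | 70 µm² | NSCLC-like tumor nuclei |
| non-neoplastic mean area | 25 µm² | lymphocyte/stromal nuclei |
| area CV | 0.25 | per-class size dispersion |
| max_overlap_frac | 0.0 | pairwise polygon overlap bound |

Nuclei are ellipses (axis ratio ≤ 1.6 tumor, ≤ 1.25 non-neoplastic)
perturbed by low-order radial harmonics — the simplest shape family that
exposes the area/eccentricity/solidity features the classifier uses. The
only size information available for the two populations is that tumor
nuclei are larger; the 70/25 µm² defaults are typical morphometry for
tumor vs small-round-cell populations and are free parameters.

Rendering uses a Beer–Lambert two-stain model with fixed unit
Ruifrok–Johnston H&E vectors: nuclei are hematoxylin-dominant
(OD_H ∈ [0.80, 1.15], OD_E = 0.12), the stromal background is faint
(0.04/0.18), and non-nuclear artifacts carry a distinct signature
(OD_H ∈ [0.40, 0.60] — above the detection threshold but strictly below
the nucleus floor — with heavy eosin 0.85), so the Ignore class is both
detectable and learnable. Because the renderer and the deconvolution
share the stain basis, deconvolution is exact on synthetic data up to
8-bit quantization; the per-pixel OD error is bounded by ≈ 0.5/I
amplified ~1.6× by the correlated stain pair, i.e. ~1e−2 in the densest
regime.

What the generator does **not** emulate: tissue architecture (glands,
nests, necrosis), chromatin texture, stain variation across scanners,
out-of-focus regions, and overlapping 3-D cell clusters. Passing tests
therefore demonstrate correctness of the pipeline's logic and its
parameter recovery under a controlled appearance model — not performance
on real slides, where the detector and the 8-feature classifier would
need re-tuning or replacement (external detections can be imported as
QuPath-dialect GeoJSON for exactly this reason).

### Observer model

Visual scoring is emulated as `rating = clip(round5(truth + bias +
N(0, σ)), 0, 100)` with defaults bias = +18, σ = 10, rounding to the
nearest 5 %. The positive bias encodes the documented over-estimation of
visual TCF relative to cell-by-cell ground truth (area dominates
perception because tumor cells are larger); the defaults reproduce a
~50 ± 19 visual vs ~34 ± 19 true pattern.

### Synthetic CNV cohort

`cnv_cohort_pair` emits paired gene-level tables for a 121-case cohort
that share genes, observed copy numbers and QC fields and differ only in
the cellularity column (visual vs revised). Records are drawn from
archetype parameter boxes with a provable relation to the call predicate
and the confidence gate under both cellularity columns, so the cohort
realizes fixed study conditions — 29 vs 27 primary-call cases, 7 vs 13
confidently reported cases (15 gene-level calls in the 13, two cases
carrying two genes), 7 of 29 initial calls changing final status. All
percentages are computed by `compare_call_sets` at run time.

## Detection

Classical stand-in for a learned nucleus detector: hematoxylin OD
threshold (0.35) → hole filling → distance-transform maxima (Gaussian
σ = 2, minimum separation 9 px) → watershed → polygonization →
area gates (8–400 µm²) → centroid-inside-ROI rule. The centroid rule,
rather than polygon overlap, matches per-cell counting semantics and is
unambiguous at the ROI boundary. Detection is fully deterministic.

## Classification

Eight features per nucleus: area, perimeter, circularity 4πA/P²,
eccentricity, solidity, mean/SD hematoxylin OD, mean eosin OD. The
classifier is a seeded random-forest ensemble (200 trees) — the
randomized-tree family used by interactive object classifiers — trained
under the balanced-annotation protocol: equal Tumor and Non-neoplastic
exemplar counts (unbalanced sets are rejected), at most 10 per class;
Ignore is exempt from balance (0–10 exemplars). Ties in predicted
probability break by the fixed class order Tumor < Non-neoplastic <
Ignore for determinism. `learning_curve` measures accuracy as a function
of the per-class budget with distinct sub-seeds per repetition.

## TCF and adequacy

`cTCF = n_tumor / (n_tumor + n_nonneo)`; Ignore never enters the ratio.
With no countable cells the fraction is reported as undefined (None), not
0 — "no tumor" and "no tissue" are different findings. Adequacy requires
n_tumor ≥ 100 and cTCF ≥ 0.20, both inclusive, and is monotone in both
arguments. The area comparator reports the fraction of ROI area covered
by (unioned) tumor-labeled regions; `tumor_foci` derives focus outlines
from nucleus labels by halo dilation and merging. In score comparisons
the observer comparator is the across-observer mean, and "equal" means
equal after rounding to integer percent, since visual scores are reported
as integers.

## Copy-number correction and gating

`x = (C − 2(1−f)) / f` for f ∈ (0, 1]; C = 2 is a fixed point and f = 1
the identity. Negative x (possible when C < 2(1−f)) is preserved and
flagged implausible rather than clamped. The six criteria are evaluated
with inclusive thresholds; the "level ≥ 5 copies" criterion is evaluated
on the corrected x — the only reading under which revising f can change
call status — and the 5 % confidence bound is an input field, not
recomputed (its estimator is proprietary to the sequencing vendor). A
missing QC field counts as unmet. The primary-call predicate ("software
call") is modeled separately as x ≥ 4 (configurable); the *reported* set
is primary calls that also pass the ≥5-of-6 gate. Call-set comparisons
count at the case level (a case counts once even with multiple gene
calls), report percent changes to one decimal and the discrepancy percent
to zero decimals, and return undefined (None) percentages when the before
count is zero. When the gate is re-evaluated after revision, the
cellularity criterion uses the f in effect for that call set.

## Agreement statistics

Quadratic weighted kappa in the disagreement form
κ = 1 − ΣwO/ΣwE, w_ij = (i−j)²/(k−1)². Binning of percent scores is
`floor(v / bin_width)` with the top edge merged into the last bin
(width 1 keeps the raw integer-percent scale; the single value 100 then
joins category 99). κ is undefined (reported with an explanation) when
the expected weighted disagreement is zero, i.e. both raters constant on
the same category. The default p-value is a seeded permutation test
(10,000 permutations, add-one two-sided estimator, permuting one vector;
ΣwE is permutation-invariant so only ΣwO is recomputed), with the
Fleiss–Cohen–Everitt large-sample normal approximation reported
alongside; the two agree within Monte-Carlo error at large n. With k = 2
the quadratic weights reduce to unweighted Cohen kappa. Group tests
delegate to standard implementations: two-sided t, Mann–Whitney U, and
uncorrected Pearson chi-square (matching hand-computed values on 2×2
adequacy tables).

## Pipeline and reproducibility

`run_report` chains simulate → detect → classify → tcf → cnv-adjust →
agree over a synthetic cohort. A single master seed derives per-stage
seeds through `SeedSequence([master, stage, index])` (kept below 2³¹), so
identical config + seed reproduce every output bit-identically; the run
manifest records versions, seeds and a config digest. Default report
sizes (6 cases, 512 px tiles, 100 nuclei/case, 2,000 permutations) keep a
full run in the seconds range; the reference scene used by the test suite
and the acceptance script is one 1024 px tile with 150 nuclei + 10
artifacts, and kappa checks run 100 oracle pairs plus one n = 10,000
chance-level draw.

## Known limitations

- The detector is threshold/watershed-based and tuned to the synthetic
  appearance model; it is not a general H&E nucleus segmenter.
- The 8-feature set suffices for the synthetic acceptance surface;
  real-slide deployment would extend it (texture, haralick, context).
- Viability is equated with detectability: necrotic/apoptotic nuclei are
  not modeled, so "viable tumor cells" means detected non-Ignore tumor
  nuclei within the ROI.
- Whether the ≥100-cell criterion refers to the ROI or the whole
  microdissected tissue is ambiguous in routine practice; the package
  counts tumor cells within the ROI.
- Multi-rater agreement generalizations (Fleiss, Krippendorff) are out of
  scope; all agreement is pairwise.
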