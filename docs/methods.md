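# Methods

## Measurement model

A cuvette backlit by a fixed white LED is photographed with fixed camera
settings; the transmitted light in each RGB channel is attenuated by the
pigments the spirit acquired during oak aging. Within the fixed region of
interest (ROI, 1244 × 231 px by default) the per-channel mean intensity
`I_sample,c` is compared with that of a deionised-water blank `I_blank,c`
measured in the same session, giving the experimental absorbance

    a_c = log10(I_blank,c / I_sample,c),    c ∈ {R, G, B}.

The logarithm is base 10 throughout (Beer–Lambert convention). The total
absorbance is defined as the arithmetic mean of the three channels; this
convention is enforced as an invariant of `AbsorbanceVector` on every code
path and verified against the packaged reference table (e.g. the S1 row:
mean(0.0729, 0.0720, 0.0729) = 0.0726). No concentrations, molar
absorptivities or path lengths are estimated — the absorbance triplet is
used purely as a color fingerprint.

Numerical choices:

* channel means are computed in floating point with no intermediate
  rounding; integer-rounded values in summary tables are treated as a
  reporting artifact, not a pipeline step;
* sample channel means below a floor of 1.0 intensity unit are clamped
  before the log (keeping absorbance finite on dead/dark pixels) with a
  warning, since such values indicate an acquisition problem;
* blank referencing is per channel (the reference blank is (255, 251, 253),
  not a single scalar), one blank per measurement session.

## Synthetic data generator

The original raw images are not publicly deposited; the generator
reproduces the *statistical* structure of the study from its published
per-sample summaries: 25 samples (8 Silver, 12 Aged, 5 Extra-aged), each
measured in 3 cuvettes × 10 images (750 replicates), plus the blank.

* **Feature mode** (default) draws each replicate's channel absorbances
  independently from `Normal(mean_c, sd_c)` truncated at zero, with the
  per-sample means and SDs of the packaged reference table. Only
  mean ± SD are published, so normality and cross-channel independence are
  modelling assumptions, not measured properties. The truncation is
  implemented as a clamp; at the study's signal-to-noise (means ≥ 0.035,
  SDs ≤ 0.009) it fires with probability ≈ 0.
* **Image mode** renders frames (default 2592 × 1944): one per-replicate
  mean intensity triplet is drawn from the intensity-level Gaussian
  (replicate-to-replicate scatter, matching the published SDs), then
  per-pixel texture noise (`texture_sd`, default 2.0 intensity units — a
  free knob describing sensor/texture noise, not constrained by the
  published summaries) is added inside the ROI; the surround is a dark
  constant. Pixels are rounded and clipped to [0, 255]; PNG output keeps
  tests bit-exact (JPEG export exists but is excluded from exact checks).

Reproducibility: each (sample, replicate) pair owns an RNG stream derived
from `(master seed, CRC32 of the tag, replicate index)`, so datasets are
bit-identical for a given seed and independent of generation order.

What the generator does **not** emulate: cross-channel noise correlation
(likely present in reality via common-mode illumination fluctuations),
vignetting, LED spectra, cuvette reflections, JPEG artifacts, and any
systematic drift between sessions. Consequences below.

## Classifier

Feature vector: `(a_R, a_G, a_B)` per replicate (the total is excluded as
linearly dependent). The observation unit is one image replicate (750
rows) by default; per-cuvette averaging (75 rows) is available via
`PipelineConfig(unit="cuvette")`.

1. **Min–max scaling** to [0, 1] per feature; constant features map to 0
   with a warning; validation data is not clipped.
2. **PCA**, 3 retained components, computed by SVD of the centered data;
   loadings sign-fixed (largest-magnitude element positive) for
   reproducibility. With the default 3-feature set this is a pure
   rotation; the explained-variance report is emitted for whatever feature
   set is configured.
3. **LDA**: Gaussian linear discriminant with pooled within-class
   covariance; prediction maximises
   `δ_k(x) = xᵀΣ⁻¹μ_k − ½μ_kᵀΣ⁻¹μ_k + ln π_k`; ties break toward the
   earlier class in the fixed order Silver < Aged < Extra-aged. Priors are
   equal by default (avoiding a bias toward the majority Aged class;
   proportional priors are a config option). If the pooled covariance is
   numerically singular (smallest eigenvalue ≤ 1e-12 · trace/d, which
   happens with exactly-replicated zero-noise data), a ridge
   `λI, λ = 1e-8 · trace/d` is added with a warning.

**Cross-validation** is leave-one-sample-out: all replicates of one bottle
form the validation set of one fold (25 folds on the full study). By
default the scaler and PCA are fitted once globally — mirroring the
exploratory-PCA-then-LDA sequence of the original workflow — and only the
LDA is refitted per fold; `fit_scope="per_fold"` refits everything inside
each fold and is the statistically preferred, leakage-free option. For
this 3-feature pipeline the two coincide (min–max and full-rank PCA are
affine maps, and LDA is affine-invariant), which the test suite confirms.

## Evaluation

From the pooled confusion matrix (rows = truth, columns = prediction,
aggregated over folds): per-class one-vs-rest sensitivity (= recall; the
"classification rate" in percent), specificity, precision (0 with a
warning for a never-predicted class), and accuracy, plus unweighted macro
averages. Cohen's kappa is computed in count form,
`κ = (N·Σmᵢᵢ − ΣGᵢCᵢ)/(N² − ΣGᵢCᵢ)`, which is asserted equal to
`(p_o − p_e)/(1 − p_e)` as an algebraic identity; κ < 0 is allowed
(worse-than-chance) even though the customary verbal bands start at 0.
Two secondary aggregations are reported because the primary one is not the
only defensible reading: per-fold-averaged class rates, and the mean of
per-fold kappas where defined (single-sample folds are usually degenerate:
κ is 1 when the fold is perfectly predicted and its denominator vanishes,
and mostly 0 otherwise).

## Fidelity of the synthetic reproduction

The deterministic aggregates reproduce the published table arithmetic
exactly: per-sample totals are the channel means to ±0.0001, the class
averages of the totals are 0.0644 / 0.0785 / 0.0931, and the macro Average
row of the published per-class metrics is 90.02% / 0.90 / 0.96.

The stochastic pipeline, however, measures lower classification rates than
those published for the original instrument data (seeds 1–10 averaged,
replicate-level recall): Silver ≈ 84.5% vs 100%, Aged ≈ 76.8% vs 91.67%,
Extra-aged ≈ 61.8% vs 78.40%, overall ≈ 74.4% vs 90.02%, pooled κ ≈ 0.62
vs 0.87. This gap is a property of what the published summaries can and
cannot determine, not of the classifier implementation (an independent
scikit-learn LDA run on identical folds reproduces our rates to the
replicate):

* Two Extra-aged samples (EA3, EA4) have mean fingerprints lying inside
  the Aged cloud of sample means. Under sample-level LOOCV a classifier
  trained without a sample cannot learn its idiosyncrasy, so those two
  samples are essentially unrecoverable, capping Extra-aged recall near
  60% at sample granularity — yet the published Extra-aged rate, 78.40%,
  is not an integer fraction of either 5 samples or 150 replicates, so the
  original aggregation cannot be reconstructed from the published table.
* The original PCA operated on a 30 × 75 data arrangement whose 3
  components carried 99.96% of the variance — a feature space with more
  than three inputs, hence different from (and richer than) the 3-channel
  summary fingerprints available here.
* Sampling channels independently puts replicate noise into the
  color-contrast directions that separate a neutral (R ≈ G ≈ B) Silver
  from slightly tinted samples; if real replicate noise is common-mode
  across channels, those directions are far quieter in the real data,
  which would raise Silver toward 100%.

The qualitative structure does transfer: Silver is the best-recovered
class, Aged loses exactly its one anomalous sample (A7, a pale Aged whose
fingerprint is Silver-like — matching the published 11/12), Extra-aged is
the hardest class, and specificity exceeds sensitivity throughout.
Passing tests therefore demonstrate correct arithmetic and a faithful
pipeline on data with the published first- and second-moment structure;
they do not certify the published headline rates, which depend on raw data
that is not available.

## Problem sizes

Default test and acceptance runs use the full study geometry (750
replicates, 25 folds) over ten seeds; the whole acceptance computation is
a few seconds on one CPU. Property tests use 100–1,000 small random
fixtures each. Image-mode tests render reduced frames except for one
full-size (2592 × 1944) check of the default ROI geometry.
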