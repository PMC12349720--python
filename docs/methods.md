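# Methods

## What the pipeline measures

The unit of analysis is a pair of 2-D tumor crops — a ground-truth (GT)
phase image of a four-phase renal CECT study and its imputed (or, here,
surrogate) counterpart — sharing one pixel grid and one tumor ROI.
All intensity work happens in Hounsfield Units after clipping to
[−150, 1000] HU; clipping precedes every statistic, including the
pixel-wise enhancement maps (post-contrast minus precontrast), because
the order changes extreme values. Enhancement-derived features are
undefined for the precontrast image itself and propagate as missing;
missing values are excluded pairwise from each statistic with counts
logged.

Feature concordance is summarized as per-feature agreement fractions
(13 categorical features), least-squares fits with R² = squared Pearson
correlation (8 quantitative features), and four-phase mean-ROI-intensity
profiles with signed and magnitude difference summaries. The signed
difference is oriented imputed − GT. The Hallucination Index of a pair
is the Hellinger distance between the tumor-ROI histograms of the two
clipped images. Diagnostic-feature scoring uses a fixed map of 6
benign-typical and 8 malignant-typical feature values; "exceeds"
thresholds are strict everywhere (mean enhancement > 10 HU,
longest dimension > 10 mm), so boundary values count toward the benign
side of the map.

## Phantom model

A phantom is a 128×128 crop (1 mm/px isotropic by default) containing
a parametric kidney — elliptical cortex/medulla/sinus compartments with
a pelvis disk at the hilum, on a perinephric-fat background — and a
parametric tumor. Compartment HU curves encode the qualitative phase
physiology: cortex peaks in the corticomedullary phase (180 HU),
cortex and medulla are jointly bright in the nephrographic phase,
the collecting system peaks in the excretory phase (250 HU), and all
soft tissue sits near muscle attenuation (~35 HU) before contrast.
All curves are configurable; the defaults are plausible round numbers,
not fits to data.

Tumor knobs and their realizations:

- **Phase curve** — mean HU of solid tumor tissue per phase; default
  (30, 80, 110, 90), an avidly enhancing mass.
- **Margin shape** — lobulated margins are a sinusoidal radial
  perturbation of the tumor ellipse (relative amplitude ~0.3, 7 lobes).
- **Margin definition** — infiltrative margins are rendered as an
  *outward* intensity fade (a renormalized Gaussian ramp of the stated
  width beyond the mask; the interior is untouched). A symmetric blur
  would contaminate interior ROI statistics and couple margin
  definition to enhancement pattern; the outward fade keeps the two
  knobs orthogonal.
- **Heterogeneity** — a smooth zero-mean Gaussian random field
  (correlation length ~2 px), scaled to SD = amplitude/2 over enhancing
  tumor tissue and added to the post-contrast phases only (the same
  field in each phase, mimicking enhancing tissue architecture).
- **Necrosis / fat** — interior disks covering the stated area
  fractions; necrotic tissue keeps its precontrast attenuation in every
  phase (non-enhancing), fat sits at −40 HU throughout.
- **Exophytic fraction** — the tumor center is placed by bisection
  along an outward ray until the mask fraction outside the kidney hits
  the target (±0.005).
- **Noise** — additive Gaussian HU noise before clipping, default
  7 HU in cohort simulation; the simplest CT-plausible model (no
  streaks, no beam hardening, no texture correlation).

The degradation simulator produces surrogate "imputed" images:
Gaussian blur → heterogeneity damping (shrinking ROI deviations toward
the ROI mean by a factor 1−d) → additive intensity bias → residual
Gaussian noise. An all-zero spec is the identity. Cohort defaults
(blur σ ∈ [0.5, 1.5] px, bias ~ N(0, 15 HU), damping ∈ [0, 0.3],
residual noise ∈ [2, 8] HU, drawn independently per phase) were chosen
once as a plausible error scale for a well-trained generative model —
large enough to flip image-derived categorical calls occasionally,
small enough to keep most features concordant. The simulated cohort
uses 37 studies (148 image pairs) with an 89% malignant case mix.

What the generator does **not** emulate: real anatomy (single
idealized kidney section, no neighboring organs), 3-D context, partial
volume effects, realistic imputation error structure (a cGAN's
residuals are spatially structured and content-dependent; the
degradation family is an explicit stand-in), or reader behavior.
Passing tests therefore demonstrate that the *pipeline* is correct and
internally consistent, not that any particular imputation model is
clinically adequate.

## Proxy classifiers

Categorical features of real images come from reader annotations; the
pixel-rule proxies exist so synthetic studies have a fully automatic
path, and are labeled `proxy` in the output's source field. Rules and
defaults (all config-exposed):

- *Enhancement pattern*: heterogeneous iff the CV of ROI enhancement
  exceeds 0.25 in any post-contrast phase; below a 10 HU mean the CV is
  unstable and an absolute SD cutoff (15 HU) is used instead.
- *Margin shape*: lobulated iff ROI area / convex-hull polygon area
  < 0.95. The hull is the polygon over pixel centers; a pixel-count
  hull image undershoots 0.95 even for perfect small ellipses.
- *Margin aggressiveness*: infiltrative iff the boundary is gradual.
  For each boundary pixel a ray is cast outward from the ROI centroid;
  the first value outside the ROI is compared with the tumor edge value
  and a far value 4 px further out, giving the fraction of local
  contrast lost immediately at the edge. Rays whose outside value falls
  outside the [edge, far] bracket cross an unrelated tissue interface
  and are discarded. The measure is computed on difference images
  between post-contrast phase pairs — intratumoral texture is largely
  shared across phases and cancels there, while the margin profile
  survives. Median over rays < 0.75 ⇒ infiltrative (sharp phantom
  edges score 1.0, 3–5 px fades score ≤ 0.55).
- *Composition*: cystic iff precontrast ROI mean < 20 HU and no phase
  has mean enhancement ≥ 10 HU. Necrosis: a connected non-enhancing
  (< 10 HU mean enhancement), non-fat subregion covering ≥ 5% of an
  otherwise-enhancing ROI. Fat: ≥ 1% of ROI pixels below −10 HU on
  precontrast.
- *Location*: exophytic category from the mask fraction outside the
  kidney (endophytic ≤ 0.005, half-and-half within ±0.05 of 0.5);
  medial/lateral from the ROI centroid relative to the kidney centroid
  along the hilum axis; depth from the majority-overlap compartment
  (cortex → cortical, medulla → corticomedullary, sinus → sinus);
  pelvis invasion from any mask overlap with the pelvis.

These cutoffs were designed against a 33-point grid of noiseless,
well-separated phantoms on which the proxies must recover the
constructed truth exactly (a standing test). They are not claimed to
match radiologist judgment on patient images.

## Statistical choices

- Binomial agreement tests are exact, two-sided by the
  minimum-likelihood method, against a default null of 0.5 (the paper
  names the test but not the null; 0.5 is the conservative
  chance-agreement choice and is config-exposed).
- The two-proportion z-test uses the pooled-variance form; a pooled
  proportion of exactly 0 or 1 leaves the statistic flagged undefined.
- Wilcoxon rank-sum uses midranks; the exact null distribution when
  the combined sample is ≤ 20 without ties, a tie-corrected normal
  approximation otherwise. Benjamini–Hochberg adjustment is the
  standard step-up procedure. (BH is not idempotent in general — a
  re-adjusted family can change — so only monotonicity and order
  preservation are asserted as invariants.)
- Weighted κ uses disagreement weights |i−j|/(k−1) (linear default;
  quadratic available); PABAK is (k·Pₒ−1)/(k−1) with k = 2 on scores
  dichotomized at 2 (score < 2 ⇒ "dissimilar") by default, since the
  published reliability analysis reports a thresholded value. CIs are
  seeded nonparametric bootstrap percentile intervals (2000 resamples)
  rather than asymptotic formulas.
- The rater-score summary pools all (image, rater) scores for the mean;
  "fraction below 2" aggregates raters by each image's mean score
  (the aggregation rule is not published; mean is the documented
  default).
- Histograms use 64 uniform bins over [−150, 1000] HU with edges
  shared within each pair (shared edges are what make the Hellinger
  distance meaningful); empty bins contribute nothing (no smoothing by
  default). Cohort variance of the index is the population variance.
  Identical histograms score exactly 0 (short-circuited ahead of
  floating-point mass sums).
- Lesion size is automated from the mask: d1 is the maximum pairwise
  distance between ROI pixel centers (max Feret diameter, via the
  convex hull), d2 the perpendicular extent, both floored at one pixel
  spacing (a single-pixel ROI reports d1 = d2 = spacing); accuracy is
  ±1 px against the continuous shape. SD analyses use the population
  SD over the tumor ROI by default (`full_crop` available; the
  published analysis does not state which region was used).

## Problem sizes

The standing test suite and the acceptance script run the full design
size — 37 studies / 148 image pairs — for cohort-level checks, a
33-phantom grid for parameter recovery, 1000 simplex pairs for the
Hellinger oracle, and 2000 simulated datasets per test for type-I-error
calibration; these sizes make every check complete in seconds while
keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

- The degradation family cannot reproduce structured generative-model
  failure modes (anatomically plausible hallucinations); the
  Hallucination Index is exercised against blur/bias/noise only.
- Proxy margin aggressiveness depends on tumor-vs-surround contrast;
  on low-contrast real images it will be noisy (mirroring the low
  reader agreement reported for that feature).
- Phantoms are single 2-D slices; features defined "in any plane"
  reduce to in-plane definitions.
- The published inter-rater table cannot be reproduced from its own
  printed marginals under either k = 2 or k = 5 (the printed PABAK and
  total agreement are mutually inconsistent), so rater reliability is
  validated against algebraic identities and simulations instead.
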