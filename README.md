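# cectfidelity

Clinical-fidelity evaluation of imputed four-phase renal CECT images.

Renal masses are characterized on four-phase contrast-enhanced CT
(precontrast, corticomedullary, nephrographic, excretory). When one
phase is missing or corrupted, generative models can impute it from the
other three — but an imputed image is only useful if it preserves the
features a radiologist actually reads. This package measures that: it
extracts the 21 clinically relevant features of a tumor crop
(13 categorical, e.g. enhancement pattern, margin shape and
aggressiveness, composition, necrosis, fat, location; 8 quantitative,
e.g. ROI intensity and enhancement statistics and lesion dimensions)
from paired ground-truth/imputed images and quantifies their
concordance. It is aimed at researchers evaluating medical image
synthesis and imputation models.

## The statistics at its core

- **Feature concordance.** Per-feature agreement fractions over paired
  images (exact binomial test against a configurable null), pooled and
  per phase; least-squares fits with R² (squared Pearson correlation)
  for quantitative features; four-phase mean-ROI-intensity profiles
  with signed (imputed − GT) and magnitude difference summaries.
- **Diagnostic-feature scoring.** A fixed map of 6 benign-typical and
  8 malignant-typical feature values; the fraction of images showing
  the value typical of their diagnosis, compared GT vs imputed by a
  pooled two-proportion z-test.
- **Hallucination Index.** The tumor region of each image is reduced
  to a histogram of HU values (64 shared bins over the clipped range
  [−150, 1000] HU) and each pair scored by the Hellinger distance
  H(p,q) = √(1 − Σᵢ √(pᵢqᵢ)) ∈ [0, 1]: 0 = identical distributions,
  1 = no overlap.
- **Rater reliability.** 1–5 similarity scores summarized per phase;
  inter-rater agreement by weighted Cohen's κ (linear or quadratic
  weights) and PABAK = (k·Pₒ − 1)/(k − 1), with seeded bootstrap CIs.

Because patient data cannot ship with the package, a **synthetic
phantom generator** renders 128×128 HU-valued four-phase kidney crops
with fully known feature truth (margin shape/definition, heterogeneity,
necrosis, fat, cystic composition, exophytic fraction, side, depth,
pelvis invasion, size), and a **degradation simulator** (blur, bias,
heterogeneity damping, noise) stands in for imputation error. Every
stage of the pipeline is exercised end to end against this known truth.

## Worked example

```python
from cectfidelity import (PhantomSpec, DegradationSpec, render_phantom,
                          apply_degradation, assemble_features, hallucination_index)

spec = PhantomSpec(heterogeneity=40.0, necrosis_fraction=0.2,
                   margin_shape="lobulated", lobulation_amplitude=0.3)
study = render_phantom(spec, seed=42)
fv = assemble_features(study, "nephrographic")
print("pattern:", fv.enhancement_pattern, "| margins:", fv.margin_shape, fv.margin_aggressiveness)
print("necrosis:", fv.necrosis, "| d1 = %.1f mm" % fv.d1_mm, "| mean enh = %.1f HU" % fv.mean_enh)

surr = apply_degradation(study, "nephrographic",
                         DegradationSpec(blur_sigma=1.0, intensity_bias=15.0,
                                         residual_noise_sigma=5.0, seed=0))
print("HI: %.3f" % hallucination_index(study["nephrographic"], surr, study.tumor_roi))
```

prints

```
pattern: heterogeneous | margins: lobulated well_marginated
necrosis: present | d1 = 24.0 mm | mean enh = 63.3 HU
HI: 0.317
```

The proxy classifiers recover the phantom's constructed truth (a
heterogeneous, necrotic, lobulated but sharp-edged 24 mm enhancing
mass), and a mildly blurred, biased surrogate of the nephrographic
image scores a Hallucination Index of 0.317 — intensity distributions
clearly perturbed, far from disjoint.

A full run (simulation → features → concordance → diagnosis map → HI →
reliability) is one call:

```python
from cectfidelity import RunConfig, run_pipeline
results = run_pipeline(RunConfig(n_studies=37, seed=1, output_dir="results/demo"))
```

or from the shell: `cectfidelity report --seed 1 --out results/demo`
(see also the `simulate`, `extract`, `evaluate` and `reliability`
subcommands, and `examples/demo_config.yaml`).

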