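# octspeckle

Quantitative analysis of endoscopic OCT B-scans of brain tissue:
per-A-scan attenuation coefficients, wavelet-domain speckle features, and
Fisher linear discriminant analysis for distinguishing glioma from intact
cortex and white matter.

## The problem

Optical coherence tomography can flag brain-tumor margins during
neurosurgery, classically through the tissue attenuation coefficient μ:
in the single-scattering approximation the OCT signal decays as
`I(z) = I0·exp(−μ z)` with depth, and myelinated white matter attenuates
much faster than glioma. But μ alone fails for several tissue pairs
(cortex vs tumor, high-grade glioma vs intact tissue). The speckle
pattern — the granular interference texture produced by sub-resolution
scatterers — carries complementary structural information. This package
implements a pipeline that extracts both feature families and evaluates
how their combinations discriminate tissue classes:

* **Attenuation**: each A-scan (image column) is fitted with a
  two-segment model — an exponential decay above a noise floor, with the
  decay/noise boundary `z_noise` chosen by minimizing
  `SSE_decay/N_decay + SSE_noise/N_noise` over all admissible
  boundaries. Image features are the mean attenuation μ (1/mm) and
  σ_μ, the mean sliding-window lateral standard deviation of the
  per-column μᵢ (window 150 µm ≈ one vessel calibre ≈ 30 A-scans at the
  native 4.9 µm pitch).
* **Speckle**: the ROI is decomposed with the 2-D discrete wavelet
  transform (*bior3.5*, symmetric extension). At levels a = 1, 2 the
  power of local brightness fluctuations
  `P_a = (Σ|HDC|² + Σ|VDC|² + Σ|DDC|²)/K` (K = detail-array pixel
  count) and its lateral standard deviation σ_Pa form the speckle
  feature space.
* **Classification**: for each pair of tissue classes and each of 15
  feature combinations (μ, P₁, P₂ singly, with their dispersions, and
  mixed), a Fisher LDA direction `w` solving `S_W w = m₂ − m₁` is fitted,
  a threshold maximizing sensitivity + specificity is selected, and
  performance is estimated by patient-grouped k-fold cross-validation
  (all scans of a patient stay on one side of every split), reporting
  Se/Sp/Pr and ROC/AUC.

Because clinical OCT data of this kind are not publicly available, the
package includes a first-class synthetic generator producing OCT-like
B-scans — exponential decay with laterally correlated μ heterogeneity,
multiplicative speckle with controllable grain and contrast, an additive
noise floor and a bright probe/glass interface band — organized into
patient-structured cohorts, so the entire pipeline is testable end to
end.

## Worked example

```python
from octspeckle import PipelineConfig, generate_cohort, grouped_kfold_cv
from octspeckle.pipeline import extract_features, preprocess_scan

config = PipelineConfig(
    classes={
        "white_matter": {"mu_mean": 8.0, "n_patients": 3, "n_scans": 4},
        "glioma": {"mu_mean": 4.0, "n_patients": 3, "n_scans": 4},
    },
    geometry={"n_lateral": 200, "n_axial": 256},
    seed=1,
)
scans = generate_cohort(config.cohort_spec())
rois = [preprocess_scan(s, config) for s in scans]
features = extract_features(rois, config)
print(features.groupby("label")[["mu", "sigma_mu", "p1", "p2"]].mean().round(4))

result = grouped_kfold_cv(features, ("mu", "p1", "p2"), positive_label="glioma")
print(result.summary())
```

prints

```
                  mu  sigma_mu      p1      p2
label
glioma        4.0149    0.6206  0.0001  0.0051
white_matter  7.4484    0.9254  0.0001  0.0039

Fisher LDA, features [mu, p1, p2], positive = glioma vs white_matter
patient-grouped 3-fold CV (3 folds used, 0 skipped)
  Se = 1.000   Sp = 1.000   Pr = 1.000   AUC = 1.000
```

The recovered image-mean attenuations sit close to the generating values
(4 and 8 1/mm; the white-matter mean is pulled slightly low by the noise
floor and per-patient jitter), and with this much attenuation contrast
the combined feature set separates every held-out patient, so all
averaged metrics are 1. `evaluate_combinations(features)` runs the same
cross-validation for all 15 feature combinations and marks the best one
per tissue pair.

The same pipeline is scriptable from the shell:

```bash
octspeckle run-all --config config.yaml --seed 1 --out runs/demo
```

with subcommands `simulate`, `preprocess`, `features`, `evaluate` for
stage-by-stage runs on TIFF/CSV inputs.

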