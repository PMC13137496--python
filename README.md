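# dtialps

Tools for the **DTI-ALPS** index — "diffusion tensor image analysis
along the perivascular space" — a non-invasive proxy for glymphatic
(perivascular) water movement extracted from routine diffusion MRI,
studied as a severity marker in Lewy body dementia (dementia with Lewy
bodies, Parkinson's disease dementia) against Parkinson's with normal
cognition and controls.

The package is aimed at neuroimaging methods researchers who want a
fully testable ALPS pipeline: every estimator can be run against
synthetic data with known ground truth.

It provides:

* **Phantom simulation** — multi-tensor diffusion phantoms with the
  periventricular geometry ALPS assumes (y-oriented association
  fibres, z-oriented projection fibres, an x-axis perivascular
  compartment, optional crossing fibres), the study's four-shell
  acquisition (b = 50/17, 300/8, 1000/64, 2000/64), Rician noise, and
  analytic ground truth.
* **Tensor fitting** — log-linear least squares with one weighted
  re-fit; scanner-frame diagonal maps Dxx/Dyy/Dzz.
* **The ALPS index** —

  `ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)`

  per hemisphere and bilaterally, from spherical ROI specs or masks.
* **Fixel complexity** — single-shell constrained spherical
  deconvolution, watershed fixel segmentation, and the [0,1]
  complexity metric (0 = one fibre bundle, 1 = equal crossing
  bundles) used to control for white-matter distribution.
* **Clinical scores** — composite cognitive z-score, configurable
  NPI-4 estimate, LBD symptom composite, vascular-risk total (0–7),
  total SVD burden (0–4), and cohort inclusion filters.
* **Statistics** — ANCOVA with planned pairwise contrasts,
  covariate-adjusted Cohen's d, Benjamini–Hochberg FDR, nested
  regressions with VIF, paired hemisphere t-test, Kruskal–Wallis /
  rank-sum with Dunn post-hoc, plus Monte-Carlo calibration of type-I
  error and effect-size recovery.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
from dtialps import (PhantomConfig, build_alps_phantom, ground_truth_alps,
                     fit_tensor, axis_diffusivities, compute_alps,
                     simulate_cohort, ancova_omnibus, planned_contrasts)
from dtialps.pipeline import phantom_rois

# phantom at Rician SNR 30 with a 10% perivascular x-axis compartment
ph = build_alps_phantom(PhantomConfig())
truth = ground_truth_alps(ph)                      # analytic oracle
maps = axis_diffusivities(fit_tensor(ph.signal, ph.gtab))
res = compute_alps(maps, phantom_rois(ph.config))  # fitted pipeline
print(f"truth {truth['alps']:.4f}  fitted {res.alps:.4f}")
# truth 1.5161  fitted 1.5089

# four-group synthetic cohort (26 / 60 / 35 / 51) and group statistics
df = simulate_cohort(seed=7)
o = ancova_omnibus(df, "alps")                     # controls age + sex
print(f"F({o.df1}, {o.df2}) = {o.F:.2f}, p = {o.p:.3g}")
# F(3, 166) = 13.04, p = 1.08e-07
for c in planned_contrasts(df, "alps"):
    print(f"{c.label}: F = {c.F:.1f}, p_FDR = {c.p_fdr:.2g}, d = {c.d:.2f}")
# control vs PD-NC: F = 0.5, p_FDR = 0.48, d = 0.17
# PD-NC vs PDD:     F = 9.0, p_FDR = 0.0068, d = -0.81
# PD-NC vs DLB:     F = 23.0, p_FDR = 3.1e-05, d = -1.40
# PDD vs DLB:       F = 7.3, p_FDR = 0.013, d = -0.60
```

The ground-truth ALPS of 1.516 comes from the analytic voxel-average
tensors; the fitted value agrees to 0.5% at SNR 30 (and to machine
precision without noise).  In the cohort, the omnibus F tests the
group effect on ALPS controlling for age and sex; each planned
contrast is a two-group ANCOVA whose Cohen's d is the
covariate-adjusted mean difference over the pooled residual SD
(negative d: the second-named group has lower ALPS).

A command-line interface mirrors the library:

```sh
alps simulate-phantom --seed 1 --out phantom/
alps fit-tensor --dwi phantom/dwi.nii.gz --bval phantom/dwi.bval \
                --bvec phantom/dwi.bvec --out maps/
alps index --dxx maps/dxx.nii.gz --dyy maps/dyy.nii.gz \
           --dzz maps/dzz.nii.gz --rois rois.yaml --out alps.csv
alps simulate-cohort --seed 17 --out cohort.csv
alps stats --cohort cohort.csv --out stats/
alps run --seed 0 --out results/       # full pipeline + manifest
```

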