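# rpvkit

3D CT radiomics for segmented tumor volumes and the **Radiomic
Prognostic Vector (RPV)** — a four-feature survival score for high-grade
serous ovarian cancer — together with the signature-discovery pipeline
that produces such scores and the robustness analyses that audit them.

Epithelial ovarian cancer has a five-year survival around 35-40%, and the
clinical factors available at presentation (stage, age, residual disease)
stratify patients poorly. Radiomics offers a non-invasive alternative:
mathematical descriptors of the preoperative contrast-enhanced CT of the
primary tumor, computed from the radiologist's segmentation. `rpvkit` is
for imaging researchers and biostatisticians who want to

* extract the full **657-descriptor radiomic profile** of a segmented 3D
  CT volume — shape/size, first-order intensity, GLCM / GLRLM / NGTDM
  texture, and box-counting fractal features, on the original image and
  on 8 coiflet-1 wavelet sub-bands at the 25-HU gray-level quantization;
* compute **RPV** with its published coefficients and risk boundaries:

  ```
  RPV = -0.0876 * FD_max_25HUgl
        + 0.0869 * GLRLM_SRLGLE_LLL_25HUgl
        + 0.165  * NGTDM_Contra_HLL_25HUgl
        + 0.250  * FOS_Imedian_LHH
  ```

  with risk groups low < 0.0950 <= medium < 0.658 <= high, and the
  higher-RPV tumor selected for bilateral disease;
* re-run **signature discovery** on any cohort: adjusted univariate Cox
  screen with Benjamini-Hochberg FDR control, LASSO-penalized Cox with
  the penalty at minimum 10-fold cross-validated partial-likelihood
  deviance, 1D k-means risk grouping, and prognostic evaluation (hazard
  ratios, concordance index, log-rank, Kaplan-Meier);
* audit **robustness**: RPV stability under mask erosion/dilation (-4 to
  +4 voxels), feature-wise correlation reproducibility across cohorts,
  and PCA-based batch screening;
* generate **synthetic phantoms and cohorts** (solid rim + cystic core
  ellipsoids; block-correlated proportional-hazards cohorts with planted
  signatures) so every stage is testable without patient data.

## Worked example

```python
import rpvkit

# a synthetic 64^3 tumor phantom and its segmentation
volume, mask = rpvkit.default_phantom()

features = rpvkit.extract_all(volume, mask)
print(len(features))                                 # 657
print(round(features["FOS_Imedian_LHH"], 4))         # 0.1344

score = rpvkit.compute_rpv(features)
print(round(score, 4), rpvkit.assign_risk_group(score))  # -0.193 low
```

The phantom's RPV of -0.19 falls below the 0.0950 boundary: a low-risk
tumor. Discovery on a simulated cohort with a known 4-feature signature:

```python
from rpvkit.discovery import univariate_cox_screen, lasso_cox_select
cohort = rpvkit.default_cohort()                    # n=400, 42 candidates
screen = univariate_cox_screen(cohort)
print(len(screen.passing_features))                 # 9   (FDR < 0.05)
model = lasso_cox_select(cohort, screen.passing_features, seed=0)
print({"feat_01", "feat_07", "feat_13", "feat_19"} <= set(model.features))
# True ... the selected set contains the planted signature
```

The same operations are available from the shell:

```bash
rpv simulate phantom --seed 4 --out phantom/
rpv extract --volume phantom/phantom.nii.gz --mask phantom/phantom_mask.nii.gz --out features.csv
rpv score --features cohort_features.csv --out scores.csv
rpv discover --cohort cohort.csv --fdr 0.05 --folds 10 --seed 1 --out-dir run/
rpv perturb --volume v.nii.gz --mask m.nii.gz --range -4:4 --out stability.csv
```

Every command writes a JSON manifest (resolved configuration, input
checksums) next to its outputs.

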