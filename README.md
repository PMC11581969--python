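# habitatrad

Habitat radiomics for two-phase contrast-enhanced CT: partition each tumor
into intratumoral subregions ("habitats"), extract IBSI-style radiomic
features per habitat and for the whole tumor, reduce them through a staged
selection funnel, and compare subregion-aware against whole-tumor
classifiers of an immunohistochemical label (Tim-3 expression in
hepatocellular carcinoma). A pathology arm computes IHC H-scores and
survival-optimal expression cutoffs, and a synthetic-cohort generator with
planted habitats provides ground truth for every stage.

## Who this is for

Researchers building or stress-testing subregion ("habitat") radiomics
pipelines: the package gives them a fully seeded, end-to-end
implementation — preprocessing, SLIC + K-means habitat generation with
cross-patient label harmonization, feature extraction and selection, five
classifier families with discrimination/calibration/decision-curve
evaluation — plus a generator that plants known subregional structure so
each stage can be validated against truth.

## The method in brief

Per patient, with co-registered arterial (ACE) and venous (VCE) volumes
and a tumor mask:

1. **Preprocess** — clip to the −200..300 HU window, map to [0, 1],
   resample to 1 mm isotropic voxels.
2. **Habitats** — SLIC superpixels on the joint (ACE, VCE) image inside
   the ROI; K-means (K = 3) on standardized superpixel intensity profiles;
   merge components smaller than 64 voxels; harmonize labels across
   patients by ranking clusters on mean arterial intensity (ReMap), so
   habitat 1 is always the least-enhancing subregion.
3. **Features** — first-order, 3D shape, and GLCM/GLRLM/GLSZM/NGTDM
   texture features (F = 75 per region and phase, fixed 25 HU bins), for
   the whole ROI (Rad signature, 2F columns) and per habitat (Habitat
   signature, 2·K·F columns), fused across phases by column concatenation.
4. **Selection** — ICC(2,1) ≥ 0.85 robustness (when re-segmentation data
   exist; skipped for habitat signatures), Shapiro-Wilk screen, Pearson
   pruning at |r| > 0.9, then LASSO with 10-fold CV (λ at minimum mean CV
   error). Stages are strictly nested and fitted on the training split only.
5. **Models** — logistic regression, random forest, extra trees, XGBoost,
   LightGBM on a stratified 70/30 split; ROC/AUC with bootstrap CI,
   calibration + Hosmer-Lemeshow, decision curves
   (net benefit = TP/n − (FP/n)·p_t/(1−p_t)), stratified 5-fold CV.

The pathology arm scores IHC fields as
H-score = 3·%high-positive + 2·%positive + 1·%low-positive ∈ [0, 300],
dichotomizes at 92.3 (boundary in the low group), and re-implements the
X-tile idea as an exhaustive max-log-rank-chi-square cutoff scan with a
10 % minimum group size.

See `docs/methods.md` for assumptions, defaults, and what the synthetic
generator does and does not emulate.

## Worked example

```python
from habitatrad.pipeline import run_signature_comparison
from habitatrad.pathology import h_score, dichotomize, optimal_cutoff

# whole pipeline on one synthetic cohort (102 patients, ~1 min)
res = run_signature_comparison(seed=1)
rad, hab = res["rad"], res["habitat"]
print(f"Rad     best={rad.best_algorithm:19s} test AUC={rad.test_auc:.3f}")
print(f"Habitat best={hab.best_algorithm:19s} test AUC={hab.test_auc:.3f}")
print("habitat signature:", hab.selected_features[:3], "...")

# pathology arm
print(h_score((50, 30, 20, 0)), dichotomize(h_score((50, 30, 20, 0))))
clin = res["clinical"]
cut, chi2, p = optimal_cutoff(clin["h_score"], clin["os_months"],
                              clin["os_event"])
print(f"survival-optimal H-score cutoff {cut:.1f} (chi2={chi2:.2f})")
```

prints

```
Rad     best=lightgbm            test AUC=0.775
Habitat best=xgboost             test AUC=0.942
habitat signature: ['ACE__habitat2__glrlm__long_run_emphasis_high_gl', 'ACE__habitat3__glcm__inverse_difference', 'ACE__habitat3__glcm__asm'] ...
230.0 high
survival-optimal H-score cutoff 209.0 (chi2=14.81)
```

The habitat signature outperforms the whole-tumor signature because the
synthetic Tim-3 signal exists only as subregional organization — an
arterial-phase texture exchange between two habitats plus a compensated
mean shift — which whole-ROI statistics marginalize away; accordingly the
selected features concentrate in the arterial-phase habitat texture
blocks. H-score arithmetic:
3·50 + 2·30 + 1·20 = 230 > 92.3 → "high". The cutoff scan finds a strong
survival split because the generator ties survival hazard to the Tim-3
class (hazard ratio 2.2), which the H-score tracks.

A command-line interface mirrors the library:

```bash
habitatrad simulate --out cohort --seed 3 --n-patients 20
habitatrad preprocess --ace cohort/P0000/ace.nii.gz \
    --vce cohort/P0000/vce.nii.gz --roi cohort/P0000/roi.nii.gz --out prep/P0000
habitatrad habitats --cohort prep --k 3 --seed 0
habitatrad features --cohort prep --mode habitat --out features.csv
habitatrad select --table features.csv --labels cohort/clinical.csv
habitatrad pathology --clinical cohort/clinical.csv --cutoff auto
```

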