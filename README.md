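# papkit

Non-invasive assessment of pulmonary artery pressure (PAP) from cardiac CT
morphometry. `papkit` implements the full analysis chain a CTPA-based
pulmonary-hypertension study needs once substructure segmentations exist:

* **mask refinement** — a contour-intensity self-attention classifier that
  decides whether a candidate mask is well placed, and an iterative
  resize-until-accepted loop that fixes over- and under-segmentations;
* **morphometry** — the 16 standard features from an eight-substructure
  label map (LV, RV, LA, RA, MPA, LPA, RPA, AA): axial diameters
  (equivalent-circle for vessels, maximum Feret for chambers), chamber
  areas, and the ratios MPAd/AAd, RPAd/LPAd, RVd/LVd, RAd/LAd;
* **feature selection** — Spearman screen (p < 0.05), pairwise Pearson
  prune at |r| > 0.9 keeping the feature better correlated with the
  target, standardization, PCA at 95% explained variance;
* **PAP models** — depth-3 gradient-boosted trees for mPAP/sPAP/dPAP/TPR
  regression and for severity classification at the clinical cutoffs
  (mPAP ≥ 40 mmHg, sPAP ≥ 55 mmHg), under repeated stratified 10-fold
  cross-validation with fold-internal feature selection;
* **agreement statistics** — Dice, paired t (including reconstruction from
  printed summaries), Bland–Altman limits of agreement, Spearman/Pearson
  with exact small-sample p, two-way mixed consistency ICC
  (ICC_single = (MSR−MSE)/(MSR+(k−1)·MSE), ICC_average = 1 − 1/F,
  Spearman–Brown step-up), ROC/AUC via the rank-sum statistic;
* **phantoms** — a synthetic thoracic cohort (ellipsoid chambers,
  cylindrical vessels, CT-like intensities with blur and noise) whose
  hemodynamics match a real PH cohort's moments (mPAP 42.82 ± 12.74 mmHg,
  sPAP 68.35 ± 20.62 mmHg) and whose geometry plants the clinically
  reported correlation signs (left atrium shrinks, RVd/LVd and RAd/LAd
  grow with pressure), so the entire pipeline is testable without any
  patient data.

Intended users: researchers in cardiovascular image analysis who need a
tested, reproducible reference implementation of this pipeline or of its
agreement-statistics battery.

## Worked example

```python
from papkit import phantom
from papkit.experiments import cohort_recovery

cohort = phantom.synth_cohort(120, seed=5)          # render + measure
res = cohort_recovery(n=120, seed=5, repeats=3, null_repeats=1,
                      cohort=cohort)
```

prints (via `python examples/05_pap_prediction.py`):

```
cohort: 120 patients, out-of-fold results over 3 repeats
mPAP regression:  ICC(pred, true) = 0.855, MSE = 39.7 mmHg^2
severity (mPAP >= 40 mmHg):  AUC = 0.932 (p = 4.4e-16), sens = 0.84, spec = 0.94
permuted-label null:  ICC = +0.082, AUC = 0.438
```

The ICC row says the cross-validated predictions agree with the true
pressures well beyond chance (a consistency ICC of 0.855 between predicted
and catheterization-style ground truth); the AUC row is the severity
triage performance at the 40 mmHg cutoff; the null row repeats the whole
procedure with shuffled targets and collapses to chance, showing the
cross-validation leaks nothing.

Each script in `examples/` is a self-contained capability demo: phantom
generation (`01`), mask refinement (`02`, mean Dice 0.748 → 0.927 over six
degraded cases), morphometry against planted geometry (`03`), the
selection chain (`04`), PAP prediction (`05`) and the statistics battery
(`06`).

A thin CLI mirrors the library:

```bash
papkit phantom --n 55 --seed 0 --out cohort_dir
papkit measure --labels labels.nii.gz --out features.csv
papkit select  --cohort cohort.csv --target mPAP --out report.json
papkit train   --cohort cohort.csv --target mPAP --task regression --out cv.json
papkit stats   icc --in pairs.csv --out icc.json
papkit refine  --image v.nii.gz --mask m.nii.gz --model clf.json --out r.nii.gz
```

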