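"""Predict pulmonary artery pressure from phantom CT features.

Depth-3 gradient-boosted trees under repeated stratified 10-fold CV, with
the feature-selection chain re-fit inside every training fold.
"""

from papkit import phantom
from papkit.experiments import cohort_recovery

cohort = phantom.synth_cohort(120, seed=5)
res = cohort_recovery(n=120, seed=5, repeats=3, null_repeats=1,
                      cohort=cohort)

print(f"cohort: {res['n']} patients, out-of-fold results over 3 repeats")
print(f"mPAP regression:  ICC(pred, true) = {res['regression_icc']:.3f}, "
      f"MSE = {res['regression_mse']:.1f} mmHg^2")
print(f"severity (mPAP >= 40 mmHg):  AUC = {res['classification_auc']:.3f} "
      f"(p = {res['classification_auc_p']:.2g}), "
      f"sens = {res['sensitivity']:.2f}, spec = {res['specificity']:.2f}")
print(f"permuted-label null:  ICC = {res['null_icc'][0]:+.3f}, "
      f"AUC = {res['null_auc'][0]:.3f}")
print("(the null run shuffles the target through the identical machinery; "
      "ICC near 0 and AUC near 0.5 show the CV leaks nothing)")
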