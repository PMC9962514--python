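"""End-to-end phantom experiments.

Two desk-scale experiments exercise the whole pipeline on synthetic data:

* :func:`refinement_experiment` — train the positive-mask classifier on
  phantom ground truth vs. degraded masks, then refine fresh degraded masks
  and compare Dice against truth before and after;
* :func:`cohort_recovery` — generate a measured phantom cohort, run the
  fold-internal selection + boosted-tree CV, and report out-of-fold ICC for
  mPAP regression and AUC for cutoff-40 classification, together with a
  permuted-label null as a leakage guard.
"""

from __future__ import annotations

import numpy as np

from . import phantom, refine
from .agreestats import dice
from .featsel import SelectionPipeline
from .pappredict import label_by_cutoff, repeated_cv
from .volio import FEATURE_COLUMNS


def _phantom_case(severity_seed: int, case_seed: int,
                  shape=(96, 96, 96), spacing=(1.5, 1.5, 1.5)):
    hemo = phantom.synth_hemodynamics(1, seed=severity_seed)[0]
    geom = phantom.synth_geometry(hemo, seed=case_seed)
    return phantom.render_phantom(geom, shape=shape, spacing=spacing,
                                  seed=case_seed)


def refinement_experiment(n_train: int = 10, n_test: int = 20, seed: int = 0,
                          structure: str = "MPA",
                          shape=(96, 96, 96), spacing=(1.5, 1.5, 1.5),
                          degrade_magnitude: int = 2,
                          max_iter: int = 10) -> dict:
    """Train on phantom positives/negatives, refine degraded test masks.

    Positives are ground-truth masks of ``structure``; negatives are the
    same masks eroded and dilated by ``degrade_magnitude`` voxels.  Test
    cases start from an eroded (even case index) or dilated (odd) mask.
    Returns per-case Dice before/after, scores before/after and iteration
    counts.
    """
    rng = np.random.default_rng(seed)
    positives, negatives = [], []
    for i in range(n_train):
        cs = int(rng.integers(0, 2**31 - 1))
        vol, lab = _phantom_case(seed * 1000 + i, cs, shape, spacing)
        truth = lab.mask(structure)
        positives.append((vol, truth))
        for mode in ("erode", "dilate"):
            bad = phantom.degrade_mask(lab, structure, mode,
                                       degrade_magnitude, seed=cs)
            negatives.append((vol, bad))
    clf = refine.train_classifier(positives, negatives, seed=seed)

    results = {"dice_before": [], "dice_after": [], "score_before": [],
               "score_after": [], "iterations": [],
               "train_accuracy": clf.train_accuracy}
    for j in range(n_test):
        cs = int(rng.integers(0, 2**31 - 1))
        vol, lab = _phantom_case(seed * 2000 + 500 + j, cs, shape, spacing)
        truth = lab.mask(structure)
        mode = "erode" if j % 2 == 0 else "dilate"
        start = phantom.degrade_mask(lab, structure, mode,
                                     degrade_magnitude, seed=cs)
        s0 = refine.score_mask(clf, vol, start)
        refined, iters, s1 = refine.refine_mask(clf, vol, start,
                                                max_iter=max_iter)
        results["dice_before"].append(dice(start, truth))
        results["dice_after"].append(dice(refined, truth))
        results["score_before"].append(s0)
        results["score_after"].append(s1)
        results["iterations"].append(iters)
    for key in ("dice_before", "dice_after"):
        results[f"mean_{key}"] = float(np.mean(results[key]))
    return results


def cohort_recovery(n: int = 200, seed: int = 0, folds: int = 10,
                    repeats: int = 20, cutoff_target: str = "mPAP",
                    shape=(96, 96, 96), spacing=(1.5, 1.5, 1.5),
                    null_repeats: int = 2,
                    cohort=None) -> dict:
    """Pipeline parameter-recovery on a measured phantom cohort.

    Regression: out-of-fold ICC between predicted and true mPAP.
    Classification: out-of-fold AUC at the 40 mmHg mPAP cutoff.
    A permuted-label run (same machinery, shuffled targets) provides the
    leakage-guard null.  Pass a prebuilt ``cohort`` to reuse one table.
    """
    if cohort is None:
        cohort = phantom.synth_cohort(n, seed=seed, shape=shape,
                                      spacing=spacing)
    df = cohort.df.dropna(subset=FEATURE_COLUMNS + ["mPAP"]).reset_index(drop=True)
    y = df["mPAP"].to_numpy(dtype=float)
    frame = df[FEATURE_COLUMNS + ["mPAP"]]

    def make_selector():
        return SelectionPipeline(target="mPAP")

    reg = repeated_cv(None, y, task="regression", folds=folds,
                      repeats=repeats, seed=seed,
                      selector_factory=make_selector,
                      feature_frame=frame, target="mPAP")

    labels, keep = label_by_cutoff(y, which=cutoff_target)
    frame_cls = frame.loc[keep].reset_index(drop=True)
    clf = repeated_cv(None, labels.astype(float), task="classification",
                      folds=folds, repeats=repeats, seed=seed,
                      selector_factory=make_selector,
                      feature_frame=frame_cls, target="mPAP")

    rng = np.random.default_rng(seed + 7)
    null_auc, null_icc = [], []
    for r in range(null_repeats):
        y_perm = rng.permutation(y)
        frame_perm = frame.copy()
        frame_perm["mPAP"] = y_perm
        reg_null = repeated_cv(None, y_perm, task="regression", folds=folds,
                               repeats=1, seed=seed + 100 + r,
                               selector_factory=make_selector,
                               feature_frame=frame_perm, target="mPAP")
        null_icc.append(reg_null.metrics["icc"])
        lab_perm = rng.permutation(labels).astype(float)
        frame_perm_c = frame_cls.copy()
        frame_perm_c["mPAP"] = rng.permutation(frame_cls["mPAP"].to_numpy())
        clf_null = repeated_cv(None, lab_perm, task="classification",
                               folds=folds, repeats=1, seed=seed + 200 + r,
                               selector_factory=make_selector,
                               feature_frame=frame_perm_c, target="mPAP")
        null_auc.append(clf_null.metrics["auc"])

    return {
        "n": len(df),
        "regression_icc": reg.metrics["icc"],
        "regression_mse": reg.metrics["mse"],
        "classification_auc": clf.metrics["auc"],
        "classification_auc_p": clf.metrics["auc_p"],
        "sensitivity": clf.metrics["sensitivity"],
        "specificity": clf.metrics["specificity"],
        "null_icc": null_icc,
        "null_auc": null_auc,
        "regression_report": reg,
        "classification_report": clf,
    }
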