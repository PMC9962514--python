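"""The agreement-statistics battery on published summary numbers.

Every quantity here is a deterministic function of printed inputs: Dice
summaries across the eight substructures, t statistics rebuilt from a
mean difference and its 95% CI, Bland-Altman limits of agreement, and the
internal identities of the two-way mixed consistency ICC.
"""

from papkit.agreestats import (icc_average_from_f, loa_from_summary,
                               spearman_brown, summarize_structure_scores,
                               t_from_summary)

# per-structure Dice means (%): LV, RV, LA, RA, MPA, LPA, RPA, AA
baseline = [82.4, 86.9, 86.9, 88.9, 91.6, 90.8, 86.4, 84.5]
refined = [83.2, 87.0, 87.4, 90.7, 92.5, 91.3, 86.9, 86.4]
for name, row in (("baseline", baseline), ("refined", refined)):
    mean, sd = summarize_structure_scores(row)
    print(f"{name:9s} Dice across structures: {mean:.1f}% +/- {sd:.1f}")

# manual-vs-automatic MPA diameter: mean difference -2.249 mm,
# 95% CI (-3.511, -0.9874), n = 55
t = t_from_summary(-2.249, -3.511, -0.9874, 55)
lo, hi = loa_from_summary(-2.249, t, 55)
print(f"\nMPAd manual vs automatic: t = {t:.3f}, "
      f"limits of agreement ({lo:.2f}, {hi:.2f}) mm")

# consistency ICC identities: average = 1 - 1/F = Spearman-Brown(single, 2)
F, single = 15.211, 0.877
print(f"\nmPAP regression ICC: average from F: {icc_average_from_f(F):.3f}, "
      f"from Spearman-Brown step-up: {spearman_brown(single, 2):.3f}")
print("(the two routes agree because both follow from the same two-way "
      "interaction-free ANOVA)")
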