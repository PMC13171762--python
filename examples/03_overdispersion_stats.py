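"""Williams-corrected logistic regression and the total-egg linear model.

Brood-level proportions are usually noisier than binomial sampling allows.
Williams' correction estimates a heterogeneity parameter delta and
down-weights large broods by 1/(1 + delta*(n-1)) so that deviance tests
keep their nominal size; total eggs per brood are compared with a one-way
linear model, a feminized-vs-unfeminized contrast and Tukey letters.
"""

import femcost as fc

table = fc.generate_study(fc.StudyDesign(), fc.GeneratorParams(seed=20))
filtered, tally = fc.apply_exclusions(table)
print(f"excluded broods: {tally}")

design = fc.StudyDesign()
data = fc.GroupedBinomialData.from_broods(filtered)
fem_map = {s: ("feminized" if design.is_feminizing(s) else "unfeminized")
           for s in design.symbiotypes}

test, full, _ = fc.overdispersed_group_test(data, full_design=fem_map)
print(f"\nWilliams delta = {full.delta:.4f} (brood-level heterogeneity)")
print(f"feminized vs unfeminized: dDeviance = {test.delta_deviance:.2f}, "
      f"df = {test.df}, p = {test.p_value:.2e}")
print("  -> undeveloped-egg odds differ sharply once the feminizer is present")

anova = fc.fit_anova(filtered["eggs_laid"].to_numpy(),
                     filtered["symbiotype"].to_numpy())
con = fc.planned_contrast(anova, ["RTW1", "RTW12", "RTW123"], ["U", "R", "RT"])
tukey = fc.tukey_hsd(anova, alpha=0.05)
print(f"\ntotal eggs: F({anova.df_between},{anova.df_resid}) = {anova.F:.3f}, "
      f"p = {anova.p_value:.4f}")
print(f"feminized-vs-unfeminized contrast: t = {con.t:.3f} on {con.df} df")
print(f"Tukey letters: {tukey.letters}")
print("  -> a negative t means feminized females lay fewer eggs; groups\n"
      "     sharing a letter do not differ at alpha = 0.05")
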