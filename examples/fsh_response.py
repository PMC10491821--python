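"""Does an FSH challenge raise testosterone more in males than in females?

Generates paired naive/challenged samples at the published pairing size
(23 individuals) under the fitted response model, then runs the mixed
repeated-measures ANOVA and the permutation test on per-individual change.
"""

from hatchsex import (
    PRESETS,
    generate_paired_fsh,
    pair_records,
    permutation_change_test,
    ranova_paired,
)

pairs = pair_records(generate_paired_fsh(PRESETS["paired"]))
res = ranova_paired(pairs, log_transform=True)

print(f"paired individuals: {len(pairs)}")
print(f"sex x challenge interaction: F{res.df} = {res.f_interaction:.2f}, "
      f"p = {res.p_interaction:.2f}")
print(f"challenge main effect:       F{res.df} = {res.f_challenge:.2f}, "
      f"p = {res.p_challenge:.4f}")
print(f"Levene p = {res.levene_p:.2f}, Shapiro-Wilk p = {res.shapiro_p:.2f}")

obs_abs, p_abs = permutation_change_test(pairs, "absolute", n_perm=9_999, seed=0)
obs_pct, p_pct = permutation_change_test(pairs, "percent", n_perm=9_999, seed=0)
print(f"permutation, absolute change:  M-F = {obs_abs:8.1f} pg/mL, p = {p_abs:.3f}")
print(f"permutation, percent change:   M-F = {obs_pct:8.1f} %,     p = {p_pct:.3f}")

# The generator's default shifts (0.99 for females, 0.85 for males on the log
# scale) are nearly parallel, so the interaction is usually non-significant:
# both sexes respond to FSH, neither disproportionately.  The challenge main
# effect, by contrast, is strongly positive.  On the raw pg/mL scale males
# gain far more in absolute terms simply because they start ~30x higher.
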