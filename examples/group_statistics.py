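"""Group-level statistics: the mixed model, EMM post-hocs and rank tests.

Simulates a balanced cohort of encoding accuracies in which hearing loss
(PTA) selectively lowers the word-segmentation model, fits the
encoding-accuracy mixed model and prints the interaction post-hocs, then
shows the Mann-Whitney / rank-biserial / Holm toolchain.
"""

import numpy as np
import pandas as pd

from speechtrf import (
    MODEL_SPECS,
    emm_at_pta,
    fit_lmm,
    holm_adjust,
    mann_whitney,
    u_to_p,
    u_to_rank_biserial,
)

rng = np.random.default_rng(3)
rows = []
pta_z = rng.standard_normal(44)
pta_z = (pta_z - pta_z.mean()) / pta_z.std()
u = rng.normal(0, 0.01, 44)
for i in range(44):
    group = "normal" if i < 25 else "low"
    for model in MODEL_SPECS:
        acc = 0.03 + 0.02 * (model == "acoustic") + u[i] + rng.normal(0, 0.005)
        if model == "seg_word":
            acc -= 0.004 * pta_z[i]  # worse hearing -> weaker word tracking
        rows.append(dict(participant_id=f"p{i:02d}", moca_group=group,
                         pta_z=pta_z[i], model=model, accuracy=acc))

fit = fit_lmm(pd.DataFrame(rows), "encoding_accuracy", n_boot=200, seed=0)
print("encoding-accuracy LMM (participant random intercept, sum contrasts):")
cols = ["term", "beta", "ci_low", "ci_high", "df", "t", "p"]
print(fit.coefficients[cols].round(4).to_string(index=False))

emm = emm_at_pta(fit, "seg_word")
print("\nacoustic - seg_word EMM differences at PTA z = -1, 0, +1 "
      "(Tukey-adjusted):")
print(emm.round(4).to_string(index=False))
print("A difference growing with PTA z means word-segmentation tracking "
      "declines as hearing worsens.")

x = rng.normal(70, 5, 25)  # e.g. ages of the normal group
y = rng.normal(72, 5, 19)
res = mann_whitney(x, y)
print(f"\nMann-Whitney age comparison: U = {res.U:.1f}, p = {res.p_raw:.3f}, "
      f"rank-biserial r = {res.r:+.2f}")
print(f"published-value conversion check: U=311.5 (n=25/19) -> "
      f"|r| = {abs(u_to_rank_biserial(311.5, 25, 19)):.2f}, "
      f"p = {u_to_p(311.5, 25, 19):.3f}")
print(f"Holm adjustment of [0.01, 0.04, 0.03]: "
      f"{np.round(holm_adjust([0.01, 0.04, 0.03]), 3)}")
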