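"""Find the bulk solvent that best mimics each micellar phase.

Uses the bundled 63-compound experimental table plus a synthetic
solvation panel with a planted propan-1-ol calibration, then (i) ranks
solvents by correlation with each micelle, (ii) applies the aromatic-N /
urea exclusion filter, and (iii) fits the linear calibration line.
"""

import warnings

from micellocalc import (
    bundled_compounds,
    bundled_partition_table,
    correlation_matrix,
    fit_calibration,
    logp_matrix,
    nset_filter,
    predict_micellar_logp,
    rank_surrogates,
    simulate_solvation,
)

warnings.filterwarnings("ignore")

experimental = bundled_partition_table()
truth = experimental.dropna()

# synthetic solvation panel: propan-1-ol planted as the good surrogate
# (tight residuals), hexane as a poor one (loose residuals)
solv_good = simulate_solvation(truth, {("SC", "propan-1-ol"): (0.47, 0.55)},
                               residual_sd=0.2, seed=42)
solv_poor = simulate_solvation(truth, {("SC", "hexane"): (0.47, 0.55)},
                               residual_sd=0.5, seed=43)
computed = logp_matrix(solv_good).join(logp_matrix(solv_poor))

cm = correlation_matrix(experimental, computed, min_pairs=5)
print("surrogate ranking for SC (Pearson r):")
for solvent, r in rank_surrogates(cm, "SC"):
    print(f"  {solvent:20s} r = {r:.3f}")

fr = nset_filter(bundled_compounds())
print(f"\nexclusion filter: {len(fr.excluded)} of 63 compounds carry an "
      f"aromatic-ring N or a urea group")

model = fit_calibration(computed["propan-1-ol/water"], experimental["SC"],
                        micelle="SC", solvent="propan-1-ol")
print(f"\nSC calibration: y = {model.slope:.2f} x + {model.intercept:.2f}, "
      f"R^2 = {model.r2:.2f}, MAE = {model.mae:.2f} (n = {model.n})")
print(f"predicted SC logP at x = 3.0: {predict_micellar_logp(model, 3.0):.2f}")

# The planted propan-1-ol column tops the ranking; the recovered slope
# and intercept sit near the planted 0.47/0.55 line.
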