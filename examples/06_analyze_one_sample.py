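"""Analyze a single simulated dataset: estimates, delta CIs, and MCCIs.

Generates one sample from the moderated-mediation population model and fits
the analysis model to it — the inner step the power engine repeats
thousands of times — then prints both interval types for the conditional
indirect effects.
"""

import modmedpower as mp

study = mp.moderated_mediation_study()
data = mp.generate_sample(study.population, study.design, seed=777)
fit = mp.fit_path_model(study.analysis, data)

print("point estimates:")
for lab in ("a.w0", "a.mod", "b", "c.w0"):
    print(f"  {lab:8s} {fit.estimates[lab]: .4f}  (SE {fit.se(lab):.4f})")

print("\ndefined parameters, delta method vs MCCI (95%):")
mcci_results = {t.parameter: t for t in mp.mcci(fit, seed=777)}
for d in study.analysis.defined:
    dt = mp.delta_test(fit, d)
    mt = mcci_results[d.name]
    print(f"  {d.name:9s} est {dt.estimate: .4f}  "
          f"delta CI [{dt.ci_low: .4f}, {dt.ci_high: .4f}]  "
          f"MCCI [{mt.ci_low: .4f}, {mt.ci_high: .4f}]")

print()
print("The MCCI is asymmetric for products of coefficients (shifted toward")
print("the long tail of the product distribution); the delta CI is forced")
print("symmetric.  On a single sample the two can disagree about")
print("significance — which is exactly why their power differs.")
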