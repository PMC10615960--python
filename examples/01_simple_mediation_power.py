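"""Power analysis for a simple mediation design: X -> M -> Y.

A two-arm experiment (50 per group) with standardized population paths
a = 0.5 (X -> M), b = 0.4 (M -> Y | X) and c' = 0.2 (X -> Y | M).  Power for
the indirect effect ab is estimated two ways per simulated sample: the
delta-method Wald z test and the Monte Carlo confidence interval (MCCI).
"""

import modmedpower as mp

study = mp.simple_mediation_study(a=0.5, b=0.4, c=0.2, n_per_group=50,
                                  nrep=400, seed=2026)
summary, _ = mp.run_power_study(study)

print(summary.table.loc[["a", "b", "c", "ab", "total"]].round(3))
print()
print(f"delta power for ab : {summary.power('ab', 'delta'):.2f}")
print(f"MCCI  power for ab : {summary.power('ab', 'mcci'):.2f}")
print()
print("Each power is the share of simulated experiments in which the test")
print("rejects a zero effect; the MCCI exceeds the delta test for the")
print("product ab because only a and b themselves are assumed normal.")
print("Coverage near 0.95 and |average bias| < 0.10 indicate a trustworthy")
print("simulation at this sample size.")
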