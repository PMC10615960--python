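# Multigroup formulation of the simple mediation study: X is the grouping
# factor, a and c' become intercept differences, b and the residual
# variances are constrained equal across groups.
study:
  name: multigroup_mediation
preset:
  name: multigroup_mediation
  params:
    a: 0.5
    b: 0.4
    c: 0.2
    n_per_group: 50
    equal_b: true
    equal_psi: true
monte_carlo:
  nrep: 1000
  seed: 12345
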