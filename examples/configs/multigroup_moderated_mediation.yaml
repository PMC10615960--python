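# Moderator-as-group moderated mediation: W groups with their own X->M
# slopes (0.5 vs 0.8), a shared b path, and treatment residual variances
# 50% larger than the pooled standardizing values.
study:
  name: multigroup_moderated_mediation
preset:
  name: multigroup_moderated_mediation
  params:
    a_w0: 0.5
    a_w1: 0.8
    b: 0.4
    c: 0.2
    w_variance_ratio: 1.5
    n_per_group: 50
monte_carlo:
  nrep: 1000
  seed: 12345
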