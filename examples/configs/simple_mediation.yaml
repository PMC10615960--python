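# Single-group simple mediation: X -> M -> Y with a direct path.
# Standardized population slopes a=0.5, b=0.4, c'=0.2; 50 per X group.
study:
  name: simple_mediation
design:
  factors: [X]
  n_per_cell: 50
model:
  endogenous: [M, Y]
  covariates: [X]
  meanstructure: false
  groups:
    g1:
      KA:
        M: {X: "a = 0.5"}
        Y: {X: "c = 0.2"}
      BE:
        Y: {M: "b = 0.4"}
      PS:
        M: auto   # residual variance solved so total Var(M) = 1
        Y: auto
  defined:
    - "ab := a*b"
    - "total := c + a*b"
monte_carlo:
  nrep: 1000
  seed: 12345
  alpha: 0.05
  methods: [delta, mcci]
  mcci_draws: 20000
output:
  dir: results
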