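# Single-group moderated mediation (Hayes model 7): W moderates the a path
# through the product column XW.  2x2 design, 25 per cell.
study:
  name: moderated_mediation
design:
  factors: [X, W]
  n_per_cell: 25
  interactions: [[X, W]]
model:
  endogenous: [M, Y]
  covariates: [X, W, XW]
  meanstructure: false
  groups:
    g1:
      KA:
        M: {X: "a.w0 = 0.5", W: "w.m = 0.1", XW: "a.mod = 0.3"}
        Y: {X: "c.w0 = 0.2", W: "w.y = -0.1", XW: 0}   # no direct moderation of c'
      BE:
        Y: {M: "b = 0.4"}
      PS:
        M: auto
        Y: auto
  defined:
    - "ind.w0 := a.w0*b"
    - "ind.w1 := (a.w0 + a.mod)*b"
    - "ind.diff := a.mod*b"
monte_carlo:
  nrep: 1000
  seed: 777
  alpha: 0.05
  methods: [delta, mcci]
  mcci_draws: 20000
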