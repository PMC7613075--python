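# Demo pipeline: simulate a small six-item cued-recall experiment from the
# neural binding model, estimate swap frequencies three ways, predict them
# from report errors, fit all three models and compare by AIC/BIC.
seed: 7
experiment: exp1
n_trials_per_level: 120
generator:
  model: nbm
  kappa_loc: 10.0
  kappa_feat: 5.0
  gain: 40.0
  conjunction: {low: 0.3, medium: 0.6, high: 0.9}
estimate:
  n_iter_expected: 200
  mixture_restarts: 5
predict:
  n_iter: 1000
fit:
  models: [nbm, im_full, im_partial]
  nbm: {maxiter: 250, n_rounds: 2}
  im: {n_restarts: 1, maxiter: 600}
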