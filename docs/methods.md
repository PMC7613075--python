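# Methods

This note documents the models, estimators and numerical choices behind
`swaplab`, in the spirit of a model-documentation page: what is computed,
under which assumptions, and what the synthetic benchmarks do and do not
establish.

## Task model and conventions

All features live on the circle `(-pi, pi]` in radians. Orientation, whose
physical space covers only 180 degrees, is doubled at I/O
(`circular.scale_orientation`) so that a 15-degree orientation separation is
commensurate with a 30-degree location separation; everything downstream is
agnostic about which physical dimension an angle came from. The wrap
convention maps the boundary to `+pi`, giving every direction a unique
representation.

A trial is a memory array of N items, each a (cue feature, report feature)
pair, plus a cued target. The synthetic generator reproduces three designs:

| design | N | cue x report | separation floors | levels |
|---|---|---|---|---|
| six oriented ellipses | 6 | orientation x location (either direction) | 30 deg location, 15 deg native orientation | elongation low/medium/high |
| four motion patches | 4 | direction x location | 60 deg both | coherence low/medium/high |
| spatially cued gratings | 6 | location -> orientation | none on orientation; locations fixed / rotated / random (36 deg) | configuration |

Arrays are drawn by batched rejection sampling, i.e. uniformly over the
constraint-satisfying set; the minimum pairwise circular separation of a
candidate set is its minimum adjacent gap after sorting, so acceptance is
O(N log N). Feasibility (`N * min_sep <= 2 pi`, strictly less for rejection
modes) is checked before sampling. Reproducibility comes from one top-level
seed with per-trial substreams spawned by `numpy.random.SeedSequence`, so
the generated tables are byte-identical across runs and independent of
chunking.

## Swap-frequency estimators

**Nearest item.** A response is a swap iff it is strictly closer to a
non-target's report feature than to the target's; ties go to the target
(conservative, and measure-zero under continuous features). Reliable when
report-dimension noise is small relative to the separation floor; on
simulated data with near-noiseless report decoding it reproduces the
generator's own swap labels exactly.

**Three-component mixture.** Responses are modelled as
`p_T vM(target, kappa) + p_NT/(N-1) sum_j vM(nontarget_j, kappa) + p_U / 2pi`
and fit by expectation-maximization: closed-form weight updates,
concentration updated by inverting the Bessel ratio A(kappa) = I1/I0
(piecewise approximation plus Newton refinement), convergence at 1e-6 on
the log-likelihood, best of 10 dispersed restarts. On uniform data the fit
is intentionally degenerate (kappa unidentifiable; a uniform von Mises can
absorb the weights) and is reported as-is.

**Randomization correction.** Minimum separations make the distribution of
response deviations from non-targets non-uniform even without any
non-target influence. The expected (swap-free) histogram and MAD are
estimated by replacing one randomly chosen non-target report value per
trial with a fresh value respecting the same constraints against the
remaining items, then pooling deviations of the response from this causally
inert value over (by default) 1000 iterations. Histograms use 37 equal bins
on `(-pi, pi]` — an odd count centres one bin on zero, where swap mass
peaks.

**Corrected resultant-vector method.** The mean resultant (and every
circular moment) of a mixture is the weighted sum of its components'
moments. With L_k the unknown moments of the response-error distribution,
u and v the target and total non-target weights, and c_k, d_k the moments
of the non-target-to-target and non-target-pair separation distributions,

    F_k = L_k (u + v c_k)                      (deviations from target)
    G_k = L_k (u conj(c_k) + v q_k),  q_k = [1 + (N-2) d_k] / (N-1)

The c_k, d_k terms are the expected cross-contamination created by the
separation floors. Because item selection operates in the cue dimension
and is therefore blind to report-feature geometry, they are computed
exactly from the observed stimulus values (the analytic counterpart of the
replace-one randomization, which we verified estimates the pair spectrum
with a small bias because the replacement is unconstrained against the
value it replaced). The equations for k = 1..32 are solved jointly by
alternating least squares between (u, v) and L, with L projected each
iteration onto densities that are symmetric, nonnegative and supported
within 2.5 rad of zero. The support bound is the identification
convention: from moments alone, weights and error shape are identified
only up to an exchange of uniform mass, so far-tail response mass is
attributed to the uniform component. No distributional form is assumed
otherwise; recovery was validated with wrapped-Laplace errors. Negative
non-target weights can arise by sampling error and are reported as-is —
they strongly favour an absence of swaps. The method needs pooled
group-scale data: at 10^4 trials its sampling SD is roughly 0.02 on the
target/non-target weights and 0.03–0.04 on the uniform weight. A residual
near-degeneracy remains even with the support convention — a shallow
pedestal of the reconstructed error density inside its support trades off
against the uniform weight — producing weight-dependent biases of up to
about ±0.04 on the uniform weight (e.g. with narrow von Mises errors and
a small true guess rate); the mixture fit is preferable whenever its
distributional assumption is tenable.

**Distance-binned MAD.** For spatially cued designs, the MAD of responses
from each non-target's report feature is binned by the non-target's cue
distance (seven equal bins from 34 to 180 degrees for random
configurations; the exact occupied distances 60/120/180 degrees for
equispaced ones). With unconstrained report features the no-swap
expectation is pi/2; dips below it localize swaps in cue space.

## Parameter-free Monte Carlo swap prediction

To predict location-report swap frequency from report errors observed when
the *other* feature was reported: for each trial and iteration, draw one
error per item (independently, with replacement) from the matching-level
pool, add them to the items' cue features, and count a swap when the
perturbed feature nearest the cue belongs to a non-target; 1000 iterations
per trial by default. Independence of the per-item draws is an explicit
assumption (within-trial error correlations would change predictions).
The implementation is validated against a 2-D quadrature oracle in the
two-item case and against the ground truth of a select-nearest response
generator.

## Neural binding model

Sampling formulation of conjunctive population coding: the array evokes
`M ~ Poisson(gain)` spikes allocated uniformly across items (equivalently,
independent `Poisson(gain/N)` counts per item — an equivalence the
likelihood exploits). Every spike carries a von Mises location sample
(concentration `kappa_loc`); with probability `c` (the conjunction-coding
parameter of the stimulus-quality level) it also carries a sample of the
manipulated feature (concentration `kappa_feat`). Decoding is maximum
likelihood — the resultant direction of an item's samples; zero samples
decode to a uniform draw. The item whose decoded cue feature is nearest
the cue is selected and its decoded report feature is the response. Swaps
arise solely from cue-dimension decoding noise; report-dimension noise
shapes error width. This yields the model's core dissociation: lowering
`c` raises swap rate when the manipulated feature cues, and raises report
variability (not swap rate) when it is reported.

**Decode-error density.** For m samples at concentration kappa the error
density is `p(t) ∝ ∫ q_m(rho) exp(kappa rho cos t) d rho`, with `q_m` the
resultant-length density of a uniform (Pearson) random walk — the
distribution-free part, computed once per m by recursive convolution
(4096-point angular quadrature, 384 length bins, all intermediate m
cached) and accurate to <0.5 % against independent Monte Carlo even where
the exponential tilt probes near-maximal lengths. m = 0 is uniform, m = 1
the von Mises itself.

**Likelihood.** Exact up to quadrature, with no Monte Carlo: per-item
count independence factorizes the marginal over count vectors. For each
(condition, level) cell, the probability that item i is selected given its
count is `∫ f_i(t) prod_j S_j(t) dt` over the absolute cue-deviation axis
(96 bins on [0, pi]; survival terms averaged over the Poisson count
marginals), and the response density mixes the report-decode densities
over the joint distribution of the thinned/full count pair (Binomial
thinning makes the feature-carrying and residual counts independent
Poissons). Offsets are quantized to a 2-degree grid and circle densities
to 720 points (360 during fitting; the induced likelihood shift is below
1e-3 per trial). Selection weights are renormalized to sum to one per
trial, so the density integrates to 1 by construction. Identical
parameters always give identical likelihoods.

**Fitting.** Nelder-Mead on transformed parameters (log concentrations and
gain, logit conjunctions), 3 + n_levels free parameters, with chained
restarts: the simplex is re-initialized at the incumbent until the gain
falls below 0.05 log-units. Chaining matters because the likelihood has a
curved, nearly flat ridge — scaling gain by s while scaling concentrations
and conjunctions by 1/s preserves per-item Fisher information and the
zero-feature-sample rate `exp(-gain c / N)`, leaving only count-dispersion
and low-count shape information to separate the parameters. A consequence,
verified by refitting at finer quadrature and by the fitted likelihood
exceeding the generating-parameter likelihood by the expected k/2: at 500
trials per level and condition the maximum-likelihood estimates themselves
scatter along this ridge (sd ≈ 0.1–0.15 on conjunction values, ≈ 25 % on
gain) while remaining unbiased and order-preserving. Recovery benchmarks
therefore average errors over three replicate experiments of that size.

**Diagnostics.** The marginal probability that an item carries no
cue-feature sample is `exp(-gain c / N)` (Poisson thinning); conditional
zero-sample frequencies by trial outcome and mean cue-dimension precision
(Fisher information `m kappa I1(kappa)/I0(kappa)`) by item role and
outcome are computed from mass simulation. Conditionals on empty outcome
classes are reported as NaN.

## Interference model

Closed-form response density per trial: a mixture over items and routes.
Cue-based retrieval weights each item by `exp(-|d|/s)` of its cue-feature
distance d from the cue (the target gets weight 1; the scale of this route
is fixed, A_c = 1); cue-independent retrieval adds weight `A_a` to every
item; background noise adds a uniform component with weight `A_b`. Report
noise is von Mises with concentration `kappa`, except that with
probability 1/N the target is the focused item, reported at `kappa_f`
while `A_a` and `A_b` shrink by the factor `r`. Only the target-focused
state is treated as special; a focused non-target is assumed to behave as
baseline, and `A_b` is not rescaled with set size (set size is constant
within each experiment here). The model links nothing across conditions,
so it is fit per (report condition x level) cell: 6 free parameters per
cell for the full variant, 5 with `A_a` frozen at zero — 36 vs 30 across
the six cells of a three-level, two-condition experiment. Fitting uses
Nelder-Mead on log/logit-transformed parameters with 3 dispersed restarts.
When `A_a = A_b = 0` the focus-reduction factor r is unidentified and its
fitted value is meaningless (a flat direction the simplex tolerates).

## Model comparison

AIC = 2k − 2 ln L; BIC = k ln(n) − 2 ln L with n the number of trials
entering the likelihood (for per-cell fits, the BIC penalty is accumulated
per cell with that cell's n). Comparison tables report per-dataset deltas
to the best model and best-model counts per criterion; exact ties are
broken by a fixed model order and logged.

## What the synthetic benchmarks show — and what they do not

The generator reproduces the designs' structural constraints and known
generative processes, which is exactly what estimator validation needs:
every recovery test has ground truth. It does not emulate human
idiosyncrasies — response biases (cardinal repulsion, range effects),
sequential dependencies, lapses correlated with stimulus quality, or the
non-metric encoding of diametrically opposite locations that real
spatially cued data can show. Passing tests therefore establish the
correctness and calibration of the machinery, not the truth of any model
for human data. Study-condition defaults (e.g. wrapped-Laplace error scale
0.4 rad for the distribution-free recovery benchmark, circular SD ≈ 0.6,
typical of good orientation report; generating parameters kappa_loc = 10,
kappa_feat = 5, gain = 40, conjunctions 0.3/0.6/0.9) were fixed before the
benchmarks were frozen.

## Numerical summary

| choice | value | note |
|---|---|---|
| histogram bins | 37 on `(-pi, pi]` | odd, zero-centred |
| randomization iterations | 1000 | expected histograms / MAD |
| resultant-vector harmonics | 32 | alternating solve, 60 iterations |
| error-density support bound | 2.5 rad | uniform-mass identification |
| decode-density circle grid | 720 (360 in fits) | midpoint grid |
| cue-deviation grid | 96 bins on [0, pi] | selection integral |
| offset quantization | 2 deg | likelihood lookup |
| Poisson tail truncation | 1e-7 per stream | count marginals |
| EM tolerance | 1e-6 log-likelihood | mixture fit |
| Nelder-Mead | adaptive, log/logit transforms | all model fits |
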