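# Methods

## The model

`antddm` analyses two-choice reaction times from the Attention Network
Task (ANT) with the full drift diffusion model (DDM).  Evidence follows a
Wiener process with drift `v` and diffusion coefficient `s`, starting at
`z` between absorbing boundaries at `0` (error) and `a` (correct; accuracy
coding — the ANT's left/right responses are collapsed into correct/error,
and the starting point is unbiased, `z = a/2`).  The observed response
time is the boundary-crossing time plus a non-decision time `Ter`.  Across
trials the drift is `Normal(v, eta)`, the starting point
`Uniform(z - sz, z + sz)` and the non-decision time
`Uniform(Ter - st, Ter + st)`.  `sz` and `st` default to 0; `eta` is a
first-class estimated parameter, since fluctuations in drift are the
model's handle on attentional variability.

The scaling constant is `s = 0.1` with time in seconds, the convention in
which boundary separations of 0.2–0.28 and drifts of 0.6–0.8 are typical
for fast perceptual decisions.  All model predictions are invariant to a
common rescaling of `a, z, v, eta, sz, s`.

## First-passage distributions

The defective first-passage density at a boundary is computed from two
classical series expansions of the unit-diffusion kernel: the
method-of-images ("small-time") sum and the spectral ("large-time") sum.
Each evaluation picks the series needing fewer terms (truncation bound
`eps ~ 1e-20`), with a stability guard: when the spectral prefactor
`exp(-v z)` exceeds `e^28` the image series is used instead, because its
per-term exponents can be combined before exponentiation and are always
non-positive.  The CDF uses the term-wise integral of the spectral series
(`F(t) = P_boundary - sum_k (k / lambda_k) sin(k pi z / a) e^{-v z - lambda_k t}`),
falling back to composite Gauss–Legendre quadrature of the image-series
density for very small `t` or extreme drift.  The two series agree to
below 1e-8 where both converge, and the density integrates to the
closed-form absorption probability to 1e-6; both facts are asserted in the
test suite.

Across-trial variability is integrated numerically: 24-node
Gauss–Hermite over the normal drift distribution, 12-node Gauss–Legendre
over the uniform `sz` and `st` ranges.  Variability parameters below
1e-10 switch to the exact no-variability kernel.

## Trial simulator

The independent oracle for all of the above is an Euler–Maruyama
simulator (`dt = 1e-4` s by default).  Because the Euler increments of a
constant-drift Wiener process are exact in distribution, the only
discretisation error is boundary crossing *between* grid points; the
simulator therefore applies the Brownian-bridge crossing test at every
step (crossing probability `exp(-2 d0 d1 / (s^2 dt))` for gap `d0`, `d1`
to the boundary before and after the step).  With the correction the
Kolmogorov–Smirnov distance to the analytic distribution at n = 200,000
is ~0.003 — the Monte-Carlo noise floor — across the parameter range the
analysis works in; without it, ~0.008.  Trials still undecided at the
censoring horizon (1.7 s target window + `Ter`, mirroring the task's
response deadline) are flagged censored.

## Quantile-multinomial fitting

Each condition's correct and error RTs are reduced to their 0.1 / 0.3 /
0.5 / 0.7 / 0.9 quantiles (type-7 linear interpolation), giving 6 bins per
response side.  A side with fewer than 11 observations — routine for
errors, since accuracy in this task is near ceiling — collapses to a
single bin, so the model's predicted error probability is still
constrained through the normalisation of the correct-side masses.  The
objective is the multinomial deviance `-2 sum n_i log p_i` over bins
(quantile maximum probability estimation), with predicted masses floored
at 1e-10; a Pearson X² variant is available behind a config switch.  RTs
below 0.150 s are trimmed as fast guesses before binning (configurable).

Minimisation is bounded Nelder–Mead (parameter/objective tolerance 1e-4,
2000 iterations per restart), multi-started from 5 moment-heuristic
(EZ-style) initial values jittered ±20% with a recorded jitter seed.
Bounds: `a` in [0.06, 0.6], `v` in [0.01, 3], `eta` in [0, 0.5], `Ter`
between 0.05 s and just below the smallest observed quantile edge.

## Model space and selection

Four candidate models let subsets of `{a, v, eta, Ter}` vary across the
conditions of an analysis (congruency: 3 conditions collapsed over cues;
cue: 4 conditions collapsed over congruency), the rest shared:
`{a, eta, v}`, `{a, eta}`, `{a, eta, v, Ter}`, `{a, v, Ter}`.  Free
parameter counts are `|free| * C + |shared|`.  Candidates are compared per
participant by `BIC = -2 log L + k ln(n)` with `n` the total trial count
entering the analysis; ties go to fewer parameters, then to the canonical
order above.  Because the schemes are nested, a larger scheme fitting
worse than one it contains flags an optimiser failure and triggers one
re-fit from fresh starting points.

## Synthetic ANT data

A session is 3 blocks of 94 trials (24 training trials are generated
nowhere — they are excluded from analysis by design), 12 cells = 4 cue x 3
congruency conditions, allocated 8 trials to ten cells and 7 to two, with
the short cells rotating across blocks; trials are shuffled within block.
Cell parameters compose marginal effects additively around centred
deviations:

* congruency: `a` = 0.27 incongruent vs 0.23 congruent/neutral; `v` = 0.58
  vs 0.79; `eta` = 0.05 vs 0.07;
* cue: `a` = 0.28 (no cue), 0.25 (center), 0.24 (double), 0.20
  (time-space); `eta` = 0.08 time-space vs 0.06 otherwise.  The
  center/double thresholds interpolate the two established extremes, and
  the drift is the congruency grand mean (0.72) for all cue conditions —
  cue-specific drifts are not separately established;
* group: mean threshold 0.25 (meditators) vs 0.20 (controls), with the
  congruency modulation expressed 1.5x by meditators and 0.5x by controls
  so the cohort-averaged condition deviations keep their marginal values;
* `Ter` = 0.30 s everywhere; `z = a/2`; `sz = st = 0`.

Group marginals are anchored exactly; the printed condition marginals and
group marginals cannot all hold simultaneously as cell means, and the
group anchor was chosen because the group contrast is what the cohort
recovery measures.  Between-participant heterogeneity is multiplicative
normal jitter (10% CV, truncated) on each parameter; optional uniform-RT
contaminants (rate <= 0.1) model guesses.  Simulated mean RTs are faster
than the task's published condition means (~500 vs ~640 ms for no-cue)
because the published condition-mean parameters combined with a nominal
0.30-s non-decision time under-predict the observed RT level; no analysis
in this package depends on absolute simulated RT means.

## Recovery protocols and their problem sizes

Recovery uses an inflated-trials mode — 2,000 trials per condition, 20
replicate seeds (40 participants for the cohort experiment) — because
94-trial blocks cannot support tight recovery.  These sizes make the full
parameter-, group- and model-recovery suite run in roughly twenty minutes
on one core.

In the parameter- and group-recovery fits the non-decision time is held
at its generating 0.30 s rather than estimated.  This is deliberate: at
the generating parameter values accuracy is at ceiling (the drift is 5–8
diffusion SDs from the error boundary), so the five correct-RT quantiles
carry almost no information separating `a` from `Ter` — the Fisher
information is near-singular along that trade-off, and the
Cramér–Rao bound for the threshold is ~0.09 per 2,000-trial replicate
with `Ter` free versus ~0.014 with `Ter` known.  Threshold recovery is
therefore only a meaningful check with `Ter` fixed.  Model recovery, by
contrast, fits all four candidate schemes exactly as the method would be
applied to real data, with `Ter` estimated wherever a scheme shares or
frees it.

Even with `Ter` known, drift variability remains weakly identified at
ceiling accuracy: `eta` contributes only a few percent of the RT variance
there, its maximum-likelihood estimate has an atom at zero (the profile
likelihood genuinely peaks at 0 in a minority of replicates), and the
20-seed median of the incongruent-condition `eta` swings by roughly
±0.03 across independent replications.  The corresponding acceptance
check is at the edge of what the data can support, and can fail for
an unlucky seed; thresholds and drift rates recover comfortably.

## What the synthetic data do and do not show

The generator reproduces the design's factorial structure, the
condition/group parameter differences, reproducible randomisation, and
(optionally) contaminant guesses.  It does not model sequential effects,
learning or fatigue across blocks, cue-timing effects on `Ter`, RT
censoring asymmetries beyond the response deadline, or any departure of
real data from the DDM itself.  Passing recovery tests therefore shows
the estimation machinery is correct and calibrated for DDM-generated
data at these parameter values — not that the model is true of, or
identifiable in, any particular empirical data set.

## Statistical conventions

Behavioral summaries use correct trials only for RT means (standard ANT
practice).  Attention-network scores: alerting = no-cue − double-cue,
orienting = center-cue − time-space-cue, conflict = incongruent −
congruent.  Within-subject error bars use Cousineau normalisation
(subtract the participant mean, add the grand mean) with the Morey
`sqrt(C/(C-1))` correction.  Group contrasts use Welch's t, condition
contrasts a paired t; these summarise per-participant statistics and are
deliberately simpler than a mixed-effects analysis, which is outside this
package's scope.  Under a null generator the Welch comparison's measured
type-I error at alpha = 0.05 is within 1.5 percentage points of nominal
(1,000 replicates; asserted in the test suite).
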