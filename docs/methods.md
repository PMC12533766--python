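# Methods

## The behavioral task and the data model

The package analyzes closed-set keyword recognition during simulated online
communication.  Two listener groups — cochlear-implant users (CI) and an
acoustic-hearing comparison group (AH) — each complete 60 sentence trials,
20 in each of three presentation modes (audio only; audio-visual "video";
audio-visual plus captions), in seeded random order.  Every trial requires
three sequential keyword selections among four options: the keyword itself
plus a semantically similar, a phonetically similar, and an unrelated foil.
Each keyword selection yields a response category and a response time (RT),
so a full cohort of 100 participants produces 18,000 (response, RT) pairs.

Accuracy and speed are modeled jointly with a linear ballistic accumulator
(LBA) race.  Each response option has an evidence accumulator that starts
at a point drawn uniformly from `[0, A]` and grows linearly at a rate drawn
from `Normal(v, s)` across trials; the first accumulator to reach the
threshold `b > A` determines the response, and the observed RT adds a
non-decision time `t0 >= 0.150 s` for encoding and motor execution.  The
between-trial drift SD is fixed at `s = 1`, the standard scaling constraint
that makes the remaining parameters identifiable.  The joint density of
(response r, decision time t) is the defective density

    f_r(t) * prod_{j != r} (1 - F_j(t)),

where `f` and `F` are the closed-form LBA first-passage density and CDF.
This density is *defective*: its mass over responses and times is
P(at least one accumulator ever finishes), which has the closed form
`p_any = 1 - prod_j Phi(-v_j)` and sits around 99.5% at plausible drifts.
The low-level race functions and the default trial likelihood leave the
density defective, the common convention for LBA implementations.  The
hierarchical model, however, divides the race term by `p_any`
(`renormalize_race=True`, the default), making it a proper density over
finishing events.  The reason is measurable rather than cosmetic: no
generative process can produce data distributed exactly as a defective
density — its missing mass has to land somewhere — and the resulting
~0.5% discrepancy, though tiny in probability, exerts a systematic score
along the model's nearly flat drift/threshold trade-off ridge.  In
calibration experiments this displaced maximum-likelihood drifts by about
+0.1 and capped interval coverage well below nominal; with the
closed-form renormalization (one extra normal-CDF evaluation per
accumulator) and lapse-resolved stalled races, the generator and the
fitted model agree exactly and recovery is unbiased.

Each participant has 17 free parameters: 12 drift means (4 response types x
3 modes), two serial-dependency boosts, and `A`, `b`, `t0`.  The boosts act
on the correct-response accumulator only: `boost_kw2` is added to the
correct drift on keyword 2 when keyword 1 was answered correctly, and
`boost_kw3` on keyword 3 when both earlier keywords were.  This captures
the within-sentence context effect — a listener who has the sentence frame
right accumulates evidence toward the remaining keywords faster.

### Contaminant mixture

Real response sets contain lapses — wrong-window clicks, attention drops,
walk-aways — that no race model should be forced to explain.  Each keyword
selection is therefore a mixture: with probability `1 - lambda` it comes
from the race, with probability `lambda` from a lapse whose response is
uniform over the four options and whose RT is uniform on `(0, t_max)`,
where `t_max` is the maximum observed RT of the dataset being fitted.
The mixture guarantees a finite log likelihood for every observable row,
including responses faster than `t0` (the race density there is zero; the
lapse component carries the mass).  Numerical floors: log densities are
floored at -745 to avoid `-inf` propagation, and normal CDF evaluations
saturate exactly beyond `|z| = 37`, below which the closed forms cannot
retain any contribution.

## Hierarchical structure and priors

Individual parameter vectors (on an unconstrained scale) are modeled as
multivariate normal around their group's mean:

    theta_i = mu[group(i)] + diag(tau) L z_i,    z_i ~ Normal(0, I),

a non-centered parameterization in which the sampler explores standardized
offsets `z_i` rather than the correlated raw parameters.  `L` is the
Cholesky factor of a 17x17 correlation matrix estimated from the data.
Constraint maps keep every draw legal by construction: drifts and boosts
are unconstrained, `A = exp(a)`, `b = A + exp(d)` (so `b > A` always), and
`t0 = 0.150 + exp(e)` seconds.

Priors: `mu ~ Normal(0, 5^2)` componentwise; `tau ~ half-Student-t(3, 0,
2.5)`; correlation `~ LKJ(1)` (uniform over correlation matrices) via the
canonical-partial-correlation transform with its exact Jacobian; `lambda ~
Beta(1, 19)` (mean 5%, weakly informative).  These are deliberately wide:
the likelihood dominates at cohort scale, and all values are configurable.
Between-subject scales `tau` and the correlation matrix are shared across
the two groups — only the means differ.  Sharing stabilizes estimation at
the cohort sizes used here; group-specific dispersion would add 153
weakly-identified parameters per extra group.  `lambda` is a single global
parameter.

## Sampling

Posteriors are explored with an in-package No-U-Turn sampler (multinomial
variant): dual-averaging step-size adaptation targeting 0.8 acceptance,
diagonal metric estimated in expanding warmup windows, divergence threshold
of 1000 on the Hamiltonian error, and a default tree-depth cap of 7 (128
leapfrog steps — about twice the trajectory length this posterior settles
on after adaptation; the cap bounds the cost of early-warmup excursions).
The likelihood gradient is analytic: closed-form partials of `f` and `F`
with respect to drift, threshold, start-point range and decision time,
chained through the constraint maps, the non-centered identity and the
correlation transform.  Gradients are verified against finite differences
in the test suite.  The default configuration is 4 chains x (1000 warmup +
2000 retained) = 8000 draws; runs are deterministic given the seed.
Convergence is summarized by split-Rhat and bulk/tail effective sample
sizes per parameter (computed with ArviZ), with 1.01 as the flagging bar.
"Group-level parameters" in reports means the constrained group means plus
the global contaminant proportion.

The same sampler drives the preference models (below); nothing in the
likelihood uses a backend-provided race distribution.

## Listening efficiency

For each group and mode, listening efficiency is the correct-response
drift minus the mean of the three error-response drifts.  A random guesser
(all drifts equal) scores exactly zero; adding any constant to all four
drifts leaves the score unchanged.  Group-level efficiency is computed
from the group-mean (`mu`) drift draws, not from averaged individual
draws, matching the convention of reporting group-level parameter
posteriors.  For reporting, every draw is divided by that draw's AH
mode-average, so the normalized AH mean is exactly 1 per draw and the
normalized posterior propagates joint uncertainty; draws with a
non-positive reference mean cannot be normalized and are counted and
reported rather than dropped.  Effects are summarized by the posterior
median, a 95% highest-density interval (narrowest window over sorted
draws; assumes unimodality, which holds for these posteriors), and a
credibility — the posterior probability that the difference is positive,
with exact ties counted one half so self-comparison gives exactly 0.5.

Response caution is reported as `b - A/2`, the distance from the mean
start point to the threshold; `b / A` is available as an alternative
definition.

## Preference-count analysis

Participants' preferred presentation mode per example conversation is
analyzed as Poisson counts with a log link: `Counts ~ Mode x Group`
(counts summed over conversations) and the saturated `Counts ~ Mode x
Group x Conversation`.  Treatment coding uses AH / audio / conversation A
as reference levels; coefficients get `Normal(0, 5^2)` priors on the log
scale; fits use 4 chains x (2000 warmup + 2000 retained).  Conditional
effects exponentiate the linear predictor per cell and summarize with
central 95% credible intervals.  Counts are modeled as independent Poisson
even though each (group, conversation) cell's votes sum to the panel size;
a multinomial log-likelihood helper is provided for comparison but is not
the default.

## The synthetic-data generator

No public accession exists for the study's trial-level data, so the
generator is the test bed for the whole pipeline.  It reproduces the
design exactly (balanced seeded mode order, 60 x 3 keyword slots per
participant), draws individuals from the multivariate-normal population on
the unconstrained scale, simulates every keyword selection from the LBA
race with the serial-dependency boosts applied according to the simulated
correctness of earlier keywords, and writes the prior-correctness context
flags alongside each row.  A stalled race (every drift sample negative,
~0.4% of draws at the default values) resolves as a lapse whenever a
lapse process exists — the participant eventually guesses — which parks
the race's defective mass in the contaminant component, matching the
renormalized likelihood exactly; with `lam = 0` the race is redrawn
instead, so without a contaminant every RT still exceeds `t0`.

Default generative values: AH correct drifts 3.0 in all modes; CI correct
drifts 1.8 / 2.1 / 2.4 (audio / video / captions); error drifts 0; boosts
0.5 / 0.7 (AH) and 0.4 / 0.55 (CI); `A = 0.8`, `b = 1.3`, `t0 = 0.3 s`,
`lambda = 0.02`, `t_max = 10 s`; between-subject SDs 0.3 (drifts), 0.15
(boosts), 0.15 (log-scale architecture parameters); identity generating
correlation.  Error drifts sit at zero because, with the `s = 1` scaling,
the drift separation — not the threshold — controls accuracy: zero error
drifts put CI-audio accuracy near 78% and AH accuracy near 94%, the
qualitative pattern of the study population (mode-graded CI performance,
near-ceiling AH performance); error drifts of 0.5 would leave CI-audio
near 64%, far too low.  The preference-vote generator uses multinomial
draws with caption-heavy CI probabilities (0.92 for the lowest-quality
conversation) and video-heavy AH probabilities.

One generator convention deserves emphasis.  The LBA race has a heavy
first-passage tail (drift samples barely above zero), so a large simulated
cohort contains a few RTs of minutes; fitting defines the contaminant
bound as the *maximum observed RT*.  Dataset simulation therefore draws
lapse RTs uniform on `(0, ceiling)` with `ceiling = max(t_max, slowest
race RT in the dataset)`: the generated data then carry exactly the
contaminant density the fitted model reconstructs from them.  Had lapses
been bounded at a fixed constant instead, a single slow race outlier
would dilute the reconstructed contaminant density roughly 30-fold,
collapse the recovered lapse proportion (measured: 0.0013 against a true
0.02 at 20,000 trials) and drag drift estimates with it.  Truncating the
race at the ceiling is no better: removing the slow tail the likelihood
expects tilts maximum-likelihood drifts upward by about +0.2.  With the
convention used here, single-individual maximum likelihood and
hierarchical posteriors recover the generating values without systematic
bias (22/24 pooled interval coverage in the scaled recovery checks).

What the generator does *not* emulate: real lexical structure (foil
confusability is collapsed into three error drift means), within-
participant learning or fatigue, input-device differences, caption-reading
strategies, or missing/aborted trials (complete data are assumed).
Passing recovery tests therefore demonstrate that the estimation machinery
is consistent with its own generative assumptions — not that those
assumptions capture every feature of real listeners.

## Problem sizes and numerical choices

Desk-scale defaults used by the tests and the acceptance script: recovery
studies run 20 replicate cohorts of 10 participants per group (60 trials
each) with single short chains (150 warmup + 300 retained for the first
replicate; later replicates share the same design and population, so they
warm-start from the first fit's adapted mass matrix and use 60 warmup +
240 retained) — enough for interval coverage at the 18-of-20 standard;
the convergence check fits one such cohort with 4 chains (400 warmup +
650 retained each); the headline acceptance run
(`scripts/acceptance.py`) fits the 10-per-group cohort with 4 chains at
500 warmup + 1000 retained iterations — at this cohort size the maximum
group-level split-Rhat is indistinguishable between that budget and the
full default one (1.004 vs 1.002 in our runs), and the shorter budget
keeps the whole script to minutes on one CPU.  Chains are
initialized from `Uniform(-0.5, 0.5)` on the unconstrained scale, redrawn
(up to 20 times) if the joint log posterior is not finite.  The group-mean
non-decision coordinates are recentred at -2 before the uniform jitter:
a plain uniform draw would start `t0` at 0.76-1.8 s — above most observed
RTs, leaving every row contaminant-explained — and an occasional chain
then falls into a poor local mode with `t0` pinned at the 150 ms floor
and inflated drifts.  Starting `t0` at 0.20-0.37 s, inside the plausible
region, lets warmup find the dominant mode reliably.  The
correlation block uses the tanh canonical-partial-correlation transform;
its LKJ prior and Jacobian are evaluated in closed form with gradients.

## Known limitations

- The diagonal metric cannot absorb position-dependent curvature (the
  `t0`-near-`min RT` wall), so step sizes settle near 0.03 and typical
  trajectories need ~64 leapfrog steps; full-budget fits take minutes, not
  seconds, on one CPU.
- `tau` and the correlation matrix are shared across groups by design;
  group differences in dispersion are not estimable in this model.
- The mixture weight attributed to the contaminant absorbs the stalled-
  race mass, so the recovered lapse proportion estimates
  `lambda + (1 - lambda) (1 - p_any)` — about 0.4 points of mass above
  the generating `lambda` at the default drifts; p_any also varies
  slightly across boost contexts while `lambda` is global, a second-order
  approximation.
- The HDI routine assumes unimodal posteriors.
- Preference fits treat counts as independent Poisson (the fixed-total
  multinomial structure is ignored, as is conventional for log-linear
  analyses of this kind).
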