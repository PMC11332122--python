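# Methods

## The task and the model

`stargrid` implements a multi-agent "star-harvest" grid world and a family
of trial-by-trial social-learning models of the decision to *zap* — a
costly aggressive act that replaces a move and sends any player caught in
the ray to a time-out zone.  Five players (one modelled learner, four
scripted bots) move on a 10×10 grid collecting stars over 100 rounds.
After each round a new star appears anywhere on the grid with probability
0.75 and existing stars can expire.  Bots come in two behavioral types:
*zappers* zap a competitor who is closer to their nearest star and shares
a row or column; *avoiders* reroute instead and never zap.  Group identity
is minimal-group: in grouped conditions two bots share the learner's team
color (ingroup) and two belong to the other team (outgroup); colors never
change behavior.

The learner decides, for every candidate target it shares a row or column
with, whether to zap:

    p(zap) = logistic( Bias + Prior_rel
                       + w_StarDist * StarDist + w_TargetDist * TargetDist
                       + w_TargetZap * belief_target )

`Prior_rel` is `Prior_in` for ingroup targets, `Prior_out` for outgroup,
and 0 for neutral targets.  `belief_target` ∈ [0, 1] is the learner's
running estimate of that target's likelihood to zap.  Beliefs start at 0
(prior inclinations live in the Prior terms) and change only when an
observed act is informative:

* an observed **zap** or **avoidance** moves the actor's own belief by a
  learning rate on the prediction error, `b ← b + LR·(outcome − b)` with
  outcome 1 for zap and 0 for avoidance, and separate rates
  `LR_{zap,avoid}^{in,out}`;
* under group-level attribution the same prediction error also moves the
  beliefs about the actor's *teammates*, with attribution rates
  `At_{zap,avoid}^{in,out}`.

An avoidance is defined as moving while able to zap someone (sharing a row
or column) *and* not being the strictly closest player to any star; moves
made while closest to a star, or with nobody in line, carry no information
and trigger no update.  Three nested variants are fitted: `P` (priors
only), `PL` (priors + direct learning), `PLA` (priors + learning +
attribution).  Only decisions where the learner could zap enter the
likelihood, one Bernoulli term per (turn, target) opportunity.

## Engine conventions and tie-breaks

All design points the task description leaves open are fixed
deterministically so that a (config, seed) pair reproduces a game
byte-for-byte:

* distances are Manhattan (L1) everywhere — the path metric of a
  4-connected grid; decision covariates are divided by 10 (the grid side)
  before entering the decision rule, so the fitted `w_StarDist = 0.26` /
  `w_TargetDist = −1.84` convention applies;
* the zap ray hits **all** active players in the line (a first-hit-only
  mode sits behind `ray_stops_at_first`);
* star expiry probability is 0.05 per star per round (configurable; the
  task description only says stars "can disappear");
* at most one star spawns per round, uniformly over cells free of players
  and stars; games start with 5 stars already on the board so the opening
  rounds are not degenerate;
* blocked moves (edge or occupied cell) fall back to the other
  distance-reducing axis, then any legal direction, before accepting a
  no-op; movement prefers the row axis; all "nearest"/"lowest" ties break
  by lowest index;
* a zapped player re-enters at a uniformly random free cell after sitting
  out exactly `timeout_turns` (3) subsequent rounds; counters tick in the
  end-of-round phase, which draws in the fixed order spawn → expiry →
  re-entry;
* the RNG is a single seeded `numpy` generator per game; policy randomness
  draws after the round bookkeeping, in turn order.

Event extraction mirrors the generative conventions: covariates come from
the pre-move snapshot stored in every turn record, observations include
bot-vs-bot acts, the learner's own actions never update its beliefs, and a
zap records as `observed_action="zap"` only for targets actually in the
ray.  In the neutral condition each player has a distinct color, the Prior
term is 0, one shared learning-rate pair applies (default: the in/out
average) and attribution never fires (no two players share a team).

## Generative use of the model

The closed-loop agent (`simulate_participant`) observes every bot act as
it happens, updates beliefs online, and on its own turn evaluates the
in-line candidates in random order, drawing an independent Bernoulli at
each candidate's model probability; the first success produces a zap
toward that candidate, otherwise the agent moves by the avoider policy.
This keeps the generative process aligned with the per-opportunity
Bernoulli likelihood, at the cost that at most one zap can occur per turn
— candidates evaluated after a success are recorded as not-zapped without
a draw.  With ~1.3 in-line candidates per decision turn this
misspecification is mild, but it is one reason fitted belief weights run
slightly high at small samples (see Limitations).

Replay prediction (`replay_predict`) runs the same learner against a
recorded game: the bots' logged acts form the observation stream, the
participant slot's logged positions anchor the covariates, and the slot's
recorded choices are discarded in favor of the model's sampled decisions.
Bot-only logs for replay come from the engine with the participant seat
played by the avoider policy as a stand-in.

## Synthetic studies

`simulate_study` samples per-participant parameters from group-level
normal distributions — linear parameters directly, rates on the logit
scale — and plays one closed-loop game per participant.  Defaults are the
study conditions: 10×10 grid, 100 turns, mixed grouped condition (each
team one zapper + one avoider), spawn 0.75, expiry 0.05, group means at
the fitted values (Bias −1.01, Prior_in −0.87, Prior_out −0.12,
w_StarDist 0.26, w_TargetDist −1.84, w_TargetZap 0.89, LR_zap 0.71/0.84,
LR_avoid 0.08/0.13, At_zap 0.19/0.22, At_avoid 0.14/0.02) and a
between-participant sd of 0.5 on the sampling scale — moderate, realistic
heterogeneity chosen once.  Generated cohorts yield roughly 35–50 zap
opportunities and a handful to ~20 zaps per participant, matching the
order of magnitude implied by the original cohort's fit statistics.

What the generator does **not** emulate: human moment-to-moment motor
noise and exploration, any drift in strategy unrelated to the model,
questionnaire responses, dropout, or the original pilot logs' exact star
statistics.  Passing recovery tests therefore show that the pipeline is
self-consistent at realistic signal levels, not that the model is the true
account of human play.

## Estimation

Participant parameters live on a sampling scale (linear directly, rates
through a logit link) with independent normal population distributions
`theta_i ~ N(mu, diag(sigma²))`, hyperpriors `mu_j ~ N(0, 2.5)` and
`sigma_j ~ half-N(1)`.  Two fitters share this model:

* **`method="map"`** — empirical-Bayes EM: per-participant penalized-ML
  fits with a Laplace (inverse-Hessian) Gaussian approximation alternate
  with closed-form group updates; the E-step variance enters the sd update
  so weakly identified participants do not collapse the population sd.
  The EM is anchored by a multi-start *pooled* fit (one common parameter
  vector for the whole cohort) because the joint surface is multimodal:
  learning rates trade off against the belief weight, and an EM started
  at zero reliably walks into a spurious mode.  Posterior draws come from
  the Gaussian approximations.  Fast (seconds), but its draws concentrate
  at the joint mode, which overstates lppd for flexible models.
* **`method="mcmc"`** (reference) — Metropolis-within-Gibbs on the joint
  posterior, initialized from the EM fit: preconditioned Metropolis
  blocks per participant, conjugate draws for the group means, log-scale
  random-walk steps for the sds, coordinate-wise *translation moves* that
  shift one group mean together with every participant's matching
  coordinate (these traverse the group-level ridges that per-participant
  steps cannot cross), and a dedicated translation along
  (+Bias, −Prior_in, −Prior_out): with only in/out targets the likelihood
  depends on the two sums alone, so that direction is likelihood-invariant
  and mixes by the hyperprior.  Warmup adapts all proposal scales toward
  25% acceptance; chains are independent given the seed; rank-normalized
  split-rhat is reported per group-level parameter and flagged above 1.05.

The non-centered Cholesky-correlated random-effects parameterization used
by gradient-based samplers is not reproduced here: it is a device for a
different sampler family, and group-level parameters are treated as
independent.  WAIC uses the standard pointwise definition on the deviance
scale with sample (ddof = 1) variances, `dSE` is the standard error of the
pointwise WAIC differences against the best model, and Akaike weights are
`exp(−dWAIC/2)` renormalized.  When several variants are compared, they
are fitted in nesting order with each fit anchoring the next, plus a
downward pass re-anchoring nested fits at the top model's solution — so a
richer model never loses to optimizer luck.  The 89% HDI is the shortest
contiguous interval; participants with fewer than one zap are excluded
before fitting.

## Numerical choices

Probabilities entering log-likelihoods are floored at 1e-12; Hessians are
inverted with escalating jitter and fall back to a diagonal approximation;
rate parameters are clipped away from {0, 1} only through the logit
parameterization (never in the likelihood); the population sd is floored
at 0.05 to prevent EM collapse; the forward pass has a plain sequential
implementation (the public API) and a flat-array kernel (optionally
numba-compiled) used by the fitters, tested to agree to 1e-12.

## Experiment design choices

* **Parameter recovery** runs at the study conditions: n = 60
  participants, 100 turns, group means at the fitted values, sd 0.5.
* **Model recovery** generates under the *simulation-regime* parameter
  values (zap LR 0.8, avoid LR 0.25, zap attribution 0.5 for the
  attribution model; zap LR 0.9, attribution 0 for the learning model) —
  the values chosen in the original simulations precisely because they
  make each mechanism express itself in behavior.  At the fitted group
  means the attribution mechanism contributes only a few nats of evidence
  per hundred participants (the original model comparison separated the
  top two models by dWAIC ≈ 5 at n = 132), so no n = 30 comparison can
  resolve it; a recovery study at those values would measure noise.
  Model comparison uses the MCMC fitter: Laplace-draw WAIC concentrates
  at the joint mode and systematically flatters the more flexible model.

## Limitations

* **Avoidance learning rates are weakly identified at desk scale.**  With
  ~40 opportunities per participant, the marginal posterior for
  `LR_avoid` spans most of [0, 1] even at n = 60, and its posterior mean
  sits mid-scale regardless of the generating value; pooled-likelihood
  profiles confirm the information is a few nats.  Point-recovery of
  these two rates to ±0.15 is not achievable under the study conditions;
  interval coverage is honest (the HDIs are wide and cover the truth).
* The belief weight `w_TargetZap` and the zap learning rates form a soft
  ridge (belief magnitude × weight is what the data constrain); posterior
  means land on the ridge near the truth but individual coordinates carry
  substantial uncertainty.
* `Bias`, `Prior_in` and `Prior_out` are identified only through their
  sums in grouped data without neutral targets; their individual
  posteriors are prior-dominated, exactly as wide as they should be.
* Model recovery at n = 30 is reliable for detecting the *absence* of
  attribution (the learning-only model wins on its own data) but the
  attribution model wins on its own data only about half the time even at
  regime parameter values — the evidence per dataset is comparable to the
  complexity penalty.
* The one-zap-per-turn generative constraint is not represented in the
  per-opportunity Bernoulli likelihood (both sides of that trade-off
  follow the same design decision); the induced bias is small but visible
  as a mild upward pull on `w_TargetZap` at small n.
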