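# Methods

`adocnet` models how a user-interaction network forms in an online mental
health community.  The data are directed *reply* relations — user *i* posted
a comment or reply to user *j*'s content — together with four coded node
attributes: gender, community experience, emotion polarity and preferred
discussion topic.  The scientific questions are the classic ones of social
network formation: do users reciprocate attention, do similar users attract
each other (homophily), do experienced members accumulate replies, and how
do polarized emotions shape who answers whom.

## The model

The network is a binary digraph `y` on `n` labelled nodes, `y_ij = 1` when
`i` replied to `j`.  It is modelled as an exponential random graph model
(ERGM)

    P(Y = y | theta) = exp( sum_k theta_k z_k(y) ) / c(theta)

where each `z_k` counts one configuration and `c(theta)` normalizes over
all `2^(n(n-1))` digraphs.  The full specification (`adoc_spec()`, 15
terms) contains:

| term                         | count                                            | hypothesis |
|------------------------------|--------------------------------------------------|------------|
| `edges`                      | ties (density intercept)                         | —          |
| `mutual`                     | reciprocated unordered pairs                     | H1         |
| `nodematch.gender`           | ties joining same-gender users                   | H2         |
| `nodematch.topic_preference.l` (l = 1..7) | ties with both endpoints preferring topic l | H3 |
| `nodeifactor.experience.1`   | ties received by experienced users               | H4         |
| `nodemix.emotion_polarity.s.r` (4 cells) | ties from sender polarity s to receiver polarity r, s,r in {pos, neg} | H5 |

Design points:

* An explicit `edges` term is always included even though the reference
  coefficient table reports none — an ERGM without a density intercept
  cannot match the observed tie count, and every other effect is
  interpreted conditional on it.  Its ground-truth value in simulations is
  *calibrated*, not assumed (below).
* Emotion mixing models exactly the four polarized cells
  (pos→pos, neg→neg, pos→neg, neg→pos); any cell involving a neutral user
  is the implicit reference category.
* Topic homophily is differential (one term per topic); gender homophily is
  uniform (a single match term).  Experience enters only as a receiver
  effect — the hypothesis is about *receiving* replies, and no
  sender-experience term is included.
* Every term in this family is within-dyad: the only state-dependent
  configuration is the reciprocal tie.  The machinery (change statistics,
  sampler, estimators) does not rely on that and is written for general
  binary terms, but the tests exploit it: a dyad-factorized exact
  likelihood provides an independent oracle at any `n`.

## Simulation

`mh_sample` runs a Metropolis–Hastings chain over single ordered-pair
toggles: pick a dyad uniformly, accept the toggle with probability
`min(1, exp(±theta·delta(i,j)))` where `delta` is the change-statistic
vector.  Defaults: burn-in `20·n(n-1)` proposals, one retained draw per
`n(n-1)` proposals; the seed is mandatory and identical inputs give
bit-identical draws.  A "tie / no tie" proposal mixture (`tnt=True`) that
proposes deletions from the current edge list half the time is available
for low-density regimes, off by default to keep the audited chain simple.
For `n(n-1) <= 20` dyads `enumerate_distribution` tabulates all states
exactly — the oracle used to validate the chain (total variation < 0.02
against the enumerated law at n = 3 with 10^6 draws).

A degeneracy guard watches model-based simulation: if the running mean of
any statistic drifts monotonically past 5x its observed value, sampling
aborts with a diagnostic instead of returning a collapsed or saturated
graph.  The reply-network family itself is dyad-separable and cannot be
degenerate, so the guard matters only for user-supplied coefficients.

## Estimation

* **MPLE** — logistic regression of each tie indicator on its change
  statistics.  All change statistics in this family are 0/1, so the
  `n(n-1)` dyads collapse onto at most a few hundred covariate patterns;
  the Newton–Raphson solver works on the collapsed table (gradient norm
  <= 1e-8) and a 6,000-node network fits in a few seconds of memory-light
  streaming.  Collinear or separated designs are rejected naming the term.
  MPLE is the exact MLE when no dyad-dependent term is present (verified
  against enumeration to 1e-6).
* **MCMC-MLE** — Geyer–Thompson: initialize at the MPLE; at each step
  simulate 512 networks at the current `theta`, maximize the
  importance-sampled log-likelihood ratio (Newton with step-halving inside
  a trust region of radius 0.5, stopped if the importance weights'
  effective sample size collapses), and repeat.  Convergence is declared
  when the parameter update norm falls below 1e-3 *or* the observed
  statistics lie within 3 autocorrelation-adjusted Monte-Carlo standard
  errors of the simulated means (the estimating-equation condition).  The
  update-norm rule alone is unreachable at 512 draws per iteration — one
  update carries ~0.04 of Monte-Carlo jitter on the rare emotion-mixing
  coordinates — which is why the moment condition is the operative rule.
  A final 4x-larger sample polishes the estimate; standard errors are the
  inverse of the importance-reweighted statistic covariance (the estimated
  Fisher information), and a fresh sample at the final estimate reports
  the moment diagnostic.  The estimation chain thins at a quarter dyad
  sweep; the moment t-statistics correct for the residual autocorrelation
  through a lag-1 effective sample size.
* **Exact MLE** — direct Newton maximization of the enumerated
  log-likelihood for `n(n-1) <= 20`, to gradient norm 1e-8.  Observed
  statistics on the boundary of their attainable range (e.g. no mutual
  dyads with `mutual` in the model) are rejected as infinite estimates
  rather than returned as large finite numbers.

Inference is two-sided Wald: `z = theta_hat / SE`, normal p-values,
`*`/`**`/`***` at 0.05/0.01/0.001.  Text reports print p at three decimals
(so p < 0.0005 renders "0.000"); JSON artifacts keep full precision.  The
reference study names neither its estimation algorithm nor its software,
and does not say whether its "S.D." column is MCMC-adjusted; the choices
above are conventional ones and the report header states the method used.

Hypothesis verdicts from a full-model fit: H1/H2/H4 are supported by a
significantly positive coefficient (alpha = 0.05); H3 is supported when
all seven topic terms are significantly positive, partially supported when
at least one is and at least one is not; H5 is supported when both
positive-sender cells (pos→pos, pos→neg) are significantly positive,
partially when exactly one is.

## Attribute coding

Raw records carry per user a gender label, a registration time, and one
sentiment score + topic label per text.  Coding is deterministic and
rank-based:

* *Emotion polarity*: users ranked by mean sentiment (ties broken by user
  table order); top `ceil(q·N)` coded positive, bottom `ceil(q·N)`
  negative, q = 0.10.  Tail counts are exact by construction.  The rule is
  invariant to strictly increasing transforms of the *user score*; with
  several texts per user the mean is taken first, so only affine
  transforms of raw text scores commute exactly.
* *Experience*: the `ceil((1-f)·N)` most recently registered users are
  inexperienced (f = 0.75): registration time is read as length of
  membership, earliest = most experienced.
* *Topic preference*: modal topic over the user's texts, ties to the
  smallest topic code.

Ceiling rounding is used throughout so the coded counts are exactly
testable (N = 6,158 gives 1,540 inexperienced / 4,618 experienced and
616 users per emotion tail).

The robustness sweep refits the model over columns M0 (baseline), M1
(gender term dropped) and M2–M5 (experience fractions 0.70/0.73/0.77/0.80),
and `sign_consistency_report` lists every term whose sign or significance
class (starred vs unstarred at 0.05) departs from the baseline column.  The
sweep's default estimator is MPLE — consistent for this family and ~30x
cheaper than MCMC-MLE across six refits — with MCMC-MLE available by flag.

## Synthetic data

The community the reference model was fitted on is not deposited, so the
generator emulates its stated shape rather than reproducing its data: a
green test establishes that the *pipeline* recovers known ground truth
from data of that shape, not that the original study is reproduced.

Stated-world defaults: 6,158 users (200 at test scale), 16,521 expected
ties (mean degree ~2.68), gender Bernoulli(0.5), a 10/10/80
positive/negative/neutral latent sentiment mix, 75/25
experienced/inexperienced split, 7 topics, and the published coefficient
vector as ground truth for all hypothesis terms.  Choices the sources do
not pin down, made once: registration times uniform over a 10-year day
span; texts per user `1 + Poisson(3)`; latent class mean sentiments
+4/−4/0 with unit text noise (separation chosen so coded polarity agrees
with the latent class for >= 95% of users — it is a *stated* world, not a
hard one); per-user topic distributions Dirichlet(0.5) over the 7 topics,
giving distinct but not degenerate preferences.

Generation order matters: attributes are coded *first* and the network is
simulated conditional on the coded (not latent) attributes — exactly what
the estimation stage later sees.  The edges coefficient is calibrated by
bisection on simulated mean degree (5% relative stopping rule), starting
from the analytic `logit(target density)`, which is already exact when all
other coefficients are zero.  Everything is seed-deterministic.

What the generator does **not** emulate: heavy-tailed degree
distributions, topic-sentiment correlation, temporal posting dynamics,
or any text content.  Conclusions about those features cannot be drawn
from green tests here.

## Scaled-down experiments and what they can show

The recovery experiment (20 replicates at n = 200) checks that each
coefficient's mean estimate sits within 2 Monte-Carlo standard errors of
its generating value — an unbiasedness check that scales with its own
noise.  The qualitative sign-pattern experiment is harder than it looks:
at 1/30th of the reference scale the weak effects (receiver experience
0.103, topic homophilies ~0.3, the rarer emotion cells) have per-fit
standard errors of the same order as the coefficients themselves, so the
probability that *every* sign in the pattern is right in a single seed is
well below one even for a perfect estimator.  The experiment reports the
observed fraction honestly; the per-term directions, and the strong terms'
significance (reciprocity, neg→pos), are stable.

## Known limitations

* Only within-dyad terms are implemented — no triadic closure (GWESP),
  degree terms, or curved families.
* MPLE standard errors are the naive logistic ones; for dyad-dependent
  models use the MCMC-MLE errors.
* The exact enumerator is limited to 20 dyads (n <= 5) by design.
* Weighted, temporal and bipartite networks are out of scope.
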