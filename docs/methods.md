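# Methods

## The contest game

Two larvae with relative sizes $s_1, s_2 > 0$ (dimensionless; nothing
requires $s \le 1$) simultaneously choose aggressiveness $a_i \ge 0$.
Competitive strength is multiplicative, $\theta_i = s_i a_i$: a given
increment of aggressiveness counts for more in a larger animal. Contestant 1
wins with probability $\omega_1 = \theta_1/(\theta_1 + \theta_2)$; exactly
one contestant survives. The survivor's direct fitness $\upsilon_i$ falls
with its own aggressiveness at an accelerating rate (mild aggression is
cheap, escalated aggression very costly) under three alternative cost
structures: size-independent ($1 - a^2$), size-proportional ($s - a^2$) and
size-scaled cost ($1 - (a/s)^2$). Killing a relative of relatedness $r$
forfeits $r$ times the victim's prospective fitness, so the focal's expected
inclusive fitness is $F_1 = \omega_1(\upsilon_1 - r \upsilon_2)$; the
loser's inclusive fitness is zero.

**Strategy domain.** Aggressiveness is restricted to
$[0, a_{\max}(s)]$ where direct fitness reaches zero
($a_{\max} = 1, \sqrt{s}, s$ respectively). Values beyond the bound are
rejected rather than clamped: a winner with negative reproductive success is
meaningless and silent clamping would create spurious flat regions for the
optimizer.

**Degenerate win probability.** $\omega$ is undefined at
$\theta_1 + \theta_2 = 0$. We define $\omega_1 = s_1/(s_1+s_2)$ there — the
limit along any path $a_1 = a_2 \to 0^+$. The alternative convention (1/2)
changes nothing at any equilibrium with positive aggression.

**Supremum-type best responses.** Against a passive opponent
($a_2 = 0$), any $a_1 > 0$ wins outright, so $F_1$ is maximised in the limit
$a_1 \to 0^+$ and no maximiser exists whenever the limiting payoff
$\upsilon_1(0) - r\upsilon_2(0)$ exceeds the payoff at exactly zero. Such
best responses are reported as the limit point 0.0 with a
`sup_not_attained` flag. Reporting a small positive epsilon instead would
tie the reported value to the solver's grid resolution, making fixed points
disagree with their independent fine-grid verification; the flag keeps the
open-limit character of these equilibria visible (they matter in the
size-proportional formulation, where a smaller relative cedes the contest
once $s_{\text{large}} > s_{\text{small}}/r$ and the equilibrium is the
closure point of $(\varepsilon, 0)$ pairs).

## Equilibrium computation

Best responses are computed by a coarse scan (default 1001 grid points)
over the admissible interval followed by bounded Brent refinement around
the best grid point; both endpoints are always evaluated (corner equilibria
are real possibilities here) and ties break toward the smallest
aggressiveness, a deterministic and biologically conservative rule.
Equilibria come from Gauss–Seidel iterated best response, run from the two
corner pairs plus 8 quasi-random starts (golden-ratio lattice), stopping
when the max absolute strategy change falls below `br_tol` (1e-8; at most
500 iterations). A restart that fails to settle is retried once with
damping 0.5 and flagged as oscillation rather than hidden. Distinct fixed
points across restarts (separated by more than 10x the refinement
tolerance) are recorded in `multiplicity_note`; the reported equilibrium is
the lexicographically smallest, a deterministic choice since uniqueness is
not guaranteed in general.

Verification is independent of the solver path:
`verify_mutual_best_response` recomputes both best responses on a dense
grid (default 2e5 points) and checks agreement within tolerance. For
symmetric contests the first-order condition
$\partial F_1/\partial a_1 = 0$ at $a_1 = a_2$ gives, for all three
formulations, $(1-r)\,\upsilon(a) = 4a^2 \cdot (\text{cost scale})$ and
hence the closed forms $a^* = \sqrt{(1-r)/(5-r)}$,
$\sqrt{s(1-r)/(5-r)}$, $s\sqrt{(1-r)/(5-r)}$; the tests confirm these
against brute-force payoff grids of 1e6 points before using them as
oracles, and check that numeric equilibria are invariant to doubling the
grid resolution.

The default sweep holds the smaller contestant at $s = 0.1$ and varies the
larger's size over 0.1–1.0 in steps of 0.01 for $r \in \{0, 0.25, 0.5\}$
and all three formulations (819 rows). Its tested qualitative structure:
with size-independent costs the smaller contestant is at least as
aggressive as the larger (compensation); with size-proportional fitness a
related smaller contestant has a zero-aggression corner beyond some size
gap (sacrifice); with size-scaled costs the larger contestant is at least
as aggressive everywhere and its equilibrium aggression does not increase
with relatedness.

## The synthetic-trial generator

The generator emulates the dyadic experiment the statistical models were
designed for, with these defaults as the study conditions:

* **Roster.** 15 dyads per relatedness level (full sibling $r=0.5$,
  paternal half sibling $r=0.25$, non-sibling $r=0$; 45 dyads, 90
  animals). Masses are two independent uniforms on 0.04–0.38 g accepted
  when their difference lies in 0.03–0.30 g (so the mass-difference
  marginal is triangular); the heavier animal is "large". Full siblings
  share a breeding pair; half siblings share only a sire; non-siblings
  share nothing.
* **Observation scheme.** Scan sampling every 15 s: 40 acclimation scans
  (10 min, pre-contact) and up to 240 experimental scans (60 min). Counts
  are capped at the phase's scan budget — an instrument property the
  unbounded GLMMs cannot represent — and cap hits are counted. An optional
  early-termination switch truncates a trial (emulating stopping a
  potentially lethal attack); it is off by default.
* **Count models.** Per tadpole, log mean = intercept + relatedness +
  relative size + interaction + pair intercept + family intercept +
  log(duration in seconds). Aggression (bites + chases) is Poisson with
  intercept −8.03 (≈1.2 events per hour for a small non-sibling), size
  effect 1.42 and siblings × size −1.12; pair variance 1.04, family 0.13.
  Experimental activity is NB2 with ratio-scale effects converted to log
  scale (size 3.46 → 1.241); its printed intercept is only a rounded ratio
  ("0.00"), so we set log(0.005) per second (~18 active scans/h at
  baseline), the value consistent with the reported z ≈ −22 and interval
  after back-transformation. Acclimation activity carries no size or
  relatedness effects (none are detectable before contact) and an
  intercept giving 20 of 40 scans active. NB2 sizes $\theta$ (1.86
  experimental, 0.23 acclimation) map the two reported residual variances
  through $\sigma^2 \approx \ln(1 + 1/\theta)$ — a documented
  approximation, not an exact identity.
* **Offset units.** Exposure is the trial duration in seconds (3600 for a
  full trial); this makes the aggression intercept imply a plausible
  ~1.2 baseline events per trial.
* **Random effects.** One standard-normal draw per pair and per family,
  shared across the activity and aggression arms (the models are fitted
  separately but describe the same animals) and scaled by each arm's own
  variance; sharing is configurable off.
* **Latency.** One first-bite time per dyad, exponential with hazard
  $\lambda_0 \exp(\eta)$ per second, $\eta$ linear in relatedness, mass
  difference (per gram: main 0.89, half-siblings × 9.62, siblings ×
  16.32), censored at trial end. No family frailty by default (no
  random-effect variance is reported for this model); the hook exists and
  is configurable. The baseline $\lambda_0 = 4.933\times10^{-4}$/s is the
  output of `calibrate_baseline_hazard`, which integrates the event
  probability over the design's covariate distribution and solves for the
  pooled empirical event fraction 38/45; the first biter is the larger
  animal with probability 29/38 (the pooled empirical fraction),
  independent of the time, with per-level probabilities configurable.

What the generator deliberately does **not** emulate: scan-by-scan
behavioral sequences (only phase totals and first-event times, which is all
the fitted models consume), behavioral dependence between the latency and
count outcomes beyond shared covariates, and any kin-recognition mechanism.
Passing recovery tests therefore show that the statistical design
identifies its coefficients under its own assumptions — not that those
models are correctly specified for real animals.

## Refitting and recovery

The refits mirror the generating structures: Poisson GLM (log link,
duration offset) for aggression; NB2 maximum likelihood for activity; Cox
proportional hazards on relatedness × mass difference for latency, with
the non-sibling/small cell as reference levels throughout. Dyad and family
random intercepts are handled **marginally**: the count models use
pair-clustered sandwich covariances and the Cox model family-clustered
robust covariances, because the pinned Python stack has no frequentist
mixed-GLMM fitter (and none at all for negative-binomial responses). This
is a deliberate design, not an approximation of convenience: with a log
link and covariate-independent random intercepts the slope coefficients of
the marginal and conditional models coincide, so every coefficient the
recovery study tracks is estimated without bias; only count-model
intercepts absorb the usual $+\sigma^2/2$ lognormal shift, which the
recovery summaries display rather than hide. Replicate fits never raise:
non-convergence is flagged and counted.

`recovery_experiment` splits one master seed into per-replicate seeds,
generates independent experiments, refits the requested models, and
summarises per coefficient: generating value, mean estimate, bias,
empirical SD, 95%-interval coverage, and non-convergence count.

**Problem sizes.** Headline recovery runs use 200 replicates at 100 dyads
per level (count models) and 150 per level (latency, baseline recalibrated
to an ~85% event fraction), separating estimator small-sample bias from
implementation error; paper-scale runs (15 per level) are available through
the same interface. Null calibration uses an intercept-only generator with
all slopes and variance components zero (so the marginal fits are exactly
correctly specified) at 50 dyads per level, 500 replicates, checking that
95% intervals cover zero 90–99% of the time.

## Numerical and degenerate-input choices

* Best-response refinement tolerance 1e-9 (Brent `xatol`); equilibrium
  separation and symmetric-equality checks at 10x that.
* $r = 1$ symmetric contests: the analytic equilibrium degenerates to 0
  (the $(1-r)$ numerator vanishes); handled, tested.
* Zero trial duration yields zero counts (zero exposure), not an error.
* All-censored latency data and single-level designs are rejected as
  precondition errors before fitting.
* The NB2 refit is started from the Poisson solution with a moderate
  dispersion guess and optimised by BFGS; near-Poisson data drive the
  dispersion parameter toward its boundary, which affects the dispersion
  estimate, not the slopes.

## Known limitations

* Equilibrium multiplicity is recorded (restart-based), not exhaustively
  resolved; no stability classification (ESS/convergence stability) is
  attempted.
* The marginal-fit design recovers fixed-effect slopes but does not
  estimate random-intercept variances; researchers needing variance
  components should fit the generated CSVs with a dedicated mixed-model
  package.
* The scan-budget cap truncates the extreme upper tail of generated counts
  (≈0.02% of aggression rows at default settings, more for the strongly
  overdispersed acclimation arm), slightly attenuating means relative to
  the unbounded GLMM; this is a property of scan sampling itself.
* Cox small-sample bias at paper-scale n (15 dyads/level, ~38 events) is
  visible in single fits; the recovery design quantifies rather than
  corrects it.
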