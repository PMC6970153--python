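# Methods

## The game and its solution

The asymmetric matching-pennies game is parameterized by four strictly
positive win payoffs: the participant's match payoffs (60 and 20 JPY for
HIGH and LOW by default) and the opponent's mismatch payoffs, keyed to the
*participant's* chosen symbol (40 JPY after a HIGH mismatch, 20 after a
LOW mismatch). The loser of every trial receives 0. With this keying, each
player's equilibrium mixing rate is the point at which the *other* player
is indifferent:

- opponent HIGH rate `q* = p_win_low / (p_win_high + p_win_low)` = 1/4,
- participant HIGH rate `p* = o_after_low / (o_after_high + o_after_low)` = 1/3.

At (1/3, 1/4) both players' options have equal expected value (15 JPY for
the participant). The solver refuses non-positive payoffs rather than
clamping. Payoffs with `p_win_high = p_win_low` are allowed (they give the
symmetric 50/50 equilibrium and are useful as a degenerate control), but
`p_win_high < p_win_low` is rejected so that "HIGH" always names the
better-paying match.

The schedule is 4 runs × 3 blocks × 12 trials; each run contains exactly
one block per opponent type, with block order drawn from the six
permutations by a seeded pick and rotated Latin-square fashion across
runs. Physical details (left/right placement, symbol identity, response
timing) are deliberately not modeled: the HIGH/LOW abstraction carries all
the decision-relevant structure.

## Opponents

**FIX** chooses HIGH with the constant equilibrium probability, ignoring
history. **LRN** is a single-layer perceptron with sigmoid output

```
f(x) = 1 / (1 + exp(w · x)),
```

over 19 inputs: for each of the six most recent trials, three binary
features (participant chose HIGH, LRN chose HIGH, participant won), most
recent trial first, zeros where history is shorter than six; plus a
constant 1 whose weight absorbs the participant's average HIGH bias. Note
the sign convention — the exponent is *plus* `w·x`, so larger weighted
sums mean a *lower* probability of LRN choosing HIGH. A ±1 feature
encoding is available behind the `encoding="signed"` flag; binary 0/1 is
the default.

Each trial, weights move one gradient step on the squared prediction
error `E = (T − f(x))²`, where `T = 1` if the participant chose LOW:

```
Δw_i = −a ∂E/∂w_i = −2a (T − f) f (1 − f) x_i,     a = 0.25.
```

Because LRN then chooses HIGH with probability `f(x)` — its prediction
that the participant will choose LOW — it probability-matches rather than
best-responds. Against a player choosing HIGH with constant rate `p`, its
HIGH rate converges to `1 − p` and its win rate to `p² + (1 − p)²`
(0.68 at `p = 0.8`); the simulation studies verify this asymptote.
Weights start at zero (an uninformative prior over the participant's
bias); weights and the six-trial history persist across blocks and runs
within a session, modeling continuous learning through the experiment.
Pre-training on warm-up data amounts to running `lrn_update` on it before
play.

## Behavioral models

All three models map a value difference to a HIGH-choice probability
through the softmax `P(H) = 1/(1 + exp(−β(V_H − V_L)))`.

- **WRM** (winning-rate maximization): delta rule
  `V_chosen ← V_chosen + α (r − V_chosen)` with `r = 1` on a win, 0 on a
  loss, regardless of money.
- **RL**: the same delta rule with the monetary outcome rescaled onto
  [0, 1]: `r = 1` for a HIGH win, `1/3` for a LOW win (20/60), 0 for a
  loss. The rescaling puts β on the same scale as WRM's, so AICs and β
  values are comparable across the two.
- **QRE**: no learning; `V_H, V_L` are the expected values
  `EV_H = p_win_high · q̂`, `EV_L = p_win_low · (1 − q̂)` computed from the
  opponent's empirical HIGH rate `q̂` over the analyzed trials. Its only
  free parameter is β. When the opponent plays exactly the equilibrium
  rate the two EVs tie, the likelihood is flat in β, and the parameter is
  unidentified — the fit then reports β at whatever bound the optimizer
  reaches first; downstream code should treat QRE fits against
  equilibrium opponents as baselines, not estimates.

Likelihoods accumulate `−log P(observed choice)` trial by trial, with
values updated on the observed choice and recoded reward. Both values
initialize at 0.5 (the midpoint of the aligned reward range; configurable
via `FitConfig.v_init`), and the first trial is included in the
likelihood — at initialization it always contributes exactly `ln 2`.

Fitting is maximum likelihood by L-BFGS-B under box bounds `α ∈ [0, 1]`,
`β ∈ [0, 50]`, with 10 starts (one fixed at the center, nine seeded
uniform draws) and tolerance 1e-6; the best start wins and results are
bit-reproducible given the seed. A grid-search audit (51 × 101 lattice)
found the multi-start optimum at or below the grid optimum in ~99% of
fits, the exceptions being degenerate ridges where the "global" optimum
is a boundary artifact. Fits with β at the upper bound are logged as
warnings: they indicate near-deterministic choice sequences for which α
is weakly identified. AIC = 2k + 2·NLL with k = 2 (WRM, RL) or 1 (QRE).

The posterior predictive check runs the fitted model forward on the
observed history and draws simulated choices from its per-trial
probabilities; the match rate against the observed sequence has chance
level 0.5.

## Synthetic study conditions

No behavioral or imaging data from the original experiment is deposited,
so the generators define the study conditions the pipeline is validated
under:

- **Cohorts.** Each participant is a WRM learner with per-condition
  (α, β). Learning-rate means follow the fitted participant values (0.34
  for HUM and FIX, 0.40 for LRN) with sd 0.15, clipped to [0, 1]. β has
  no reported population estimate; β ~ N(5, 1.5²) truncated at 0 was
  chosen once for healthy identifiability at 48 trials per condition
  (β = 5 puts softmax choice around 0.92 at the game's typical value
  separations — decisive but stochastic). The human opponent is proxied
  by an independent WRM learner in the opponent role (it wins on
  mismatches) with α = 0.26, the learning rate fitted to the real human
  opponents, and β = 5. Per-participant seeds spawn from a master seed;
  the truth table stores the generating parameters.
- **ROI patterns.** Per participant, each of the six (opponent × choice)
  patterns over `n_voxels = 200` voxels is
  `u_opponent + λ_shared·s·[opponent ∈ {HUM, LRN}] + σ_choice·c_choice +
  σ_noise·ε` with independent standard-normal voxel vectors. λ_shared = 0
  makes the three opponents exchangeable (the null of the similarity
  contrast); λ_shared = 1 with σ_choice = 0.5, σ_noise = 1 plants a
  HUM–LRN similarity excess detectable at n = 30. Patterns are generated
  directly at the beta level — no BOLD forward model, no fMRI noise
  spectrum — because the RSA stage consumes beta patterns and nothing
  upstream of them.

What passing the studies shows, and does not: recovery and calibration
results demonstrate that the fitting and contrast machinery is correct
and adequately powered *under these generative assumptions* (softmax
delta-rule choice, Gaussian voxel patterns, no session drift, no missed
trials, no motion or physiological artifacts). They do not certify
effect sizes or power for real participants.

## RSA

Pattern distances are `1 − Spearman ρ` (average ranks on ties; constant
patterns are an error, not a silent NaN), collected into a symmetric 6 × 6
RDM with zero diagonal and entries in [0, 2] — violations raise. The
headline contrast first collapses high/low choices by voxelwise averaging
of the two beta maps within each opponent ("collapse, then correlate";
averaging the four pairwise choice-level correlations instead is available
via `method="average_correlations"`), Fisher-z-transforms the HUM–LRN and
HUM–FIX Spearman correlations, and applies a paired t test across
participants. |ρ| = 1 raises rather than returning an infinite z.
Bonferroni correction across ROIs is the caller's responsibility — the
module analyzes a single ROI.

## Simulation studies and numerical choices

`matchingpennies.studies` packages the validation studies used by the
test suite and the reproduction script:

- *Gradient check*: the analytic 19-element weight step is compared to a
  central finite difference of `a·E` at step 1e-6 over 1000 random
  states, in vector norm with mixed tolerance
  `||Δ_analytic − Δ_fd|| ≤ rtol·||Δ_fd|| + 5e-10`; the absolute floor is
  the FD roundoff scale (eps/h), which dominates on saturated-sigmoid
  states whose true gradient is smaller than the noise of the oracle
  itself.
- *Exploitation*: 20 seeds × 2000 trials against a 0.8-HIGH scripted
  player; mean LRN win rate over the last 500 trials vs the 0.68
  asymptote.
- *Learning-rate recovery*: 50 participants, one true α ~ U(0.2, 0.5)
  each, β = 5, full schedule; WRM fit per condition and the participant
  estimate is the mean of the three condition fits (a single 48-trial fit
  is heavy-tailed — occasional sequences are genuinely best explained by
  near-deterministic parameters — and averaging the three conditions is
  the natural participant-level estimator in this design). Reported:
  Pearson correlation and median |α̂ − α|. The single-study correlation
  has sampling sd ≈ 0.08 around ≈ 0.58.
- *Model recovery*: 25 replicate cohorts of 8 participants per generator
  (WRM, RL), α ~ N(0.35, 0.1) clipped, β = 5, 48 trials against each of
  the three opponents; success = the generator achieves the lowest mean
  AIC across all fits. Cohort size 8 keeps a replicate under two seconds
  while the mean-AIC ordering is already stable at that n.
- *RSA calibration/power*: 500 null replicates (λ_shared = 0) for the
  type-I error of the paired test at nominal 0.05, and 200 replicates at
  λ_shared = 1, n = 30 for directional power.

Ties at p = 0.5 need no special handling anywhere: choices are drawn by
comparing a uniform variate to the probability, which is the seeded coin
flip. All randomness flows through `numpy.random.default_rng` seeds;
every study, generator, and fit is reproducible from its seed alone.

## Known limitations

- The QRE implementation is the printed one-shot logit response to the
  empirical opponent rate, not an iterated fixed-point equilibrium.
- The RL reward rescaling {1, 1/3, 0} is participant-side; the generative
  `ValueLearnerAgent` in the opponent role applies win/loss (WRM) coding,
  which is the only opponent variant the cohort generator uses.
- Learning-rate estimates from 48-trial conditions are noisy by nature;
  single-condition α̂ should not be interpreted individually, only in
  aggregate.
- The beta-pattern generator shares the choice component `c_choice`
  across opponents, so choice decodability is uniform by construction;
  analyses of choice × opponent interactions in pattern space would need
  a richer generator.
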