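# Methods

`igtrl` models choice behavior in the Iowa Gambling Task (IGT): 100 trials of
drawing from four card decks whose gains are immediate and whose losses are
scheduled per block, so that decks A/B (100 per draw) lose 250 net per ten
draws while decks C/D (50 per draw) gain 250. This note documents the models,
the estimation and comparison machinery, the behavioral metrics, the
synthetic-data generator, and the numerical choices behind them.

## Task environment

`build_bechara_scheme()` encodes the classic payoff table: per ten draws from
a deck, gains are fixed per draw and a fixed multiset of loss magnitudes is
dispensed (A: {150, 200, 250, 300, 350}; B: {1250}; C: {25, 50, 50, 50, 75};
D: {250}). The table fixes only the per-block multiset, not the position of
each loss within a block, and published implementations differ, so two
scheduling modes exist:

* `random-position` (default): each block's losses land at uniformly random
  positions without replacement, keyed by `(seed, deck, block)` so stateless
  calls within one block are mutually consistent;
* `fixed-order`: losses land at canonical within-block positions (A and C at
  positions 3, 5, 7, 9, 10; B at 9; D at 10), replicating the commonly used
  first-block card order and giving exact-replay tests a deterministic
  schedule.

Deck C's multiset {25, 50, 50, 50, 75} is the unique widely used schedule
consistent with loss amounts {25, 50, 75}, five losses per block, and a +250
block net. Losses are stored as magnitudes; files that encode losses as
negative numbers are sign-normalized on read. Sessions store raw currency;
division by `scale_divisor` happens only inside utility computations.

## The EEF model

Each deck *d* carries two latent weights. After choosing deck *c* and
observing gain/loss feedback with subjective value
V(t) = (gain/s)^θ − LA·(loss/s)^θ:

```
Exploitation_c ← (1 − λ)·Exploitation_c + V(t)      chosen deck
Exploitation_d ← (1 − λ)·Exploitation_d             unchosen decks
Exploration_c  ← 0                                  chosen deck
Exploration_d  ← λ·Exploration_d + (1 − λ)·φ        unchosen decks
P(choice = d)  = softmax over (Exploitation + Exploration)·C,  C = 3^β − 1
```

Parameters: forgetting rate λ ∈ [0, 1], outcome sensitivity θ ∈ [0, 1],
exploration incentive φ ∈ [−5, 5], inverse temperature β ∈ [0, 5]
(consistency C ∈ [0, 242]), and loss aversion LA ∈ [0, 5] (free only in the
EEFLA variant; EEF pins LA = 1). λ governs both channels: at λ = 1 only the
current trial's outcome matters and exploration weights never leave zero; a
never-chosen deck's exploration weight approaches φ geometrically,
|e_t − φ| = λ^t·|e_0 − φ|.

**First-choice prior.** Initial exploitation weights are inverted from the
pooled first choices of the public 504-participant dataset
(A: 193, B: 126, C: 105, D: 80): w_d = (ln p_d − mean ln p)/C at β = 3,
giving w_ini ≈ [0.0184, 0.0020, −0.0050, −0.0155]. The prior sits in the
exploitation channel so it decays by (1 − λ) per trial like any other value
memory; it applies to EEF/EEFLA only (the baselines have no decaying memory
trace to host it) and a `use_prior=False` switch gives the zero-initialized
variant.

**Payoff scaling.** Raw currency divided by 100 before the utility — the
natural unit given softmax gains up to 242 and prior weights of order 0.02;
unscaled payoffs of ±1250 would saturate the softmax. The divisor is
configurable and is part of every scheme object.

**Edge cases.** 0^θ is defined as 0 for all θ (a no-gain or no-loss side
contributes nothing), which also fixes the 0^0 corner. State updates are
pure functions, so teacher-forced likelihood and free simulation share one
code path; a jitted kernel reimplements the same walk for speed and is
tested for exact equality against the agent objects.

## Baseline models

The six comparison models are implemented from their original publications
under the same agent interface (reset / choice probabilities / update), all
consuming scaled currency and starting from zero values:

| model | k | core rule |
|---|---|---|
| EV (Busemeyer & Stout 2002) | 3 | valence (1−w)·gain − w·loss, delta rule, trial-dependent sensitivity (t/10)^c |
| PVL (Ahn et al. 2008) | 4 | prospect utility x^α / −w·\|x\|^α on net, decay-reinforcement, sensitivity 3^c − 1 |
| PVL-Delta (Ahn et al. 2008) | 4 | prospect utility, delta rule on the chosen deck |
| ORL (Haines et al. 2018) | 5 | split reward/punishment learning rates, signed win-frequency trace with fictive updates, perseveration decaying by 1/(1+K) |
| VPP (Worthy et al. 2013) | 8 | PVL-Delta value mixed (w) with a decaying perseveration trace taking ±impulses |
| VSE (Ligneul 2019) | 5 | value module with multiplicative decay plus delta-rule exploration toward a bonus φ |

Bounds not printed in any source were set to the conventional boxes
(learning/decay/shape/weight parameters in [0, 1], loss aversion and
consistency in [0, 5], signed bonuses in [−5, 5], VPP impulses in [−1, 1]).
Variant details differ across published implementations of ORL/VPP/VSE
(e.g., the exact perseveration bookkeeping); the choices here are documented
in the class docstrings rather than guessed to match any particular toolbox.

## Estimation and model comparison

**Likelihood.** Teacher forcing: the model is updated on the participant's
actual choice and outcome each trial, and the NLL sums −ln P over trials.
Probabilities are floored at 1e−12 before the log so the NLL stays finite at
bound-edge parameters.

**Fitting.** Each bounded parameter is mapped to the real line by a scaled
logit; `fit_mle` runs Nelder-Mead from `n_starts` (default 20) uniformly
drawn seeded starting points and keeps the best NLL, breaking ties toward
the earlier start. Convergence tolerances: fatol 1e−6, xatol 1e−4, at most
2000 evaluations per start. Fits are deterministic given the seed.

**Criteria.** AIC = 2k + 2·NLL and BIC = k·ln(n) + 2·NLL with n the trial
count. Free energy is a Laplace approximation to the log evidence:
independent N(0, 1.5²) priors on the transformed parameters, the posterior
mode found by re-optimizing the penalized objective from the MLE, and
F = log L(θ*) + log p(θ*) + (k/2)·ln 2π − ½·ln det H with H the
finite-differenced Hessian of the negative log joint. The additive
breakdown (accuracy, prior, dimensionality, entropy terms) is reported so
the approximation is auditable; a non-positive-definite Hessian triggers a
flagged fallback to −BIC/2. −2F is emitted for comparison tables so free
energy lives on the same scale as AIC/BIC. A full variational inversion is
not attempted, so numerical equality with variational-Bayes toolbox outputs
is not claimed — at n = 100 the Laplace evidence and −BIC/2 agree to O(1).

**Fixed effects** sums each criterion over sessions and reports deltas
against a reference model (positive = worse than the reference).
**Random effects** is the variational Dirichlet-multinomial scheme:
responsibilities u_nk ∝ exp(ψ(α_k) − ψ(Σα) + log E_nk), α = α₀ + Σu,
iterated to max|Δα| < 1e−6 (α₀ = 1), reporting expected model frequencies
α/Σα. Frequencies are invariant to per-session constant shifts of the log
evidence.

## Behavioral forgetting metrics

**SE events / SED.** An SE event is four consecutive trials visiting four
distinct decks (overlapping windows count). Sequential Exploration Decay is
the ratio of SE events in trials 1–50 to trials 51–100; windows never
straddle the boundary, keeping the phases disjoint. Cohort SED is
pooled-counts by default (robust to sessions with zero late-half events; a
zero pooled denominator sets an infinity flag); a per-session-mean mode is
available. Under uniform random choice the per-window SE rate is
4!/4⁴ = 9.375% and SED is 1 in expectation.

**Forgetting Interval.** After a trial whose chosen-deck net outcome is
negative, FI is the number of trials until that deck is reselected; events
with no reselection are censored and excluded from the mean (censored +
measured = feedback-event count). "Negative feedback" defaults to net < 0 —
deck C's small losses net ≥ 0 and do not count — with an `any-loss`
alternative since a large-loss reading is also defensible. Under uniform
random choice the interval is geometric with mean 1/p = 4 trials. (A
published expectation formula for this baseline contains a typographical
slip; the standard geometric expectation, which matches the stated value of
4, is used.)

**Statistics.** The group-test helpers delegate to scipy (chi-square
goodness of fit, one-sample and Welch t, binomial test) plus a hand-rolled
Fisher z for comparing correlations. Statistics are always recomputed from
the data: the chi-square for the first-choice counts [193, 126, 105, 80]
against uniformity recomputes to 7046/126 ≈ 55.92, and that recomputed value
is what the package reports.

## Synthetic cohorts and recovery

`generate_synthetic_cohort` draws independent parameter sets (uniform over
the model's parameter box by default; a range-restricting dict or a callable
sampler may replace it), simulates one 100-trial session per set, and
returns the cohort with its truth table. All randomness flows from one root
seed through split child streams (parameters, choices, loss placement), so
cohorts are bit-reproducible.

`parameter_recovery` refits each simulated session and reports per-parameter
Pearson correlations between z-scored generating and recovered values
(z-scoring leaves r unchanged; it matches how recovery scatter is usually
plotted), their mean as the composite, and two accuracy measures:
*fitted-choice accuracy* (one-step-ahead argmax prediction under teacher
forcing, ties to the lowest deck index; a probability-weighted score is
available behind a flag, since the argmax convention is a design choice) and
*simulated-choice agreement* (trial-indexed match rate of free-running
simulations, default one generating session per parameter set and a small
number of agreement replicates). Zero-variance parameters are flagged NaN
and excluded from the composite. `compare_recovery` applies Fisher z to
composites and Welch t to per-session accuracies.

Under the defaults (uniform sampling over the full box, N = 200, T = 100,
20-start fits) the exploration bonus and consistency recover well
(r ≈ 0.9 and 0.75) while the forgetting rate and especially the outcome
sensitivity are attenuated (r ≈ 0.6 and 0.4): a uniform box places many
agents in weakly identified corners (β near 0 yields near-random choices; θ
near 0 flattens utilities), where the MLE is noise-dominated. Holding the
other parameters at informative values, λ alone recovers at r ≈ 0.99, so the
attenuation is a property of the sampling conditions, not of the optimizer —
fitted NLLs match or beat the generating parameters on every session.
Recovery correlations reported for cohorts whose generating parameters come
from fits to real participants (a much more informative distribution) are
therefore expected to be substantially higher than the uniform-box figures.

## What the generator does and does not emulate

Synthetic cohorts reproduce the task's payoff structure, trial count, and
model-driven choice stochasticity, and they give recovery studies exact
ground truth. They do not emulate human features outside the fitted models:
session-to-session nonstationarity, boredom or fatigue drifts, response
times, or the demographic structure of real cohorts. Tests passing on
synthetic data therefore validate the machinery (simulation, likelihoods,
estimation, metrics) and the models' internal consistency — not any claim
about how well a model describes human data, which requires fitting the
public datasets through the same I/O layer.

## Problem sizes and determinism

Default study sizes were chosen to estimate each quantity to useful
precision on a single CPU: recovery and model-comparison studies use N = 200
sessions of T = 100 trials with 20-start fits; chance-level baselines are
verified on a 100,000-trial uniform-agent run (≥ 3σ Monte-Carlo agreement);
metric-faithfulness checks use 10 simulation replicates per parameter set.
Every stochastic routine takes an explicit seed and derives child streams
via `numpy` seed sequences; identical seeds give bit-identical outputs.

## Known limitations

* Estimation is per-session maximum likelihood; no hierarchical pooling or
  MCMC posteriors.
* The free energy is a Laplace approximation, not a variational inversion.
* Baseline formulations follow the cited papers; toolbox-specific variants
  of ORL/VPP/VSE may differ in detail.
* The loss-schedule dialect used by any particular empirical study (fixed
  card order vs randomized positions) is not always documented; both modes
  are provided and the choice is recorded in session metadata.
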