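# Methods

`dvbelief` implements a family of Bayesian observer models for sequential
magnitude decisions, together with the statistical machinery used to measure
the history effects those observers produce: choice-decomposed probit
regressions, KL-divergence influence measures, synthetic experiment
generators and a grid-search model-comparison harness.

## The observer family

An observer experiences a sequence of stimulus magnitudes `s_t` drawn from a
fixed normal population and performs up to three tasks on each:
*classification* (sort `s_t` into one of G quantile-defined classes),
*scaling* (report the stimulus's quantile on a continuous 0–1 scale) and
*reproduction* (report the absolute magnitude).  The model separates two
representational spaces:

* **Stimulus space.**  A sensory measurement `m_s ~ N(s, σ_s)` is combined
  with a prior over magnitudes (base prior `N(s0, σ_s0)`) and the stimulus
  estimate `ŝ` is the posterior mode (MAP).  Reproduction reports `ŝ`.
* **Decision-variable (DV) space.**  The DV is the quantile of the stimulus
  within its population, bounded in [0, 1].  The estimate `ŝ` is mapped
  through the CDF of the current stimulus prior (the probability integral
  transform) into a DV measurement `m_v`; the DV estimate `v̂` is the MAP of
  the product of a DV prior with the bounded-diffusion likelihood
  `B(·, σ_v)` evaluated at `m_v`.  Scaling reports `v̂`; classification
  commits to the class whose bin `((k-1)/G, k/G]` contains `v̂`.

`B(v, σ)` is the density of a Brownian particle released at `v` on [0, 1]
with reflecting walls.  It is constructed exactly as in its generative
description: a normal `N(v, σ)` is laid out on an effectively bounded space
`[-b, b]` with `b = 4` (at the largest start point and diffusion strength
considered, the normal density at the bound is below 10⁻⁴⁸ of its peak) and
repeatedly folded about 0 and 1 until no mass remains outside.  Folding is
performed on the evaluation grid, whose spacing divides both the unit
interval and `b`, so reflections map grid points onto grid points; the
folded result agrees with the method-of-images closed form to better than
10⁻⁶ relative error everywhere (tested).

Two prior beliefs are updated **in parallel** between trials:

* the stimulus prior is attracted toward a noisy memory trace
  `mm ~ N(s_t, σ_s′)` of the previous stimulus, with
  `σ_s′² = σ_s² + σ_mms²` (sensory plus memory diffusion variance); and
* after a classification commitment, the DV prior is conditioned on the
  chosen class -- masked to the chosen bin, renormalized -- and blurred with
  a leak kernel `N(0, σ_leak)`, then folded back into [0, 1].

The finer the previous decision (larger G), the narrower the conditioned DV
prior, hence the stronger the pull it exerts on the next DV estimate: this
is the mechanism behind the granularity effect on choice attraction.  The
stimulus-prior attraction, passed through the probability integral
transform, shifts the transform itself toward the previous stimulus and
thereby *repels* the next DV measurement away from it -- stimulus repulsion
in scaling and classification without any repulsion in reproduction.

### Variants

| variant | free parameters | removed / added machinery |
|---|---|---|
| `standard` | σ_s0, σ_s, σ_mms, σ_leak, σ_v | both updating streams |
| `sensory_adaptation` | σ_s0, σ_s, g | no belief updating; likelihood gain `f(x) = 1 − g·N(x; m_s_prev, σ_s)` (clamped at 0) dents the likelihood around the previous measurement |
| `stim_prior_by_stimulus` | σ_s0, σ_s, σ_mms | stimulus-prior updating only; flat DV prior, `v̂ = m_v` |
| `stim_prior_by_choice` | σ_s0, σ_s, σ_mms, σ_leak | stimulus-prior updating plus conditioning of the stimulus prior on the chosen class via its own inter-quantile interval; flat DV prior |
| `dv_prior_by_choice` | σ_s0, σ_s, σ_leak, σ_v | DV-prior conditioning only; static stimulus prior |

Each variant accepts exactly its own parameter subset; supplying an unused
parameter is an error, which keeps grid definitions honest.

### Numerical choices

* Grids: 2001 points spanning `s0 ± 6 σ_s0` for stimulus space, 1001 points
  on [0, 1] for DV space.  MAP estimates are refined by quadratic
  interpolation around the grid argmax, which brings conjugate-Gaussian
  cases to within 10⁻⁴ of the closed-form posterior mode.
* The generative DV-likelihood convention (the likelihood of state `v` is
  the density of `B(v, σ_v)` at the measurement) is the default.  The
  folded density obeys the exchange symmetry `B(v, σ)(x) = B(x, σ)(v)`
  term-by-term in its image expansion, so the likelihood profile over `v`
  is computed as the single density `B(m_v, σ_v)` on the `v` grid; the
  truncation at `±b` perturbs this identity only below 10⁻⁴⁸.  The alternate
  reading (measurement as diffusion start point) is a config switch and is
  numerically identical for the same reason.
* Stimulus-prior updating defaults to **one-back**: each trial's prior is
  the base prior updated by the single most recent memory trace.  Literal
  recursive chaining is available but sharpens the prior without bound over
  a long session, progressively flattening all history effects; the
  one-back reading keeps the update stationary.  DV-prior conditioning *is*
  recursive by default (the leaked previous prior is conditioned), because
  the leak bounds the recursion; a one-back-from-uniform mode exists.
* Scaling and reproduction trials read but never condition the DV prior --
  conditioning is defined only on decision commitment.
* The memory trace `mm` is drawn once per trial, after the response, and
  used only for the next trial's prior.
* The leak convolution is a discrete convolution on the belief grid
  followed by the same fold-truncation as `B(v, σ)` (DV space) or by plain
  renormalization (stimulus space, which is unbounded).  A leak SD below
  half a grid step is treated as the identity: the sampled kernel would
  degenerate to a delta and alias boundary values.
* Classification bins are half-open on the left, `((k-1)/G, k/G]`, with
  `v̂ = 0` assigned to class 1; the same convention defines true stimulus
  classes, so boundary ties are deterministic and measure-zero.
* Reports carry no motor noise; the models produce no response times.

## History regressions

The regressand for classification is the binarized current choice (upper
half of the classes = 1).  The previous choice is decomposed into up to
three ordered binary components -- which half, which half within that half,
which half within that quarter -- encoded as the binary expansion of
`choice − 1`, most-significant bit first.  The first component is the
granularity-comparable measure of choice history; the higher components
absorb finer structure so it cannot masquerade as a stimulus effect.

Non-interaction regressors are standardized to mean 0, SD 1 (sample SD)
within each block; interaction columns are products of standardized factors
with the unstandardized granularity code ([0, 1, 2] for levels [2, 4, 8],
or [0, 1] for [2, 8]) or the ITI code (±½), so that main-effect
coefficients describe the coarsest granularity.  Columns constant within a
block (higher-order choice codes in coarse-G blocks) are centred to zero
rather than scaled.  Columns identically zero over a dataset, or exactly
linearly dependent on earlier columns (the reducible interactions that
arise when only two granularity levels are present), are dropped
deterministically, base terms taking precedence; the full ten-lag design
with RT and granularity interactions on three-level data retains exactly
154 coefficients including the intercept.

History regressors use same-block predecessors only; the first `max_lag`
trials of a block (and any trial whose lag window contains a missed choice)
serve only as history.  In paired-trial designs (classification followed by
scaling or reproduction on a fresh stimulus), the classification decision
immediately precedes the second response, so lag 1 refers to the same trial
pair's classification.

Fits are maximum-likelihood probit (IRLS via GLM) for binary responses,
quasi-likelihood probit for bounded continuous scaling responses (clipped
to [10⁻⁴, 1−10⁻⁴]), and OLS for blockwise-standardized reproduction
responses.  p-values are adjusted by Benjamini–Hochberg FDR within each
fitted model; individual-level analyses t-test per-participant coefficients
against zero and adjust across coefficients.  Psychometric summaries bin
the conditioning stimulus into octiles, cross them with the previous-choice
class and granularity, and compare observed response proportions with the
model's predicted cell means (R² = 1 − SSE/SST over occupied cells).

## KL history measures

For each current-choice state, the distributions of the previous choice,
previous stimulus (both octile-binned) and current stimulus are estimated
within each occupied cell of the other two conditioning variables, averaged
uniformly over occupied cells, and renormalized.  (Averaging uniformly over
occupied cells is the only reading of the tabulated-average construction
that yields a proper probability vector in general; empty cells are skipped
rather than zero-filled.)  Each distribution's KL divergence from uniform
is divided by the current stimulus's own divergence, giving an influence
measure where 0 means no influence and 1 means influence equal to the
current stimulus.  Stimulus bins are equal-probability (quantile) bins,
matching the quantile-based class definitions used everywhere else.

## Synthetic data

Schedule templates reproduce the testing-phase block structures of the
blocked (21 × 45 trials, granularity balanced over {2, 4, 8} → 315 trials
per level), trial-interleaved, trial-varying-granularity (fixed-G=2 blocks
vs blocks alternating 2/8 every trial), paired-task (3 testing blocks × 35
trial pairs per [G × task] condition), hand-randomized, and ITI-manipulated
designs.  Because the printed per-level totals are exactly equal, blockwise
granularity assignment is a balanced random permutation by default, with
i.i.d. assignment as an option.  The staircase calibration of the stimulus
SD is not simulated; the population SD is a parameter, defaulted per
template so that a sensory-noise-limited binary classifier is right about
nine times in ten on extreme-octile stimuli.  Where one template's printed
trial counts conflict internally, the explicit per-condition total
(3 × 35) wins.

Probit agents provide exact ground truth for the regression machinery: a
binary upper/lower-half choice is drawn through a probit link from injected
effects (stimulus, ±1-coded previous binarized choice, their granularity
interactions), and the within-half class is assigned uniformly.  Parameter
recovery against these agents is the package's primary correctness check
for the whole regression stack.

## Grid-search protocol

Per parameter set: repeated sessions of 1000 stimuli from N(0, 1) with G
drawn per trial from {2, 8}; the observer performs all three tasks on the
same sequence, with classification (run on every trial) providing the
single stream of commitments that drives belief updating -- this keeps one
coherent history while all three response streams are observed.  Per
session, RT-free lag-1 history regressions are fitted per task on trials
whose current granularity is 2, and coefficients are averaged across
repetitions (non-convergent repetitions are dropped and counted).
Parameter sets are filtered by mean classification accuracy (default
plausibility band [0.6, 0.9], configurable -- the behavioural confidence
interval it stands for is an external input), and the best set minimizes
the summed absolute error of the eight scaling + reproduction history
coefficients against reference values supplied by the user (ties broken by
grid order).  The full protocol (10 values per parameter, 100 repetitions)
sits behind a `paper` profile; the default `desk` profile (3 values per
parameter, 10 repetitions of 500 trials) preserves the qualitative sign
patterns of all five variants at a fraction of the cost, and the test suite
uses desk-scale sizes throughout.

In qualitative sign-pattern judgements, a coefficient is treated as null
when it is within two standard errors of zero or smaller in magnitude than
a practical-equivalence margin of 0.05 -- about a tenth of the benchmark
previous-stimulus repulsion -- so that finite-coding artifacts (the three
binary choice components span only a linear subspace of the eight-class
contrasts, leaving residual class information to correlate with the
previous stimulus) are not mistaken for model-generated history effects.

## What the synthetic data do and do not show

The generators emulate the *structure* of the behavioural designs --
schedules, granularity manipulations, quantile class boundaries, paired
tasks -- and the generative assumptions of the observers.  They do not
emulate attention lapses, response-time dynamics, motor noise, learning
within training blocks, or between-participant heterogeneity beyond
independent seeds.  Passing tests therefore demonstrate that the analysis
code measures what the models generate (and recovers known injected
effects without bias), not that the models fit any particular behavioural
dataset; fitting real data requires trial tables in the documented format
and reference coefficients estimated from them.

## Known limitations

* The standard observer's stimulus-prior attraction produces a small
  positive previous-stimulus coefficient in the *reproduction* task
  (≈ +0.05 at mid-grid parameters): the same attraction of the prior that
  causes DV-space repulsion necessarily pulls the absolute magnitude
  estimate toward the previous stimulus.  The model therefore predicts
  no stimulus *repulsion* in reproduction, but not an exact zero.
* KL estimates are plug-in estimates with positive finite-sample bias;
  the normalization by the current-stimulus KL reduces but does not remove
  it.  No smoothing or bias correction is applied.
* Group-level fits pool participants after block-wise standardization;
  no hierarchical shrinkage is offered.
* The hypothesis-count conventions reported alongside designs (`counts()`)
  expose total, non-intercept and history-only tallies, because published
  per-model hypothesis counts mix these conventions.
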