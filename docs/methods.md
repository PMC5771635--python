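# Methods

## Model

The model is a three-layer rate network. An input layer presents task
events as time courses over a trial; a *state encoding layer* (SEL) — a
reservoir of N = 500 rate neurons with fixed, sparse random recurrent
connectivity — transforms the event sequence into a high-dimensional
dynamical state; a two-unit decision layer reads the SEL state at a
fixed decision time through plastic weights and picks the next action
through a softmax. Crucially, *reward is itself an input*: the SEL state
therefore encodes conjunctions of sensory events and outcomes ("chose A
and was rewarded"), i.e. task states, and the readout can attach actions
to them.

### State encoding layer

Each neuron carries an activation x_i updated by Euler steps of

    tau dx_i/dt = -x_i + g * sum_j w_ij y_j + (W_in I(t))_i + sigma_noise u_i

with dt = 1 ms, and a saturating rate function

    y = y0 + y0 tanh(x / y0)                    for x <= 0
    y = y0 + (ymax - y0) tanh(x / (ymax - y0))  for x > 0

with baseline y0 = 0.1, bounds [0, 1]. u_i is a fresh uniform [0, 1]
draw per neuron and step (implemented exactly in this form, including
its small positive mean; a zero-mean variant is available via
`zero_mean_noise`). x is re-initialized N(0, sigma_ini^2) at every trial
start; no state carries over between trials.

Recurrent weights are zero with probability 1 - p (p = 0.1), otherwise
N(0, 1/(pN)). The gain g multiplies the recurrent term once, in the
dynamics, so the effective coupling variance is g^2/(pN) and g acts as
the usual chaos control parameter. (Scaling the sampling variance by g^2
*and* multiplying by g in the dynamics would apply the gain twice; that
literal reading is available via `literal_double_gain` but is not the
default.) Input weights are zero with probability 1 - p_IR (0.2),
otherwise N(0, g_IR^2).

### Decision readout and learning

Output drives are v_k = sum_i w_ik y_i with the decision-time rates; the
choice is sampled from p_k proportional to exp(+beta v_k). The positive
sign is the package default: under it, rewarded strengthening of a drive
raises that action's probability, which is what the learning dynamics
require. (The sign-flipped variant is available as
`sign_convention="literal"`.) After the outcome, the chosen column takes
one reward-modulated Hebbian step

    dw_ik = eta (r - E[r]) (y_i - y_th) z_k,    y_th = 0.2

and every column is rescaled to unit Euclidean norm, which bounds the
weights. For the binary-reward tasks, E[r] is the probability of the
chosen option (the softmax output itself); in the economic task it is
the probability-weighted sum of the two offer values. The session's
first trial presents a randomly selected choice input with its
environment-consistent outcome and applies no update.

### Per-task parameters

| parameter      | reversal | two-stage | economic |
|----------------|----------|-----------|----------|
| tau (ms)       | 100      | 500       | 100      |
| g              | 2        | 2.25      | 2.5      |
| beta           | 4        | 2         | 4        |
| eta            | 0.001    | 0.001     | 0.005    |
| sigma_noise    | 0.01     | 0.01      | 0.05     |
| sigma_ini      | 0.01     | 0.01      | 0.2      |
| g_IR           | 4        | 2         | 2        |
| p_IR           | 0.2      | 0.2       | 0.2      |

## Tasks

**Reversal learning.** Three inputs (A, B, R) as unit boxcars on
[200, 700) ms; decision read at 900 ms. One option is rewarded; the
contingency flips every 100 trials. Learning criterion: 28-of-30
correct in a sliding window for the initial block, 24-of-30 afterwards
(the 93% / 80% performance thresholds). Errors-to-criterion counts the
error trials strictly before the criterion trial.

**Two-stage Markov decision task.** Six inputs (A1, A2, B1, B2, R, N)
activated sequentially (A on [200, 700), B on [700, 1200), outcome on
[1200, 1700)); decision at 1900 ms. Choices map to intermediate
outcomes with fixed 0.8/0.2 transitions; reward depends only on the
intermediate outcome (0.8 vs 0.2), and that contingency flips every 50
trials. The explicit non-reward unit N marks unrewarded trials.

**Value-based economic choice.** Two inputs carry the offer magnitudes
of juices A and B with range adaptation: the drive is
(m - m_min) g(t) / ((m_max - m_min) max g), where g(t) is a product of
a rising (center 475 ms, slope 30 ms) and a decaying (center 700 ms,
slope 100 ms) sigmoid, presented on [300, 1300) ms; decision at
1400 ms. One unit of A is worth gamma = 2 units of B; the reward for
choosing A is gamma * m_A, for B it is m_B, and
E[r] = p_A gamma m_A + p_B m_B. Offers are drawn uniformly from
m_A in {0..3}, m_B in {0..8} excluding (0, 0); the grid and block
composition are a package choice (the design leaves them open), picked
so both juices span comparable value ranges around the indifference
ratio.

**Manipulations.** The lesion model removes the outcome inputs (R, and
for the two-stage task N as well, both carrying outcome information; a
flag restricts the removal to R). Decision-time inactivation zeroes a
chosen set of neurons only in the readout computation — the integration
is untouched. Learning freezes simply stop the Hebbian update from a
given trial on.

## Analyses

**Selectivity.** Per neuron, a one-way ANOVA across task conditions on
the single decision-time rate per trial; the preferred condition must be
the strict maximum and beat every other condition in pairwise Welch
t-tests, Bonferroni-corrected over the comparisons. In the reversal
task, neurons failing this conjunction test are further tested on the
two marginal input factors (choice identity, outcome) and labelled
'A'/'B'/'R'/'N' when exactly the marginal contrast is reliable. For the
two-stage task the eight conditions map to evidence categories (e.g.
A1R collects every condition in which A1 co-occurs with reward or A2
with non-reward).

**Population PCA.** Condition-averaged, time-resolved rates (5-ms
stored resolution) are stacked over (condition x time) and decomposed
over the neuron dimension. The default epoch is the *outcome
presentation window* — [200, 700) ms for the reversal task, the
[1200, 1700) ms reward window for the two-stage task — i.e. the period
in which the full task state has been delivered and the condition
trajectories are maximally separated. The reported number is the
cumulative variance fraction of the first three components on this
matrix; a decision-time-only variant is available.

**Two-stage behavior.** Trials are classed common/rare x rewarded/
unrewarded; the task-structure index is
(p_CR + p_RN - p_CN - p_RR) / (sum of the four). Stay counts can be
pooled across replicate sessions, and a delta-method variance for the
index supports trial-level significance tests. The hybrid fit mixes a
model-free learner (learning rate alpha1, eligibility lambda) and a
model-based learner (alpha2) that projects intermediate-state values
through the true transition matrix; the mixture weight w is the
quantity of interest. beta = 2 and the perseveration term are fixed;
(alpha1, alpha2, lambda, w) are estimated in [0, 1]^4 by L-BFGS-B from
multiple restarts (20 by default). When behavior carries no reward
dependence the likelihood is flat in w (the learning rates fit to ~0)
and the maximizer is a set; among restart solutions within 0.1 nats of
the best, the minimum-norm parameter vector is returned, a
deterministic minimal-complexity convention for set-valued maxima. The lagged-state logistic regression
uses deviation coding with an intercept (the four state indicators at a
lag are collinear as printed; the fourth coefficient and its standard
error are reconstructed from the sum-to-zero constraint). The factor
regression codes Correct, Reward, Stay, Transition and Trans x Out as
±1 regressors in the direction of repeating toward option A1.

**Economic choice.** The psychometric model is a logistic fit of
p(choose B) on log(m_B/m_A) over non-forced trials; the relative value
is the indifference point exp(-a/b). The value taxonomy regresses each
neuron's mean post-offer rate ([300, 800) ms window) on each of ten
value variables; a variable qualifies at p < 0.05 Bonferroni-corrected
across the ten, and the neuron joins the qualifying variable with the
highest R^2. Trials with zero chosen value are excluded from the value
ratio, and the juice-conditional variables use only their own trials.

## Numerical choices

- Integration runs in float32 by default (configurable to float64); the
  recurrent matrix-vector product is the cost floor, and float32 keeps
  the matrix cache-resident. Oracle tests for the integrator use
  float64.
- The per-step noise is not rescaled by sqrt(dt); the stated rule is a
  per-step draw.
- Randomness is split from a master seed into five named streams
  (reservoir build, readout init, trial noise, environment, choice
  sampling), so e.g. removing an input never shifts the environment's
  draws. Sessions are bit-reproducible from their config.
- Softmax probabilities are computed with a max-shift; categorical
  sampling is inverse-CDF on the dedicated choice stream.
- Hybrid likelihoods use numerically stable log1p forms; probabilities
  cannot hit exactly 0 for parameters in the box.

## Economic-choice convergence protocol

The model is sensitive to initialization (a property it openly shares
with its design goals: the reservoir is random and untrained). A
fraction of economic-choice training runs degenerate into one-sided,
offer-independent choice: once the softmax saturates, the prediction
error is proportional to the vanishing probability of the unchosen
option and learning stalls. Normalizing the reward units by the
largest available option value (the default) keeps the prediction
error on the same [0, 1] scale as the binary-reward tasks and makes
such collapses rare, but they still occur. Analyses therefore operate
on *converged* runs: a training run is accepted when both options are
chosen on at least 5% of analysis trials and the psychometric slope is
positive (> 0.5) — a health check agnostic to the fitted preference
value — and a degenerate run is retried once with the next derived
seed. Both the retry and the attempt count are reported.

## Scales used by the tests and the acceptance script

Simulations are sized for a single CPU. The acceptance script trains
the reversal network for 20 blocks (2,000 trials) and tests
inactivation on 20 further blocks; the two-stage network for 2,000
trials plus 500 trace-collection trials; the economic network for
8,000 trials plus 2,000 analysis trials. The test suite uses smaller
versions: 2 seeds x 12 reversal blocks per arm, 2 seeds x 2,600
two-stage trials per arm (1,600 training + 1,000 analysis), and a
4,000 + 1,200-trial economic session. These are the package's test-scale
defaults; the two-stage behavioral contrasts in particular are
underpowered at this scale (see the limitations below) and the
corresponding tests can fail for unlucky replicate draws. The
experiment drivers accept the full-scale settings (10 replicate seeds,
30+ blocks, 2,000 + 2,000 two-stage trials) unchanged.

## What the simulations do and do not show

All inputs are generated by the package's own task environments; there
is no external data. The synthetic tasks reproduce the *structure* of
the animal paradigms (contingency reversals, fixed transition
probabilities, range-adapted offers) but none of the sensory or motor
richness of real experiments, so passing tests demonstrate properties
of the model — that a fixed random recurrent expansion plus a
reward-gated Hebbian readout can acquire task structure — not claims
about any particular recorded dataset. Known limitations: learning
collapses for extreme softmax saturation (all-one-side choice
sequences) if the value ranges of the two economic offers are made very
asymmetric; the number of encodable task states is limited by the
fixed reservoir dimension; and run-to-run variability is substantial,
which is why replicate seeds are averaged wherever the analyses report
population statistics. Two further caveats concern the two-stage
battery. First, the reward-input-lesioned network is not inert: its
readout updates are still gated by reward, so it relearns a
stimulus-response mapping within each block, which both lifts its
task-structure index slightly above zero and presents to the hybrid
model as weak, small-learning-rate model-based behavior; with few
replicates the fitted mixture weight w therefore discriminates the two
networks poorly. Second, the intact-vs-lesioned contrasts
(task-structure index, w) have small effect sizes relative to
between-run variability at short training, so multi-thousand-trial
sessions and several replicates are needed before their significance
tests are reliable.
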