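# taskspace

A simulator of how a fixed random recurrent network — a reservoir
playing the role of the orbitofrontal cortex — can *acquire the
structure of a task* purely from reward feedback, and a complete
analysis battery for its behavior and population activity.

## The model in one paragraph

Task events (chosen option, intermediate outcome, and — crucially —
reward) drive a sparse random rate network of N = 500 neurons (the
*state encoding layer*, SEL):

    tau dx/dt = -x + g W y + W_in I(t) + sigma u,     y = f(x) in [0, 1]

Because reward is an input, the SEL's dynamical state encodes
*conjunctions* of events and outcomes — task states such as "chose A
and was rewarded". Only a two-unit linear readout learns: choices are
sampled from p_k ∝ exp(beta v_k) with v_k = Σ_i w_ik y_i at the
decision time, and after each outcome the chosen column takes a
reward-modulated Hebbian step

    Δw_ik = eta (r − E[r]) (y_i − y_th) z_k,

followed by renormalization to unit column norm. That is the entire
learning machinery — no backprop, no training of the recurrent weights
— yet the network learns reversal tasks faster and faster across
reversals, exploits the transition structure of a two-stage Markov
decision task, and reproduces the heterogeneous value coding
(offer value / chosen value / chosen juice) reported in primate
orbitofrontal cortex during economic choice.

Who this is for: computational neuroscientists and students who want a
compact, fully reproducible reference implementation of
reservoir-plus-reinforcement-learning task-space acquisition, with the
standard analyses (errors-to-criterion, selectivity/ANOVA
classification, population PCA, stay-probability factorials, hybrid
model-based/model-free fits, psychometric and value-regression
taxonomies) implemented against tidy trial logs.

## Worked example

```python
from taskspace import SessionConfig, run_session, errors_to_criterion

cfg = SessionConfig(task="reversal", n_trials=1200, seed=1)
res = run_session(cfg)
crit = errors_to_criterion(res.log)
print(crit[["block", "block_type", "errors_before_criterion"]].to_string(index=False))
```

prints the per-block errors made before the 28-of-30 (first block) or
24-of-30 (reversals) sliding criterion:

```
 block block_type  errors_before_criterion
     0          A                       18
     1          B                       19
     2          A                       16
     3          B                       16
     4          A                       17
     5          B                       13
     6          A                       19
     7          B                       11
     8          A                       11
     9          B                        4
    10          A                        6
    11          B                       10
```

The signature of task-structure learning is the fall from ~19 errors
at the early reversals to single digits by the tenth: the network has
learned that "chose A, no reward" itself predicts that B is now the
good option, and the trend continues over further reversals. Removing
the reward input
(`cfg.task_config = cfg.task_config.replace(reward_input_present=False)`)
abolishes exactly this acceleration.

The higher-level drivers in `taskspace.experiments` run the multi-seed
batteries (learning curves, decision-time inactivation of selectivity
groups, learning freezes, the two-stage factorial/hybrid-fit battery,
the economic-choice session), and the fitting components follow the
statsmodels Model/Results pattern:

```python
from taskspace import HybridModel
fit = HybridModel.from_log(two_stage_log).fit()
print(fit.summary())          # alpha1, alpha2, lambda, w with SEs
```

A thin CLI wraps the same functions:

```bash
taskspace simulate reversal --seed 1 --trials 1200 --out runs/rev1
taskspace analyze selectivity --in runs/rev1 --out runs/rev1/analysis
taskspace reproduce learning-curves --seed 0 --scale 0.3 --out runs/curves
```

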