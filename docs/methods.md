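# Methods

## The model

`pcdraw` implements a predictive-coding account of drawing completion. The
internal model is a stochastic continuous-time recurrent network (S-CTRNN)
that performs one-step-ahead prediction of 2-D pen trajectories
`x_t = (x, y, pen)`, with `pen ∈ {0, 1}` marking whether the pen touches the
tablet. The context layer of N leaky-integrator units evolves as

    u_{t+1} = (1 − 1/τ) u_t + (1/τ) (W_in v_t + W_rec tanh(u_t) + b)
    μ_net(t)  = tanh(W_μ tanh(u_{t+1}) + b_μ)
    σ²_net(t) = exp(W_σ tanh(u_{t+1}) + b_σ) + ε ,          ε = 10⁻⁶

so every prediction carries its own variance — the network estimates the
precision of its top-down signal. Which of the S shape classes the network
draws is selected entirely by the learnable initial state `u(s)₀`; a Gaussian
prior with learnable mean `û` and fixed variance `v_dist = 10` keeps the
initial states in one cluster:

    −ln L      = Σ_t Σ_i [ ln(2π σ²_net(t,i)) + (x_{t+1,i} − μ_net(t,i))² / (2 σ²_net(t,i)) ]
    −ln L_init = Σ_s Σ_n [ ln(2π v_dist) + (u(s)₀,n − û_n)² / (2 v_dist) ]

and training minimizes `−ln L − ln L_init` jointly over weights and initial
states.

## Precision-weighted fusion

The network never sees raw data. Its input `v_t` is the Bayesian fusion of
its own previous prediction (the prior signal) and the observed sample (the
sensory signal), with variance factors `H_prior` and `H_sensor` acting as
attention knobs:

    σ²_post = (H_s σ²_s · H_p σ²_net) / (H_s σ²_s + H_p σ²_net)
    μ_post  = σ²_post ( μ_net / (H_p σ²_net) + x / (H_s σ²_s) )

The base sensory variance σ²_s is estimated from the training data as the
mean per-dimension variance of one-step increments (≈ 0.019 for the default
synthetic set; a fixed value such as 0.05 can be pinned instead).

The input is a *sample* `v_t ~ N(μ_post, σ²_post)`, not the posterior mean.
This is the load-bearing choice: μ_post is invariant under joint scaling of
the two H factors, so a mean-propagating model cannot distinguish cells of
the precision grid that share the same H ratio. Only the variance of the
drawn signal carries absolute precision — jointly imprecise settings
(H = 1000 on both axes) scribble, jointly precise ones draw cleanly, with
identical posterior means. Training samples the same way (H = 1), which
doubles as denoising practice: a network trained on posterior means is
brittle to its own sampling noise at generation time. Gradients treat the
draw as reparameterized, `μ_post + √σ²_post · ξ` with ξ frozen, so
backpropagation through time stays exact for the realized loss (verified
against central finite differences at relative error ≤ 10⁻⁴).

## Completion procedure

A completion presents the first third (30 of 90 steps) of a held-out
trajectory and proceeds in two steps:

1. **Recognition** — with weights frozen, gradient descent (Adam, step
   0.01, 100 epochs, best-so-far state kept) on the initial state minimizes
   the prefix NLL. The forward pass uses the active H factors. The start is
   `û` plus N(0, 0.01²) noise; the repetition seed that draws this noise is
   what distinguishes the three repetitions per prefix.
2. **Generation** — the inferred state seeds a 90-step rollout. While
   prefix samples exist the drawn signal is a posterior sample (tracing
   emerges when the sensory signal is precise); afterwards the loop closes
   and the drawn signal is sampled from N(μ_net, H_prior σ²_net) — no
   sensory term exists, so the prior precision alone sets the noise. Drawn
   samples are clipped to ±1.5: the pen cannot leave the tablet.

## The sweep and its statistics

The experiment crosses H_sensor × H_prior ∈ {0.001, 1, 1000}² over
independently trained networks, all test prefixes, and 3 repetitions, with
identical prefixes and repetition seeds in every cell (paired design; the
precision configuration is the only variable). Two statistics summarize
each cell, separately for the presented (steps 1–30) and completed
(steps 31–90) segments:

* mean squared error to the closest training trajectory — pointwise at
  matching time indices on (x, y) (the pen channel is excluded by default
  so stroke-break encoding cannot dominate the spatial error; a flag
  includes it), minimized over all training trajectories, ties broken
  toward the lowest class code then variant id;
* the misinterpretation percentage — the share of drawings whose closest
  training trajectory belongs to a class other than the intended one,
  pooled across networks (a per-network breakdown is attached). Cells with
  mean error ≥ 0.3 are masked: such output resembles no training shape, so
  class confusion is undefined.

## Synthetic data

The six shape classes (FACE, HOUSE, CAR, FLOWER, HUMAN, ROCKET) emulate a
small corpus of hand-drawn stimuli: fixed stroke programs of 2–4 pen-down
primitives joined by pen-up transits, Gaussian control-point jitter
(σ = 0.03 in normalized units) per variant, Chaikin corner rounding
(hand-drawn strokes have no sharp vertices), arc-length-uniform resampling
to 90 steps iterated to its fixed point (which makes resampling idempotent),
and bounding-box normalization to [−1, 1]. Ten variants per class split
7 train / 3 test (variants 0–6 / 7–9).

What the generator does not emulate: pen-speed modulation (real drawing
slows in curves), stroke-order variability across instances, individual
drawing styles, and the richer stimuli of developmental experiments.
Passing tests therefore show that the precision mechanism produces the
expected behavioral phenotypes on learnable, class-separable trajectories —
not that the model reaches child-level drawing competence on real data.

## Parameters and scale

| parameter | default | notes |
| --- | --- | --- |
| context units N | 100 (30 in the scaled-down study) | capacity for six attractors |
| time constant τ | 3 | smoother pen dynamics; τ = 1 (pure discrete) and 2 remain selectable. At the scaled-down conditions τ = 2 left closed-loop completions above the scribble threshold; τ = 3 keeps them clean |
| learning rate | 10⁻³ (Adam) | higher rates degraded closed-loop stability |
| max epochs / patience | 30 000 / 5 000 | early stop when the best total loss has not improved by > 10⁻⁶ within the window |
| v_dist | 10 | initial-state prior variance |
| H grid | {0.001, 1, 1000}² | attention factors |
| scribble threshold | 0.3 | mean-MSE mask level |
| canvas clip | 1.5 | bound on drawn samples |

The test suite and the acceptance script run a scaled-down study — 3 shape
classes, 2 networks, N = 30, 2 000 epochs, 3 repetitions — chosen as the
smallest configuration at which all qualitative precision-matrix effects
are stable; the full-scale defaults (6 classes, 10 networks, N = 100,
30 000 epochs) are a command-line invocation away.

## Numerical choices and degenerate inputs

* Variance head: exponential with floor ε = 10⁻⁶; the head bias starts at
  ln 0.1 so early predictions are moderately uncertain.
* Weight init: N(0, 1/√fan-in); initial states start at zero.
* Training input at t = 0 is the raw first sample — no prediction exists
  yet to fuse.
* Recognition losses are separable across batch elements, so batched and
  single-prefix recognition agree; each element's noise comes from its own
  repetition-seeded generator.
* Sensor-variance estimation clamps at 10⁻⁶ for constant inputs; fusion
  rejects non-positive variances; training aborts with the epoch index on
  a non-finite loss, and such networks are excluded from the model set
  with a logged reason.
* Resampling requires T ≥ 2 × (number of pen segments) so every segment
  keeps both endpoints.

## Known limitations

* Same-index MSE penalizes timing drift as well as shape error; a
  completion that draws the right shape out of phase scores poorly. The
  paper's fixed-length design makes this the intended comparison, but it
  sets a floor on completed-segment errors (~0.1–0.3 at the scaled-down
  conditions).
* At high prior precision (H_prior = 0.001) the completed segment is
  noiseless but purely self-driven; whether its error stays below the
  scribble mask varies with the dataset seed.
* Misinterpretation percentages at the scaled-down size quantize coarsely
  (54 completions per cell) and are frequently 0% with only three
  well-separated classes.
* No minibatching or GPU path; full-batch NumPy BPTT is adequate at these
  scales but cubic growth in N makes N ≫ 200 impractical.
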