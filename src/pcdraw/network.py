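"""Stochastic continuous-time recurrent network with a variance head.

The internal model is a leaky-integrator recurrent network that performs
one-step-ahead prediction of (x, y, pen) trajectory samples. At each step it
emits the predictive mean mu_net (tanh head) and variance sigma_net^2
(exponential head plus a positivity floor). Which shape the network draws is
selected by a learnable per-class initial state u(s)_0 of the context layer;
a Gaussian prior with learnable mean u_hat and fixed variance v_dist keeps
the initial states clustered.

Training minimizes the sum of the Gaussian sequence negative log-likelihood

    -ln L = sum_t sum_i [ ln(2 pi s2_ti) + (x_{t+1,i} - mu_ti)^2 / (2 s2_ti) ]

and the initial-state prior term

    -ln L_init = sum_s sum_n [ ln(2 pi v_dist) + (u(s)_0n - u_hat_n)^2 / (2 v_dist) ]

jointly over the weights and the initial states. During training the input
fed to the network at each step is the precision-weighted posterior of its
own previous prediction and the observed sample (see :mod:`pcdraw.fusion`)
at veridical precision H_prior = H_sensor = 1; gradients flow through the
fusion. All gradients are analytic (backpropagation through time), verified
against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fusion import PrecisionConfig, integrate

#: positivity floor added to the exponential variance head
VARIANCE_FLOOR = 1e-6
#: bound on drawn samples during generation (slightly beyond the canvas)
CANVAS_CLIP = 1.5

_WEIGHT_FIELDS = ("w_in", "w_rec", "b_h", "w_mu", "b_mu", "w_var", "b_var")
_PARAM_FIELDS = _WEIGHT_FIELDS + ("init_states", "init_mean")


@dataclass
class NetworkParameters:
    """All learnable arrays plus the structural constants N, D, S, tau."""

    w_in: np.ndarray      # (N, D) input-to-context
    w_rec: np.ndarray     # (N, N) recurrent
    b_h: np.ndarray       # (N,)
    w_mu: np.ndarray      # (D, N) mean head
    b_mu: np.ndarray      # (D,)
    w_var: np.ndarray     # (D, N) variance head
    b_var: np.ndarray     # (D,)
    init_states: np.ndarray   # (S, N) per-class u(s)_0
    init_mean: np.ndarray     # (N,)  shared mean u_hat
    tau: float = 3.0
    eps: float = VARIANCE_FLOOR

    @property
    def n_context(self) -> int:
        return self.w_rec.shape[0]

    @property
    def dim(self) -> int:
        return self.w_in.shape[1]

    @property
    def n_classes(self) -> int:
        return self.init_states.shape[0]

    @classmethod
    def init(cls, n_context: int, dim: int = 3, n_classes: int = 6,
             tau: float = 3.0, seed: int = 0) -> "NetworkParameters":
        """Randomly initialize a network. Weight scales ~ 1/sqrt(fan-in);
        the variance-head bias starts at ln(0.1) so early predictions are
        moderately uncertain; initial states start at zero."""
        if n_context < 1:
            raise ValueError("n_context must be >= 1")
        if tau < 1:
            raise ValueError("tau must be >= 1")
        rng = np.random.default_rng(seed)
        s_in, s_rec, s_out = 1 / np.sqrt(dim), 1 / np.sqrt(n_context), \
            1 / np.sqrt(n_context)
        return cls(
            w_in=rng.normal(0, s_in, (n_context, dim)),
            w_rec=rng.normal(0, s_rec, (n_context, n_context)),
            b_h=np.zeros(n_context),
            w_mu=rng.normal(0, s_out, (dim, n_context)),
            b_mu=np.zeros(dim),
            w_var=rng.normal(0, 0.1 * s_out, (dim, n_context)),
            b_var=np.full(dim, np.log(0.1)),
            init_states=np.zeros((n_classes, n_context)),
            init_mean=np.zeros(n_context),
            tau=float(tau),
        )

    def validate(self) -> None:
        for name in _PARAM_FIELDS:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in parameter '{name}'")

    def copy(self) -> "NetworkParameters":
        kw = {n: getattr(self, n).copy() for n in _PARAM_FIELDS}
        return NetworkParameters(**kw, tau=self.tau, eps=self.eps)

    def checksum(self) -> float:
        return float(sum(np.abs(getattr(self, n)).sum()
                         for n in _PARAM_FIELDS))

    # -- checkpoint IO ------------------------------------------------------

    def save(self, path: str | Path, seed: int | None = None) -> None:
        meta = {"tau": self.tau, "eps": self.eps, "seed": seed}
        arrays = {n: getattr(self, n) for n in _PARAM_FIELDS}
        with open(path, "wb") as f:
            np.savez(f, _meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "NetworkParameters":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["_meta"]))
            kw = {n: z[n] for n in _PARAM_FIELDS}
        return cls(**kw, tau=meta["tau"], eps=meta["eps"])


@dataclass
class PredictionStep:
    """One forward step: predictive mean/variance and the new context state."""

    mu: np.ndarray
    var: np.ndarray
    context: np.ndarray


def forward_step(params: NetworkParameters, context: np.ndarray,
                 x: np.ndarray) -> PredictionStep:
    """Advance the leaky-integrator context by one step and predict.

    ``context`` is the pre-activation internal state u_t (length N);
    ``x`` is the input sample fed at this step.
    """
    params.validate()
    context = np.asarray(context, dtype=float)
    x = np.asarray(x, dtype=float)
    if not (np.all(np.isfinite(context)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite input to forward_step")
    alpha = 1.0 / params.tau
    a = params.w_in @ x + params.w_rec @ np.tanh(context) + params.b_h
    u = (1 - alpha) * context + alpha * a
    c = np.tanh(u)
    mu = np.tanh(params.w_mu @ c + params.b_mu)
    var = np.exp(params.w_var @ c + params.b_var) + params.eps
    return PredictionStep(mu, var, u)


# ---------------------------------------------------------------------------
# likelihood terms


def sequence_nll(mu: np.ndarray, var: np.ndarray,
                 targets: np.ndarray) -> float:
    """Gaussian sequence negative log-likelihood.

    All arguments have matching shape (..., T-1, D); targets are the observed
    samples shifted by one step. Additive over time steps, dimensions, and
    any leading batch axes.
    """
    mu, var, targets = (np.asarray(a, dtype=float)
                        for a in (mu, var, targets))
    if mu.shape != targets.shape or var.shape != targets.shape:
        raise ValueError("mu, var, targets must have identical shapes")
    if np.any(var <= 0):
        raise ValueError("variance must be strictly positive")
    return float(np.sum(np.log(2 * np.pi * var)
                        + (targets - mu) ** 2 / (2 * var)))


def initial_state_prior_nll(init_states: np.ndarray, mean: np.ndarray,
                            v_dist: float) -> float:
    """Gaussian prior on the per-class initial states around their mean."""
    if v_dist <= 0:
        raise ValueError("v_dist must be > 0")
    init_states = np.atleast_2d(np.asarray(init_states, dtype=float))
    mean = np.asarray(mean, dtype=float)
    if init_states.shape[1] != mean.shape[0]:
        raise ValueError("init_states and mean dimension mismatch")
    S, N = init_states.shape
    return float(S * N * np.log(2 * np.pi * v_dist)
                 + np.sum((init_states - mean) ** 2) / (2 * v_dist))


# ---------------------------------------------------------------------------
# batched forward / backward (BPTT)


def _forward_teacher(params: NetworkParameters, u0: np.ndarray,
                     X: np.ndarray, cfg: PrecisionConfig,
                     noise: np.ndarray | None = None) -> dict:
    """Run the network over observed sequences X (B, T, D) with fused input.

    Step 0 feeds the raw first sample (there is no prediction to fuse yet);
    every later step feeds the posterior of the previous prediction and the
    current observation — a sample from it when ``noise`` (standard normal
    draws, (B, T-1, D)) is given, its mean otherwise. Returns the cache
    needed for the backward pass.
    """
    B, T, D = X.shape
    N = params.n_context
    alpha = 1.0 / params.tau
    U = np.empty((B, T, N))
    C = np.empty((B, T, N))
    V = np.empty((B, T - 1, D))
    MU = np.empty((B, T - 1, D))
    VAR = np.empty((B, T - 1, D))
    U[:, 0] = u0
    C[:, 0] = np.tanh(u0)
    for t in range(T - 1):
        if t == 0:
            V[:, 0] = X[:, 0]
        else:
            post = integrate(MU[:, t - 1], VAR[:, t - 1], X[:, t], cfg)
            V[:, t] = post.mu
            if noise is not None:
                V[:, t] += np.sqrt(post.var) * noise[:, t]
        a = V[:, t] @ params.w_in.T + C[:, t] @ params.w_rec.T + params.b_h
        U[:, t + 1] = (1 - alpha) * U[:, t] + alpha * a
        C[:, t + 1] = np.tanh(U[:, t + 1])
        MU[:, t] = np.tanh(C[:, t + 1] @ params.w_mu.T + params.b_mu)
        VAR[:, t] = np.exp(C[:, t + 1] @ params.w_var.T + params.b_var) \
            + params.eps
    return {"U": U, "C": C, "V": V, "MU": MU, "VAR": VAR, "X": X,
            "noise": noise}


def _backward(params: NetworkParameters, cache: dict,
              cfg: PrecisionConfig) -> dict:
    """BPTT through the fused-input forward pass.

    When the forward pass sampled its inputs, the sample is treated as a
    reparameterized draw mu_post + sqrt(var_post) * xi with the noise xi
    frozen, so the gradients are exact for the realized loss. Returns
    gradients of the sequence NLL for every weight array and for the
    initial state of each batch element (key ``u0``, shape (B, N)).
    """
    U, C, V = cache["U"], cache["C"], cache["V"]
    MU, VAR, X = cache["MU"], cache["VAR"], cache["X"]
    noise = cache["noise"]
    B, T, _ = X.shape
    Y = X[:, 1:]
    alpha = 1.0 / params.tau
    s = cfg.h_sensor * np.asarray(cfg.sigma_sensor_sq, dtype=float)

    g = {n: np.zeros_like(getattr(params, n)) for n in _WEIGHT_FIELDS}
    gu_next = np.zeros((B, params.n_context))   # dL/dU[:, t+2]
    gv_next = np.zeros((B, params.dim))         # dL/dV[:, t+1]

    for t in range(T - 2, -1, -1):
        mu_t, var_t = MU[:, t], VAR[:, t]
        gmu = (mu_t - Y[:, t]) / var_t
        gvar = 1.0 / var_t - (Y[:, t] - mu_t) ** 2 / (2 * var_t ** 2)
        if t < T - 2:
            # fused input of the next step depends on this prediction:
            # V[t+1] = mu_post(+ sqrt(var_post) * xi), with
            # p = H_prior * var_t held in the posterior formulas
            p = cfg.h_prior * var_t
            d_mu = s / (s + p)
            d_var = cfg.h_prior * s * (X[:, t + 1] - mu_t) / (s + p) ** 2
            if noise is not None:
                var_post = s * p / (s + p)
                d_var = d_var + noise[:, t + 1] * cfg.h_prior \
                    * s ** 2 / ((s + p) ** 2 * 2 * np.sqrt(var_post))
            gmu = gmu + gv_next * d_mu
            gvar = gvar + gv_next * d_var
        gm = gmu * (1 - mu_t ** 2)
        gz = gvar * (var_t - params.eps)
        c_out = C[:, t + 1]
        g["w_mu"] += gm.T @ c_out
        g["b_mu"] += gm.sum(axis=0)
        g["w_var"] += gz.T @ c_out
        g["b_var"] += gz.sum(axis=0)
        gc = gm @ params.w_mu + gz @ params.w_var \
            + (alpha * gu_next) @ params.w_rec
        gu = gc * (1 - c_out ** 2) + (1 - alpha) * gu_next
        ga = alpha * gu
        g["w_in"] += ga.T @ V[:, t]
        g["w_rec"] += ga.T @ C[:, t]
        g["b_h"] += ga.sum(axis=0)
        gv_next = ga @ params.w_in
        gu_next = gu

    c0 = C[:, 0]
    g["u0"] = (1 - alpha) * gu_next \
        + ((alpha * gu_next) @ params.w_rec) * (1 - c0 ** 2)
    return g


def loss_and_grads(params: NetworkParameters, X: np.ndarray,
                   cls_idx: np.ndarray, cfg: PrecisionConfig,
                   v_dist: float, noise: np.ndarray | None = None
                   ) -> tuple[float, float, dict]:
    """Total training loss and its analytic gradients.

    X is the (B, T, D) batch of observed trajectories, cls_idx the class
    index of each; the initial-state prior runs over all classes regardless
    of the batch. ``noise`` supplies the standard normal draws for the
    sampled fused input (frozen during differentiation). Returns
    (nll, init_prior, grads), where grads includes ``init_states`` and
    ``init_mean``.
    """
    u0 = params.init_states[cls_idx]
    cache = _forward_teacher(params, u0, X, cfg, noise=noise)
    nll = sequence_nll(cache["MU"], cache["VAR"], X[:, 1:])
    prior = initial_state_prior_nll(params.init_states, params.init_mean,
                                    v_dist)
    g = _backward(params, cache, cfg)
    g_init = (params.init_states - params.init_mean) / v_dist
    np.add.at(g_init, cls_idx, g.pop("u0"))
    g["init_states"] = g_init
    g["init_mean"] = np.sum(params.init_mean - params.init_states,
                            axis=0) / v_dist
    return nll, prior, g


def prefix_nll_and_state_grad(params: NetworkParameters, u0: np.ndarray,
                              X: np.ndarray, cfg: PrecisionConfig
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-element prefix NLL and its gradient w.r.t. the initial state.

    Used by the recognition step: X is a (B, Tp, D) batch of prefixes, u0 a
    free (B, N) array of candidate initial states. Weights receive no update.
    """
    cache = _forward_teacher(params, u0, X, cfg)
    err = (np.log(2 * np.pi * cache["VAR"])
           + (X[:, 1:] - cache["MU"]) ** 2 / (2 * cache["VAR"]))
    per_elem = err.sum(axis=(1, 2))
    g = _backward(params, cache, cfg)
    return per_elem, g["u0"]


# ---------------------------------------------------------------------------
# optimizer and training loop


class Adam:
    """Adam over a dict of named gradient arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, arrays: dict, grads: dict) -> None:
        self.t += 1
        for k, grad in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(grad)
                self.v[k] = np.zeros_like(grad)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * grad ** 2
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            arrays[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainingConfig:
    """Knobs of the training loop; defaults mirror the study conditions."""

    max_epochs: int = 30_000
    patience_epochs: int = 5_000
    improvement_tolerance: float = 1e-6
    v_dist: float = 10.0
    learning_rate: float = 1e-3
    seed: int = 0
    n_context: int = 100
    tau: float = 3.0

    def __post_init__(self) -> None:
        if self.patience_epochs > self.max_epochs:
            raise ValueError("patience_epochs must be <= max_epochs")
        if self.v_dist <= 0:
            raise ValueError("v_dist must be > 0")


@dataclass
class LossReport:
    epoch: int
    nll: float
    init_prior: float

    @property
    def total(self) -> float:
        return self.nll + self.init_prior


def dataset_batch(dataset, which: str = "train"
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Stack a dataset partition into (B, T, D) array + class-index vector.

    Class indices are positions within the dataset's (sorted) class list, so
    a 3-class dataset maps onto a 3-row init_states array.
    """
    trajs = dataset.split(which)
    classes = dataset.classes
    X = np.stack([t.points for t in trajs])
    cls = np.array([classes.index(t.shape_class) for t in trajs])
    return X, cls


def train(params: NetworkParameters, dataset, config: TrainingConfig,
          precision_cfg: PrecisionConfig
          ) -> tuple[NetworkParameters, list[LossReport]]:
    """Full-batch joint optimization of weights and initial states.

    Each epoch is one pass over all training trajectories. The loss of the
    current parameters is recorded before the update; training stops when
    ``max_epochs`` is reached or the best total loss has not improved by more
    than ``improvement_tolerance`` within the last ``patience_epochs``
    epochs. Returns the best-so-far parameters and the full loss history.
    Fully reproducible: the fused-input sampling is driven by
    ``config.seed`` and the parameter initialization by the caller's seed.
    """
    if not dataset.classes:
        raise ValueError("dataset has no classes")
    X, cls = dataset_batch(dataset, "train")
    opt = Adam(lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: list[LossReport] = []
    best = np.inf
    best_epoch = 0
    best_params = params.copy()

    for epoch in range(config.max_epochs):
        noise = rng.standard_normal(
            (X.shape[0], X.shape[1] - 1, X.shape[2]))
        nll, prior, grads = loss_and_grads(params, X, cls, precision_cfg,
                                           config.v_dist, noise=noise)
        report = LossReport(epoch, nll, prior)
        if not np.isfinite(report.total):
            raise RuntimeError(f"training diverged at epoch {epoch}")
        history.append(report)
        if report.total < best - config.improvement_tolerance:
            best = report.total
            best_epoch = epoch
            best_params = params.copy()
        if epoch - best_epoch >= config.patience_epochs:
            break
        arrays = {n: getattr(params, n) for n in _PARAM_FIELDS}
        opt.step(arrays, grads)
    return best_params, history


# ---------------------------------------------------------------------------
# rollout (used by the generation step)


def rollout(params: NetworkParameters, u0: np.ndarray, prefix: np.ndarray,
            cfg: PrecisionConfig, T: int,
            noise: np.ndarray | None = None) -> np.ndarray:
    """Produce drawn trajectories of length T from initial states u0.

    While prefix samples are available the drawn signal is a draw from the
    fused posterior of prediction and observation (under ``cfg``);
    afterwards the loop closes and the drawn signal is a draw from the
    network's own predictive distribution, with its variance scaled by
    H_prior and no sensory term. The drawn sample is fed back as the next
    input. This is where absolute precision matters: scaling both H factors
    equally leaves the posterior mean unchanged but scales the variance of
    the drawn signal, so jointly imprecise settings scribble while jointly
    precise ones draw cleanly.

    ``prefix`` is (B, Tp, D) with Tp <= T. ``noise`` supplies the standard
    normal draws, shape (B, T-1, D); pass None for the deterministic
    mean rollout. Returns drawn (B, T, D).
    """
    B, Tp, D = prefix.shape
    if Tp < 1 or Tp > T:
        raise ValueError("prefix length must be in [1, T]")
    alpha = 1.0 / params.tau
    u = np.asarray(u0, dtype=float).copy()
    c = np.tanh(u)
    drawn = np.empty((B, T, D))
    drawn[:, 0] = prefix[:, 0]
    v = prefix[:, 0]
    for t in range(T - 1):
        a = v @ params.w_in.T + c @ params.w_rec.T + params.b_h
        u = (1 - alpha) * u + alpha * a
        c = np.tanh(u)
        mu = np.tanh(c @ params.w_mu.T + params.b_mu)
        var = np.exp(c @ params.w_var.T + params.b_var) + params.eps
        if not np.all(np.isfinite(mu)):
            raise RuntimeError(f"non-finite state at rollout step {t + 1}")
        if t + 1 < Tp:
            post = integrate(mu, var, prefix[:, t + 1], cfg)
            out, out_var = post.mu, post.var
        else:
            out, out_var = mu, cfg.h_prior * var
        if noise is not None:
            # the pen cannot leave the tablet: clip the drawn sample to
            # just beyond the canvas
            out = np.clip(out + np.sqrt(out_var) * noise[:, t],
                          -CANVAS_CLIP, CANVAS_CLIP)
        drawn[:, t + 1] = out
        v = out
    return drawn
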