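"""Precision-weighted Bayesian fusion of prediction and sensory input.

The network's one-step-ahead prediction (mean mu_net, variance sigma_net^2)
plays the role of the prior; the observed sample x with fixed variance
sigma_sensor^2 is the likelihood. Their product-of-Gaussians posterior is

    sigma_post^2 = (Hs*ss2 * Hp*sn2) / (Hs*ss2 + Hp*sn2)
    mu_post      = sigma_post^2 * (mu_net/(Hp*sn2) + x/(Hs*ss2))

where the factors H_prior and H_sensor rescale the respective variances.
H = 1 is veridical precision; H < 1 treats the signal as more precise than
it is (over-attention), H > 1 as less precise (under-attention). Scaling
both H factors by the same constant leaves mu_post unchanged and scales
sigma_post^2 — the distinction between relative and absolute precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: numerical floor for the estimated sensory variance
SENSOR_VARIANCE_FLOOR = 1e-6


@dataclass
class PrecisionConfig:
    """Variance-scaling factors and base sensory variance.

    ``sigma_sensor_sq`` may be a scalar (shared across dimensions, the
    default) or a length-D vector.
    """

    h_prior: float = 1.0
    h_sensor: float = 1.0
    sigma_sensor_sq: float | np.ndarray = 0.05

    def __post_init__(self) -> None:
        ss = np.asarray(self.sigma_sensor_sq, dtype=float)
        if self.h_prior <= 0 or self.h_sensor <= 0 or np.any(ss <= 0):
            raise ValueError("precision factors and variances must be > 0")
        if not (np.isfinite(self.h_prior) and np.isfinite(self.h_sensor)
                and np.all(np.isfinite(ss))):
            raise ValueError("precision configuration must be finite")

    def to_dict(self) -> dict:
        ss = np.asarray(self.sigma_sensor_sq, dtype=float)
        return {"h_prior": self.h_prior, "h_sensor": self.h_sensor,
                "sigma_sensor_sq": ss.tolist() if ss.ndim else float(ss)}

    @classmethod
    def from_dict(cls, d: dict) -> "PrecisionConfig":
        ss = d["sigma_sensor_sq"]
        return cls(d["h_prior"], d["h_sensor"],
                   np.asarray(ss, float) if isinstance(ss, list) else ss)


@dataclass
class PosteriorSignal:
    """Result of one fusion step: posterior mean and variance per dimension."""

    mu: np.ndarray
    var: np.ndarray


def integrate(mu_net: np.ndarray, var_net: np.ndarray, x: np.ndarray,
              cfg: PrecisionConfig) -> PosteriorSignal:
    """Fuse prediction and observation into the posterior signal.

    Operates componentwise; all arguments broadcast, so batched inputs
    of shape (B, D) work directly.
    """
    mu_net = np.asarray(mu_net, dtype=float)
    var_net = np.asarray(var_net, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(var_net <= 0):
        raise ValueError("prediction variance must be strictly positive")
    s = cfg.h_sensor * np.asarray(cfg.sigma_sensor_sq, dtype=float)
    p = cfg.h_prior * var_net
    var_post = (s * p) / (s + p)
    mu_post = var_post * (mu_net / p + x / s)
    return PosteriorSignal(mu_post, var_post)


def integrate_grads(var_net: np.ndarray, mu_net: np.ndarray, x: np.ndarray,
                    cfg: PrecisionConfig) -> tuple[np.ndarray, np.ndarray]:
    """Partial derivatives of mu_post w.r.t. (mu_net, var_net).

    Needed by backpropagation through time when the training input is the
    fused posterior: d mu_post/d mu_net = s/(s+p) and
    d mu_post/d var_net = H_prior * s * (x - mu_net)/(s+p)^2,
    with s = H_sensor*sigma_sensor^2 and p = H_prior*var_net.
    """
    s = cfg.h_sensor * np.asarray(cfg.sigma_sensor_sq, dtype=float)
    p = cfg.h_prior * np.asarray(var_net, dtype=float)
    d_mu = s / (s + p)
    d_var = cfg.h_prior * s * (np.asarray(x) - np.asarray(mu_net)) / (s + p) ** 2
    return d_mu, d_var


def estimate_sensor_variance(dataset, floor: float = SENSOR_VARIANCE_FLOOR
                             ) -> float:
    """Estimate the base sensory variance from the training trajectories.

    Computes the variance of one-step increments per input dimension over all
    training trajectories, then averages across dimensions. Deterministic for
    a given dataset; clamped below by ``floor`` for degenerate (constant)
    inputs. Use ``PrecisionConfig(sigma_sensor_sq=0.05)`` to pin a constant
    instead.
    """
    increments = []
    for traj in dataset.split("train"):
        if len(traj) >= 2:
            increments.append(np.diff(traj.points, axis=0))
    if not increments:
        raise ValueError("dataset has no trajectory with >= 2 samples")
    inc = np.concatenate(increments, axis=0)
    per_dim = inc.var(axis=0)
    return float(max(per_dim.mean(), floor))
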