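"""Drawing completion: recognize a partial trajectory, then generate.

Completion of a partial drawing is a two-step procedure on a trained
network. In the *recognition* step the first third of a test trajectory
(30 of 90 steps) is shown, and gradient descent through time — with the
network weights frozen — infers the initial context state that best
explains the prefix under the active precision configuration. In the
*generation* step that inferred state seeds a full rollout: while prefix
samples remain the drawn output is the precision-weighted posterior of
prediction and observation; for the remaining two thirds the loop closes
and the network draws from its own predictions alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fusion import PrecisionConfig
from .network import Adam, NetworkParameters, prefix_nll_and_state_grad, \
    rollout
from .shapes import ShapeClass, Trajectory

#: fraction of the trajectory presented during recognition
PREFIX_FRACTION = 1 / 3
#: gradient epochs of the recognition step
RECOGNITION_EPOCHS = 100
#: step size of the recognition optimizer
RECOGNITION_LR = 0.01
#: std of the Gaussian noise on the recognition starting state
RECOGNITION_INIT_SIGMA = 0.01


@dataclass
class Prefix:
    """The presented part of a test trajectory (first third of T steps)."""

    points: np.ndarray          # (Tp, 3)
    intended_class: ShapeClass
    variant_id: int
    full_length: int = 90

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        expected = int(round(self.full_length * PREFIX_FRACTION))
        if self.points.shape[0] != expected:
            raise ValueError(
                f"prefix must be one third of T={self.full_length} "
                f"({expected} steps), got {self.points.shape[0]}")


def prefix_of(traj: Trajectory) -> Prefix:
    """Cut the presented prefix (first third) from a full test trajectory."""
    T = len(traj)
    Tp = int(round(T * PREFIX_FRACTION))
    return Prefix(traj.points[:Tp].copy(), traj.shape_class,
                  traj.variant_id, full_length=T)


@dataclass
class CompletionResult:
    """One produced drawing with full provenance."""

    drawn: Trajectory
    inferred_initial_state: np.ndarray
    intended_class: ShapeClass
    variant_id: int
    cell: tuple[float, float]        # (h_sensor, h_prior)
    network_id: int = 0
    repetition: int = 0

    @property
    def prefix_steps(self) -> int:
        return int(round(len(self.drawn) * PREFIX_FRACTION))

    @property
    def traced_segment(self) -> np.ndarray:
        """Drawn samples while the stimulus was presented (steps 1-30)."""
        return self.drawn.points[: self.prefix_steps]

    @property
    def completed_segment(self) -> np.ndarray:
        """Drawn samples produced closed-loop (steps 31-90)."""
        return self.drawn.points[self.prefix_steps:]

    def to_record(self) -> dict:
        return {
            "network_id": self.network_id,
            "h_sensor": self.cell[0],
            "h_prior": self.cell[1],
            "intended_class": self.intended_class.name,
            "variant_id": self.variant_id,
            "repetition": self.repetition,
            "inferred_initial_state":
                np.asarray(self.inferred_initial_state).tolist(),
            "drawn": self.drawn.points.tolist(),
        }

    @classmethod
    def from_record(cls, rec: dict) -> "CompletionResult":
        c = ShapeClass[rec["intended_class"]]
        return cls(
            drawn=Trajectory(np.asarray(rec["drawn"], float), c,
                             rec["variant_id"]),
            inferred_initial_state=np.asarray(
                rec["inferred_initial_state"], float),
            intended_class=c,
            variant_id=rec["variant_id"],
            cell=(rec["h_sensor"], rec["h_prior"]),
            network_id=rec["network_id"],
            repetition=rec["repetition"],
        )


def recognize_batch(params: NetworkParameters, prefixes: np.ndarray,
                    cfg: PrecisionConfig, epochs: int = RECOGNITION_EPOCHS,
                    init_states: np.ndarray | None = None,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Infer initial context states for a batch of prefixes.

    Optimizes a free (B, N) state array to minimize each prefix's sequence
    NLL (inputs fused under ``cfg``), weights frozen. The starting point is
    the learned initial-state mean plus small Gaussian noise unless
    ``init_states`` is given explicitly. The per-element best-so-far state
    over the epochs is returned; losses are separable, so batching does not
    couple the elements.
    """
    params.validate()
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    prefixes = np.asarray(prefixes, dtype=float)
    B = prefixes.shape[0]
    N = params.n_context
    if init_states is None:
        rng = rng or np.random.default_rng(0)
        u0 = params.init_mean[None, :] \
            + rng.normal(0.0, RECOGNITION_INIT_SIGMA, (B, N))
    else:
        u0 = np.array(init_states, dtype=float)
    best_loss = np.full(B, np.inf)
    best_u0 = u0.copy()
    opt = Adam(lr=RECOGNITION_LR)
    for _ in range(epochs):
        loss, grad = prefix_nll_and_state_grad(params, u0, prefixes, cfg)
        better = loss < best_loss
        best_loss[better] = loss[better]
        best_u0[better] = u0[better]
        opt.step({"u0": u0}, {"u0": grad})
    return best_u0


def recognize(params: NetworkParameters, prefix: Prefix,
              cfg: PrecisionConfig, epochs: int = RECOGNITION_EPOCHS,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Recognition step for a single prefix; returns the inferred state."""
    return recognize_batch(params, prefix.points[None], cfg, epochs,
                           rng=rng)[0]


def generate(params: NetworkParameters, initial_state: np.ndarray,
             prefix: Prefix, cfg: PrecisionConfig,
             network_id: int = 0, repetition: int = 0,
             noise: np.ndarray | None = None) -> CompletionResult:
    """Generation step: roll the network out to the full drawing length.

    ``noise`` supplies the (T-1, D) standard normal draws for sampling the
    drawn signal from the posterior; None gives the mean rollout.
    """
    initial_state = np.asarray(initial_state, dtype=float)
    if initial_state.shape != (params.n_context,):
        raise ValueError("initial_state must have length N")
    drawn = rollout(params, initial_state[None], prefix.points[None], cfg,
                    prefix.full_length,
                    noise=None if noise is None else noise[None])[0]
    traj = Trajectory(drawn, prefix.intended_class, prefix.variant_id)
    return CompletionResult(traj, initial_state, prefix.intended_class,
                            prefix.variant_id, (cfg.h_sensor, cfg.h_prior),
                            network_id, repetition)


def complete(params: NetworkParameters, prefix: Prefix,
             cfg: PrecisionConfig, repetition_seed: int,
             network_id: int = 0, repetition: int = 0,
             epochs: int = RECOGNITION_EPOCHS) -> CompletionResult:
    """Recognition followed by generation; deterministic in its arguments.

    ``repetition_seed`` seeds both the noise on the recognition starting
    state and the posterior sampling of the generation step, which is what
    distinguishes repeated completions of the same prefix.
    """
    rng = np.random.default_rng(repetition_seed)
    state = recognize(params, prefix, cfg, epochs=epochs, rng=rng)
    noise = rng.standard_normal((prefix.full_length - 1,
                                 prefix.points.shape[1]))
    return generate(params, state, prefix, cfg, network_id, repetition,
                    noise=noise)


# ---------------------------------------------------------------------------
# results file (JSON lines, one record per CompletionResult)


def write_results(results: list[CompletionResult], path: str | Path,
                  append: bool = False) -> None:
    mode = "a" if append else "w"
    with open(path, mode) as f:
        for r in results:
            f.write(json.dumps(r.to_record()) + "\n")


def read_results(path: str | Path) -> list[CompletionResult]:
    out = []
    with open(path) as f:
        for line in f:
            if line.strip():
                out.append(CompletionResult.from_record(json.loads(line)))
    return out
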