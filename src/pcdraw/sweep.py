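"""Factorial precision-sweep experiment.

Trains a set of independently seeded networks at veridical precision
(H_prior = H_sensor = 1), then runs every cell of the 3x3 grid of
prior/sensory variance factors over all networks, test prefixes, and
repetitions. The design is paired: every cell sees the same prefixes and
the same repetition seeds, so the precision configuration is the only
variable across cells. Results stream to a JSON-lines file and runs are
resumable: already-complete (cell, network) groups are skipped.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import completion as cpl
from .fusion import PrecisionConfig, estimate_sensor_variance
from .network import NetworkParameters, TrainingConfig, rollout, train
from .shapes import DrawingDataset

log = logging.getLogger(__name__)

#: the three variance factors applied to each precision axis
H_GRID = (0.001, 1.0, 1000.0)


@dataclass
class SweepPlan:
    """Design of the full experiment."""

    h_values: tuple[float, ...] = H_GRID
    n_networks: int = 10
    n_repetitions: int = 3
    network_seeds: list[int] | None = None

    def __post_init__(self) -> None:
        if self.network_seeds is None:
            self.network_seeds = list(range(self.n_networks))
        if len(self.network_seeds) != self.n_networks:
            raise ValueError("need exactly one seed per network")

    def cells(self) -> list[tuple[float, float]]:
        """The Cartesian grid of (h_sensor, h_prior) cells."""
        return list(itertools.product(self.h_values, self.h_values))

    def repetition_seed(self, network_seed: int, repetition: int) -> int:
        return network_seed * 1000 + repetition

    def expected_records(self, n_classes: int, n_test_per_class: int) -> int:
        return (len(self.cells()) * self.n_networks * n_classes
                * n_test_per_class * self.n_repetitions)


@dataclass
class SweepResults:
    results: list[cpl.CompletionResult]
    plan: SweepPlan

    def verify_coverage(self, dataset: DrawingDataset) -> None:
        """Raise unless every (cell, network, prefix, repetition) tuple is
        present exactly once."""
        expected = set()
        prefixes = [cpl.prefix_of(t) for t in dataset.split("test")]
        for cell in self.plan.cells():
            for net in range(self.plan.n_networks):
                for p in prefixes:
                    for rep in range(self.plan.n_repetitions):
                        expected.add((cell, net, p.intended_class.name,
                                      p.variant_id, rep))
        seen = [(r.cell, r.network_id, r.intended_class.name, r.variant_id,
                 r.repetition) for r in self.results]
        if len(seen) != len(set(seen)):
            raise ValueError("duplicated sweep records")
        if set(seen) != expected:
            missing = expected - set(seen)
            raise ValueError(f"sweep coverage incomplete: {len(missing)} "
                             f"tuples missing, e.g. {sorted(missing)[:3]}")


def train_model_set(dataset: DrawingDataset, training_cfg: TrainingConfig,
                    n_networks: int, seeds: list[int] | None = None,
                    out_dir: str | Path | None = None,
                    sigma_sensor_sq: float | None = None
                    ) -> list[NetworkParameters]:
    """Train ``n_networks`` independently seeded networks at H = (1, 1).

    The base sensory variance is estimated from the training data unless
    pinned via ``sigma_sensor_sq``. Checkpoints are written to ``out_dir``
    when given (``network_<seed>.ckpt``). A network whose training diverges
    is excluded from the returned list with a logged reason.
    """
    seeds = list(range(n_networks)) if seeds is None else list(seeds)
    if len(seeds) != n_networks:
        raise ValueError("need exactly one seed per network")
    if sigma_sensor_sq is None:
        sigma_sensor_sq = estimate_sensor_variance(dataset)
    cfg = PrecisionConfig(1.0, 1.0, sigma_sensor_sq)
    models = []
    for seed in seeds:
        params = NetworkParameters.init(
            training_cfg.n_context, dim=3, n_classes=len(dataset.classes),
            tau=training_cfg.tau, seed=seed)
        try:
            trained, history = train(params, dataset,
                                     TrainingConfig(**{**training_cfg.__dict__,
                                                       "seed": seed}),
                                     cfg)
        except RuntimeError as exc:
            log.warning("network seed=%d excluded: %s", seed, exc)
            continue
        log.info("network seed=%d trained: %d epochs, final total %.2f",
                 seed, len(history), history[-1].total)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            trained.save(out_dir / f"network_{seed}.ckpt", seed=seed)
        models.append(trained)
    return models


def _record_key(rec: dict) -> tuple:
    return (rec["h_sensor"], rec["h_prior"], rec["network_id"],
            rec["intended_class"], rec["variant_id"], rec["repetition"])


def run_sweep(model_set: list[NetworkParameters], dataset: DrawingDataset,
              plan: SweepPlan, sigma_sensor_sq: float | None = None,
              out_path: str | Path | None = None,
              recognition_epochs: int = cpl.RECOGNITION_EPOCHS
              ) -> SweepResults:
    """Run every sweep cell over every network, prefix, and repetition.

    Completions within one (cell, network) group are batched through
    recognition; each batch element's recognition start is drawn from its
    own repetition seed, so results are independent of grouping. If
    ``out_path`` exists, groups whose records are already present are
    skipped and the run resumes where it left off.
    """
    if len(model_set) < plan.n_networks:
        raise ValueError("missing checkpoints: model set smaller than plan")
    if sigma_sensor_sq is None:
        sigma_sensor_sq = estimate_sensor_variance(dataset)

    prefixes = [cpl.prefix_of(t) for t in dataset.split("test")]
    if not prefixes:
        raise ValueError("dataset has no test prefixes")
    T = prefixes[0].full_length

    existing: dict[tuple, dict] = {}
    if out_path is not None and Path(out_path).exists():
        with open(out_path) as f:
            for line in f:
                if line.strip():
                    rec = json.loads(line)
                    existing[_record_key(rec)] = rec

    all_records: dict[tuple, dict] = {}
    for cell in plan.cells():
        h_sensor, h_prior = cell
        cfg = PrecisionConfig(h_prior=h_prior, h_sensor=h_sensor,
                              sigma_sensor_sq=sigma_sensor_sq)
        for net_id, params in enumerate(model_set[: plan.n_networks]):
            net_seed = plan.network_seeds[net_id]
            group_keys = [(h_sensor, h_prior, net_id, p.intended_class.name,
                           p.variant_id, rep)
                          for p in prefixes
                          for rep in range(plan.n_repetitions)]
            if all(k in existing for k in group_keys):
                for k in group_keys:
                    all_records[k] = existing[k]
                continue

            batch = np.stack([p.points for p in prefixes
                              for _ in range(plan.n_repetitions)])
            # one rng per element, seeded by repetition: the same stream a
            # single complete() call with that repetition_seed would draw
            rngs = [np.random.default_rng(plan.repetition_seed(net_seed, rep))
                    for _ in prefixes for rep in range(plan.n_repetitions)]
            init = np.stack([
                params.init_mean + r.normal(0.0, cpl.RECOGNITION_INIT_SIGMA,
                                            params.n_context)
                for r in rngs])
            states = cpl.recognize_batch(params, batch, cfg,
                                         epochs=recognition_epochs,
                                         init_states=init)
            noise = np.stack([r.standard_normal((T - 1, batch.shape[2]))
                              for r in rngs])
            drawn = rollout(params, states, batch, cfg, T, noise=noise)
            new_records = []
            i = 0
            for p in prefixes:
                for rep in range(plan.n_repetitions):
                    res = cpl.CompletionResult(
                        drawn=cpl.Trajectory(drawn[i], p.intended_class,
                                             p.variant_id),
                        inferred_initial_state=states[i],
                        intended_class=p.intended_class,
                        variant_id=p.variant_id,
                        cell=cell, network_id=net_id, repetition=rep)
                    rec = res.to_record()
                    key = _record_key(rec)
                    all_records[key] = rec
                    if key not in existing:
                        new_records.append(rec)
                    i += 1
            if out_path is not None and new_records:
                with open(out_path, "a") as f:
                    for rec in new_records:
                        f.write(json.dumps(rec) + "\n")
            log.info("cell H_sensor=%g H_prior=%g network %d done",
                     h_sensor, h_prior, net_id)

    ordered = [cpl.CompletionResult.from_record(all_records[k])
               for k in sorted(all_records)]
    results = SweepResults(ordered, plan)
    results.verify_coverage(dataset)
    return results
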