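"""Shared fixtures: a scaled-down study — 3 shape classes, 2 networks of 30
context units trained for 2,000 epochs — plus the full precision sweep over
it. Session-scoped because training dominates the suite's runtime."""

import numpy as np
import pytest

import pcdraw as pc

SCALED_CLASSES = [pc.ShapeClass.FACE, pc.ShapeClass.HOUSE, pc.ShapeClass.CAR]
SCALED_N_CONTEXT = 30
SCALED_EPOCHS = 2_000
NETWORK_SEEDS = [0, 1]


@pytest.fixture(scope="session")
def dataset3():
    return pc.build_dataset(0, classes=SCALED_CLASSES)


@pytest.fixture(scope="session")
def dataset6():
    return pc.build_dataset(0)


@pytest.fixture(scope="session")
def sensor_var(dataset3):
    return pc.estimate_sensor_variance(dataset3)


@pytest.fixture(scope="session")
def training_config():
    return pc.TrainingConfig(max_epochs=SCALED_EPOCHS,
                             patience_epochs=SCALED_EPOCHS,
                             n_context=SCALED_N_CONTEXT)


@pytest.fixture(scope="session")
def model_set(dataset3, training_config, sensor_var):
    """Two independently seeded trained networks (the scaled-down study)."""
    return pc.train_model_set(dataset3, training_config, 2, NETWORK_SEEDS,
                              sigma_sensor_sq=sensor_var)


@pytest.fixture(scope="session")
def trained_model(model_set):
    return model_set[0]


@pytest.fixture(scope="session")
def sweep_results(model_set, dataset3, sensor_var):
    plan = pc.SweepPlan(n_networks=2, n_repetitions=3,
                        network_seeds=NETWORK_SEEDS)
    return pc.run_sweep(model_set, dataset3, plan,
                        sigma_sensor_sq=sensor_var)


@pytest.fixture(scope="session")
def sweep_distances(sweep_results, dataset3):
    return pc.evaluate_completions(sweep_results.results,
                                   dataset3.split("train"))


@pytest.fixture(scope="session")
def sweep_matrix(sweep_distances):
    return pc.misinterpretation_rate(sweep_distances)


def cell_mean(distances, cell, segment):
    vals = [d.error for d in distances
            if d.cell == cell and d.segment == segment]
    assert vals, f"no results for cell {cell} segment {segment}"
    return float(np.mean(vals))
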