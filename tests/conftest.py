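import numpy as np
import pytest

from tanglekit.datatypes import PopulationRates
from tanglekit.synthetic import (
    MuscleFactorSpec,
    StackedEllipseSpec,
    generate_muscle_factors,
    generate_stacked_population,
)


@pytest.fixture(scope="session")
def factor_spec():
    return MuscleFactorSpec(seed=7)


@pytest.fixture(scope="session")
def muscle_factors(factor_spec):
    return generate_muscle_factors(factor_spec)


@pytest.fixture(scope="session")
def stacked_population(muscle_factors):
    spec = StackedEllipseSpec(seed=11)
    return generate_stacked_population(spec, muscle_factors)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


class TrainedNet:
    """Bundle of a trained network and its task, unpackable as a 3-tuple."""

    def __init__(self, params, protocol, spec, history):
        self.params = params
        self.protocol = protocol
        self.spec = spec
        self.history = history

    def __iter__(self):
        return iter((self.params, self.protocol, self.spec))


@pytest.fixture(scope="session")
def mini_network():
    """A small two-speed network trained to emit sinusoid pairs.

    Deliberately modest (two conditions, pure sinusoids, loose convergence
    target) so the fixture trains in well under a minute while still
    exhibiting the stacked-limit-cycle solution the analyses interrogate.
    """
    from tanglekit.rnn import InputProtocol, TrainConfig, train

    spec = MuscleFactorSpec(
        n_factors=2, n_speeds=2, base_freqs=(1.5, 2.0),
        harmonic_amps=(1.0, 0.0, 0.0), seed=5,
    )
    targets = generate_muscle_factors(spec)
    protocol = InputProtocol(n_speeds=2, total_steps=2000)
    config = TrainConfig(max_iterations=1500, total_steps=2000,
                         target_nmse=0.04, lr_milestones=((800, 0.3),))
    params, history = train(targets, protocol, config, seed=5, n_units=30)
    return TrainedNet(params, protocol, spec, history)


def circle_rates(radii, n_units=6, n_points=200, seed=0):
    """Concentric-circle populations embedded in n_units dims (test helper)."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n_units, 2)))
    values = []
    for r in radii:
        theta = 2 * np.pi * np.arange(n_points) / n_points
        values.append(q @ np.stack([r * np.cos(theta), r * np.sin(theta)]))
    return PopulationRates(values, time_step=1.0,
                           speed_bins=list(range(len(radii))), kind="neural")
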