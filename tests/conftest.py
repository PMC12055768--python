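import numpy as np
import pytest

from affectdyn.codes import CodeStream, WeightTable, WeightedSeries
from affectdyn.model import DyadModel, InfluenceFunction, ModelParameters, RepairTerm


@pytest.fixture
def default_weights() -> WeightTable:
    return WeightTable()


@pytest.fixture
def null_dyad() -> DyadModel:
    """Stable dyad with no cross-actor coupling."""
    return DyadModel(
        therapist=ModelParameters("therapist", initial_state=-0.2, inertia=0.4),
        client=ModelParameters("client", initial_state=-0.1, inertia=0.5),
    )


def make_actor(
    actor: str,
    a: float,
    r: float,
    influence: InfluenceFunction | None = None,
    repair: RepairTerm | None = None,
) -> ModelParameters:
    return ModelParameters(
        actor=actor,
        initial_state=a,
        inertia=r,
        influence_from_partner=influence or InfluenceFunction(),
        repair=repair or RepairTerm(),
    )


def simulate_actor(
    a: float,
    r: float,
    partner_scores: np.ndarray,
    influence: InfluenceFunction | None = None,
    repair: RepairTerm | None = None,
    noise_sd: float = 0.0,
    x0: float = 0.0,
    rng: np.random.Generator | None = None,
) -> WeightedSeries:
    """Drive one actor's update with a prescribed partner score sequence."""
    influence = influence or InfluenceFunction()
    repair = repair or RepairTerm()
    n = len(partner_scores)
    x = np.empty(n)
    x[0] = x0
    noise = (
        rng.normal(0.0, noise_sd, size=n)
        if noise_sd > 0 and rng is not None
        else np.zeros(n)
    )
    for t in range(1, n):
        z = partner_scores[t - 1]
        x[t] = r * x[t - 1] + a + influence(z) + repair(z) + noise[t]
    return WeightedSeries("therapist", x)
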