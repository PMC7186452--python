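from typing import Dict, Tuple

import numpy as np
import pytest

from mon.network import (
    MultiplexNetwork,
    PinGraph,
    ProteinUniverse,
    WeightedLayer,
)


def make_layer(universe: ProteinUniverse, weights: Dict[Tuple[str, str], float],
               name: str = "layer") -> WeightedLayer:
    canon = {tuple(sorted(p)): w for p, w in weights.items()}
    return WeightedLayer(universe, canon, name)


def random_multiplex(n: int, L: int, rng: np.random.Generator,
                     density: float = 0.4) -> MultiplexNetwork:
    """Random weighted multiplex with weights in (0, 1]."""
    ids = [f"p{i:03d}" for i in range(n)]
    universe = ProteinUniverse.from_ids(ids)
    layers = []
    for k in range(L):
        weights = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < density:
                    weights[(ids[i], ids[j])] = float(rng.uniform(0.05, 1.0))
        layers.append(WeightedLayer(universe, weights, f"layer{k}"))
    return MultiplexNetwork(universe, tuple(layers))


@pytest.fixture
def triangle_pin() -> PinGraph:
    return PinGraph.from_edges([("a", "b"), ("a", "c"), ("b", "c")])


@pytest.fixture
def star_plus_pin() -> PinGraph:
    # hub a with leaves b, c, d, and one chord b-c
    return PinGraph.from_edges([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")])


@pytest.fixture
def small_bundle():
    from mon.simulate import SyntheticConfig, generate

    return generate(SyntheticConfig(n_proteins=60, n_essential=12, n_modules=3,
                                    n_domains=12, n_timepoints=10, seed=7))
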