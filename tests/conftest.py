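"""Shared fixtures: tiny hand-checkable networks and random communities."""

from __future__ import annotations

import numpy as np
import pytest

from thermoweb import (
    AllometricModel,
    Consumer,
    Resource,
    SyntheticConfig,
    TemperatureSizeRule,
    build_network,
)

REF_T = 20.0


def make_consumer(cid: str, bite_force: float) -> Consumer:
    """Consumer with unit mass and exponent 0, so bite force == prefactor."""
    return Consumer(id=cid, reference_mass=1.0, allometry=AllometricModel(bite_force, 0.0))


def make_resources(cuts: list[float]) -> list[Resource]:
    return [Resource(id=f"p{j + 1}", cutting_force=c) for j, c in enumerate(cuts)]


def random_community(rng: np.random.Generator, n_consumers: int, n_resources: int):
    """Random community whose force ranges overlap, for property tests."""
    exponent = rng.uniform(0.2, 1.2)
    allometry = AllometricModel(float(rng.uniform(2, 20)), float(exponent))
    consumers = [
        Consumer(
            id=f"c{i}",
            reference_mass=float(rng.lognormal(np.log(10), 0.5)),
            allometry=allometry,
        )
        for i in range(n_consumers)
    ]
    bites = np.array([c.baseline_bite_force for c in consumers])
    cuts = np.exp(rng.uniform(np.log(bites.min() / 3), np.log(bites.max() * 3), n_resources))
    resources = [Resource(id=f"p{j}", cutting_force=float(x)) for j, x in enumerate(cuts)]
    return consumers, resources


def brute_force_edges(consumers, resources, temperature, rule):
    """Independent double-loop oracle for feasibility edges."""
    edges = set()
    for c in consumers:
        mass = c.reference_mass * rule.alpha ** (temperature - rule.reference_temperature)
        bite = c.allometry.prefactor * mass**c.allometry.exponent
        for r in resources:
            if bite >= r.cutting_force:
                edges.add((c.id, r.id))
    return edges


@pytest.fixture
def no_shrink_rule() -> TemperatureSizeRule:
    return TemperatureSizeRule(alpha=1.0, reference_temperature=REF_T)


@pytest.fixture
def worked_network():
    """Bites {20, 35} mN vs cuts {10, 25, 50} mN: edges c1-p1, c2-p1, c2-p2."""
    consumers = [make_consumer("c1", 20.0), make_consumer("c2", 35.0)]
    resources = make_resources([10.0, 25.0, 50.0])
    rule = TemperatureSizeRule(alpha=1.0, reference_temperature=REF_T)
    return build_network(consumers, resources, REF_T, rule), consumers, resources


@pytest.fixture
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=42)
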