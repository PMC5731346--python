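"""Shared fixtures: toy networks, scenario bundles, random-network generator."""

from __future__ import annotations

import numpy as np
import pytest

from fluxcycle import FluxMap, load_default_network, parse_network
from fluxcycle.labeling import TracerSpec, fully_labeled_mid
from fluxcycle.synthetic import _anchor_fluxmap

TOY_CHAIN = """
[metabolites]
S, 2, 1.0, source, 0.0
A, 2, 1.5, balanced, 0.0
B, 2, 0.8, balanced, 0.0
C, 2, 2.0, balanced, 0.0
Snk, 2, 1.0, sink, 0.0
[reactions]
vin: S (ab) -> A (ab)
vab: A (ab) -> B (ab)
vbc: B (ab) -> C (ab)
vout: C (ab) -> Snk (ab)
"""

TOY_BRANCH = """
[metabolites]
S, 2, 1.0, source, 0.0
A, 2, 1.5, balanced, 0.0
B, 2, 0.8, balanced, 0.0
Snk, 2, 1.0, sink, 0.0
[reactions]
vin: S (ab) -> A (ab)
v1: A (ab) -> B (ab)
vb: B (ab) -> Snk (ab)
v2: A (ab) -> Snk (ab)
"""


@pytest.fixture(scope="session")
def tca_network():
    return load_default_network()


@pytest.fixture(scope="session")
def tca_fluxmap():
    """A balanced flux map on the default network (G1-anchor values)."""
    return _anchor_fluxmap(1.4, 0.6, 0.15)


@pytest.fixture(scope="session")
def glc_tracer():
    return TracerSpec("glc", {"GlcPyr": fully_labeled_mid(3)})


@pytest.fixture(scope="session")
def gln_tracer():
    return TracerSpec("gln", {"GlnSrc": fully_labeled_mid(5)})


@pytest.fixture(scope="session")
def toy_chain():
    return parse_network(TOY_CHAIN)


@pytest.fixture(scope="session")
def toy_branch():
    return parse_network(TOY_BRANCH)


@pytest.fixture(scope="session")
def toy_branch_fluxmap():
    return FluxMap(net={"vin": 1.5, "v1": 1.0, "vb": 1.0, "v2": 0.5})


@pytest.fixture(scope="session")
def osc_bundle():
    """One noisy oscillating-scenario experiment, shared across tests."""
    from fluxcycle.synthetic import generate_experiment, make_scenario

    return generate_experiment(make_scenario("oscillating", seed=7))


def random_toy_network(rng: np.random.Generator):
    """A random small atom-mapped network with a balanced flux map.

    Chains of 1-3 metabolites off a 2-carbon source, an optional condensation
    of two 1-carbon intermediates, random pools, and a random dilution
    fraction on one pool: enough variety to exercise the EMU tracer against
    the positional-isotopomer integrator.
    """
    letters = "ab"
    mets = ["S, 2, 1.0, source, 0.0"]
    rxns = ["vin: S (ab) -> A0 (ab)"]
    n_chain = int(rng.integers(1, 4))
    dil_at = int(rng.integers(0, n_chain))
    for i in range(n_chain):
        pool = float(rng.uniform(0.5, 3.0))
        dil = float(rng.uniform(0.0, 0.5)) if i == dil_at else 0.0
        mets.append(f"A{i}, 2, {pool}, balanced, {dil}")
        if i > 0:
            amap = "ab" if rng.random() < 0.5 else "ba"
            rxns.append(f"v{i}: A{i-1} (ab) -> A{i} ({amap})")
    last = f"A{n_chain-1}"
    if rng.random() < 0.5:
        # split the last 2-carbon pool and recondense with scrambling
        mets += [
            f"X, 1, {float(rng.uniform(0.5, 2.0))}, balanced, 0.0",
            f"Y, 1, {float(rng.uniform(0.5, 2.0))}, balanced, 0.0",
            f"Z, 2, {float(rng.uniform(0.5, 2.0))}, balanced, 0.0",
        ]
        rxns += [
            f"vsplit: {last} (ab) -> X (a) + Y (b)",
            "vcond: X (a) + Y (b) -> Z (ba)",
            "vz: Z (ab) -> Snk (ab)",
        ]
    else:
        rxns.append(f"vend: {last} (ab) -> Snk (ab)")
    mets.append("Snk, 2, 1.0, sink, 0.0")
    text = "[metabolites]\n" + "\n".join(mets) + "\n[reactions]\n" + "\n".join(rxns) + "\n"
    net = parse_network(text)
    v = float(rng.uniform(0.5, 2.0))
    fluxmap = FluxMap(net={r.id: v for r in net.reactions.values()})
    return net, fluxmap
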