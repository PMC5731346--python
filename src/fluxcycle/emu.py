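"""Elementary metabolite unit (EMU) decomposition.

An EMU is a subset of one metabolite's carbons; its mass-isotopomer
distribution can be simulated without tracking full positional isotopomers.
Starting from the observation targets, carbons are traced backward through
every atom-map variant of every producing reaction; a condensation whose
product draws carbons from several substrates yields a convolution edge
joining the corresponding smaller EMUs. The result is the minimal EMU system
needed to determine the target MIDs, grouped by EMU size (size classes are
solved in ascending order; cycles within a class are solved jointly).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .network import Network, NetworkFormatError, ReactionVariant

__all__ = ["EmuNode", "EmuEdge", "EmuSystem", "emu_decompose"]


@dataclass(frozen=True, order=True)
class EmuNode:
    """One EMU: a metabolite plus an ascending tuple of 1-based carbon indices."""

    metabolite: str
    carbons: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.carbons or list(self.carbons) != sorted(set(self.carbons)):
            raise ValueError(f"EMU carbons must be ascending and unique: {self.carbons}")

    @property
    def size(self) -> int:
        return len(self.carbons)


@dataclass(frozen=True)
class EmuEdge:
    """A production route for ``target``: flux flows from ``sources`` into it.

    ``sources`` has one entry per substrate contributing carbons; more than one
    entry means the target MID gains the convolution of the source MIDs.
    ``direction`` +1/-1 selects forward/backward flux of the reaction, scaled
    by the symmetry ``weight``.
    """

    target: EmuNode
    sources: tuple[EmuNode, ...]
    reaction_id: str
    direction: int
    weight: float


class EmuSystem:
    """EMU nodes grouped by size with their production edges."""

    def __init__(self, network: Network, nodes: set[EmuNode], edges: list[EmuEdge]):
        self.network = network
        self.nodes = sorted(nodes)
        self.edges = edges
        sizes = sorted({n.size for n in self.nodes})
        self.size_classes: dict[int, list[EmuNode]] = {
            s: [n for n in self.nodes if n.size == s] for s in sizes
        }
        self.edges_by_target: dict[EmuNode, list[EmuEdge]] = {n: [] for n in self.nodes}
        for e in self.edges:
            self.edges_by_target[e.target].append(e)

    @property
    def sizes(self) -> list[int]:
        return list(self.size_classes)

    def solved_nodes(self) -> list[EmuNode]:
        """Nodes whose MID must be integrated (non-source metabolites)."""
        return [n for n in self.nodes if not self.network.metabolites[n.metabolite].is_source]

    def source_nodes(self) -> list[EmuNode]:
        return [n for n in self.nodes if self.network.metabolites[n.metabolite].is_source]


def _trace_variant_product(
    variant: ReactionVariant, product_index: int, carbons: tuple[int, ...]
) -> tuple[EmuNode, ...]:
    """Find the substrate EMUs supplying ``carbons`` of one product instance."""
    _, pmap = variant.products[product_index]
    wanted = [pmap[c - 1] for c in carbons]
    per_substrate: dict[int, list[int]] = {}
    for letter in wanted:
        for si, (_, smap) in enumerate(variant.substrates):
            pos = smap.find(letter)
            if pos >= 0:
                per_substrate.setdefault(si, []).append(pos + 1)
                break
        else:  # pragma: no cover - Reaction invariants forbid this
            raise NetworkFormatError(
                f"reaction {variant.reaction_id}: letter {letter!r} missing on substrate side"
            )
    return tuple(
        EmuNode(variant.substrates[si][0], tuple(sorted(positions)))
        for si, positions in sorted(per_substrate.items())
    )


def emu_decompose(
    network: Network, targets: list[tuple[str, tuple[int, ...]]]
) -> EmuSystem:
    """Build the minimal EMU system determining the target MIDs.

    ``targets`` are (metabolite name, carbon index subset) pairs; indices are
    1-based. Source metabolites terminate the backward trace.
    """
    worklist: deque[EmuNode] = deque()
    nodes: set[EmuNode] = set()
    for name, carbons in targets:
        met = network.metabolites.get(name)
        if met is None:
            raise KeyError(f"target references unknown metabolite {name}")
        if any(c < 1 or c > met.n_carbons for c in carbons):
            raise ValueError(f"target carbons {carbons} outside 1..{met.n_carbons} for {name}")
        node = EmuNode(name, tuple(sorted(carbons)))
        if node not in nodes:
            nodes.add(node)
            worklist.append(node)

    edges: list[EmuEdge] = []
    variants = network.variants()
    while worklist:
        node = worklist.popleft()
        if network.metabolites[node.metabolite].is_source:
            continue
        for var in variants:
            for pi, (pname, _) in enumerate(var.products):
                if pname != node.metabolite:
                    continue
                sources = _trace_variant_product(var, pi, node.carbons)
                edges.append(
                    EmuEdge(
                        target=node,
                        sources=sources,
                        reaction_id=var.reaction_id,
                        direction=var.direction,
                        weight=var.weight,
                    )
                )
                for src in sources:
                    if src not in nodes:
                        nodes.add(src)
                        worklist.append(src)
    return EmuSystem(network, nodes, edges)
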