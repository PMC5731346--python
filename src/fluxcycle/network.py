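"""Atom-mapped metabolic network: parsing, validation, flux maps.

A network is a set of metabolites (with carbon counts, pool sizes and roles)
plus reactions whose carbon transitions are written in per-reaction lowercase
letter notation, e.g. ``cs: OAA (abcd) + AcCoA (ef) -> Cit (dcbfea)``.
Reversible reactions are parameterized as a net flux plus a non-negative
exchange flux (forward = net + exchange, backward = exchange), the standard
identifiable parameterization in 13C metabolic flux analysis.

Two-fold rotationally symmetric metabolites (succinate, fumarate) are handled
by expanding every reaction that consumes them into two half-weighted atom-map
variants with reversed carbon order, which scrambles positional fates exactly
as the molecular symmetry does.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NetworkFormatError",
    "Metabolite",
    "Reaction",
    "ReactionVariant",
    "Network",
    "FluxMap",
    "BalanceViolation",
    "parse_network",
    "serialize_network",
    "validate_steady_state",
]

ROLES = ("balanced", "source", "sink")


class NetworkFormatError(ValueError):
    """Raised when a network document violates the format or atom balance."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species with a carbon backbone.

    ``pool_size`` is the intracellular amount per cell (arbitrary units); it is
    the capacity term C of the labeling ODE d(C·X)/dt = influx − efflux·X.
    ``dilution_fraction`` is the fraction of influx drawn from an unlabeled
    sink (e.g. exchange with a large unlabeled compartment).
    """

    name: str
    n_carbons: int
    pool_size: float = 1.0
    role: str = "balanced"
    dilution_fraction: float = 0.0
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise NetworkFormatError(f"{self.name}: n_carbons must be >= 1")
        if self.role not in ROLES:
            raise NetworkFormatError(f"{self.name}: unknown role {self.role!r}")
        if self.role == "balanced" and not self.pool_size > 0:
            raise NetworkFormatError(f"{self.name}: balanced pool_size must be > 0")
        if not 0.0 <= self.dilution_fraction <= 1.0:
            raise NetworkFormatError(f"{self.name}: dilution_fraction outside [0, 1]")

    @property
    def is_source(self) -> bool:
        return self.role == "source"

    @property
    def is_balanced(self) -> bool:
        return self.role == "balanced"


@dataclass(frozen=True)
class Reaction:
    """One reaction with per-instance atom maps.

    ``substrates`` and ``products`` are tuples of (metabolite name, letter map);
    a stoichiometric coefficient of 2 is written as two instances. Every letter
    must appear exactly once on each side.
    """

    id: str
    substrates: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]
    reversible: bool = False

    def __post_init__(self) -> None:
        for side_name, side in (("substrate", self.substrates), ("product", self.products)):
            letters = "".join(m for _, m in side)
            if len(set(letters)) != len(letters):
                raise NetworkFormatError(
                    f"reaction {self.id}: duplicate carbon letter on {side_name} side"
                )
        sub_letters = set("".join(m for _, m in self.substrates))
        prod_letters = set("".join(m for _, m in self.products))
        if sub_letters != prod_letters:
            raise NetworkFormatError(
                f"reaction {self.id}: unbalanced carbons "
                f"(substrate letters {sorted(sub_letters)}, product letters {sorted(prod_letters)})"
            )


@dataclass(frozen=True)
class ReactionVariant:
    """One atom-map variant of a reaction after symmetry expansion.

    ``direction`` is +1 (as written) or -1 (backward of a reversible reaction);
    ``weight`` is the symmetry weight (1, 1/2, 1/4, ...). The flux carried by a
    variant is weight × (net + exchange) forward, weight × exchange backward.
    """

    reaction_id: str
    substrates: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]
    direction: int = 1
    weight: float = 1.0


@dataclass
class FluxMap:
    """Net (and optional exchange) fluxes per reaction id."""

    net: dict[str, float]
    exchange: dict[str, float] = field(default_factory=dict)

    def forward_backward(self, reaction: Reaction) -> tuple[float, float]:
        v = self.net.get(reaction.id, 0.0)
        if reaction.reversible:
            ex = self.exchange.get(reaction.id, 0.0)
            return v + ex, ex
        return v, 0.0

    def scaled(self, c: float) -> "FluxMap":
        return FluxMap(
            net={k: c * v for k, v in self.net.items()},
            exchange={k: c * v for k, v in self.exchange.items()},
        )


@dataclass(frozen=True)
class BalanceViolation:
    metabolite: str
    imbalance: float  # influx − efflux


class Network:
    """Immutable-ish container of metabolites and reactions."""

    def __init__(self, metabolites: Iterable[Metabolite], reactions: Iterable[Reaction]):
        self.metabolites: dict[str, Metabolite] = {}
        for m in metabolites:
            if m.name in self.metabolites:
                raise NetworkFormatError(f"duplicate metabolite {m.name}")
            self.metabolites[m.name] = m
        self.reactions: dict[str, Reaction] = {}
        for r in reactions:
            if r.id in self.reactions:
                raise NetworkFormatError(f"duplicate reaction id {r.id}")
            self._check_reaction(r)
            self.reactions[r.id] = r
        self._variants: list[ReactionVariant] | None = None

    def _check_reaction(self, r: Reaction) -> None:
        for name, amap in r.substrates + r.products:
            met = self.metabolites.get(name)
            if met is None:
                raise NetworkFormatError(f"reaction {r.id}: unknown metabolite {name}")
            if len(amap) != met.n_carbons:
                raise NetworkFormatError(
                    f"reaction {r.id}: atom map {amap!r} has {len(amap)} letters "
                    f"but {name} has {met.n_carbons} carbons"
                )

    # -- symmetry / reversibility expansion ---------------------------------

    def variants(self) -> list[ReactionVariant]:
        """All atom-map variants after symmetry and reversibility expansion."""
        if self._variants is not None:
            return self._variants
        out: list[ReactionVariant] = []
        for r in self.reactions.values():
            directions = [(1, r.substrates, r.products)]
            if r.reversible:
                directions.append((-1, r.products, r.substrates))
            for direction, subs, prods in directions:
                for subs_variant, weight in self._symmetry_expand(subs):
                    out.append(
                        ReactionVariant(
                            reaction_id=r.id,
                            substrates=subs_variant,
                            products=prods,
                            direction=direction,
                            weight=weight,
                        )
                    )
        self._variants = out
        return out

    def _symmetry_expand(
        self, substrates: tuple[tuple[str, str], ...]
    ) -> list[tuple[tuple[tuple[str, str], ...], float]]:
        variants: list[tuple[tuple[tuple[str, str], ...], float]] = [((), 1.0)]
        for name, amap in substrates:
            met = self.metabolites[name]
            options = [(name, amap)]
            if met.symmetric:
                options.append((name, amap[::-1]))
            new: list[tuple[tuple[tuple[str, str], ...], float]] = []
            for prefix, w in variants:
                for opt in options:
                    new.append((prefix + (opt,), w / len(options)))
            variants = new
        return variants

    # -- stoichiometry ------------------------------------------------------

    def balanced_metabolites(self) -> list[str]:
        return [m.name for m in self.metabolites.values() if m.is_balanced]

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Net stoichiometric matrix over balanced metabolites.

        Returns (S, metabolite names, reaction ids) with S[i, j] the net
        production of metabolite i by unit net flux through reaction j.
        """
        mets = self.balanced_metabolites()
        rxns = list(self.reactions)
        idx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(rxns)))
        for j, rid in enumerate(rxns):
            r = self.reactions[rid]
            for name, _ in r.substrates:
                if name in idx:
                    S[idx[name], j] -= 1.0
            for name, _ in r.products:
                if name in idx:
                    S[idx[name], j] += 1.0
        return S, mets, rxns

    def consumption_flux(self, fluxmap: FluxMap) -> dict[str, float]:
        """Total consumption flux (turnover) per metabolite, symmetry-aware."""
        out = {m: 0.0 for m in self.metabolites}
        for var in self.variants():
            r = self.reactions[var.reaction_id]
            fwd, bwd = fluxmap.forward_backward(r)
            v = var.weight * (fwd if var.direction == 1 else bwd)
            for name, _ in var.substrates:
                out[name] += v
        return out


def validate_steady_state(
    fluxmap: FluxMap, network: Network, tol_factor: float = 1e-9
) -> list[BalanceViolation]:
    """Check influx == efflux for every balanced metabolite.

    Tolerance is ``tol_factor`` × the largest absolute flux. Returns a (possibly
    empty) list of violations; never raises for imbalance.
    """
    for rid in list(fluxmap.net) + list(fluxmap.exchange):
        if rid not in network.reactions:
            raise KeyError(f"flux given for unknown reaction {rid}")
    S, mets, rxns = network.stoichiometric_matrix()
    v = np.array([fluxmap.net.get(rid, 0.0) for rid in rxns])
    imbalance = S @ v
    all_fluxes = list(fluxmap.net.values()) + list(fluxmap.exchange.values())
    vmax = max((abs(x) for x in all_fluxes), default=0.0)
    tol = tol_factor * max(vmax, 1.0)
    return [
        BalanceViolation(m, float(d))
        for m, d in zip(mets, imbalance)
        if abs(d) > tol
    ]


# -- text format ------------------------------------------------------------

_REACTION_RE = re.compile(r"^(?P<id>[\w.\-]+)\s*:\s*(?P<body>.+)$")
_TERM_RE = re.compile(r"^(?P<name>[\w.\-]+)\s*\(\s*(?P<map>[a-z]+)\s*\)$")


def _parse_side(text: str, rid: str) -> tuple[tuple[str, str], ...]:
    terms = []
    for raw in text.split("+"):
        raw = raw.strip()
        if not raw:
            raise NetworkFormatError(f"reaction {rid}: empty term")
        m = _TERM_RE.match(raw)
        if not m:
            raise NetworkFormatError(f"reaction {rid}: cannot parse term {raw!r}")
        terms.append((m.group("name"), m.group("map")))
    return tuple(terms)


def parse_network(text: str) -> Network:
    """Parse a network-definition document.

    Format: a ``[metabolites]`` section with one metabolite per line
    (``name, n_carbons, pool_size, source|balanced|sink, dilution_fraction
    [, symmetric]``), then a ``[reactions]`` section with one reaction per line
    (``id: A (ab) + B (c) -> C (abc) [rev] [sym:NAME]``). ``#`` starts a
    comment.
    """
    metabolites: dict[str, Metabolite] = {}
    reactions: list[Reaction] = []
    seen_ids: set[str] = set()
    sym_tags: set[str] = set()
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower() in ("[metabolites]", "[reactions]"):
            section = line.lower().strip("[]")
            continue
        if section == "metabolites":
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 5:
                raise NetworkFormatError(
                    f"line {lineno}: metabolite needs name, n_carbons, pool_size, role, dilution"
                )
            name, n_c, pool, role, dil, *rest = parts
            symmetric = any(p.lower() == "symmetric" for p in rest)
            if name in metabolites:
                raise NetworkFormatError(f"line {lineno}: duplicate metabolite {name}")
            metabolites[name] = Metabolite(
                name=name,
                n_carbons=int(n_c),
                pool_size=float(pool),
                role=role.lower(),
                dilution_fraction=float(dil),
                symmetric=symmetric,
            )
        elif section == "reactions":
            m = _REACTION_RE.match(line)
            if not m:
                raise NetworkFormatError(f"line {lineno}: cannot parse reaction {line!r}")
            rid, body = m.group("id"), m.group("body")
            if rid in seen_ids:
                raise NetworkFormatError(f"line {lineno}: duplicate reaction id {rid}")
            seen_ids.add(rid)
            tokens = body.split()
            reversible = False
            while tokens and (tokens[-1] == "rev" or tokens[-1].startswith("sym:")):
                tok = tokens.pop()
                if tok == "rev":
                    reversible = True
                else:
                    sym_tags.add(tok[4:])
            body = " ".join(tokens)
            if "->" not in body:
                raise NetworkFormatError(f"reaction {rid}: missing '->'")
            lhs, rhs = body.split("->", 1)
            reactions.append(
                Reaction(
                    id=rid,
                    substrates=_parse_side(lhs, rid),
                    products=_parse_side(rhs, rid),
                    reversible=reversible,
                )
            )
        else:
            raise NetworkFormatError(f"line {lineno}: content outside a section")
    for name in sym_tags:
        if name not in metabolites:
            raise NetworkFormatError(f"sym: tag names unknown metabolite {name}")
        metabolites[name] = replace(metabolites[name], symmetric=True)
    return Network(metabolites.values(), reactions)


def serialize_network(network: Network) -> str:
    """Write a network back to the text format (canonical ordering)."""
    lines = ["[metabolites]"]
    for name in sorted(network.metabolites):
        m = network.metabolites[name]
        tail = ", symmetric" if m.symmetric else ""
        lines.append(
            f"{m.name}, {m.n_carbons}, {m.pool_size!r}, {m.role}, {m.dilution_fraction!r}{tail}"
        )
    lines.append("[reactions]")
    for rid in sorted(network.reactions):
        r = network.reactions[rid]
        lhs = " + ".join(f"{n} ({a})" for n, a in r.substrates)
        rhs = " + ".join(f"{n} ({a})" for n, a in r.products)
        rev = " rev" if r.reversible else ""
        lines.append(f"{rid}: {lhs} -> {rhs}{rev}")
    return "\n".join(lines) + "\n"
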