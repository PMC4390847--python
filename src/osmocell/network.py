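"""Chemical species and mass-action reaction networks.

A :class:`ReactionNetwork` is an ordered list of species names together with
elementary :class:`Reaction` steps (at most trimolecular).  The only dynamics
it knows about is bulk mass-action kinetics: :func:`mak_rates` evaluates the
net production rate of every species at a given concentration state.

Rate constants are stored as bare numbers in the molar convention:
a step of total reactant order ``m`` carries a constant in M^(1-m) s^-1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np

from .constants import MAX_ORDER

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "parse_reaction",
    "parse_network",
    "mak_rates",
    "net_stoichiometry_change",
]


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action step, optionally reversible.

    Parameters
    ----------
    reactants, products
        Species name -> positive integer stoichiometric count.
    k
        Forward rate constant, M^(1-order) s^-1 where order is the total
        reactant molecularity.
    kr
        Reverse rate constant (0 or None means irreversible).
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    k: float
    kr: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "reactants", dict(self.reactants))
        object.__setattr__(self, "products", dict(self.products))
        for side, name in ((self.reactants, "reactant"), (self.products, "product")):
            for sp, nu in side.items():
                if not (isinstance(nu, (int, np.integer)) and nu > 0):
                    raise ValueError(
                        f"{name} stoichiometry for {sp!r} must be a positive "
                        f"integer, got {nu!r}"
                    )
            total = sum(side.values())
            if total > MAX_ORDER:
                raise ValueError(
                    f"total {name} molecularity {total} exceeds {MAX_ORDER} "
                    "(elementary steps are at most trimolecular)"
                )
        if not self.k > 0:
            raise ValueError(f"forward rate constant must be > 0, got {self.k}")
        if self.kr is None:
            object.__setattr__(self, "kr", 0.0)
        if self.kr < 0:
            raise ValueError(f"reverse rate constant must be >= 0, got {self.kr}")

    @property
    def order(self) -> int:
        """Total reactant molecularity (forward reaction order)."""
        return sum(self.reactants.values())

    @property
    def reverse_order(self) -> int:
        return sum(self.products.values())

    @property
    def reversible(self) -> bool:
        return self.kr > 0

    def net_change(self, species: str) -> int:
        """Net stoichiometric change of one species in the forward direction."""
        return self.products.get(species, 0) - self.reactants.get(species, 0)

    def __str__(self) -> str:
        def side(d: Mapping[str, int]) -> str:
            return " + ".join(
                (f"{nu} {sp}" if nu > 1 else sp) for sp, nu in d.items()
            ) or "0"

        arrow = "<->" if self.reversible else "->"
        rates = f"k={self.k:g}" + (f", kr={self.kr:g}" if self.reversible else "")
        return f"{side(self.reactants)} {arrow} {side(self.products)} ({rates})"


@dataclass
class ReactionNetwork:
    """An ordered set of species and the reactions connecting them."""

    species: List[str]
    reactions: List[Reaction] = field(default_factory=list)

    def __post_init__(self):
        self.species = list(self.species)
        self.reactions = list(self.reactions)
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique")
        declared = set(self.species)
        for rx in self.reactions:
            used = set(rx.reactants) | set(rx.products)
            missing = used - declared
            if missing:
                raise ValueError(
                    f"reaction {rx} uses undeclared species {sorted(missing)}"
                )

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        return self.species.index(name)

    def concentrations_to_array(self, s: Mapping[str, float]) -> np.ndarray:
        try:
            return np.array([float(s[sp]) for sp in self.species])
        except KeyError as exc:
            raise KeyError(f"species {exc.args[0]!r} missing from concentration map")

    def array_to_concentrations(self, v: Sequence[float]) -> Dict[str, float]:
        return {sp: float(x) for sp, x in zip(self.species, v)}

    def stoichiometry_matrix(self) -> np.ndarray:
        """Net stoichiometric matrix, shape (n_species, n_reactions)."""
        S = np.zeros((self.n_species, len(self.reactions)))
        for j, rx in enumerate(self.reactions):
            for i, sp in enumerate(self.species):
                S[i, j] = rx.net_change(sp)
        return S

    def __str__(self) -> str:
        return "; ".join(str(rx) for rx in self.reactions)


_SIDE_TERM = re.compile(r"^\s*(\d*)\s*([A-Za-z_]\w*)\s*$")


def _parse_side(text: str) -> Dict[str, int]:
    out: Dict[str, int] = {}
    text = text.strip()
    if text in ("", "0"):
        return out
    for term in text.split("+"):
        m = _SIDE_TERM.match(term)
        if not m:
            raise ValueError(f"cannot parse reaction side term {term!r}")
        nu = int(m.group(1)) if m.group(1) else 1
        sp = m.group(2)
        out[sp] = out.get(sp, 0) + nu
    return out


def parse_reaction(text: str) -> Reaction:
    """Parse one reaction string like ``"X + 2Y <-> 3Y (k=5.25e4, kr=2.85e3)"``."""
    m = re.match(r"^(.*?)\(([^()]*)\)\s*$", text.strip())
    if not m:
        raise ValueError(f"reaction {text!r} must end with '(k=..., [kr=...])'")
    body, params = m.group(1), m.group(2)
    kwargs: Dict[str, float] = {}
    for item in params.split(","):
        key, _, val = item.partition("=")
        key = key.strip().lower()
        if key not in ("k", "kr"):
            raise ValueError(f"unknown rate parameter {key!r} in {text!r}")
        kwargs[key] = float(val)
    if "k" not in kwargs:
        raise ValueError(f"missing forward rate constant in {text!r}")
    if "<->" in body:
        lhs, rhs = body.split("<->")
        reversible = True
    elif "->" in body:
        lhs, rhs = body.split("->")
        reversible = False
    else:
        raise ValueError(f"no reaction arrow ('->' or '<->') in {text!r}")
    if not reversible and "kr" in kwargs and kwargs["kr"] != 0:
        raise ValueError(f"irreversible reaction {text!r} cannot have kr")
    return Reaction(_parse_side(lhs), _parse_side(rhs), kwargs["k"], kwargs.get("kr", 0.0))


def parse_network(config_text: str, species: Iterable[str] | None = None) -> ReactionNetwork:
    """Parse a network from reaction strings separated by ';' or newlines.

    Species are collected in order of first appearance unless an explicit
    ordered ``species`` list is given (which must then cover every name used).
    """
    chunks = [c for c in re.split(r"[;\n]", config_text) if c.strip()]
    reactions = [parse_reaction(c) for c in chunks]
    if species is None:
        seen: List[str] = []
        for rx in reactions:
            for sp in list(rx.reactants) + list(rx.products):
                if sp not in seen:
                    seen.append(sp)
        species = seen
    return ReactionNetwork(list(species), reactions)


def mak_rates(network: ReactionNetwork, s: Mapping[str, float]) -> Dict[str, float]:
    """Net mass-action production rate r_i of every species, in M/s.

    For each reaction, the net flux is ``k * prod(reactant concs) -
    kr * prod(product concs)``; each species gains that flux times its net
    stoichiometric change.
    """
    v = network.concentrations_to_array(s)
    return network.array_to_concentrations(mak_rates_vec(network, v))


def mak_rates_vec(network: ReactionNetwork, v: np.ndarray) -> np.ndarray:
    """Array form of :func:`mak_rates`; ``v`` ordered like ``network.species``."""
    r = np.zeros_like(v, dtype=float)
    idx = {sp: i for i, sp in enumerate(network.species)}
    for rx in network.reactions:
        fwd = rx.k
        for sp, nu in rx.reactants.items():
            fwd *= v[idx[sp]] ** nu
        flux = fwd
        if rx.kr > 0:
            rev = rx.kr
            for sp, nu in rx.products.items():
                rev *= v[idx[sp]] ** nu
            flux -= rev
        for sp in set(rx.reactants) | set(rx.products):
            r[idx[sp]] += rx.net_change(sp) * flux
    return r


def net_stoichiometry_change(network: ReactionNetwork) -> List[int]:
    """Per-reaction net molecule production (sum of products - sum of reactants).

    A network is molecule-conserving iff every entry is 0; only then can
    chemistry alone leave the vesicle's osmotic balance untouched.
    """
    return [
        sum(rx.products.values()) - sum(rx.reactants.values())
        for rx in network.reactions
    ]
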