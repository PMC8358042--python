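"""Monomers, polymer grammar and reaction rules of the DNA stack chemistry.

The stack is operated with nine short ssDNA strands:

========  ========  =====================================================
token     role      function
========  ========  =====================================================
``s``     start     nucleates a stack; hybridises the bead-bound linker
``p``     push      spacer added between signals; presents the BC overhang
``X``     signal    hairpin signal, 107 nt
``Y``     signal    hairpin signal, 137 nt
``w``     signal    linear (hairpin-free) signal used for gel calibration
``r``     read      displaces the last signal as an inert signal·read duplex
``q``     pop       displaces the exposed push as an inert push·pop duplex
``k``     linker    biotinylated strand anchoring stacks to beads
``z``     releaser  displaces start from linker, ejecting a whole stack
========  ========  =====================================================

All binding happens through two 28 nt domain types: the *A* domain
(``alpha`` sites) and the *BC* overhang (``beta`` sites).  Signals carry a
beta-binding head and expose an alpha site at their tail; pushes carry an
alpha-binding head and expose a beta overhang.  A linear complex is
therefore an alternating token chain, e.g. ``k.s.p.X.p.Y`` for a tethered
stack holding signals X then Y, or ``p.w.p`` for an off-target solution
complex.

Reactions are generated just-in-time by pattern matching on the exposed
interfaces of the species currently present, which keeps the unbounded
polymer state space from ever being enumerated up front.
"""

from __future__ import annotations

import enum
import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

__all__ = [
    "SIGNAL_TOKENS",
    "ALL_TOKENS",
    "MonomerSpec",
    "SiteType",
    "EndSites",
    "Species",
    "RateConstants",
    "RuleConfig",
    "Reaction",
    "define_monomers",
    "species_from_tokens",
    "exposed_sites",
    "enumerate_reactions",
    "pair_reactions",
    "apply_reaction",
    "total_nucleotides",
    "InvalidSpeciesError",
    "ConfigurationError",
]

SIGNAL_TOKENS = ("X", "Y", "w")
ALL_TOKENS = ("s", "p", "X", "Y", "w", "r", "q", "k", "z")

#: Default strand lengths in nucleotides.  X and Y are the synthesised
#: hairpin signals (107 and 137 nt).  push is 28 nt (A-binding) + 28 nt
#: (BC overhang) = 56 nt.  The remaining lengths are not printed anywhere
#: and are package assumptions: start, write, read and pop are taken as
#: two-domain 56 nt strands like push; linker and releaser as 40 nt
#: (anchoring domain plus a short toehold).
DEFAULT_LENGTHS = {
    "s": 56,
    "p": 56,
    "X": 107,
    "Y": 137,
    "w": 56,
    "r": 56,
    "q": 56,
    "k": 40,
    "z": 40,
}

_ROLES = {
    "s": "start",
    "p": "push",
    "X": "signal",
    "Y": "signal",
    "w": "signal",
    "r": "read",
    "q": "pop",
    "k": "linker",
    "z": "releaser",
}


class ConfigurationError(ValueError):
    """Raised when a monomer/rate configuration is malformed."""


class InvalidSpeciesError(ValueError):
    """Raised when a token sequence violates the complex grammar."""


class SiteType(enum.Enum):
    """Exposed single-stranded interface at the end of a complex.

    ``ALPHA_OPEN`` is an A-type 28 nt domain (presented by a bare start and
    by the last signal of a stack); ``BETA_OPEN`` is a BC-type 28 nt
    overhang (presented by the last push).  Inert duplexes expose ``NONE``.
    """

    ALPHA_OPEN = "alpha_open"
    BETA_OPEN = "beta_open"
    NONE = "none"


class EndSites(NamedTuple):
    head: SiteType
    tail: SiteType


@dataclass(frozen=True)
class MonomerSpec:
    token: str
    length_nt: int
    role: str
    sites: EndSites

    def __post_init__(self):
        if self.token not in ALL_TOKENS:
            raise ConfigurationError(f"unknown monomer token: {self.token!r}")
        if self.length_nt <= 0:
            raise ConfigurationError(
                f"monomer {self.token!r} must have positive length, got {self.length_nt}"
            )


def _monomer_sites(token: str) -> EndSites:
    # Interface the free monomer presents at head / tail, in alpha/beta terms.
    head = {
        "p": SiteType.ALPHA_OPEN,   # A*-side strand of an alpha duplex
        "X": SiteType.BETA_OPEN,
        "Y": SiteType.BETA_OPEN,
        "w": SiteType.BETA_OPEN,
        "r": SiteType.ALPHA_OPEN,
        "q": SiteType.BETA_OPEN,
    }.get(token, SiteType.NONE)
    tail = {
        "s": SiteType.ALPHA_OPEN,
        "p": SiteType.BETA_OPEN,
        "X": SiteType.ALPHA_OPEN,
        "Y": SiteType.ALPHA_OPEN,
        "w": SiteType.ALPHA_OPEN,
    }.get(token, SiteType.NONE)
    return EndSites(head, tail)


def define_monomers(config: Mapping[str, object] | None = None) -> dict[str, MonomerSpec]:
    """Build the validated nine-monomer set.

    ``config`` maps token -> length in nt (or token -> {"length": nt}).
    Missing tokens fall back to defaults only when ``config`` is ``None``;
    an explicit config must name all nine strands.
    """
    if config is None:
        lengths = dict(DEFAULT_LENGTHS)
    else:
        lengths = {}
        for token, value in config.items():
            if token not in ALL_TOKENS:
                raise ConfigurationError(f"unknown monomer token: {token!r}")
            if isinstance(value, Mapping):
                value = value.get("length", value.get("length_nt"))
            if not isinstance(value, (int, float)) or value != int(value):
                raise ConfigurationError(f"monomer {token!r}: length must be an integer")
            lengths[token] = int(value)
        for token in ALL_TOKENS:
            if token not in lengths:
                raise ConfigurationError(f"missing monomer: {token}")
    return {
        t: MonomerSpec(t, lengths[t], _ROLES[t], _monomer_sites(t)) for t in ALL_TOKENS
    }


# ---------------------------------------------------------------------------
# Species grammar
# ---------------------------------------------------------------------------

#: Allowed adjacent token pairs in a linear complex (5'->3' along the
#: assembly axis).  Everything else is a grammar violation.
_ADJACENT = frozenset(
    [("k", "s"), ("k", "z"), ("s", "p"), ("s", "r"), ("p", "q")]
    + [("p", sig) for sig in SIGNAL_TOKENS]
    + [(sig, "p") for sig in SIGNAL_TOKENS]
    + [(sig, "r") for sig in SIGNAL_TOKENS]
)

# internal head/tail classes used by rule matching
_H_NONE, _H_ALPHA, _H_BETA, _H_LINK = 0, 1, 2, 3
_T_NONE, _T_ALPHA, _T_BETA, _T_LINK = 0, 1, 2, 3

#: Blunt double-stranded products with no exposed interfaces.
_BLUNT = frozenset({("X", "r"), ("Y", "r"), ("w", "r"), ("p", "q"), ("k", "z")})


class Species:
    """A linear complex, canonically identified by its ordered token tuple.

    Tether state is implied by the tokens: a complex is bead-tethered iff
    it begins with the linker ``k``.  Nick positions and hairpin geometry
    are not part of species identity.
    """

    __slots__ = ("tokens", "tethered", "head_class", "tail_class", "inert", "_hash")

    _intern: dict[tuple[str, ...], "Species"] = {}

    def __new__(cls, tokens: Sequence[str]):
        key = tuple(tokens)
        cached = cls._intern.get(key)
        if cached is not None:
            return cached
        self = object.__new__(cls)
        self._init(key)
        cls._intern[key] = self
        return self

    def _init(self, tokens: tuple[str, ...]) -> None:
        _validate_tokens(tokens)
        self.tokens = tokens
        self.tethered = tokens[0] == "k"
        last = tokens[-1]
        if last in ("r", "q", "z"):
            self.tail_class = _T_NONE
        elif last == "p":
            self.tail_class = _T_BETA
        elif last == "k":  # bare linker
            self.tail_class = _T_LINK
        else:  # s or a signal
            self.tail_class = _T_ALPHA
        first = tokens[0]
        if tokens in _BLUNT or first in ("k", "r", "q", "z"):
            self.head_class = _H_NONE
        elif first == "p":
            self.head_class = _H_ALPHA
        elif first == "s":
            self.head_class = _H_LINK
        else:
            self.head_class = _H_BETA
        self.inert = self.tail_class == _T_NONE and self.head_class == _H_NONE
        self._hash = hash(tokens)

    @property
    def name(self) -> str:
        return ".".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __hash__(self) -> int:
        return self._hash

    def __eq__(self, other) -> bool:
        return self is other or (
            isinstance(other, Species) and self.tokens == other.tokens
        )

    def __repr__(self) -> str:
        return f"Species({self.name!r})"


def _validate_tokens(tokens: tuple[str, ...]) -> None:
    if not tokens:
        raise InvalidSpeciesError("a species needs at least one monomer")
    for t in tokens:
        if t not in ALL_TOKENS:
            raise InvalidSpeciesError(f"unknown monomer token: {t!r}")
    if "k" in tokens[1:]:
        raise InvalidSpeciesError("linker k may only appear at the head of a complex")
    for a, b in zip(tokens, tokens[1:]):
        if (a, b) not in _ADJACENT:
            raise InvalidSpeciesError(
                f"tokens {a!r} and {b!r} cannot be adjacent in a complex "
                f"({'.'.join(tokens)})"
            )


def species_from_tokens(
    tokens: Sequence[str], tethered: bool | None = None
) -> Species:
    """Canonical species for a token sequence; rejects grammar violations.

    ``tethered`` may be passed for validation: tether state is implied by a
    leading ``k`` and a contradictory flag is an error.
    """
    sp = Species(tokens)
    if tethered is not None and tethered != sp.tethered:
        raise InvalidSpeciesError(
            f"species {sp.name} is {'tethered' if sp.tethered else 'free'}; "
            f"tethered={tethered} contradicts its tokens"
        )
    return sp


def exposed_sites(species: Species) -> EndSites:
    """Deterministic report of the reactive interfaces at both ends."""
    head = {
        _H_ALPHA: SiteType.ALPHA_OPEN,
        _H_BETA: SiteType.BETA_OPEN,
    }.get(species.head_class, SiteType.NONE)
    tail = {
        _T_ALPHA: SiteType.ALPHA_OPEN,
        _T_BETA: SiteType.BETA_OPEN,
    }.get(species.tail_class, SiteType.NONE)
    if len(species.tokens) == 1 and species.tokens[0] in ("r", "q"):
        # free displacer monomers: report the toehold they present
        head = (
            SiteType.ALPHA_OPEN if species.tokens[0] == "r" else SiteType.BETA_OPEN
        )
    return EndSites(head, tail)


def total_nucleotides(
    species: Species | Iterable[str], monomers: Mapping[str, MonomerSpec]
) -> int:
    """Total nt over both backbones of the (nicked) complex.

    Gel migration of write-signal stacks is linear in this number, which is
    why it defines the apparent band size.
    """
    tokens = species.tokens if isinstance(species, Species) else tuple(species)
    return sum(monomers[t].length_nt for t in tokens)


# ---------------------------------------------------------------------------
# Reaction rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateConstants:
    """Bimolecular hybridisation rate constants (M^-1 s^-1).

    All principal reactions reduce to alpha-site binding (k_A) or beta-site
    binding (k_BC); displacement reactions inherit the rate of their
    toehold-binding site.  UV-absorbance calibrated default:
    k_A = k_BC = 3e4 M^-1 s^-1.
    """

    k_A: float = 3.0e4
    k_BC: float = 3.0e4

    def __post_init__(self):
        if self.k_A <= 0 or self.k_BC <= 0:
            raise ConfigurationError("rate constants must be positive")


@dataclass(frozen=True)
class RuleConfig:
    """Switches over the rule classes, for sensitivity experiments.

    ``read_caps_start``: allow read to cap the A site of a bare start
    (the site is sequence-identical to a signal's A site).
    ``pop_binds_free_push``: allow pop to hybridise a free push in solution.
    ``polymer_polymer_joins``: allow joins where both partners are chains
    (disabling restricts joining to monomer partners).
    ``disabled_rules``: rule ids to suppress entirely.
    """

    read_caps_start: bool = True
    pop_binds_free_push: bool = True
    polymer_polymer_joins: bool = True
    disabled_rules: frozenset = frozenset()


@dataclass(frozen=True)
class Reaction:
    reactants: tuple[Species, ...]
    products: tuple[Species, ...]
    rate_constant: float
    rule_id: str

    @property
    def same_reactants(self) -> bool:
        return len(self.reactants) == 2 and self.reactants[0] is self.reactants[1]

    def __repr__(self) -> str:
        lhs = " + ".join(s.name for s in self.reactants)
        rhs = " + ".join(s.name for s in self.products)
        return f"<{self.rule_id}: {lhs} -> {rhs}>"


def _is_monomer(sp: Species, token: str) -> bool:
    return len(sp.tokens) == 1 and sp.tokens[0] == token


_JOIN_RULES = {
    # tail class of A  : (head class of B, rule id, rate attr)
    _T_ALPHA: (_H_ALPHA, "R1", "k_A"),
    _T_BETA: (_H_BETA, "R2", "k_BC"),
    _T_LINK: (_H_LINK, "R5", "k_A"),
}


def _join(a: Species, b: Species, rates: RateConstants, cfg: RuleConfig):
    """Elongation of a's exposed tail by chain b's head (b joins on top)."""
    rule = _JOIN_RULES.get(a.tail_class)
    if rule is None:
        return None
    head_needed, rule_id, rate_attr = rule
    if b.head_class != head_needed or rule_id in cfg.disabled_rules:
        return None
    if b.tokens[0] in ("r", "q", "z"):  # displacers never join
        return None
    if not cfg.polymer_polymer_joins and len(a) > 1 and len(b) > 1:
        return None
    product = Species(a.tokens + b.tokens)
    return Reaction((a, b), (product,), getattr(rates, rate_attr), rule_id)


def _displacement(mono: Species, target: Species, rates: RateConstants, cfg: RuleConfig):
    """Reactions of the free displacer monomers r, q, z against ``target``."""
    tok = mono.tokens[0]
    if tok == "r" and "R3" not in cfg.disabled_rules:
        if target.tail_class != _T_ALPHA:
            return None
        last = target.tokens[-1]
        if last in SIGNAL_TOKENS:
            duplex = Species((last, "r"))
            if len(target) == 1:  # free signal -> blunt signal-read duplex
                return Reaction((mono, target), (duplex,), rates.k_A, "R3")
            rest = Species(target.tokens[:-1])
            return Reaction((mono, target), (rest, duplex), rates.k_A, "R3")
        # tail is a bare start: degenerate capping of the empty stack
        if cfg.read_caps_start and "R3cap" not in cfg.disabled_rules:
            capped = Species(target.tokens + ("r",))
            return Reaction((mono, target), (capped,), rates.k_A, "R3cap")
        return None
    if tok == "q" and "R4" not in cfg.disabled_rules:
        if target.tail_class != _T_BETA:
            return None
        duplex = Species(("p", "q"))
        if len(target) == 1:  # free push in solution
            if not cfg.pop_binds_free_push:
                return None
            return Reaction((mono, target), (duplex,), rates.k_BC, "R4")
        rest = Species(target.tokens[:-1])
        return Reaction((mono, target), (rest, duplex), rates.k_BC, "R4")
    if tok == "z" and "R5r" not in cfg.disabled_rules:
        if not target.tethered or "z" in target.tokens:
            return None
        kz = Species(("k", "z"))
        if len(target) == 1:  # bare linker
            return Reaction((mono, target), (kz,), rates.k_A, "R5r")
        released = Species(target.tokens[1:])
        return Reaction((mono, target), (kz, released), rates.k_A, "R5r")
    return None


def pair_reactions(
    a: Species,
    b: Species,
    rates: RateConstants | None = None,
    cfg: RuleConfig | None = None,
) -> list[Reaction]:
    """All concrete reactions with reactant multiset {a, b}."""
    rates = rates or RateConstants()
    cfg = cfg or RuleConfig()
    out: list[Reaction] = []
    pairs = [(a, b)] if a is b else [(a, b), (b, a)]
    for x, y in pairs:
        rxn = _join(x, y, rates, cfg)
        if rxn is not None:
            out.append(rxn)
        if len(x.tokens) == 1 and x.tokens[0] in ("r", "q", "z") and x is not y:
            rxn = _displacement(x, y, rates, cfg)
            if rxn is not None:
                out.append(rxn)
    return out


def enumerate_reactions(
    species: Iterable[Species],
    rates: RateConstants | None = None,
    cfg: RuleConfig | None = None,
) -> list[Reaction]:
    """Every reaction instantiable from the rule set on the present species.

    Returns each distinct (rule, reactant pair) exactly once; output is
    independent of input ordering.
    """
    rates = rates or RateConstants()
    cfg = cfg or RuleConfig()
    present = sorted(set(species), key=lambda s: s.tokens)
    for sp in present:
        if not isinstance(sp, Species):
            raise InvalidSpeciesError(f"unknown species object: {sp!r}")
    out: list[Reaction] = []
    for a, b in itertools.combinations_with_replacement(present, 2):
        out.extend(pair_reactions(a, b, rates, cfg))
    return out


def apply_reaction(counts: dict[Species, int], reaction: Reaction) -> dict[Species, int]:
    """Fire one reaction event on a species->count map (mutates and returns).

    Token multisets are conserved: every monomer entering the reactants
    leaves in the products.
    """
    need = Counter(reaction.reactants)
    for sp, n in need.items():
        if counts.get(sp, 0) < n:
            raise ValueError(
                f"insufficient {sp.name}: have {counts.get(sp, 0)}, need {n}"
            )
    for sp in reaction.reactants:
        counts[sp] -= 1
        if counts[sp] == 0:
            del counts[sp]
    for sp in reaction.products:
        counts[sp] = counts.get(sp, 0) + 1
    return counts
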