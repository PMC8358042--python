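"""Monomer set, complex grammar and reaction-rule enumeration."""

from __future__ import annotations

import itertools
import random
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

import stackdna.chemistry as chem
from stackdna.chemistry import (
    ALL_TOKENS,
    ConfigurationError,
    InvalidSpeciesError,
    RateConstants,
    RuleConfig,
    SiteType,
    Species,
    apply_reaction,
    define_monomers,
    enumerate_reactions,
    exposed_sites,
    species_from_tokens,
    total_nucleotides,
)


class TestMonomers:
    def test_default_table(self):
        m = define_monomers()
        assert len(m) == 9
        assert m["X"].length_nt == 107
        assert m["Y"].length_nt == 137
        assert m["p"].length_nt == 56  # 28 nt A-binding head + 28 nt BC overhang

    def test_explicit_config_must_be_complete(self):
        cfg = {t: 56 for t in ALL_TOKENS if t != "z"}
        with pytest.raises(ConfigurationError, match="missing monomer: z"):
            define_monomers(cfg)

    @pytest.mark.parametrize(
        "bad", [{"s": 0}, {"s": -10}, {"s": 56.5}, {"bogus": 56}]
    )
    def test_invalid_entries_rejected(self, bad):
        cfg = {t: 56 for t in ALL_TOKENS}
        cfg.update(bad)
        with pytest.raises(ConfigurationError):
            define_monomers(cfg)

    def test_push_sites(self):
        m = define_monomers({t: 56 for t in ALL_TOKENS} | {"p": 56})
        assert m["p"].sites.head is SiteType.ALPHA_OPEN
        assert m["p"].sites.tail is SiteType.BETA_OPEN


# token adjacency derivable from the domain design: push bridges alpha to
# beta, signals bridge beta to alpha, caps terminate.  Used as an
# independent oracle for the species grammar.
_ORACLE_ADJ = {
    "k": {"s", "z"},
    "s": {"p", "r"},
    "p": {"X", "Y", "w", "q"},
    "X": {"p", "r"},
    "Y": {"p", "r"},
    "w": {"p", "r"},
    "r": set(),
    "q": set(),
    "z": set(),
}


def _oracle_valid(tokens) -> bool:
    if not tokens or any(t not in _ORACLE_ADJ for t in tokens):
        return False
    if "k" in tokens[1:]:
        return False
    return all(b in _ORACLE_ADJ[a] for a, b in zip(tokens, tokens[1:]))


class TestSpeciesGrammar:
    @pytest.mark.parametrize(
        "tokens, tethered",
        [
            (("k", "s", "p", "X"), True),
            (("p", "w", "p"), False),
            (("w", "p", "w"), False),
            (("k",), True),
            (("s",), False),
            (("X", "r"), False),
            (("k", "z"), True),
        ],
    )
    def test_valid_species(self, tokens, tethered):
        sp = species_from_tokens(tokens)
        assert sp.tokens == tokens
        assert sp.tethered is tethered

    @pytest.mark.parametrize(
        "tokens",
        [("s", "X"), ("s", "s"), ("X", "Y"), ("p", "p"), ("s", "k"), (), ("b",)],
    )
    def test_grammar_violations(self, tokens):
        with pytest.raises(InvalidSpeciesError):
            species_from_tokens(tokens)

    def test_tether_flag_must_match_tokens(self):
        assert species_from_tokens(("k", "s"), tethered=True).tethered
        with pytest.raises(InvalidSpeciesError):
            species_from_tokens(("s", "p"), tethered=True)

    def test_identity_is_token_sequence(self):
        assert species_from_tokens(["k", "s"]) is species_from_tokens(("k", "s"))

    def test_exhaustive_small_grammar_matches_oracle(self):
        # every token string up to length 4 is accepted iff the
        # domain-adjacency oracle accepts it
        for n in range(1, 5):
            for tokens in itertools.product(ALL_TOKENS, repeat=n):
                expected = _oracle_valid(tokens)
                try:
                    species_from_tokens(tokens)
                    accepted = True
                except InvalidSpeciesError:
                    accepted = False
                assert accepted == expected, tokens


class TestExposedSites:
    @pytest.mark.parametrize(
        "tokens, tail",
        [
            (("k", "s", "p"), SiteType.BETA_OPEN),
            (("k", "s", "p", "X"), SiteType.ALPHA_OPEN),
            (("k", "s"), SiteType.ALPHA_OPEN),
            (("X", "r"), SiteType.NONE),  # blunt signal-read duplex
            (("p", "q"), SiteType.NONE),
            (("k", "z"), SiteType.NONE),
        ],
    )
    def test_growing_end(self, tokens, tail):
        assert exposed_sites(species_from_tokens(tokens)).tail is tail

    def test_at_most_one_reactive_site_at_growing_end(self):
        for tokens in itertools.chain.from_iterable(
            itertools.product(ALL_TOKENS, repeat=n) for n in range(1, 4)
        ):
            try:
                sp = species_from_tokens(tokens)
            except InvalidSpeciesError:
                continue
            sites = exposed_sites(sp)
            assert sites.tail in (
                SiteType.ALPHA_OPEN, SiteType.BETA_OPEN, SiteType.NONE
            )


class TestTotalNucleotides:
    def test_sums_both_backbones(self, monomers):
        assert total_nucleotides(["s", "p", "w"], monomers) == 168
        assert total_nucleotides(["X", "r"], monomers) == 163
        assert total_nucleotides([], monomers) == 0


# ---------------------------------------------------------------------------
# Rule enumeration against a brute-force oracle
# ---------------------------------------------------------------------------


def _oracle_reactions(species_list, rates, cfg):
    """Independent re-derivation of the rule set from the domain design.

    Works on token strings and tests every ordered pair against every
    rule; returns a set of (rule, reactants, products) signatures.
    """
    sigs = set()
    sigs_add = lambda rule, rs, ps: sigs.add(
        (rule, tuple(sorted(rs)), tuple(sorted(ps)))
    )
    species = {sp.tokens for sp in species_list}
    signals = ("X", "Y", "w")
    for a, b in itertools.product(species, repeat=2):
        # joins: a's growing tail accepts b's head
        head, tail = b[0], a[-1]
        b_is_chainable = head in ("p", "s") + signals and not (
            len(b) == 2 and b[0] in signals and b[1] == "r"
        ) and not (b == ("p", "q"))
        if b_is_chainable and "k" not in b:
            ok = (
                (tail in ("s",) + signals and head == "p")
                or (tail == "p" and head in signals)
                or (a == ("k",) and head == "s")
            )
            # capped chains have no live tail
            if a[-1] in ("r", "q", "z"):
                ok = False
            if ok:
                rule = (
                    "R5" if a == ("k",) else ("R1" if head == "p" else "R2")
                )
                sigs_add(rule, [a, b], [a + b])
    for t in species:
        if t[-1] in ("r", "q", "z"):
            continue
        if ("r",) in species and t[-1] in signals:
            if len(t) == 1:
                sigs_add("R3", [("r",), t], [t + ("r",)])
            else:
                sigs_add("R3", [("r",), t], [t[:-1], (t[-1], "r")])
        if ("r",) in species and t[-1] == "s" and cfg.read_caps_start:
            sigs_add("R3cap", [("r",), t], [t + ("r",)])
        if ("q",) in species and t[-1] == "p":
            if len(t) == 1:
                if cfg.pop_binds_free_push:
                    sigs_add("R4", [("q",), t], [("p", "q")])
            else:
                sigs_add("R4", [("q",), t], [t[:-1], ("p", "q")])
    if ("z",) in species:
        for t in species:
            if t[0] == "k" and "z" not in t:
                if len(t) == 1:
                    sigs_add("R5r", [("z",), t], [("k", "z")])
                else:
                    sigs_add("R5r", [("z",), t], [("k", "z"), t[1:]])
    return sigs


def _signatures(reactions):
    return {
        (
            r.rule_id,
            tuple(sorted(sp.tokens for sp in r.reactants)),
            tuple(sorted(sp.tokens for sp in r.products)),
        )
        for r in reactions
    }


_POOL = [
    ("k",), ("s",), ("p",), ("X",), ("Y",), ("w",), ("r",), ("q",), ("z",),
    ("k", "s"), ("k", "s", "p"), ("k", "s", "p", "X"), ("k", "s", "p", "Y", "p"),
    ("s", "p"), ("s", "p", "w"), ("p", "w"), ("w", "p"), ("p", "w", "p"),
    ("w", "p", "w"), ("X", "r"), ("w", "r"), ("p", "q"), ("k", "z"),
    ("s", "r"), ("k", "s", "r"), ("k", "s", "p", "X", "p", "Y"),
]


class TestEnumeration:
    def test_single_nucleation_pair(self):
        rxns = enumerate_reactions([Species(("s",)), Species(("k",))])
        assert len(rxns) == 1 and rxns[0].rule_id == "R5"

    def test_read_displacement_products(self):
        rxns = enumerate_reactions([Species(("k", "s", "p", "X")), Species(("r",))])
        assert _signatures(rxns) == {
            (
                "R3",
                ((("k", "s", "p", "X")), ("r",)),
                ((("X", "r")), ("k", "s", "p")),
            )
        }

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_bruteforce_oracle_on_small_states(self, trial):
        rng = random.Random(trial)
        chosen = [Species(t) for t in rng.sample(_POOL, rng.randint(2, 6))]
        rates, cfg = RateConstants(), RuleConfig()
        got = _signatures(enumerate_reactions(chosen, rates, cfg))
        assert got == _oracle_reactions(chosen, rates, cfg)

    def test_order_independent(self):
        sps = [Species(t) for t in _POOL[:8]]
        a = _signatures(enumerate_reactions(sps))
        b = _signatures(enumerate_reactions(list(reversed(sps))))
        assert a == b

    def test_no_reactions_between_inert_duplexes(self):
        inert = [Species(t) for t in [("X", "r"), ("Y", "r"), ("w", "r"),
                                      ("p", "q"), ("k", "z")]]
        assert enumerate_reactions(inert) == []

    def test_rule_switches(self):
        cfg = RuleConfig(read_caps_start=False)
        rxns = enumerate_reactions([Species(("k", "s")), Species(("r",))], cfg=cfg)
        assert rxns == []
        cfg = RuleConfig(disabled_rules=frozenset({"R1"}))
        rxns = enumerate_reactions([Species(("k", "s")), Species(("p",))], cfg=cfg)
        assert rxns == []

    def test_tethered_partner_yields_tethered_product(self):
        rxns = enumerate_reactions([Species(("k", "s")), Species(("p", "w"))])
        (join,) = [
            r for r in rxns
            if r.rule_id == "R1" and Species(("k", "s")) in r.reactants
        ]
        assert join.products[0].tokens == ("k", "s", "p", "w")
        assert join.products[0].tethered


class TestApplyReaction:
    def test_stoichiometry(self):
        rxn = enumerate_reactions([Species(("k", "s")), Species(("p",))])[0]
        counts = {Species(("k", "s")): 5, Species(("p",)): 2}
        apply_reaction(counts, rxn)
        assert counts == {
            Species(("k", "s")): 4,
            Species(("p",)): 1,
            Species(("k", "s", "p")): 1,
        }

    def test_insufficient_reactants(self):
        rxn = enumerate_reactions([Species(("k", "s")), Species(("p",))])[0]
        with pytest.raises(ValueError, match="insufficient"):
            apply_reaction({Species(("k", "s")): 1}, rxn)

    @given(st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_token_conservation_over_random_firing_sequences(self, seed):
        rng = random.Random(seed)
        counts = {
            Species(t): rng.randint(1, 5)
            for t in rng.sample(_POOL, rng.randint(2, 6))
        }

        def token_totals(c):
            tot = Counter()
            for sp, n in c.items():
                for t in sp.tokens:
                    tot[t] += n
            return tot

        before = token_totals(counts)
        for _ in range(10):
            rxns = [
                r
                for r in enumerate_reactions(counts)
                if all(counts.get(sp, 0) >= n
                       for sp, n in Counter(r.reactants).items())
            ]
            if not rxns:
                break
            apply_reaction(counts, rng.choice(rxns))
        assert token_totals(counts) == before
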