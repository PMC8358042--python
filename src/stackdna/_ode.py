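"""Deterministic mass-action backend on a truncated species set.

The reaction network is closed over the currently present species by
repeatedly applying the rule set; joins whose product would exceed
``lmax`` monomers are dropped.  Species within one monomer of the cutoff
(which can no longer accept a push+signal record unit) are *boundary*
species: after integration the token mass they hold is checked against a
tolerance, so silent truncation error cannot pass unnoticed.

Compiled networks are cached on the support set, since staged protocols
and grid searches integrate the same support many times.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import csr_matrix

from .chemistry import RateConstants, Reaction, RuleConfig, Species, pair_reactions

__all__ = ["integrate_ode", "build_closure", "TruncationError"]

_MAX_CLOSURE = 20000


class TruncationError(RuntimeError):
    """Raised when too much mass accumulates at the polymer-length cutoff."""


def build_closure(
    initial: list[Species],
    rates: RateConstants,
    cfg: RuleConfig,
    lmax: int,
) -> tuple[list[Species], list[Reaction], set[Species]]:
    """Species list, reactions, and boundary species reachable from ``initial``."""
    species: list[Species] = []
    seen: set[Species] = set()
    reactions: list[Reaction] = []
    queue = sorted(set(initial), key=lambda s: s.tokens)
    seen.update(queue)
    while queue:
        new = queue.pop(0)
        species.append(new)
        for other in species:  # every unordered pair is visited exactly once
            for rxn in pair_reactions(new, other, rates, cfg):
                if any(len(p) > lmax for p in rxn.products):
                    continue
                reactions.append(rxn)
                for p in rxn.products:
                    if p not in seen:
                        seen.add(p)
                        queue.append(p)
        if len(seen) > _MAX_CLOSURE:
            raise TruncationError(
                f"ODE species closure exceeded {_MAX_CLOSURE} species; "
                f"reduce lmax or the species diversity of the input state"
            )
    boundary = {sp for sp in species if len(sp) >= lmax - 1}
    return species, reactions, boundary


class _CompiledNetwork:
    def __init__(self, species, reactions, boundary):
        self.species = species
        self.index = {sp: i for i, sp in enumerate(species)}
        nrx = len(reactions)
        self.r1 = np.empty(nrx, dtype=np.int64)
        self.r2 = np.empty(nrx, dtype=np.int64)
        self.k = np.empty(nrx)
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(reactions):
            a, b = rxn.reactants
            self.r1[j], self.r2[j] = self.index[a], self.index[b]
            # event rate k[A][B]; self reactions carry the 1/2 combinatorial
            # factor matching the SSA propensity n(n-1)/2
            self.k[j] = rxn.rate_constant * (0.5 if rxn.same_reactants else 1.0)
            delta: dict[int, float] = {}
            for sp in rxn.reactants:
                delta[self.index[sp]] = delta.get(self.index[sp], 0.0) - 1.0
            for sp in rxn.products:
                delta[self.index[sp]] = delta.get(self.index[sp], 0.0) + 1.0
            for i, v in delta.items():
                if v != 0.0:
                    rows.append(i)
                    cols.append(j)
                    vals.append(v)
        self.stoich = csr_matrix(
            (vals, (rows, cols)), shape=(len(species), nrx)
        )
        self.token_mass = np.array([len(sp.tokens) for sp in species], dtype=float)
        self.boundary_mask = np.array([sp in boundary for sp in species])


_network_cache: dict[tuple, _CompiledNetwork] = {}


def _compiled_network(
    present: list[Species], rates: RateConstants, cfg: RuleConfig, lmax: int
) -> _CompiledNetwork:
    key = (
        tuple(sorted(sp.tokens for sp in present)),
        rates,
        cfg,
        lmax,
    )
    net = _network_cache.get(key)
    if net is None:
        net = _CompiledNetwork(*build_closure(present, rates, cfg, lmax))
        if len(_network_cache) >= 256:
            _network_cache.clear()
        _network_cache[key] = net
    return net


def integrate_ode(
    conc: dict[Species, float],
    duration: float,
    rates: RateConstants,
    cfg: RuleConfig,
    lmax: int = 16,
    boundary_tol: float = 1e-3,
    rtol: float = 1e-7,
    atol: float = 1e-14,
) -> dict[Species, float]:
    """Integrate mass-action kinetics for ``duration`` seconds.

    ``conc`` maps species to molar concentration; returns the same form.
    """
    present = [sp for sp, x in conc.items() if x > 0]
    if not present:
        return dict(conc)
    net = _compiled_network(present, rates, cfg, lmax)
    if net.r1.size == 0:
        return dict(conc)
    y0 = np.zeros(len(net.species))
    for sp, x in conc.items():
        if x > 0:
            y0[net.index[sp]] = x
    r1, r2, k, stoich = net.r1, net.r2, net.k, net.stoich

    def rhs(_t, y):
        yc = np.maximum(y, 0.0)
        return stoich @ (k * yc[r1] * yc[r2])

    sol = solve_ivp(rhs, (0.0, duration), y0, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = np.maximum(sol.y[:, -1], 0.0)
    total = float(net.token_mass @ y)
    if total > 0:
        bmass = float((net.token_mass * net.boundary_mask) @ y)
        if bmass > boundary_tol * total:
            raise TruncationError(
                f"boundary species hold {bmass / total:.2%} of token mass "
                f"(> {boundary_tol:.1%}); increase lmax"
            )
    out: dict[Species, float] = {}
    for i, sp in enumerate(net.species):
        if y[i] > 0.0:
            out[sp] = float(y[i])
    return out
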