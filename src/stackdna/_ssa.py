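"""Gillespie Direct SSA with just-in-time reaction enumeration.

The polymer chemistry has an unbounded species space, so reaction channels
are instantiated lazily: a species' channels are enumerated (against the
set of species already seen) the first time its copy number becomes
non-zero.  Channel products are registered but stay dormant until they are
themselves populated, so the network only ever grows one reaction ahead of
the trajectory.

The event loop is a numba kernel using incremental propensity updates and
a Fenwick (binary indexed) tree for O(log C) channel selection.  All
channel state lives in preallocated growable arrays owned by the network,
so handing control back to Python when a firing populates a dormant
species costs O(new channels), not O(network).  Randomness comes from a
PCG32 stream seeded per run, so trajectories are bit-reproducible for a
given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .chemistry import (
    RateConstants,
    RuleConfig,
    Species,
    _displacement,
    _join,
    _H_ALPHA,
    _H_BETA,
    _H_LINK,
    _T_ALPHA,
    _T_BETA,
    _T_LINK,
)

AVOGADRO = 6.02214076e23

_STATUS_DONE = 0
_STATUS_PENDING = 1


@njit(cache=True, inline="always")
def _pcg32(rng):
    old = rng[0]
    rng[0] = old * np.uint64(6364136223846793005) + (rng[1] | np.uint64(1))
    xorshifted = np.uint32(((old >> np.uint64(18)) ^ old) >> np.uint64(27))
    rot = np.uint64(old >> np.uint64(59))
    out = np.uint32(
        (xorshifted >> np.uint32(rot))
        | (xorshifted << (np.uint32(64 - rot) & np.uint32(31)))
    )
    return (np.float64(out) + 0.5) * (1.0 / 4294967296.0)


@njit(cache=True, inline="always")
def _propensity(j, counts, r1, r2, same, cprop):
    n1 = counts[r1[j]]
    if same[j]:
        return cprop[j] * n1 * (n1 - 1) * 0.5
    return cprop[j] * n1 * counts[r2[j]]


@njit(cache=True)
def _fenwick_build(tree, a, nchan):
    tree[:] = 0.0
    n = tree.shape[0] - 1
    for i in range(1, nchan + 1):
        tree[i] += a[i - 1]
        j = i + (i & (-i))
        if j <= n:
            tree[j] += tree[i]


@njit(cache=True, inline="always")
def _fenwick_add(tree, i, delta):
    n = tree.shape[0] - 1
    while i <= n:
        tree[i] += delta
        i += i & (-i)


@njit(cache=True)
def _fenwick_total(tree):
    n = tree.shape[0] - 1
    s = 0.0
    i = n
    while i > 0:
        s += tree[i]
        i -= i & (-i)
    return s


@njit(cache=True, inline="always")
def _fenwick_find(tree, x):
    """Largest prefix with cumulative sum < x; returns its 0-based end."""
    n = tree.shape[0] - 1
    idx = 0
    bitmask = 1
    while (bitmask << 1) <= n:
        bitmask <<= 1
    while bitmask:
        nxt = idx + bitmask
        if nxt <= n and tree[nxt] < x:
            x -= tree[nxt]
            idx = nxt
        bitmask >>= 1
    return idx


@njit(cache=True)
def _sync_new_channels(tree, a, counts, r1, r2, same, cprop, j0, j1):
    """Compute propensities of freshly appended channels and insert them."""
    for j in range(j0, j1):
        a[j] = _propensity(j, counts, r1, r2, same, cprop)
        if a[j] != 0.0:
            _fenwick_add(tree, j + 1, a[j])


@njit(cache=True)
def _ssa_kernel(
    counts, active, t0, t_end, r1, r2, p1, p2, same, cprop,
    adj_head, adj_next, a, tree, nchan, rng,
):
    total = _fenwick_total(tree)
    t = t0
    changed = np.empty(4, dtype=np.int64)
    events = 0
    while True:
        if total <= 1e-300:
            return _STATUS_DONE, t_end, np.int64(-1)
        dt = -np.log(_pcg32(rng)) / total
        if t + dt >= t_end:
            return _STATUS_DONE, t_end, np.int64(-1)
        t = t + dt
        j = _fenwick_find(tree, _pcg32(rng) * total)
        if j >= nchan:
            j = nchan - 1
        i1 = r1[j]
        i2 = r2[j]
        counts[i1] -= 1
        counts[i2] -= 1
        changed[0] = i1
        changed[1] = i2
        nch = 2
        pending = np.int64(-1)
        k1 = p1[j]
        counts[k1] += 1
        if active[k1] == 0:
            pending = k1
        changed[nch] = k1
        nch += 1
        k2 = p2[j]
        if k2 >= 0:
            counts[k2] += 1
            if active[k2] == 0 and pending < 0:
                pending = k2
            changed[nch] = k2
            nch += 1
        for c in range(nch):
            s = changed[c]
            ptr = adj_head[s]
            while ptr >= 0:
                ci = ptr >> 1
                new = _propensity(ci, counts, r1, r2, same, cprop)
                old = a[ci]
                if new != old:
                    _fenwick_add(tree, ci + 1, new - old)
                    total += new - old
                    a[ci] = new
                ptr = adj_next[ptr]
        if pending >= 0:
            return _STATUS_PENDING, t, pending
        events += 1
        if events & 0xFFFF == 0:
            total = _fenwick_total(tree)  # resync against float drift


class ReactionNetwork:
    """Growable reaction network over the species seen so far in a run."""

    def __init__(self, rates: RateConstants, cfg: RuleConfig, volume_l: float):
        self.rates = rates
        self.cfg = cfg
        self.inv_vna = 1.0 / (volume_l * AVOGADRO)
        self.species: list[Species] = []
        self.index: dict[Species, int] = {}
        scap, ccap = 256, 1024
        self.counts = np.zeros(scap, dtype=np.int64)
        self.active = np.zeros(scap, dtype=np.uint8)
        self.adj_head = np.full(scap, -1, dtype=np.int64)
        self.nchan = 0
        self._synced = 0  # channels already inserted into the Fenwick tree
        self.r1 = np.zeros(ccap, dtype=np.int64)
        self.r2 = np.zeros(ccap, dtype=np.int64)
        self.p1 = np.zeros(ccap, dtype=np.int64)
        self.p2 = np.zeros(ccap, dtype=np.int64)
        self.same = np.zeros(ccap, dtype=np.uint8)
        self.cprop = np.zeros(ccap, dtype=np.float64)
        self.a = np.zeros(ccap, dtype=np.float64)
        self.adj_next = np.full(2 * ccap, -1, dtype=np.int64)
        self.tree = np.zeros(ccap + 1, dtype=np.float64)
        self.rule: list[str] = []
        # buckets of ACTIVE species indices
        self._by_tail = {_T_ALPHA: [], _T_BETA: [], _T_LINK: []}
        self._by_head = {_H_ALPHA: [], _H_BETA: [], _H_LINK: []}
        self._tethered_active: list[int] = []
        self._displacers: dict[str, int] = {}

    # -- storage growth -----------------------------------------------------
    def _grow_species(self) -> None:
        scap = 2 * self.counts.shape[0]
        for name in ("counts", "active"):
            arr = getattr(self, name)
            new = np.zeros(scap, dtype=arr.dtype)
            new[: arr.shape[0]] = arr
            setattr(self, name, new)
        new = np.full(scap, -1, dtype=np.int64)
        new[: self.adj_head.shape[0]] = self.adj_head
        self.adj_head = new

    def _grow_channels(self) -> None:
        ccap = 2 * self.r1.shape[0]
        for name in ("r1", "r2", "p1", "p2", "same", "cprop", "a"):
            arr = getattr(self, name)
            new = np.zeros(ccap, dtype=arr.dtype)
            new[: arr.shape[0]] = arr
            setattr(self, name, new)
        new = np.full(2 * ccap, -1, dtype=np.int64)
        new[: self.adj_next.shape[0]] = self.adj_next
        self.adj_next = new
        # the Fenwick tree cannot grow in place: rebuild at the new capacity
        self.tree = np.zeros(ccap + 1, dtype=np.float64)
        _fenwick_build(self.tree, self.a, self._synced)

    # -- species / channel management ---------------------------------------
    def ensure_species(self, sp: Species) -> int:
        idx = self.index.get(sp)
        if idx is not None:
            return idx
        idx = len(self.species)
        self.species.append(sp)
        self.index[sp] = idx
        if idx >= self.counts.shape[0]:
            self._grow_species()
        return idx

    def _add_channel(self, rxn, ia: int, ib: int) -> None:
        j = self.nchan
        if j >= self.r1.shape[0]:
            self._grow_channels()
        self.r1[j] = ia
        self.r2[j] = ib
        prods = [self.ensure_species(p) for p in rxn.products]
        self.p1[j] = prods[0]
        self.p2[j] = prods[1] if len(prods) > 1 else -1
        self.same[j] = ia == ib
        self.cprop[j] = rxn.rate_constant * self.inv_vna
        self.rule.append(rxn.rule_id)
        self.adj_next[2 * j] = self.adj_head[ia]
        self.adj_head[ia] = 2 * j
        if ib != ia:
            self.adj_next[2 * j + 1] = self.adj_head[ib]
            self.adj_head[ib] = 2 * j + 1
        self.nchan = j + 1

    def activate(self, idx: int) -> None:
        if self.active[idx]:
            return
        self.active[idx] = 1
        sp = self.species[idx]
        rates, cfg = self.rates, self.cfg
        # joins with sp as the growing (tail) partner
        head_cls = {_T_ALPHA: _H_ALPHA, _T_BETA: _H_BETA, _T_LINK: _H_LINK}.get(
            sp.tail_class
        )
        if head_cls is not None:
            for ib in list(self._by_head[head_cls]):
                rxn = _join(sp, self.species[ib], rates, cfg)
                if rxn is not None:
                    self._add_channel(rxn, idx, ib)
        # joins with sp as the joining (head) partner; sp enters the buckets
        # only afterwards so the self pair is created exactly once, below
        if sp.head_class in self._by_head:
            tail_cls = {_H_ALPHA: _T_ALPHA, _H_BETA: _T_BETA, _H_LINK: _T_LINK}[
                sp.head_class
            ]
            for ia in self._by_tail[tail_cls]:
                rxn = _join(self.species[ia], sp, rates, cfg)
                if rxn is not None:
                    self._add_channel(rxn, ia, idx)
            if tail_cls == sp.tail_class:
                rxn = _join(sp, sp, rates, cfg)
                if rxn is not None:
                    self._add_channel(rxn, idx, idx)
            self._by_head[sp.head_class].append(idx)
        if sp.tail_class in self._by_tail:
            self._by_tail[sp.tail_class].append(idx)
        # displacement channels
        tok = sp.tokens[0] if len(sp.tokens) == 1 else None
        if tok in ("r", "q", "z"):
            if tok == "r":
                targets = list(self._by_tail[_T_ALPHA])
            elif tok == "q":
                targets = list(self._by_tail[_T_BETA])
            else:
                targets = list(self._tethered_active)
            for it in targets:
                if it != idx:
                    rxn = _displacement(sp, self.species[it], rates, cfg)
                    if rxn is not None:
                        self._add_channel(rxn, idx, it)
            self._displacers[tok] = idx
        else:
            for dtok in ("r", "q", "z"):
                di = self._displacers.get(dtok)
                if di is not None:
                    rxn = _displacement(self.species[di], sp, rates, cfg)
                    if rxn is not None:
                        self._add_channel(rxn, di, idx)
        if sp.tethered:
            self._tethered_active.append(idx)

    # -- simulation ---------------------------------------------------------
    def set_counts(self, counts: dict[Species, int]) -> None:
        for sp, n in sorted(counts.items(), key=lambda kv: kv[0].tokens):
            idx = self.ensure_species(sp)
            self.counts[idx] = n

    def run(self, t0: float, duration: float, rng_state: np.ndarray) -> float:
        """Advance the jump process by ``duration`` seconds; returns end time."""
        t_end = t0 + duration
        t = t0
        while True:
            nsp = len(self.species)
            dormant = np.nonzero(
                (self.counts[:nsp] > 0) & (self.active[:nsp] == 0)
            )[0]
            for idx in dormant:
                self.activate(int(idx))
            if self.nchan > self._synced:
                _sync_new_channels(
                    self.tree, self.a, self.counts, self.r1, self.r2,
                    self.same, self.cprop, self._synced, self.nchan,
                )
                self._synced = self.nchan
            if self.nchan == 0:
                return t_end
            status, t, pending = _ssa_kernel(
                self.counts, self.active, t, t_end,
                self.r1, self.r2, self.p1, self.p2, self.same, self.cprop,
                self.adj_head, self.adj_next, self.a, self.tree,
                self.nchan, rng_state,
            )
            if status == _STATUS_DONE:
                return t_end

    def counts_dict(self) -> dict[Species, int]:
        out = {}
        for idx, sp in enumerate(self.species):
            n = int(self.counts[idx])
            if n > 0:
                out[sp] = n
        return out

    def reactions_frame(self):
        """Channel table (reactants, products, rate, rule) for export."""
        import pandas as pd

        rows = []
        for j in range(self.nchan):
            reactants = [self.species[self.r1[j]].name]
            if not self.same[j] or True:
                reactants.append(self.species[self.r2[j]].name)
            products = [self.species[self.p1[j]].name]
            if self.p2[j] >= 0:
                products.append(self.species[self.p2[j]].name)
            rows.append(
                {
                    "reactants": " + ".join(reactants),
                    "products": " + ".join(products),
                    "rate_constant": self.cprop[j] / self.inv_vna,
                    "rule_id": self.rule[j],
                }
            )
        return pd.DataFrame(rows)
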