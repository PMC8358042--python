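"""Shared fixtures: monomer table and a memoised benchmark-run cache.

Several tests evaluate pop limits of the same 40-operation benchmark
sequences under the same washing procedures; the session-scoped cache
runs each (sequence, wash, replicate) condition once.  Replicate k uses
arrangement seed k (a fresh X/Y labelling) and an independent trajectory
seed, so averages over replicates are arrangement averages.
"""

from __future__ import annotations

import numpy as np
import pytest

import stackdna as sd
from stackdna.engine import WashParams


def make_benchmark_sequence(name: str, arrangement_seed: int):
    if name == "seqR":
        return sd.make_seqR(seed=arrangement_seed)
    return sd.make_seqN(int(name.removeprefix("seq")), seed=arrangement_seed)


@pytest.fixture(scope="session")
def monomers():
    return sd.define_monomers()


_POP_CACHE: dict[tuple, int] = {}


@pytest.fixture(scope="session")
def benchmark_pop_limit():
    """pop limit of (sequence name, WashParams, replicate index), memoised."""

    def run(seq_name: str, wash: WashParams, replicate: int) -> int:
        key = (seq_name, wash.mu, wash.phi0, replicate)
        if key not in _POP_CACHE:
            opseq = make_benchmark_sequence(seq_name, replicate)
            outcome = sd.simulate_sequence(opseq, wash, seed=1000 + replicate)
            _POP_CACHE[key] = outcome.pop_limit
        return _POP_CACHE[key]

    return run
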