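"""Stack-level operation sequences and their compilation to stage lists.

An operation sequence is a string of record and pop operations applied to
the stack, e.g. ``REC(X) REC(Y) POP POP``.  Each record compiles to a
push stage followed by a signal stage; each pop compiles to a read stage
(with a supernatant readout taken before its wash) followed by a pop
stage.  The benchmark sequences each contain 20 records and 20 pops:
``seqN`` repeats blocks of N records then N pops (N in 1, 5, 10, 20) and
``seqR`` arranges the 40 operations randomly subject to prefix validity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .engine import ProtocolStage, STANDARD_CONC, STANDARD_WAIT

__all__ = [
    "Operation",
    "OperationSequence",
    "StageDefaults",
    "rec",
    "pop",
    "parse_ops",
    "make_seqN",
    "make_seqR",
    "ideal_pops",
    "compile_operations",
]

REC = "rec"
POP = "pop"
_SEQ_RECORDS = 20  # records (and pops) per benchmark sequence


@dataclass(frozen=True)
class Operation:
    kind: str  # "rec" | "pop"
    signal: str | None = None  # X, Y or w for records

    def __post_init__(self):
        if self.kind not in (REC, POP):
            raise ValueError(f"unknown operation kind {self.kind!r}")
        if self.kind == REC and self.signal not in ("X", "Y", "w"):
            raise ValueError(f"record needs a signal in X/Y/w, got {self.signal!r}")
        if self.kind == POP and self.signal is not None:
            raise ValueError("pop takes no signal")


def rec(signal: str) -> Operation:
    return Operation(REC, signal)


def pop() -> Operation:
    return Operation(POP)


@dataclass(frozen=True)
class OperationSequence:
    ops: tuple[Operation, ...]
    name: str = ""

    def __post_init__(self):
        depth = 0
        for op in self.ops:
            depth += 1 if op.kind == REC else -1
            if depth < 0:
                raise ValueError(
                    f"invalid sequence {self.name or self.token_string()!r}: "
                    "a pop precedes its record"
                )

    @property
    def n_records(self) -> int:
        return sum(1 for op in self.ops if op.kind == REC)

    @property
    def n_pops(self) -> int:
        return sum(1 for op in self.ops if op.kind == POP)

    def token_string(self) -> str:
        """Plain-text form: record by signal letter, pop as 'q'."""
        return " ".join(op.signal if op.kind == REC else "q" for op in self.ops)


def parse_ops(text: str, name: str = "") -> OperationSequence:
    """Parse 'X Y q q' style token strings (q = pop; X/Y/w = record)."""
    ops = []
    for tok in text.replace(",", " ").split():
        if tok == "q":
            ops.append(pop())
        elif tok in ("X", "Y", "w"):
            ops.append(rec(tok))
        else:
            raise ValueError(f"unknown operation token {tok!r}")
    return OperationSequence(tuple(ops), name=name or text)


def _assign_signals(n: int, rng: np.random.Generator, signals=("X", "Y")) -> list[str]:
    """Balanced label list (|#X - #Y| <= 1), order shuffled by ``rng``."""
    labels = [signals[i % len(signals)] for i in range(n)]
    rng.shuffle(labels)
    return labels


def make_seqN(N: int, seed: int = 0, signals=("X", "Y")) -> OperationSequence:
    """Periodic sequence: blocks of N records then N pops, 20 records total."""
    if N not in (1, 2, 4, 5, 10, 20):
        raise ValueError(f"N must divide 20 (one of 1, 2, 4, 5, 10, 20), got {N}")
    rng = np.random.default_rng(seed)
    labels = iter(_assign_signals(_SEQ_RECORDS, rng, signals))
    ops: list[Operation] = []
    for _ in range(_SEQ_RECORDS // N):
        ops.extend(rec(next(labels)) for _ in range(N))
        ops.extend(pop() for _ in range(N))
    return OperationSequence(tuple(ops), name=f"seq{N}")


def make_seqR(seed: int = 0, signals=("X", "Y")) -> OperationSequence:
    """Random arrangement of 20 records and 20 pops, prefix-valid.

    Rejection-sampled uniform shuffle: resampled until no prefix has more
    pops than records.
    """
    rng = np.random.default_rng(seed)
    kinds = [REC] * _SEQ_RECORDS + [POP] * _SEQ_RECORDS
    while True:
        rng.shuffle(kinds)
        depth = 0
        for kind in kinds:
            depth += 1 if kind == REC else -1
            if depth < 0:
                break
        else:
            break
    labels = iter(_assign_signals(_SEQ_RECORDS, rng, signals))
    ops = tuple(rec(next(labels)) if k == REC else pop() for k in kinds)
    return OperationSequence(ops, name="seqR")


def ideal_pops(opseq: OperationSequence) -> list[str]:
    """Signals an ideal (in silico) LIFO stack would emit at each pop."""
    stack: list[str] = []
    out: list[str] = []
    for op in opseq.ops:
        if op.kind == REC:
            stack.append(op.signal)
        else:
            out.append(stack.pop())
    return out


@dataclass(frozen=True)
class StageDefaults:
    """Standard stage conditions: gamma = 300 nM strands, 30 min waits.

    ``read_concentration`` overrides the read-strand concentration alone
    (the optimised experimental protocol used 50 nM read).
    """

    gamma: float = STANDARD_CONC
    wait: float = STANDARD_WAIT
    read_concentration: float | None = None
    wash_after: bool = True

    def conc_for(self, token: str) -> float:
        if token == "r" and self.read_concentration is not None:
            return self.read_concentration
        return self.gamma


def compile_operations(
    opseq: OperationSequence, defaults: StageDefaults | None = None
) -> tuple[list[ProtocolStage], list[str]]:
    """Compile stack operations to chemistry stages.

    Setup is a single start stage (the linker is already bead-bound in the
    initial state).  REC(sigma) -> push stage then signal stage;
    POP -> read stage (readout before its wash) then pop stage.  Returns
    the stage list and the expected pop signals in operation order.
    """
    d = defaults or StageDefaults()

    def stage(token: str, **kw) -> ProtocolStage:
        return ProtocolStage(
            strand=token,
            concentration=d.conc_for(token),
            wait=d.wait,
            wash_after=d.wash_after,
            **kw,
        )

    expected = ideal_pops(opseq)
    stages: list[ProtocolStage] = [stage("s")]
    pop_i = 0
    for op in opseq.ops:
        if op.kind == REC:
            stages.append(stage("p"))
            stages.append(stage(op.signal))
        else:
            stages.append(
                stage("r", readout_before_wash=True, expected_pop=expected[pop_i])
            )
            stages.append(stage("q"))
            pop_i += 1
    return stages, expected
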