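"""Staged protocol execution: add strands, react, wash.

The in vitro protocol is a loop of (strand addition, timed incubation,
mechanical wash).  Washing is modelled with two parameters: ``mu``, the
fraction of beads lost per wash, and ``phi0``, the fraction of supernatant
species non-specifically transferred through a wash at the initial bead
mass.  The transfer fraction decays with bead mass over successive
washes, phi_n = phi0 * (1 - mu)^n.

Two kinetics backends execute the incubation intervals:

``ssa``
    Exact Gillespie Direct simulation of the reaction jump process in a
    fixed volume (default 0.15 pl, where 300 nM is ~2.7e4 copies), with
    reaction channels enumerated just in time.
``ode``
    Deterministic mass-action rate equations on a species set truncated
    at ``lmax`` monomers per complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import chemistry
from .chemistry import RateConstants, RuleConfig, Species
from ._ssa import AVOGADRO, ReactionNetwork
from ._ode import integrate_ode, TruncationError

__all__ = [
    "AVOGADRO",
    "SystemState",
    "WashParams",
    "ProtocolStage",
    "PipettingNoise",
    "ReadoutSnapshot",
    "StageSnapshot",
    "ProtocolResult",
    "init_state",
    "add_strand",
    "advance",
    "wash",
    "run_protocol",
    "copies_from_concentration",
    "TruncationError",
]

DEFAULT_VOLUME_L = 0.15e-12  # 0.15 pl
STANDARD_CONC = 300e-9  # gamma, M
LINKER_CONC = 200e-9  # linker/releaser concentration, M
STANDARD_WAIT = 30 * 60.0  # t_w, s


def copies_from_concentration(conc: float, volume_l: float) -> int:
    """Molar concentration -> integer copy number (round half to even)."""
    return int(round(conc * volume_l * AVOGADRO))


@dataclass(frozen=True)
class WashParams:
    """Bead-loss fraction per wash and initial supernatant carry-over."""

    mu: float
    phi0: float

    PRESETS = {"W1": (0.1, 0.33), "W2": (0.05, 0.15), "W3": (0.02, 0.05)}

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        if not 0.0 <= self.phi0 <= 1.0:
            raise ValueError(f"phi0 must be in [0, 1], got {self.phi0}")

    @classmethod
    def preset(cls, name: str) -> "WashParams":
        try:
            mu, phi0 = cls.PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown washing preset {name!r}; choose from {sorted(cls.PRESETS)}"
            ) from None
        return cls(mu, phi0)

    def phi(self, wash_index: int) -> float:
        """Supernatant transfer fraction for the wash at index ``wash_index``."""
        return min(1.0, self.phi0 * (1.0 - self.mu) ** wash_index)


PERFECT_WASH = WashParams(0.0, 0.0)


@dataclass(frozen=True)
class PipettingNoise:
    """Uniform pipetting error: drawn conc ~ U(c - eta, c + eta), floored at 0."""

    eta: float = 0.0

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be non-negative")


@dataclass(frozen=True)
class ProtocolStage:
    """One add/wait/wash step compiled from a stack operation."""

    strand: str | None
    concentration: float = STANDARD_CONC
    wait: float = STANDARD_WAIT
    wash_after: bool = True
    readout_before_wash: bool = False
    expected_pop: str | None = None

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("stage concentration must be >= 0")
        if self.wait < 0:
            raise ValueError("stage wait must be >= 0")


@dataclass
class SystemState:
    """Species populations plus bead/wash bookkeeping.

    ``counts`` maps species to integer copy numbers under the SSA backend
    and to molar concentrations under the ODE backend.
    """

    counts: dict[Species, float]
    volume_l: float = DEFAULT_VOLUME_L
    bead_fraction: float = 1.0
    wash_index: int = 0
    time: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def concentration(self, sp: Species, backend: str = "ssa") -> float:
        """Concentration of ``sp`` in M."""
        n = self.counts.get(sp, 0)
        if backend == "ode":
            return float(n)
        return n / (self.volume_l * AVOGADRO)

    def supernatant_nM(self, backend: str = "ssa") -> dict[str, float]:
        """Supernatant (untethered) species concentrations in nM."""
        out = {}
        for sp, n in self.counts.items():
            if not sp.tethered:
                out[sp.name] = self.concentration(sp, backend) * 1e9
        return out

    def tethered_nM(self, backend: str = "ssa") -> dict[str, float]:
        out = {}
        for sp, n in self.counts.items():
            if sp.tethered:
                out[sp.name] = self.concentration(sp, backend) * 1e9
        return out


def init_state(
    volume_l: float = DEFAULT_VOLUME_L,
    linker_concentration: float = LINKER_CONC,
    seed: int | np.random.SeedSequence | None = 0,
    backend: str = "ssa",
) -> SystemState:
    """Fresh system: bead-borne linker only, full bead mass, wash count 0."""
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    linker = Species(("k",))
    if backend == "ode":
        counts: dict[Species, float] = {linker: float(linker_concentration)}
    else:
        counts = {linker: copies_from_concentration(linker_concentration, volume_l)}
    return SystemState(
        counts=counts, volume_l=volume_l, rng=np.random.default_rng(seed)
    )


def add_strand(
    state: SystemState,
    token: str,
    concentration: float,
    noise: PipettingNoise | None = None,
    backend: str = "ssa",
) -> float:
    """Add free monomer at (possibly noise-perturbed) concentration.

    Returns the concentration actually delivered (M).
    """
    if token not in chemistry.ALL_TOKENS:
        raise ValueError(f"unknown monomer token: {token!r}")
    conc = concentration
    if noise is not None and noise.eta > 0:
        conc = state.rng.uniform(concentration - noise.eta, concentration + noise.eta)
        conc = max(0.0, conc)
    sp = Species((token,))
    if backend == "ode":
        state.counts[sp] = state.counts.get(sp, 0.0) + conc
    else:
        state.counts[sp] = state.counts.get(sp, 0) + copies_from_concentration(
            conc, state.volume_l
        )
    return conc


def advance(
    state: SystemState,
    duration: float,
    backend: str = "ssa",
    rates: RateConstants | None = None,
    cfg: RuleConfig | None = None,
    lmax: int = 16,
    boundary_tol: float = 1e-3,
) -> SystemState:
    """Run the reaction kinetics for ``duration`` seconds (in place)."""
    if duration < 0:
        raise ValueError("duration must be >= 0")
    rates = rates or RateConstants()
    cfg = cfg or RuleConfig()
    if duration == 0 or not state.counts:
        state.time += duration
        return state
    if backend == "ssa":
        network = ReactionNetwork(rates, cfg, state.volume_l)
        network.set_counts({sp: int(n) for sp, n in state.counts.items()})
        rng_state = state.rng.integers(0, 2**63, size=2, dtype=np.uint64)
        network.run(state.time, duration, rng_state)
        state.counts = network.counts_dict()
    elif backend == "ode":
        state.counts = integrate_ode(
            state.counts, duration, rates, cfg, lmax=lmax, boundary_tol=boundary_tol
        )
    else:
        raise ValueError(f"unknown backend {backend!r}")
    state.time += duration
    return state


def wash(state: SystemState, params: WashParams, backend: str = "ssa") -> SystemState:
    """One mechanical wash: thin beads by mu, supernatant by phi_n.

    Tethered species follow the bead mass (each retained with probability
    1 - mu under the SSA backend; exact multiplication under ODE).
    Supernatant species are retained with the carry-over fraction
    phi_n = phi0 (1 - mu)^n where n counts previous washes.
    """
    keep_bead = 1.0 - params.mu
    keep_sup = params.phi(state.wash_index)
    new_counts: dict[Species, float] = {}
    if backend == "ode":
        for sp, x in state.counts.items():
            x2 = x * (keep_bead if sp.tethered else keep_sup)
            if x2 > 0.0:
                new_counts[sp] = x2
    else:
        for sp, n in sorted(state.counts.items(), key=lambda kv: kv[0].tokens):
            p = keep_bead if sp.tethered else keep_sup
            n2 = int(state.rng.binomial(int(n), p)) if p < 1.0 else int(n)
            if n2 > 0:
                new_counts[sp] = n2
    state.counts = new_counts
    state.bead_fraction *= keep_bead
    state.wash_index += 1
    return state


@dataclass(frozen=True)
class ReadoutSnapshot:
    """Supernatant measurement taken at the end of a read stage, pre-wash."""

    stage_index: int
    expected: str | None
    supernatant_nM: dict[str, float]


@dataclass(frozen=True)
class StageSnapshot:
    stage_index: int
    strand: str | None
    delivered_concentration: float | None
    counts: dict[Species, float]
    bead_fraction: float
    wash_index: int
    time: float


@dataclass
class ProtocolResult:
    state: SystemState
    readouts: list[ReadoutSnapshot]
    trace: list[StageSnapshot] | None


def run_protocol(
    state: SystemState,
    stages: Sequence[ProtocolStage],
    backend: str = "ssa",
    wash_params: WashParams = PERFECT_WASH,
    noise: PipettingNoise | None = None,
    rates: RateConstants | None = None,
    cfg: RuleConfig | None = None,
    record_trace: bool = False,
    lmax: int = 16,
) -> ProtocolResult:
    """Execute stages: add strand -> incubate -> optional readout -> wash."""
    readouts: list[ReadoutSnapshot] = []
    trace: list[StageSnapshot] | None = [] if record_trace else None
    for i, stage in enumerate(stages):
        delivered = None
        if stage.strand is not None:
            delivered = add_strand(
                state, stage.strand, stage.concentration, noise, backend
            )
        advance(state, stage.wait, backend, rates, cfg, lmax=lmax)
        if stage.readout_before_wash:
            readouts.append(
                ReadoutSnapshot(
                    stage_index=i,
                    expected=stage.expected_pop,
                    supernatant_nM=state.supernatant_nM(backend),
                )
            )
        if record_trace:
            trace.append(
                StageSnapshot(
                    stage_index=i,
                    strand=stage.strand,
                    delivered_concentration=delivered,
                    counts=dict(state.counts),
                    bead_fraction=state.bead_fraction,
                    wash_index=state.wash_index,
                    time=state.time,
                )
            )
        if stage.wash_after:
            wash(state, wash_params, backend)
    return ProtocolResult(state=state, readouts=readouts, trace=trace)
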