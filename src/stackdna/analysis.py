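"""Observables and computational experiments on the simulated stack.

The headline statistic is the *pop limit*: the number of consecutive
correct pop operations before the signals popped into supernatant become
indistinguishable (|[Xr] - [Yr]| below 10 nM) or the majority popped
signal is wrong.  This module also predicts gel band patterns from
species populations, scores predicted-vs-observed band orderings, fits
the washing parameters (mu, phi0) by grid search over that score, and
runs the parameter sweeps (washing heatmaps, concentration x wait-time
heatmaps, pipetting-noise curves).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import chemistry, engine, protocol
from .chemistry import MonomerSpec, RateConstants, RuleConfig, Species
from .engine import (
    PipettingNoise,
    ProtocolResult,
    ProtocolStage,
    ReadoutSnapshot,
    SystemState,
    WashParams,
)
from .protocol import OperationSequence, StageDefaults, compile_operations

__all__ = [
    "POP_DISTINGUISH_NM",
    "PopReadout",
    "BandPattern",
    "SweepResult",
    "SimulationOutcome",
    "simulate_sequence",
    "simulate_stages",
    "readouts_from_snapshots",
    "pop_limit",
    "band_pattern",
    "band_order_error",
    "fit_wash_params",
    "FitResult",
    "make_fit_fixture",
    "FitFixture",
    "default_write_lanes",
    "sweep",
    "save_heatmap",
    "noise_onset",
    "WashGrid",
    "ConcWaitGrid",
    "NoiseCurve",
]

#: Detection/indistinguishability threshold on popped-signal duplexes (nM).
POP_DISTINGUISH_NM = 10.0


# ---------------------------------------------------------------------------
# Pop readouts and the pop limit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopReadout:
    """Supernatant [Xr]/[Yr] (and [wr]) at the end of one read stage, pre-wash."""

    expected: str
    xr_nM: float = 0.0
    yr_nM: float = 0.0
    wr_nM: float = 0.0

    def __post_init__(self):
        if min(self.xr_nM, self.yr_nM, self.wr_nM) < 0:
            raise ValueError("readout concentrations must be non-negative")


def readouts_from_snapshots(snapshots: Iterable[ReadoutSnapshot]) -> list[PopReadout]:
    out = []
    for snap in snapshots:
        c = snap.supernatant_nM
        out.append(
            PopReadout(
                expected=snap.expected,
                xr_nM=c.get("X.r", 0.0),
                yr_nM=c.get("Y.r", 0.0),
                wr_nM=c.get("w.r", 0.0),
            )
        )
    return out


def pop_limit(readouts: Sequence[PopReadout]) -> int:
    """Consecutive correct pops before the first indistinguishable/wrong one.

    Two-signal rule: a pop is correct iff |[Xr] - [Yr]| exceeds 10 nM and
    the majority duplex matches the expected signal (a difference of
    exactly 10 nM counts as indistinguishable).  Write-only runs use the
    10 nM detection floor on [wr] instead.
    """
    n = 0
    for ro in readouts:
        if ro.expected == "w":
            ok = ro.wr_nM >= POP_DISTINGUISH_NM
        else:
            diff = ro.xr_nM - ro.yr_nM
            majority = "X" if diff > 0 else "Y"
            ok = abs(diff) > POP_DISTINGUISH_NM and majority == ro.expected
        if not ok:
            break
        n += 1
    return n


# ---------------------------------------------------------------------------
# One full protocol run
# ---------------------------------------------------------------------------


@dataclass
class SimulationOutcome:
    opseq: OperationSequence | None
    readouts: list[PopReadout]
    pop_limit: int
    state: SystemState
    result: ProtocolResult


def simulate_stages(
    stages: Sequence[ProtocolStage],
    wash: WashParams,
    seed: int | np.random.SeedSequence | None = 0,
    backend: str = "ssa",
    eta: float = 0.0,
    rates: RateConstants | None = None,
    cfg: RuleConfig | None = None,
    volume_l: float = engine.DEFAULT_VOLUME_L,
    linker_concentration: float = engine.LINKER_CONC,
    record_trace: bool = False,
    lmax: int = 16,
) -> SimulationOutcome:
    """Run an explicit stage list from a fresh bead-bound-linker state."""
    state = engine.init_state(volume_l, linker_concentration, seed, backend)
    noise = PipettingNoise(eta) if eta > 0 else None
    result = engine.run_protocol(
        state,
        stages,
        backend=backend,
        wash_params=wash,
        noise=noise,
        rates=rates,
        cfg=cfg,
        record_trace=record_trace,
        lmax=lmax,
    )
    readouts = readouts_from_snapshots(result.readouts)
    return SimulationOutcome(
        opseq=None,
        readouts=readouts,
        pop_limit=pop_limit(readouts),
        state=state,
        result=result,
    )


def simulate_sequence(
    opseq: OperationSequence,
    wash: WashParams,
    seed: int | np.random.SeedSequence | None = 0,
    backend: str = "ssa",
    defaults: StageDefaults | None = None,
    **kwargs,
) -> SimulationOutcome:
    """Compile and run a stack operation sequence; see ``simulate_stages``."""
    stages, _ = compile_operations(opseq, defaults)
    outcome = simulate_stages(stages, wash, seed=seed, backend=backend, **kwargs)
    outcome.opseq = opseq
    return outcome


# ---------------------------------------------------------------------------
# Gel band patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandPattern:
    """Ranked gel bands: (apparent size in nt, stain intensity).

    Intensity of a size bin is the nt-weighted concentration (nM * nt),
    approximating intercalating-stain signal; ``bands`` is sorted by
    decreasing intensity.
    """

    bands: tuple[tuple[int, float], ...]

    @property
    def sizes_by_intensity(self) -> list[int]:
        return [size for size, _ in self.bands]

    def __len__(self) -> int:
        return len(self.bands)


def band_pattern(
    state: SystemState,
    monomers: Mapping[str, MonomerSpec] | None = None,
    compartment: str = "tethered",
    backend: str = "ssa",
    release_linker: bool = True,
    detection_threshold_nM_kb: float = 1.0,
) -> BandPattern:
    """Predict the banding pattern of one gel lane from a system state.

    ``compartment`` selects tethered (bead) species, supernatant species,
    or ``all``.  With ``release_linker`` the tethered complexes are viewed
    as after releaser treatment: the linker is stripped before sizing and
    linker-only species (k, kz) are dropped, mirroring how bead samples
    are actually loaded on a gel.
    """
    monomers = monomers or chemistry.define_monomers()
    if compartment not in ("tethered", "supernatant", "all"):
        raise ValueError(f"unknown compartment {compartment!r}")
    intensity: dict[int, float] = {}
    for sp, _n in state.counts.items():
        if compartment == "tethered" and not sp.tethered:
            continue
        if compartment == "supernatant" and sp.tethered:
            continue
        tokens = sp.tokens
        if sp.tethered and release_linker:
            if "z" in tokens:
                continue
            tokens = tokens[1:]
            if not tokens:
                continue
        conc_nM = state.concentration(sp, backend) * 1e9
        nt = chemistry.total_nucleotides(tokens, monomers)
        intensity[nt] = intensity.get(nt, 0.0) + conc_nM * nt
    threshold = detection_threshold_nM_kb * 1000.0  # nM * nt
    bands = [(size, inten) for size, inten in intensity.items() if inten >= threshold]
    bands.sort(key=lambda b: (-b[1], b[0]))
    return BandPattern(tuple(bands))


def band_order_error(
    predicted: BandPattern | Sequence[int], observed: Sequence[int]
) -> float:
    """Normalised pairwise rank disagreement between band orderings.

    Both inputs are band sizes ranked by decreasing intensity.  Over the
    union of bands, every unordered pair is scored: 1 if the pair's
    relative order differs, or if either band is missing from one of the
    orderings; 0 otherwise.  The result is the disagreeing fraction,
    0 for identical orderings, 1 for fully reversed ones.
    """
    if isinstance(predicted, BandPattern):
        pred = predicted.sizes_by_intensity
    else:
        pred = list(predicted)
    obs = list(observed)
    if not obs:
        raise ValueError("observed band list is empty")
    if len(set(pred)) != len(pred) or len(set(obs)) != len(obs):
        raise ValueError("band orderings must not repeat sizes")
    union = sorted(set(pred) | set(obs))
    if len(union) < 2:
        return 0.0
    prank = {size: i for i, size in enumerate(pred)}
    orank = {size: i for i, size in enumerate(obs)}
    bad = 0
    total = 0
    for a, b in itertools.combinations(union, 2):
        total += 1
        if a not in prank or b not in prank or a not in orank or b not in orank:
            bad += 1
            continue
        if (prank[a] - prank[b]) * (orank[a] - orank[b]) < 0:
            bad += 1
    return bad / total


# ---------------------------------------------------------------------------
# Washing-parameter calibration
# ---------------------------------------------------------------------------


def default_write_lanes(defaults: StageDefaults | None = None):
    """Seventeen write-signal lane protocols analogous to the PAGE series.

    Lanes are stage-boundary prefixes of 1-, 2- and 3-record record/pop
    runs with the linear signal w: the full 3-record/3-pop run contributes
    a lane per stage (13), and the 1- and 2-record runs contribute their
    read and pop lanes (2 each).
    """
    d = defaults or StageDefaults()

    def stages_for(tokens: list[str], readout_last=False) -> list[ProtocolStage]:
        out = []
        for i, tok in enumerate(tokens):
            out.append(
                ProtocolStage(
                    strand=tok,
                    concentration=d.conc_for(tok),
                    wait=d.wait,
                    wash_after=d.wash_after,
                )
            )
        return out

    lanes: list[tuple[str, list[ProtocolStage]]] = []
    full3 = ["s", "p", "w", "p", "w", "p", "w", "r", "q", "r", "q", "r", "q"]
    for i in range(1, len(full3) + 1):
        lanes.append((f"rec3:{'.'.join(full3[:i])}", stages_for(full3[:i])))
    rec1 = ["s", "p", "w"]
    for extra in (["r"], ["r", "q"]):
        toks = rec1 + extra
        lanes.append((f"rec1:{'.'.join(toks)}", stages_for(toks)))
    rec2 = ["s", "p", "w", "p", "w"]
    for extra in (["r"], ["r", "q"]):
        toks = rec2 + extra
        lanes.append((f"rec2:{'.'.join(toks)}", stages_for(toks)))
    return lanes


@dataclass
class FitFixture:
    """Synthetic observed gel lanes for calibration testing."""

    mu: float
    phi0: float
    lanes: list[tuple[list[ProtocolStage], list[int]]]
    degenerate: bool = False  # True when lanes came out empty (e.g. mu = 1)


def _simulate_lane_bands(
    stages: Sequence[ProtocolStage],
    wash: WashParams,
    rates: RateConstants | None,
    cfg: RuleConfig | None,
    lmax: int = 24,
    **band_kwargs,
) -> BandPattern:
    outcome = simulate_stages(
        stages, wash, seed=0, backend="ode", rates=rates, cfg=cfg, lmax=lmax
    )
    return band_pattern(outcome.state, backend="ode", **band_kwargs)


def make_fit_fixture(
    mu: float,
    phi0: float,
    stage_lists: Sequence[Sequence[ProtocolStage]] | None = None,
    seed: int = 0,
    p_swap: float = 0.0,
    rates: RateConstants | None = None,
    cfg: RuleConfig | None = None,
    lmax: int = 24,
) -> FitFixture:
    """Simulate lanes at known (mu, phi0) and emit observed band rankings.

    ``p_swap`` perturbs each ranking by swapping adjacent ranks with the
    given probability, emulating densitometry ambiguity.
    """
    wash = WashParams(mu, phi0)
    if stage_lists is None:
        stage_lists = [stages for _name, stages in default_write_lanes()]
    rng = np.random.default_rng(seed)
    lanes = []
    degenerate = False
    for stages in stage_lists:
        pattern = _simulate_lane_bands(stages, wash, rates, cfg, lmax)
        ranking = pattern.sizes_by_intensity
        if not ranking:
            degenerate = True
        if p_swap > 0 and len(ranking) > 1:
            for i in range(len(ranking) - 1):
                if rng.random() < p_swap:
                    ranking[i], ranking[i + 1] = ranking[i + 1], ranking[i]
        lanes.append((list(stages), ranking))
    return FitFixture(mu=mu, phi0=phi0, lanes=lanes, degenerate=degenerate)


@dataclass
class FitResult:
    mu: float
    phi0: float
    mu_grid: np.ndarray
    phi0_grid: np.ndarray
    error_surface: np.ndarray  # shape (len(mu_grid), len(phi0_grid)); NaN = invalid

    def surface_frame(self) -> pd.DataFrame:
        rows = [
            {"mu": m, "phi0": p, "error": self.error_surface[i, j]}
            for i, m in enumerate(self.mu_grid)
            for j, p in enumerate(self.phi0_grid)
        ]
        return pd.DataFrame(rows)


def fit_wash_params(
    experiments: Sequence[tuple[Sequence[ProtocolStage], Sequence[int]]],
    mu_grid: Sequence[float],
    phi0_grid: Sequence[float],
    rates: RateConstants | None = None,
    cfg: RuleConfig | None = None,
    lmax: int = 24,
) -> FitResult:
    """Grid search (mu, phi0) minimising the mean band-ordering error.

    Every experiment (stage list + observed ranked band sizes) is
    simulated with the deterministic backend at each grid cell; cells
    where any lane fails to simulate or predicts no detectable bands are
    marked invalid (NaN) and excluded from the argmin.
    """
    mu_grid = np.asarray(list(mu_grid), dtype=float)
    phi0_grid = np.asarray(list(phi0_grid), dtype=float)
    surface = np.full((mu_grid.size, phi0_grid.size), np.nan)
    for i, mu in enumerate(mu_grid):
        for j, phi0 in enumerate(phi0_grid):
            wash = WashParams(float(mu), float(phi0))
            errors = []
            try:
                for stages, observed in experiments:
                    pattern = _simulate_lane_bands(stages, wash, rates, cfg, lmax)
                    if not observed:
                        continue
                    errors.append(band_order_error(pattern, observed))
            except (engine.TruncationError, RuntimeError) as exc:
                logging.getLogger(__name__).warning(
                    "fit cell (mu=%.3f, phi0=%.3f) invalid: %s", mu, phi0, exc
                )
                continue
            if errors:
                surface[i, j] = float(np.mean(errors))
    if np.all(np.isnan(surface)):
        raise RuntimeError("no valid cells in the washing-parameter grid")
    best = np.unravel_index(np.nanargmin(surface), surface.shape)
    return FitResult(
        mu=float(mu_grid[best[0]]),
        phi0=float(phi0_grid[best[1]]),
        mu_grid=mu_grid,
        phi0_grid=phi0_grid,
        error_surface=surface,
    )


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WashGrid:
    """Pop limit per (mu, phi0) cell, one simulation per cell."""

    mus: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 0.2, 11), 3))
    phi0s: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 0.6, 13), 3))


@dataclass(frozen=True)
class ConcWaitGrid:
    """Pop limit per (gamma, wait) cell at a fixed washing procedure."""

    gammas: tuple[float, ...] = tuple(np.geomspace(30e-9, 3e-6, 9))
    waits: tuple[float, ...] = tuple(np.geomspace(60.0, 2 * 3600.0, 9))
    wash: WashParams = WashParams(*WashParams.PRESETS["W1"])


@dataclass(frozen=True)
class NoiseCurve:
    """Mean +/- sd of pop limit over replicates per pipetting noise eta."""

    etas: tuple[float, ...] = tuple(np.arange(0.0, 301.0, 25.0) * 1e-9)
    n_replicates: int = 25
    wash: WashParams = WashParams(*WashParams.PRESETS["W1"])


def noise_onset(
    noise_frame: pd.DataFrame, alpha: float = 0.05
) -> tuple[float | None, pd.DataFrame]:
    """Smallest pipetting noise with a significant pop-limit drop.

    ``noise_frame`` is the long-format result of a ``NoiseCurve`` sweep.
    Each noise level is compared against the eta = 0 replicates with a
    one-sided Welch t-test (drop in mean pop limit); returns the smallest
    eta (nM) significant at ``alpha``, or None if the curve stays flat,
    together with the per-eta comparison table.
    """
    from scipy import stats

    etas = sorted(noise_frame["eta_nM"].unique())
    base = noise_frame.loc[np.isclose(noise_frame["eta_nM"], etas[0]), "pop_limit"]
    rows = []
    onset = None
    for eta in etas[1:]:
        group = noise_frame.loc[np.isclose(noise_frame["eta_nM"], eta), "pop_limit"]
        if group.std() == 0 and base.std() == 0:
            pvalue = 1.0 if group.mean() >= base.mean() else 0.0
        else:
            pvalue = float(
                stats.ttest_ind(
                    base, group, equal_var=False, alternative="greater"
                ).pvalue
            )
        significant = pvalue < alpha
        rows.append(
            {
                "eta_nM": eta,
                "mean": group.mean(),
                "drop": base.mean() - group.mean(),
                "pvalue": pvalue,
                "significant": significant,
            }
        )
        if significant and onset is None:
            onset = float(eta)
    return onset, pd.DataFrame(rows)


@dataclass
class SweepResult:
    plan: object
    frame: pd.DataFrame
    meta: dict

    def summary(self) -> pd.DataFrame:
        axes = [c for c in self.frame.columns if c not in ("seed", "pop_limit")]
        return (
            self.frame.groupby(axes)["pop_limit"].agg(["mean", "std", "count"])
            .reset_index()
        )


def save_heatmap(result: "SweepResult", path) -> None:
    """Render a grid sweep (wash or conc/wait plan) as a heatmap PNG.

    Cell colour is the pop limit; conc/wait grids get log-scaled axes.
    Noise-curve results are one-dimensional and are drawn as mean +- sd.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = result.frame
    fig, ax = plt.subplots(figsize=(5, 4))
    if isinstance(result.plan, NoiseCurve):
        summary = result.summary()
        ax.errorbar(summary["eta_nM"], summary["mean"], yerr=summary["std"].fillna(0))
        ax.set_xlabel("pipetting noise eta (nM)")
        ax.set_ylabel("pop limit")
    else:
        if isinstance(result.plan, WashGrid):
            xcol, ycol, logscale = "phi0", "mu", False
        else:
            xcol, ycol, logscale = "wait_min", "gamma_nM", True
        pivot = frame.pivot_table(index=ycol, columns=xcol, values="pop_limit")
        mesh = ax.pcolormesh(
            pivot.columns, pivot.index, pivot.values, shading="nearest"
        )
        if logscale:
            ax.set_xscale("log")
            ax.set_yscale("log")
        fig.colorbar(mesh, ax=ax, label="pop limit")
        ax.set_xlabel(xcol)
        ax.set_ylabel(ycol)
    ax.set_title(result.meta.get("sequence", ""))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def sweep(
    opseq: OperationSequence,
    plan: WashGrid | ConcWaitGrid | NoiseCurve,
    backend: str = "ssa",
    seed: int = 0,
    rates: RateConstants | None = None,
    cfg: RuleConfig | None = None,
) -> SweepResult:
    """Run a sweep plan over one operation sequence.

    Seeding is counter-based: replicate/cell k of the sweep draws its own
    child seed from the root, so any single cell is reproducible in
    isolation.
    """
    root = np.random.SeedSequence(seed)
    rows = []
    if isinstance(plan, WashGrid):
        cells = list(itertools.product(plan.mus, plan.phi0s))
        for idx, (mu, phi0) in enumerate(cells):
            child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(idx,))
            outcome = simulate_sequence(
                opseq, WashParams(mu, phi0), seed=child, backend=backend,
                rates=rates, cfg=cfg,
            )
            rows.append(
                {"mu": mu, "phi0": phi0, "seed": idx, "pop_limit": outcome.pop_limit}
            )
    elif isinstance(plan, ConcWaitGrid):
        cells = list(itertools.product(plan.gammas, plan.waits))
        for idx, (gamma, wait) in enumerate(cells):
            child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(idx,))
            outcome = simulate_sequence(
                opseq, plan.wash, seed=child, backend=backend,
                defaults=StageDefaults(gamma=gamma, wait=wait),
                rates=rates, cfg=cfg,
            )
            rows.append(
                {
                    "gamma_nM": gamma * 1e9,
                    "wait_min": wait / 60.0,
                    "seed": idx,
                    "pop_limit": outcome.pop_limit,
                }
            )
    elif isinstance(plan, NoiseCurve):
        for i, eta in enumerate(plan.etas):
            for k in range(plan.n_replicates):
                child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(i, k))
                outcome = simulate_sequence(
                    opseq, plan.wash, seed=child, backend=backend, eta=eta,
                    rates=rates, cfg=cfg,
                )
                rows.append(
                    {
                        "eta_nM": round(eta * 1e9, 6),
                        "seed": k,
                        "pop_limit": outcome.pop_limit,
                    }
                )
    else:
        raise ValueError(f"unknown sweep plan {plan!r}")
    meta = {
        "sequence": opseq.name or opseq.token_string(),
        "ops": opseq.token_string(),
        "backend": backend,
        "seed": seed,
        "plan": type(plan).__name__,
    }
    return SweepResult(plan=plan, frame=pd.DataFrame(rows), meta=meta)
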