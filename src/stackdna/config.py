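"""Run configuration loading and result serialisation.

Configurations are JSON or YAML mappings; every field has a printed
default (300 nM strand concentration, 30 min waits, 0.15 pl volume,
k_A = k_BC = 3e4 /M/s, 200 nM linker) so the minimal config ``{}`` is a
complete standard run.  Outputs are tidy CSV tables with a JSON sidecar
echoing the fully resolved parameter set and seed, so a run can be
reproduced from its artefacts alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import analysis, engine, protocol
from .chemistry import ALL_TOKENS, ConfigurationError, RateConstants, define_monomers
from .engine import WashParams

__all__ = ["RunConfig", "load_config", "resolve_opseq", "write_outputs", "trace_frame"]


@dataclass
class RunConfig:
    """Fully resolvable description of one simulation run."""

    monomers: dict = field(default_factory=dict)  # token -> length (nt)
    k_A: float = 3.0e4
    k_BC: float = 3.0e4
    wash: WashParams = field(default_factory=lambda: WashParams(0.1, 0.33))
    volume_pl: float = 0.15
    gamma_nM: float = 300.0
    read_nM: float | None = None
    linker_nM: float = 200.0
    wait_min: float = 30.0
    backend: str = "ssa"
    ops: str | None = None  # inline token string, e.g. "X Y q q"
    generator: str | None = None  # "seqN" | "seqR"
    N: int | None = None
    arrangement_seed: int = 0
    eta_nM: float = 0.0
    lmax: int = 16
    seed: int = 0

    def rates(self) -> RateConstants:
        return RateConstants(self.k_A, self.k_BC)

    def stage_defaults(self) -> protocol.StageDefaults:
        return protocol.StageDefaults(
            gamma=self.gamma_nM * 1e-9,
            wait=self.wait_min * 60.0,
            read_concentration=None if self.read_nM is None else self.read_nM * 1e-9,
        )

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["wash"] = {"mu": self.wash.mu, "phi0": self.wash.phi0}
        d["monomers"] = {
            t: m.length_nt for t, m in define_monomers(self.monomers or None).items()
        }
        return d


def _fail(key: str, msg: str):
    raise ConfigurationError(f"config key {key!r}: {msg}")


def _parse_wash(value) -> WashParams:
    if isinstance(value, str):
        try:
            return WashParams.preset(value)
        except ValueError as e:
            _fail("wash", str(e))
    if isinstance(value, Mapping):
        extra = set(value) - {"mu", "phi0"}
        if extra:
            _fail("wash", f"unknown sub-keys {sorted(extra)}")
        try:
            return WashParams(float(value.get("mu", 0.0)), float(value.get("phi0", 0.0)))
        except (TypeError, ValueError) as e:
            _fail("wash", str(e))
    _fail("wash", "expected a preset name (W1/W2/W3) or {mu, phi0}")


_NUMERIC_KEYS = {
    "k_A": (0.0, None),
    "k_BC": (0.0, None),
    "volume_pl": (0.0, None),
    "gamma_nM": (0.0, None),
    "read_nM": (0.0, None),
    "linker_nM": (0.0, None),
    "wait_min": (0.0, None),
    "eta_nM": (0.0, None),
}


def config_from_dict(data: Mapping) -> RunConfig:
    if not isinstance(data, Mapping):
        raise ConfigurationError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"config key {sorted(unknown)[0]!r}: unknown key")
    kwargs: dict = {}
    for key, value in data.items():
        if key == "wash":
            kwargs["wash"] = _parse_wash(value)
        elif key == "monomers":
            if not isinstance(value, Mapping):
                _fail("monomers", "expected a token -> length mapping")
            define_monomers(value)  # validates completeness and lengths
            kwargs["monomers"] = dict(value)
        elif key in _NUMERIC_KEYS:
            lo, hi = _NUMERIC_KEYS[key]
            try:
                v = float(value)
            except (TypeError, ValueError):
                _fail(key, "expected a number")
            if v < lo or (v == 0.0 and key in ("volume_pl",)):
                _fail(key, f"must be > {lo}" if key == "volume_pl" else f"must be >= {lo}")
            kwargs[key] = v
        elif key in ("lmax", "seed", "N", "arrangement_seed"):
            if value is not None and (not isinstance(value, int) or isinstance(value, bool)):
                _fail(key, "expected an integer")
            kwargs[key] = value
        elif key == "backend":
            if value not in ("ssa", "ode"):
                _fail("backend", "must be 'ssa' or 'ode'")
            kwargs[key] = value
        elif key == "generator":
            if value is not None and value not in ("seqN", "seqR"):
                _fail("generator", "must be 'seqN' or 'seqR'")
            kwargs[key] = value
        elif key == "ops":
            if value is not None:
                protocol.parse_ops(str(value))  # validates
                kwargs[key] = str(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a JSON/YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text) or {}
    return config_from_dict(data)


def resolve_opseq(cfg: RunConfig) -> protocol.OperationSequence:
    """Materialise the operation sequence a config describes."""
    if cfg.ops:
        return protocol.parse_ops(cfg.ops)
    if cfg.generator == "seqN":
        if cfg.N is None:
            _fail("N", "required when generator is 'seqN'")
        return protocol.make_seqN(cfg.N, seed=cfg.arrangement_seed)
    if cfg.generator == "seqR":
        return protocol.make_seqR(seed=cfg.arrangement_seed)
    _fail("ops", "provide inline ops or a generator")


# ---------------------------------------------------------------------------
# Output serialisation
# ---------------------------------------------------------------------------


def trace_frame(result: engine.ProtocolResult, backend: str = "ssa") -> pd.DataFrame:
    """Tidy per-stage species table (requires a run with record_trace)."""
    if result.trace is None:
        raise ValueError("protocol was run without record_trace=True")
    vol = result.state.volume_l
    rows = []
    for snap in result.trace:
        for sp, n in sorted(snap.counts.items(), key=lambda kv: kv[0].tokens):
            conc_nM = (n if backend == "ode" else n / (vol * engine.AVOGADRO)) * 1e9
            rows.append(
                {
                    "stage": snap.stage_index,
                    "strand": snap.strand,
                    "species": sp.name,
                    "compartment": "tethered" if sp.tethered else "supernatant",
                    "copies": n if backend == "ssa" else float("nan"),
                    "concentration_nM": conc_nM,
                }
            )
    return pd.DataFrame(rows)


def readout_frame(readouts: Sequence[analysis.PopReadout]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pop": i,
                "expected": ro.expected,
                "Xr_nM": ro.xr_nM,
                "Yr_nM": ro.yr_nM,
                "wr_nM": ro.wr_nM,
            }
            for i, ro in enumerate(readouts)
        ]
    )


def write_outputs(
    obj,
    outdir: str | Path,
    meta: dict | None = None,
    backend: str = "ssa",
) -> list[Path]:
    """Serialise a run / sweep / fit result bundle to ``outdir``.

    Every bundle gets a ``meta.json`` echoing the resolved parameters.
    Re-running with the same config and seed reproduces the files
    byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _csv(frame: pd.DataFrame, name: str):
        p = outdir / name
        frame.to_csv(p, index=False)
        written.append(p)

    if isinstance(obj, analysis.SimulationOutcome):
        _csv(readout_frame(obj.readouts), "readouts.csv")
        if obj.result.trace is not None:
            _csv(trace_frame(obj.result, backend), "trace.csv")
    elif isinstance(obj, analysis.SweepResult):
        _csv(obj.frame, "sweep.csv")
        meta = {**obj.meta, **(meta or {})}
    elif isinstance(obj, analysis.FitResult):
        _csv(obj.surface_frame(), "fit_surface.csv")
        meta = {**(meta or {}), "mu": obj.mu, "phi0": obj.phi0}
    else:
        raise TypeError(f"don't know how to serialise {type(obj).__name__}")
    p = outdir / "meta.json"
    p.write_text(json.dumps(meta or {}, indent=2, sort_keys=True, default=str) + "\n")
    written.append(p)
    return written
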