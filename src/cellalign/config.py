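"""Run configuration, deterministic fixtures and tabular I/O.

A :class:`RunConfig` bundles model parameters, an initial condition, solver
mode and tolerances into a YAML-serialisable record so that any run is
reproducible from its config file and seed alone.  Tables are written as CSV
at full float precision with a JSON sidecar carrying the seed and a hash of
the configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import CellState, ModelParams, classify_region

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "fixture_initial_conditions",
    "write_table",
    "read_table",
]


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


_DEFAULTS = {
    "gamma": 0.0,
    "alpha0": 0.5,
    "y0": -0.5,
    "r0": None,  # defaults to rbar
    "mode": "rigid",
    "t_end": 1e4,
    "rtol": 1e-9,
    "atol": 1e-11,
    "tol_align": 1e-4,
    "seed": 0,
    "out": None,
}
_REQUIRED = {"nu", "rbar"}
_ALLOWED = _REQUIRED | set(_DEFAULTS)


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved, reproducible run description."""

    nu: float
    rbar: float
    gamma: float = 0.0
    alpha0: float = 0.5
    y0: float = -0.5
    r0: float | None = None
    mode: str = "rigid"
    t_end: float = 1e4
    rtol: float = 1e-9
    atol: float = 1e-11
    tol_align: float = 1e-4
    seed: int = 0
    out: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("full", "rigid", "nu0"):
            raise ConfigError(f"mode must be full/rigid/nu0, got {self.mode!r}")
        if self.mode == "full" and self.gamma == 0.0:
            raise ConfigError(
                "mode 'full' with gamma = 0 is invalid: rigid cells have no "
                "shape-restoration term; use mode 'rigid'"
            )
        ModelParams(nu=self.nu, gamma=self.gamma, r_bar=self.rbar)  # validates

    @property
    def params(self) -> ModelParams:
        return ModelParams(nu=self.nu, gamma=self.gamma, r_bar=self.rbar)

    @property
    def initial_state(self) -> CellState:
        r0 = self.rbar if self.r0 is None else self.r0
        return CellState(x=0.0, y=self.y0, alpha=self.alpha0, r=r0)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _from_mapping(raw: dict) -> RunConfig:
    unknown = set(raw) - _ALLOWED
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    missing = _REQUIRED - set(raw)
    if missing:
        raise ConfigError(f"missing required config key(s): {sorted(missing)}")
    merged = {**_DEFAULTS, **raw}
    try:
        return RunConfig(**merged)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON run configuration, applying defaults and overrides.

    CLI flags take precedence over file values (pass them as ``overrides``);
    unknown keys are rejected by name.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    return _from_mapping(raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def fixture_initial_conditions(
    n: int, r: float, seed: int, stratified: bool = False
) -> list[tuple[float, float]]:
    """Deterministic initial conditions ``(alpha0, y0)`` for tests and sweeps.

    Uniform over ``(0, pi/2) x (-sqrt(r), 0)``.  With ``stratified=True`` the
    sampler keeps drawing until every geometrically reachable region (A, B,
    C) is represented at least once, so region-specific properties are always
    exercised.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)

    def draw(k: int) -> list[tuple[float, float]]:
        a = rng.uniform(0.0, np.pi / 2, size=k)
        y = rng.uniform(-np.sqrt(r), 0.0, size=k)
        return list(zip(a.tolist(), y.tolist()))

    pts = draw(n)
    if stratified:
        for _ in range(200):
            regions = {
                classify_region(CellState(0.0, y0, a0, r)).label.value
                for a0, y0 in pts
            }
            if regions >= {"A", "B", "C"}:
                break
            pts[rng.integers(0, n)] = draw(1)[0]
    return pts


def write_table(path, records, metadata: dict | None = None) -> None:
    """Write records as CSV (full float precision) with a JSON sidecar.

    ``records`` is a DataFrame or a list of dicts with a consistent schema.
    The sidecar carries the caller's metadata (seed, config hash, ...).
    """
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, index=False, float_format="%.17g")
    if metadata is not None:
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(metadata, indent=2, default=str)
        )


def read_table(path) -> tuple[pd.DataFrame, dict | None]:
    """Read a table written by :func:`write_table`; returns (frame, metadata)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else None
    return df, meta
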