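"""Run configuration, figure presets, and tabular output.

A run is described by a TOML or JSON file with ``[grid]``, ``[rate]``,
``[kernel]``, ``[initial]``, ``[run]`` and ``[solver]`` blocks, all
optional.  The ``preset`` key expands to the parameter sets of the
model's four canonical numerical experiments (threshold scale ``alpha``
and reset kernel) before validation; explicit keys override the preset.

Everything is deterministic: re-running the same configuration produces
byte-identical outputs.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .coefficients import FiringRate, FragmentationKernel, ThresholdRule
from .grid import Grid
from .simulator import DensityState, Trajectory, default_grid, initial_data

__all__ = ["RunConfig", "PRESETS", "load_config", "write_outputs"]

# threshold scale and proportional-reset slope of the four study setups;
# right-hand panels of the multi-orbit comparisons use the multi_bump
# initial profile on the same coefficients
PRESETS: dict[str, dict[str, Any]] = {
    "fig1_left": {"rate": {"alpha": 2.0}, "kernel": {"psi_slope": 0.0}},
    "fig1_right": {"rate": {"alpha": 2.0}, "kernel": {"psi_slope": 0.5}},
    "fig2": {"rate": {"alpha": 4.0}, "kernel": {"psi_slope": 0.0}},
    "fig3": {"rate": {"alpha": 4.0}, "kernel": {"psi_slope": 0.5}},
    "fig4": {"rate": {"alpha": 3.0}, "kernel": {"psi_slope": 0.5}},
}


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ds: float = Field(0.01, gt=0)
    s_max: Optional[float] = Field(None, gt=0)
    n_cells: Optional[int] = Field(None, gt=0)


class RateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    family: Literal["step", "regularized"] = "step"
    alpha: Optional[float] = Field(None, gt=0)
    sigma_const: Optional[float] = Field(None, ge=0)
    pM: float = Field(1.0, gt=0)
    delta: float = Field(0.0, ge=0)
    eta: Optional[float] = Field(None, ge=0)

    @model_validator(mode="after")
    def _threshold_given(self) -> "RateConfig":
        if self.alpha is None and self.sigma_const is None:
            raise ValueError("rate needs either alpha or sigma_const")
        if self.alpha is not None and self.sigma_const is not None:
            raise ValueError("give only one of alpha / sigma_const")
        return self


class KernelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    family: Literal["point_map", "density"] = "point_map"
    psi_slope: float = Field(0.0, ge=0, lt=1)
    density_table: Optional[str] = None  # CSV with columns s, u, K
    theta: Optional[float] = Field(None, ge=0, lt=1)


class InitialConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["exp_decay", "multi_bump"] = "exp_decay"
    centers: list[float] = Field(default_factory=lambda: [1.0, 3.0])
    widths: list[float] = Field(default_factory=lambda: [0.2, 0.2])
    weights: list[float] = Field(default_factory=lambda: [1.0, 1.0])


class RunBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    T: float = Field(100.0, ge=0)
    snapshot_times: list[float] = Field(default_factory=list)


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    root_rule: Literal["lagged", "continuation", "largest"] = "lagged"
    fp_tol: float = Field(1e-8, gt=0)
    convergence_tol: float = Field(1e-3, gt=0)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: Optional[str] = None
    grid: GridConfig = Field(default_factory=GridConfig)
    rate: RateConfig = Field(default_factory=lambda: RateConfig(alpha=2.0))
    kernel: KernelConfig = Field(default_factory=KernelConfig)
    initial: InitialConfig = Field(default_factory=InitialConfig)
    run: RunBlock = Field(default_factory=RunBlock)
    solver: SolverConfig = Field(default_factory=SolverConfig)

    # -- model objects -----------------------------------------------------
    def build_rate(self) -> FiringRate:
        r = self.rate
        threshold = (
            ThresholdRule(alpha=r.alpha) if r.alpha is not None else float(r.sigma_const)
        )
        return FiringRate(
            family=r.family,
            threshold=threshold,
            pM=r.pM,
            smoothing_width=r.delta,
            eta=r.eta,
        )

    def build_kernel(self) -> FragmentationKernel:
        k = self.kernel
        if k.family == "point_map":
            return FragmentationKernel.point_map_linear(k.psi_slope)
        table = pd.read_csv(k.density_table)
        from scipy.interpolate import NearestNDInterpolator

        interp = NearestNDInterpolator(
            table[["s", "u"]].to_numpy(), table["K"].to_numpy()
        )

        def density(s, u):
            s = np.atleast_1d(np.asarray(s, dtype=float))
            vals = interp(np.column_stack([s, np.full(s.shape, float(u))]))
            vals[s > u] = 0.0
            return vals

        return FragmentationKernel(family="density", density_values=density, theta=k.theta)

    def build_grid(self) -> Grid:
        g = self.grid
        if g.s_max is not None and g.n_cells is not None:
            return Grid(s_max=g.s_max, n_cells=g.n_cells)
        if g.s_max is not None:
            return Grid.from_ds(g.s_max, g.ds)
        return default_grid(self.build_rate(), ds=g.ds)

    def build_initial(self, grid: Grid) -> DensityState:
        i = self.initial
        if i.kind == "exp_decay":
            return initial_data("exp_decay", grid)
        return initial_data(
            "multi_bump", grid, centers=i.centers, widths=i.widths, weights=i.weights
        )


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None, data: Optional[dict] = None) -> RunConfig:
    """Load and validate a run configuration (TOML or JSON).

    A ``preset`` key is expanded first; explicit keys in the file win
    over the preset's values.  An empty file yields the all-defaults
    configuration.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            path = Path(path)
            text = path.read_text()
            if not text.strip():
                data = {}
            elif path.suffix == ".json":
                data = json.loads(text)
            else:
                data = tomllib.loads(text)
    preset = data.get("preset")
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            )
        data = _merge(PRESETS[preset], data)
    return RunConfig.model_validate(data)


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------


def write_outputs(
    prefix: str | Path,
    config: Optional[RunConfig] = None,
    trajectory: Optional[Trajectory] = None,
    steady: Optional[dict] = None,
    spectral: Optional[dict] = None,
    diagnostics: Optional[dict] = None,
    A_profile: Optional[tuple[np.ndarray, np.ndarray]] = None,
    P_profile: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> list[Path]:
    """Write CSV/JSON artifacts with deterministic field ordering.

    Returns the list of files written.  The metadata JSON always echoes
    the expanded configuration, the package version, and the mass-drift
    conservation report when a trajectory is present.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    meta: dict[str, Any] = {"package_version": __version__}
    if config is not None:
        meta["config"] = config.model_dump()
    if trajectory is not None:
        path = prefix.with_name(prefix.name + "_activity.csv")
        pd.DataFrame({"t": trajectory.times, "N": trajectory.N_values}).to_csv(
            path, index=False
        )
        written.append(path)
        if trajectory.snapshots:
            rows = []
            for snap in trajectory.snapshots:
                rows.append(
                    pd.DataFrame(
                        {
                            "t": snap.time,
                            "s": snap.grid.nodes,
                            "n": snap.values,
                        }
                    )
                )
            path = prefix.with_name(prefix.name + "_snapshots.csv")
            pd.concat(rows, ignore_index=True).to_csv(path, index=False)
            written.append(path)
        meta["conservation"] = {
            "max_mass_drift": trajectory.max_mass_drift,
            "within_1e-10": bool(trajectory.max_mass_drift < 1e-10),
        }
    for name, payload in (
        ("steady", steady),
        ("spectral", spectral),
        ("diagnostics", diagnostics),
    ):
        if payload is not None:
            path = prefix.with_name(f"{prefix.name}_{name}.json")
            path.write_text(json.dumps(payload, indent=2, sort_keys=True))
            written.append(path)
    for name, profile in (("A", A_profile), ("P", P_profile)):
        if profile is not None:
            s, vals = profile
            path = prefix.with_name(f"{prefix.name}_{name}.csv")
            pd.DataFrame({"s": s, name: vals}).to_csv(path, index=False)
            written.append(path)
    path = prefix.with_name(prefix.name + "_meta.json")
    path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    written.append(path)
    return written
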