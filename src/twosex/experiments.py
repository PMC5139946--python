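"""Configuration-driven experiment runner and figure-sweep reproduction.

Experiments are described by small TOML files (or dicts) naming a case, a
task, parameter overrides on top of the standard defaults, and optional
sweep/numerics/output sections.  The named figure scenarios of the two case
studies ship as packaged configs (``fig4`` … ``fig9``) so every published
sweep is reproducible from configuration alone.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .adaptive import (
    detect_neutral_line,
    find_singular_strategy,
    integrate_strategy_trajectory,
    selection_gradient,
    union_weighted_sex_ratio,
)
from .core import solve_equilibrium
from .maternal_age import Case1Parameters, maternal_age_model
from .maternal_quality import (
    Case2Parameters,
    maternal_quality_model,
    reproductive_value_ratios,
)
from .strategy import SexRatioStrategy

__all__ = [
    "ExperimentConfig",
    "ConfigError",
    "load_config",
    "figure_config",
    "FIGURES",
    "run_experiment",
    "build_model",
]

log = logging.getLogger("twosex")

TASKS = ("equilibrium", "gradient", "trajectory", "ss-search", "neutral-line", "sweep")
CASES = ("case1a", "case1b", "case2")

#: packaged figure scenarios
FIGURES = (
    "fig4",
    "fig5a",
    "fig5b",
    "fig6a",
    "fig6b",
    "fig7a",
    "fig7c",
    "fig8a",
    "fig8b",
    "fig9",
)

#: float format used for all CSV output (12 significant digits)
FLOAT_FMT = "%.12g"


class ConfigError(ValueError):
    """Invalid experiment configuration; message carries the field path."""


@dataclass
class ExperimentConfig:
    """A fully resolved experiment description."""

    case: str
    task: str
    parameters: dict = field(default_factory=dict)
    strategy: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)
    numerics: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.case not in CASES:
            raise ConfigError(f"case: must be one of {CASES}, got {self.case!r}")
        if self.task not in TASKS:
            raise ConfigError(f"task: must be one of {TASKS}, got {self.task!r}")
        valid = {f.name for f in dc_fields(self._param_cls())}
        for key in self.parameters:
            if key not in valid:
                raise ConfigError(f"parameters.{key}: unknown parameter for {self.case}")
        if self.task == "sweep":
            if "variable" not in self.sweep:
                raise ConfigError("sweep.variable: required for task = 'sweep'")
            if "values" not in self.sweep and "grid" not in self.sweep:
                raise ConfigError("sweep: needs either 'values' or 'grid' = [lo, hi]")

    def _param_cls(self):
        return Case1Parameters if self.case in ("case1a", "case1b") else Case2Parameters

    # -- derived accessors -------------------------------------------------
    @property
    def mode(self) -> str:
        return self.numerics.get("mode", "literal")

    @property
    def seed(self) -> int:
        return int(self.numerics.get("seed", 0))

    def resolved_parameters(self, **extra):
        params = dict(self.parameters)
        params.update(extra)
        if self.case == "case1b":
            params.setdefault("beta", 0.0)
            params.setdefault("derive_k", True)
        return self._param_cls()(**params)

    def sweep_values(self) -> np.ndarray:
        if "values" in self.sweep:
            return np.asarray(self.sweep["values"], dtype=float)
        lo, hi = self.sweep["grid"]
        return np.linspace(lo, hi, int(self.sweep.get("num", 9)))

    def linked_parameters(self, value: float) -> dict:
        """Linked variables of the form name = a + b * sweep_value."""
        out = {self.sweep["variable"]: value}
        for name, (a, b) in self.sweep.get("linked", {}).items():
            out[name] = a + b * value
        return out

    def start_strategy(self) -> SexRatioStrategy:
        return SexRatioStrategy(
            float(self.strategy.get("s1", 0.5)), float(self.strategy.get("s2", 0.5))
        )


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> ExperimentConfig:
    known = {f.name for f in dc_fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    return ExperimentConfig(**raw)


def figure_config(name: str) -> ExperimentConfig:
    """Load one of the packaged figure scenarios (``fig4`` … ``fig9``)."""
    if name not in FIGURES:
        raise ConfigError(f"unknown figure config {name!r}; choose from {FIGURES}")
    ref = resources.files("twosex").joinpath(f"configs/{name}.toml")
    return config_from_dict(tomllib.loads(ref.read_text()))


def apply_overrides(config: ExperimentConfig, sets: dict[str, str]) -> ExperimentConfig:
    """Apply ``--set key=value`` style overrides (dotted paths allowed)."""
    import copy

    cfg = copy.deepcopy(config)
    for key, val in sets.items():
        try:
            parsed = json.loads(val)
        except json.JSONDecodeError:
            parsed = val
        target = cfg.parameters
        name = key
        if "." in key:
            section, name = key.split(".", 1)
            target = getattr(cfg, section, None)
            if not isinstance(target, dict):
                raise ConfigError(f"cannot override section {section!r}")
        elif key in ("s1", "s2"):
            target = cfg.strategy
        target[name] = parsed
    return config_from_dict(
        {f.name: getattr(cfg, f.name) for f in dc_fields(ExperimentConfig)}
    )


def build_model(config: ExperimentConfig, **extra):
    params = config.resolved_parameters(**extra)
    if config.case in ("case1a", "case1b"):
        return maternal_age_model(params)
    return maternal_quality_model(params)


# ---------------------------------------------------------------------------
# task runners


def _run_equilibrium(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    model = build_model(config)
    s = config.start_strategy()
    eq = solve_equilibrium(model, s)
    log.info("equilibrium: lambda=%.10g residual=%.2e", eq.lam, eq.residual)
    df = eq.to_frame()
    df["lambda"] = eq.lam
    return {"equilibrium": df}


def _run_gradient(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    model = build_model(config)
    s = config.start_strategy()
    eq = solve_equilibrium(model, s)
    res = selection_gradient(
        model, s, eq, mode=config.mode, method=config.numerics.get("method", "finite-difference")
    )
    df = pd.DataFrame(
        [
            {
                "s1": s.s1,
                "s2": s.s2,
                "D1": res.D[0],
                "D2": res.D[1],
                "lambda": eq.lam,
                "method": res.method,
                "mode": config.mode,
            }
        ]
    )
    return {"gradient": df}


def _trajectory_frame(model, traj, mode: str, n_points: int = 40) -> pd.DataFrame:
    idx = np.unique(
        np.linspace(0, len(traj.times) - 1, min(n_points, len(traj.times))).astype(int)
    )
    rows = []
    from .adaptive import _GradientField

    gf = _GradientField(model, mode=mode)
    for step, i in enumerate(idx):
        s = SexRatioStrategy(
            float(np.clip(traj.strategies[i, 0], 0, 1)),
            float(np.clip(traj.strategies[i, 1], 0, 1)),
        )
        D, eq = gf(s)
        rows.append(
            {
                "step": step,
                "t": traj.times[i],
                "s1": s.s1,
                "s2": s.s2,
                "D1": D[0],
                "D2": D[1],
                "lambda": eq.lam,
                "s_bar": union_weighted_sex_ratio(model, s, eq),
            }
        )
    return pd.DataFrame(rows)


def _run_trajectory(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    model = build_model(config)
    traj = integrate_strategy_trajectory(
        model,
        config.start_strategy(),
        mode=config.mode,
        stop_tol=float(config.numerics.get("stop_tol", 1e-7)),
        gradient_tol=float(config.numerics.get("gradient_tol", 1e-6)),
    )
    log.info("trajectory: %s", traj.summary().replace("\n", " | "))
    return {"trajectory": _trajectory_frame(model, traj, config.mode)}


def _run_ss_search(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    model = build_model(config)
    report = find_singular_strategy(model, mode=config.mode)
    log.info("ss-search: %s", report.summary().replace("\n", " | "))
    row = report.to_dict()
    row.pop("candidates")
    if report.found:
        row["D1"], row["D2"] = row.pop("gradient")
        eq = report.equilibrium or solve_equilibrium(model, report.location)
        if config.case == "case2":
            rvr = reproductive_value_ratios(eq)
            row["MRVR"], row["FRVR"] = rvr.MRVR, rvr.FRVR
        else:
            row["s_bar"] = union_weighted_sex_ratio(model, report.location, eq)
    else:
        row.pop("gradient")
    return {"ss": pd.DataFrame([row])}


def _run_neutral_line(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    model = build_model(config)
    nl = detect_neutral_line(
        model,
        mode=config.mode,
        n_starts=int(config.numerics.get("n_starts", 5)),
        seed=config.seed,
        gradient_tol=float(config.numerics.get("gradient_tol", 1e-6)),
        stop_tol=float(config.numerics.get("stop_tol", 1e-7)),
    )
    log.info("neutral-line: %s", nl.summary().replace("\n", " | "))
    pts = pd.DataFrame(
        {
            "s1": [e.s1 for e in nl.endpoints],
            "s2": [e.s2 for e in nl.endpoints],
            "D1": [g[0] for g in nl.gradients],
            "D2": [g[1] for g in nl.gradients],
            "s_bar": nl.s_bars,
        }
    )
    summary = pd.DataFrame(
        [
            {
                "is_neutral_line": nl.is_neutral_line,
                "s_bar_mean": nl.s_bar_mean,
                "s_bar_spread": nl.s_bar_spread,
                "max_pairwise_distance": nl.max_pairwise_distance,
            }
        ]
    )
    return {"endpoints": pts, "neutral_line": summary}


def _run_sweep(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    rows = []
    var = config.sweep["variable"]
    for value in config.sweep_values():
        model = build_model(config, **config.linked_parameters(float(value)))
        report = find_singular_strategy(model, mode=config.mode)
        row = {var: float(value)}
        if report.found:
            row.update(
                {
                    "s1_star": report.location.s1,
                    "s2_star": report.location.s2,
                    "ss_type": report.ss_type,
                }
            )
            eq = report.equilibrium or solve_equilibrium(model, report.location)
            if config.case == "case2":
                rvr = reproductive_value_ratios(eq)
                row["MRVR"], row["FRVR"] = rvr.MRVR, rvr.FRVR
            else:
                row["s_bar"] = union_weighted_sex_ratio(model, report.location, eq)
        else:
            row.update({"s1_star": np.nan, "s2_star": np.nan, "ss_type": 0})
        log.info("sweep %s=%g -> type %s", var, value, row.get("ss_type"))
        rows.append(row)
    return {"sweep": pd.DataFrame(rows)}


_RUNNERS = {
    "equilibrium": _run_equilibrium,
    "gradient": _run_gradient,
    "trajectory": _run_trajectory,
    "ss-search": _run_ss_search,
    "neutral-line": _run_neutral_line,
    "sweep": _run_sweep,
}


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    fmt: str = "csv",
) -> dict[str, pd.DataFrame]:
    """Dispatch a configured experiment; optionally write its result tables.

    Returns a dict of result tables.  With ``out_dir`` set, each table is
    written as ``<basename>_<table>.csv`` (or a single JSON file) with
    12-significant-digit floats; reruns with identical config and seed are
    bit-identical.
    """
    tables = _RUNNERS[config.task](config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        base = config.output.get("basename", config.task.replace("-", "_"))
        for name, df in tables.items():
            if fmt == "csv":
                path = out_dir / f"{base}_{name}.csv"
                df.to_csv(path, index=False, float_format=FLOAT_FMT)
            else:
                path = out_dir / f"{base}_{name}.json"
                path.write_text(
                    json.dumps(json.loads(df.to_json(orient="records")), indent=1)
                )
            log.info("wrote %s", path)
    return tables
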