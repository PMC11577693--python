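"""Orchestration of the full factorial simulation study.

The default configuration reproduces the study design: 5 latent
treatment effects (0, 4.4, 11, 17.6, 22 score points, i.e. Cohen's d of
0, 0.2, 0.5, 0.8, 1.0 at sigma=22) x 3 discretisation grids (RE4, BP10,
MH26) x 6 total sample sizes (100 ... 1600) = 90 scenarios, each with
5000 repetitions analysed by MLR, Tobit and median regression.

Reproducibility contract: every repetition's base latent sample is keyed
by (root_seed, n, rep_index) only, so results are independent of the
order in which scenarios are executed and identical between serial and
scenario-parallel runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import METHODS, FitResult, fit_method
from .performance import PerformanceRow, summarise_fits
from .synthetic_dgm import ScenarioSpec, generate_trial, grid_from_label

__all__ = [
    "StudyConfig",
    "StudyResults",
    "expand_scenarios",
    "run_scenario",
    "run_study",
]

logger = logging.getLogger("prosim")

DEFAULT_EFFECTS = (0.0, 4.4, 11.0, 17.6, 22.0)
DEFAULT_GRIDS = ("RE4", "BP10", "MH26")
DEFAULT_SAMPLE_SIZES = (100, 200, 400, 800, 1200, 1600)

#: canonical DGM numbering for the default effect sizes
DGM_NUMBERS = {x: i + 1 for i, x in enumerate(DEFAULT_EFFECTS)}

ESTIMATE_COLUMNS = [
    "scenario_id",
    "rep",
    "method",
    "estimate",
    "se",
    "ci_low",
    "ci_upp",
    "p_value",
    "converged",
]


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a (possibly restricted) factorial study."""

    root_seed: int = 20240
    mu: float = 50.0
    sigma: float = 22.0
    dgm_effects: tuple[float, ...] = DEFAULT_EFFECTS
    grids: tuple[str, ...] = DEFAULT_GRIDS
    sample_sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES
    nsim: int = 5000
    alpha: float = 0.05
    methods: tuple[str, ...] = METHODS
    output_dir: str | None = None
    save_estimates: bool = True

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; known: {METHODS}")
        if not (self.dgm_effects and self.grids and self.sample_sizes):
            raise ValueError("factor lists must be non-empty")
        if not self.methods:
            raise ValueError("at least one method is required")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "StudyConfig":
        """Load a flat key-value YAML config; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        for key in ("dgm_effects", "grids", "sample_sizes", "methods"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _dedup(values: Iterable, name: str) -> tuple:
    seen: list = []
    for v in values:
        if v in seen:
            warnings.warn(f"duplicate {name} value {v!r} ignored", stacklevel=3)
        else:
            seen.append(v)
    return tuple(seen)


def scenario_label(effect_x: float, grid_label: str, n: int) -> str:
    """Stable scenario identifier, e.g. 'x22_RE4_n400'."""
    return f"x{effect_x:g}_{grid_label}_n{n}"


def expand_scenarios(config: StudyConfig) -> list[ScenarioSpec]:
    """Expand the factorial design in deterministic (effect, grid, n) order."""
    effects = _dedup(config.dgm_effects, "effect")
    grids = _dedup(config.grids, "grid")
    sizes = _dedup(config.sample_sizes, "sample size")
    specs = []
    for x in effects:
        for label in grids:
            grid = grid_from_label(label)
            for n in sizes:
                specs.append(
                    ScenarioSpec(
                        mu=config.mu,
                        sigma=config.sigma,
                        effect_x=x,
                        n=n,
                        grid=grid,
                        nsim=config.nsim,
                        alpha=config.alpha,
                        seed=config.root_seed,
                        scenario_id=scenario_label(x, label, n),
                    )
                )
    return specs


def _estimate_record(scenario_id: str, rep: int, fit: FitResult) -> dict:
    return {
        "scenario_id": scenario_id,
        "rep": rep,
        "method": fit.method,
        "estimate": fit.estimate,
        "se": fit.se,
        "ci_low": fit.ci_low,
        "ci_upp": fit.ci_upp,
        "p_value": fit.p_value,
        "converged": fit.converged,
    }


def _performance_frame(
    spec: ScenarioSpec, rows: Sequence[PerformanceRow]
) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    df.insert(1, "effect_x", spec.effect_x)
    df.insert(2, "grid", spec.grid.label)
    df.insert(3, "n", spec.n)
    df.insert(4, "dgm", DGM_NUMBERS.get(spec.effect_x, pd.NA))
    return df


def run_scenario(
    spec: ScenarioSpec, methods: Sequence[str] = METHODS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one simulation cell: nsim trials, each fit by every method.

    Returns the per-repetition estimate table and one performance row
    per method.  Method failures are recorded as non-converged rows, not
    raised.
    """
    fits: dict[str, list[FitResult]] = {m: [] for m in methods}
    records: list[dict] = []
    for rep in range(spec.nsim):
        trial = generate_trial(spec, rep)
        for m in methods:
            fit = fit_method(m, trial, alpha=spec.alpha)
            fits[m].append(fit)
            records.append(_estimate_record(spec.scenario_id, rep, fit))
    perf = [
        summarise_fits(
            fits[m],
            true_x=spec.effect_x,
            alpha=spec.alpha,
            scenario_id=spec.scenario_id,
            method=m,
        )
        for m in methods
    ]
    estimates = pd.DataFrame(records, columns=ESTIMATE_COLUMNS)
    return estimates, _performance_frame(spec, perf)


@dataclass
class StudyResults:
    """Bundle returned by :func:`run_study`."""

    performance: pd.DataFrame
    estimates: pd.DataFrame | None
    manifest: dict
    output_dir: Path | None = None


def _manifest(config: StudyConfig) -> dict:
    import scipy
    import statsmodels

    return {
        "config": config.to_dict(),
        "package_version": __version__,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }


def run_study(config: StudyConfig) -> StudyResults:
    """Run every scenario in the configuration and aggregate tidy tables.

    With ``output_dir`` set, writes ``estimates.csv`` (unless disabled),
    ``performance.csv``, ``manifest.json`` and ``run.log``.  Fails fast
    on an unwritable output directory before simulating anything.
    """
    out: Path | None = None
    handler = None
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")  # fail fast if unwritable
        probe.unlink()
        handler = logging.FileHandler(out / "run.log")
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)

    specs = expand_scenarios(config)
    logger.info(
        "starting study: %d scenarios, nsim=%d, methods=%s",
        len(specs),
        config.nsim,
        ",".join(config.methods),
    )
    perf_frames: list[pd.DataFrame] = []
    est_frames: list[pd.DataFrame] = []
    try:
        for i, spec in enumerate(specs):
            t0 = time.perf_counter()
            estimates, perf = run_scenario(spec, config.methods)
            perf_frames.append(perf)
            if config.save_estimates:
                est_frames.append(estimates)
            n_missing = {
                m: int(perf.loc[perf["method"] == m, "n_missing"].iloc[0])
                for m in config.methods
            }
            logger.info(
                "[%d/%d] %s done in %.1fs (missing fits: %s)",
                i + 1,
                len(specs),
                spec.scenario_id,
                time.perf_counter() - t0,
                n_missing,
            )
        performance = pd.concat(perf_frames, ignore_index=True)
        all_estimates = (
            pd.concat(est_frames, ignore_index=True)
            if config.save_estimates
            else None
        )
        manifest = _manifest(config)
        if out is not None:
            performance.to_csv(out / "performance.csv", index=False)
            if all_estimates is not None:
                all_estimates.to_csv(out / "estimates.csv", index=False)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            logger.info("results written to %s", out)
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()
    return StudyResults(
        performance=performance,
        estimates=all_estimates,
        manifest=manifest,
        output_dir=out,
    )
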