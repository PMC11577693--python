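"""Tables and figures from tidy simulation results.

All outputs are pure functions of the results tables written by
``run_study`` (estimates.csv / performance.csv): re-rendering never
re-simulates, and display rounding never feeds back into stored
results.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .estimators import METHODS
from .study_runner import DEFAULT_EFFECTS, DEFAULT_GRIDS, DGM_NUMBERS

__all__ = [
    "PlotSpec",
    "MEASURES",
    "make_table5",
    "make_performance_plots",
    "make_estimate_histograms",
    "make_estimate_se_scatter",
    "make_method_scatter",
    "render",
]

#: performance measures that can be drawn as line plots, with the
#: dashed reference value drawn for each (None = no reference line)
MEASURES = {
    "bias": 0.0,
    "emp_se": None,
    "mse": 0.0,
    "coverage": 0.95,
    "rejection": 0.05,
}

_MEASURE_COLUMNS = {
    "bias": "bias",
    "emp_se": "emp_se",
    "mse": "mse",
    "coverage": "coverage",
    "rejection": "rejection_rate",
}

PLOT_KINDS = (
    "histogram",
    "scatter_est_se",
    "scatter_method_vs_method",
    "line_performance",
)


@dataclass(frozen=True)
class PlotSpec:
    """What to draw: a plot kind, a measure (for line plots), reference lines."""

    kind: str
    measure: str | None = None
    reference_lines: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in PLOT_KINDS:
            raise ValueError(
                f"unknown plot kind {self.kind!r}; known: {PLOT_KINDS}"
            )
        if self.kind == "line_performance":
            if self.measure is None:
                raise ValueError("line_performance requires a measure")
            if self.measure not in MEASURES:
                raise ValueError(
                    f"unknown measure {self.measure!r}; "
                    f"known: {sorted(MEASURES)}"
                )


def _ordered(values, canonical) -> list:
    vals = list(dict.fromkeys(values))
    return sorted(vals, key=lambda v: (canonical.index(v) if v in canonical else len(canonical), v))


def make_table5(performance: pd.DataFrame) -> pd.DataFrame:
    """Wide table of mean estimates: rows (DGM, n), columns (grid, method).

    Mirrors the study's headline estimate table, rounded to 3 decimal
    places for display.  Scenario cells absent from the input appear as
    NaN gap markers rather than being silently dropped.
    """
    required = {"effect_x", "grid", "n", "method", "mean_estimate"}
    missing = required - set(performance.columns)
    if missing:
        raise ValueError(f"performance table lacks columns: {sorted(missing)}")
    df = performance.copy()
    df["dgm"] = df["effect_x"].map(lambda x: DGM_NUMBERS.get(x, f"x={x:g}"))
    wide = df.pivot_table(
        index=["dgm", "n"],
        columns=["grid", "method"],
        values="mean_estimate",
        aggfunc="mean",
    )
    grids = _ordered(df["grid"], list(DEFAULT_GRIDS))
    methods = _ordered(df["method"], list(METHODS))
    cols = pd.MultiIndex.from_product([grids, methods], names=["grid", "method"])
    dgms = _ordered(df["dgm"], [DGM_NUMBERS[x] for x in DEFAULT_EFFECTS])
    ns = sorted(df["n"].unique())
    rows = pd.MultiIndex.from_product([dgms, ns], names=["dgm", "n"])
    return wide.reindex(index=rows, columns=cols).round(3)


def _facet_grid(df: pd.DataFrame):
    grids = _ordered(df["grid"], list(DEFAULT_GRIDS))
    effects = sorted(df["effect_x"].unique())
    return grids, effects


def _dgm_title(x: float) -> str:
    num = DGM_NUMBERS.get(x)
    return f"DGM {num} (x={x:g})" if num else f"x={x:g}"


_METHOD_STYLE = {
    "mlr": dict(color="#1f77b4", marker="o"),
    "tobit": dict(color="#d62728", marker="s"),
    "median": dict(color="#2ca02c", marker="^"),
}


def _save(fig, output_dir: Path, stem: str, formats: Sequence[str]) -> list[Path]:
    output_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fmt in formats:
        path = output_dir / f"{stem}.{fmt}"
        fig.savefig(path, bbox_inches="tight")
        paths.append(path)
    plt.close(fig)
    return paths


def make_performance_plots(
    performance: pd.DataFrame,
    measure: str,
    output_dir: str | Path,
    reference_lines: Sequence[float] | None = None,
    formats: Sequence[str] = ("png", "svg"),
) -> list[Path]:
    """Line plots of one performance measure against sample size.

    One panel per (grid x DGM), one line per method, with a dashed
    reference line (0 for bias/MSE, 0.95 for coverage, 0.05 for the
    Type I error panel of the rejection plot).
    """
    if measure not in MEASURES:
        raise ValueError(
            f"unknown measure {measure!r}; known: {sorted(MEASURES)}"
        )
    col = _MEASURE_COLUMNS[measure]
    df = performance
    if df.empty:
        raise ValueError("empty performance table")
    grids, effects = _facet_grid(df)
    methods = _ordered(df["method"], list(METHODS))
    if not methods:
        raise ValueError("no methods present in performance table")
    fig, axes = plt.subplots(
        len(grids),
        len(effects),
        figsize=(3.0 * len(effects), 2.6 * len(grids)),
        sharex=True,
        squeeze=False,
    )
    for i, grid in enumerate(grids):
        for j, x in enumerate(effects):
            ax = axes[i][j]
            cell = df[(df["grid"] == grid) & (df["effect_x"] == x)]
            for m in methods:
                sub = cell[cell["method"] == m].sort_values("n")
                ax.plot(
                    sub["n"], sub[col], label=m.upper(),
                    markersize=3.5, linewidth=1.2,
                    **_METHOD_STYLE.get(m, {}),
                )
            refs = reference_lines
            if refs is None:
                default = MEASURES[measure]
                # the 0.05 reference is for Type I error (null DGM only)
                if measure == "rejection" and x != 0.0:
                    default = None
                refs = () if default is None else (default,)
            for r in refs:
                ax.axhline(r, linestyle="--", color="grey", linewidth=0.9)
            if i == 0:
                ax.set_title(_dgm_title(x), fontsize=9)
            if j == 0:
                ax.set_ylabel(f"{grid}\n{measure}", fontsize=9)
            if i == len(grids) - 1:
                ax.set_xlabel("total sample size")
    axes[0][0].legend(fontsize=7)
    fig.suptitle(f"{measure} by sample size", y=1.02, fontsize=11)
    fig.tight_layout()
    return _save(fig, Path(output_dir), f"{measure}_lines", formats)


def make_estimate_histograms(
    estimates: pd.DataFrame,
    performance: pd.DataFrame,
    output_dir: str | Path,
    n: int | None = None,
    formats: Sequence[str] = ("png", "svg"),
) -> list[Path]:
    """Histograms of per-repetition estimates, faceted grid x DGM per method."""
    df = _join_scenario_info(estimates, performance)
    if n is not None:
        df = df[df["n"] == n]
    if df.empty:
        raise ValueError("no estimates to plot")
    paths = []
    grids, effects = _facet_grid(df)
    for m in _ordered(df["method"], list(METHODS)):
        fig, axes = plt.subplots(
            len(grids),
            len(effects),
            figsize=(3.0 * len(effects), 2.4 * len(grids)),
            squeeze=False,
        )
        for i, grid in enumerate(grids):
            for j, x in enumerate(effects):
                ax = axes[i][j]
                sub = df[
                    (df["grid"] == grid)
                    & (df["effect_x"] == x)
                    & (df["method"] == m)
                    & df["converged"]
                ]
                if len(sub):
                    ax.hist(sub["estimate"], bins=60, color="#777777")
                ax.axvline(0.0, linestyle=":", color="black", linewidth=0.8)
                ax.axvline(x, linestyle="--", color="black", linewidth=0.8)
                if i == 0:
                    ax.set_title(_dgm_title(x), fontsize=9)
                if j == 0:
                    ax.set_ylabel(grid, fontsize=9)
        fig.suptitle(f"{m.upper()} estimates", y=1.02, fontsize=11)
        fig.tight_layout()
        paths += _save(fig, Path(output_dir), f"estimates_hist_{m}", formats)
    return paths


def make_estimate_se_scatter(
    estimates: pd.DataFrame,
    performance: pd.DataFrame,
    output_dir: str | Path,
    n: int | None = None,
    formats: Sequence[str] = ("png", "svg"),
) -> list[Path]:
    """Scatter of estimates against their standard errors per method."""
    df = _join_scenario_info(estimates, performance)
    if n is not None:
        df = df[df["n"] == n]
    df = df[df["converged"]]
    if df.empty:
        raise ValueError("no estimates to plot")
    paths = []
    grids, effects = _facet_grid(df)
    for m in _ordered(df["method"], list(METHODS)):
        fig, axes = plt.subplots(
            len(grids),
            len(effects),
            figsize=(3.0 * len(effects), 2.4 * len(grids)),
            squeeze=False,
        )
        for i, grid in enumerate(grids):
            for j, x in enumerate(effects):
                ax = axes[i][j]
                sub = df[
                    (df["grid"] == grid)
                    & (df["effect_x"] == x)
                    & (df["method"] == m)
                ]
                ax.plot(sub["estimate"], sub["se"], ".", markersize=1.5,
                        alpha=0.4, color="#444444")
                if i == 0:
                    ax.set_title(_dgm_title(x), fontsize=9)
                if j == 0:
                    ax.set_ylabel(f"{grid}\nSE", fontsize=9)
        fig.suptitle(f"{m.upper()} estimates vs SE", y=1.02, fontsize=11)
        fig.tight_layout()
        paths += _save(fig, Path(output_dir), f"est_vs_se_{m}", formats)
    return paths


def make_method_scatter(
    estimates: pd.DataFrame,
    performance: pd.DataFrame,
    output_dir: str | Path,
    baseline: str = "mlr",
    n: int | None = None,
    formats: Sequence[str] = ("png", "svg"),
) -> list[Path]:
    """Scatter of each method's estimates against the baseline method's."""
    df = _join_scenario_info(estimates, performance)
    if n is not None:
        df = df[df["n"] == n]
    df = df[df["converged"]]
    others = [m for m in _ordered(df["method"], list(METHODS)) if m != baseline]
    if df.empty or not others:
        raise ValueError("need converged estimates from at least two methods")
    base = df[df["method"] == baseline].set_index(["scenario_id", "rep"])[
        "estimate"
    ]
    paths = []
    grids, effects = _facet_grid(df)
    for m in others:
        other = df[df["method"] == m].set_index(["scenario_id", "rep"])
        joined = other.join(base.rename("base_estimate"), how="inner")
        fig, axes = plt.subplots(
            len(grids),
            len(effects),
            figsize=(3.0 * len(effects), 2.4 * len(grids)),
            squeeze=False,
        )
        for i, grid in enumerate(grids):
            for j, x in enumerate(effects):
                ax = axes[i][j]
                sub = joined[(joined["grid"] == grid) & (joined["effect_x"] == x)]
                ax.plot(sub["base_estimate"], sub["estimate"], ".",
                        markersize=1.5, alpha=0.4, color="#444444")
                lims = ax.get_xlim()
                ax.plot(lims, lims, "--", color="grey", linewidth=0.8)
                if i == 0:
                    ax.set_title(_dgm_title(x), fontsize=9)
                if j == 0:
                    ax.set_ylabel(f"{grid}\n{m}", fontsize=9)
        fig.suptitle(f"{m.upper()} vs {baseline.upper()}", y=1.02, fontsize=11)
        fig.tight_layout()
        paths += _save(fig, Path(output_dir), f"{m}_vs_{baseline}", formats)
    return paths


def _join_scenario_info(
    estimates: pd.DataFrame, performance: pd.DataFrame
) -> pd.DataFrame:
    info = performance[["scenario_id", "effect_x", "grid", "n"]].drop_duplicates()
    return estimates.merge(info, on="scenario_id", how="inner")


def render(
    spec: PlotSpec,
    performance: pd.DataFrame,
    output_dir: str | Path,
    estimates: pd.DataFrame | None = None,
    **kwargs,
) -> list[Path]:
    """Dispatch a :class:`PlotSpec` to the matching plotting function."""
    if spec.kind == "line_performance":
        return make_performance_plots(
            performance, spec.measure, output_dir,
            reference_lines=spec.reference_lines, **kwargs,
        )
    if estimates is None:
        raise ValueError(f"plot kind {spec.kind!r} needs the estimates table")
    if spec.kind == "histogram":
        return make_estimate_histograms(estimates, performance, output_dir, **kwargs)
    if spec.kind == "scatter_est_se":
        return make_estimate_se_scatter(estimates, performance, output_dir, **kwargs)
    return make_method_scatter(estimates, performance, output_dir, **kwargs)
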