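"""Latent-normal data-generating mechanisms for discretised PRO scores.

The simulated instrument mimics an SF-36-style patient-reported outcome
(PRO) dimension score in a balanced two-arm randomised trial.  An
underlying continuous score follows ``Normal(mu, sigma**2)``; subjects in
the treatment arm receive a pure location shift ``effect_x``; scores are
then clamped to the instrument's 0-100 range and snapped onto a k-level
discrete grid.  The three built-in grids correspond to the SF-36
role-limitation-emotional (k=4), bodily-pain (k=10) and mental-health
(k=26) dimension scales.

Common random numbers: the pre-shift latent draws for a repetition depend
only on ``(seed, n, rep_index)`` — never on the treatment effect or the
grid — so the same base sample is reused across all effect sizes and all
discretisation levels, as in the original simulation design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoreGrid",
    "ScenarioSpec",
    "TrialDataset",
    "make_grid",
    "grid_from_label",
    "latent_stream",
    "generate_latent",
    "clamp_and_discretise",
    "generate_trial",
    "BUILTIN_GRID_LABELS",
]

# Built-in SF-36 dimension grids: printed score values and the interior
# bin boundaries of the left-open/right-closed discretisation intervals.
# Note the k=10 scores are the instrument's printed values, which are not
# all arithmetic midpoints (55.6 and 66.7, not 55.5 and 66.6).
_BUILTIN_SCORES = {
    4: (0.0, 33.3, 66.6, 100.0),
    10: (0.0, 11.1, 22.2, 33.3, 44.4, 55.6, 66.7, 77.8, 88.9, 100.0),
    26: tuple(float(v) for v in range(0, 101, 4)),
}
_BUILTIN_EDGES = {
    4: (16.65, 49.95, 83.25),
    10: (5.55, 16.65, 27.75, 38.85, 49.95, 61.05, 72.15, 83.25, 94.35),
    26: tuple(float(v) for v in range(2, 99, 4)),
}
_BUILTIN_LABELS = {4: "RE4", 10: "BP10", 26: "MH26"}

#: label -> k for the three built-in SF-36 dimension grids
BUILTIN_GRID_LABELS = {label: k for k, label in _BUILTIN_LABELS.items()}


@dataclass(frozen=True)
class ScoreGrid:
    """A discrete 0-100 scoring grid with k levels.

    ``scores`` are the printed discrete values the instrument can take;
    ``edges`` are the k-1 interior boundaries of the left-open /
    right-closed discretisation intervals ``(edges[j-1], edges[j]]``.
    A continuous value exactly on an edge maps to the *lower* score.
    """

    k: int
    scores: tuple[float, ...]
    edges: tuple[float, ...]
    label: str

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"grid needs at least 2 levels, got k={self.k}")
        if len(self.scores) != self.k:
            raise ValueError(
                f"expected {self.k} scores, got {len(self.scores)}"
            )
        if len(self.edges) != self.k - 1:
            raise ValueError(
                f"expected {self.k - 1} edges, got {len(self.edges)}"
            )
        if self.scores[0] != 0.0 or self.scores[-1] != 100.0:
            raise ValueError("scores must span the 0-100 scale exactly")
        for j in range(self.k - 1):
            if self.scores[j + 1] <= self.scores[j]:
                raise ValueError(
                    f"scores not strictly increasing at index {j + 1}"
                )
        for j in range(self.k - 2):
            if self.edges[j + 1] <= self.edges[j]:
                raise ValueError(
                    f"edges not strictly increasing at index {j + 1}"
                )
        for j, e in enumerate(self.edges):
            if not (self.scores[j] < e < self.scores[j + 1]):
                raise ValueError(
                    f"edge {e} at index {j} lies outside its score bracket "
                    f"({self.scores[j]}, {self.scores[j + 1]})"
                )

    @property
    def score_array(self) -> np.ndarray:
        return np.asarray(self.scores, dtype=float)

    @property
    def edge_array(self) -> np.ndarray:
        return np.asarray(self.edges, dtype=float)


def make_grid(
    k: int,
    scores: Sequence[float] | None = None,
    edges: Sequence[float] | None = None,
    label: str | None = None,
) -> ScoreGrid:
    """Build a validated :class:`ScoreGrid`.

    With ``scores``/``edges`` omitted, ``k`` in {4, 10, 26} selects the
    built-in SF-36 dimension grid (RE4, BP10, MH26); any other ``k``
    produces a generic equally spaced grid with scores ``100*j/(k-1)``
    and midpoint edges.
    """
    if k < 2:
        raise ValueError(f"grid needs at least 2 levels, got k={k}")
    if scores is None and edges is None:
        if k in _BUILTIN_SCORES:
            return ScoreGrid(
                k=k,
                scores=_BUILTIN_SCORES[k],
                edges=_BUILTIN_EDGES[k],
                label=label or _BUILTIN_LABELS[k],
            )
        vals = tuple(100.0 * j / (k - 1) for j in range(k))
        mids = tuple((vals[j] + vals[j + 1]) / 2.0 for j in range(k - 1))
        return ScoreGrid(k=k, scores=vals, edges=mids, label=label or f"G{k}")
    if scores is None or edges is None:
        raise ValueError("provide both scores and edges, or neither")
    return ScoreGrid(
        k=k,
        scores=tuple(float(s) for s in scores),
        edges=tuple(float(e) for e in edges),
        label=label or f"G{k}",
    )


def grid_from_label(label: str) -> ScoreGrid:
    """Resolve a built-in grid label ('RE4', 'BP10', 'MH26')."""
    try:
        return make_grid(BUILTIN_GRID_LABELS[label])
    except KeyError:
        raise ValueError(
            f"unknown grid label {label!r}; "
            f"known: {sorted(BUILTIN_GRID_LABELS)}"
        ) from None


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation cell of the factorial study design.

    ``effect_x`` is the location shift added to treatment-arm latent
    scores (the predefined 'truth' on the latent scale); ``n`` is the
    total sample size, split half-and-half between arms.
    """

    mu: float
    sigma: float
    effect_x: float
    n: int
    grid: ScoreGrid
    nsim: int = 5000
    alpha: float = 0.05
    seed: int = 0
    scenario_id: str = ""

    def __post_init__(self) -> None:
        if self.n < 2 or self.n % 2 != 0:
            raise ValueError(f"n must be even and >= 2 (balanced arms), got {self.n}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.nsim < 1:
            raise ValueError(f"nsim must be >= 1, got {self.nsim}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class TrialDataset:
    """One simulated two-arm trial.

    ``arm`` is 0 for control, 1 for treatment (balanced); ``latent`` the
    unbounded normal draws (shift already applied in the treatment arm),
    ``clamped`` the same values clipped to [0, 100], and ``observed`` the
    discrete grid scores actually 'recorded' for each subject.
    """

    arm: np.ndarray
    latent: np.ndarray
    clamped: np.ndarray
    observed: np.ndarray
    rep_index: int = 0

    def to_frame(self, scenario_id: str = "") -> pd.DataFrame:
        """Tidy per-subject export (one row per subject)."""
        return pd.DataFrame(
            {
                "scenario_id": scenario_id,
                "rep": self.rep_index,
                "subject": np.arange(self.arm.size),
                "arm": self.arm,
                "latent": self.latent,
                "observed": self.observed,
            }
        )


def latent_stream(seed: int, n: int, rep_index: int) -> np.random.Generator:
    """The base RNG stream for one repetition at one sample size.

    Keyed by (seed, n, rep_index) only, so the identical pre-shift latent
    sample is shared across treatment effects and grids (common random
    numbers), while different sample sizes use independent substreams.
    """
    return np.random.default_rng([seed, n, rep_index])


def generate_latent(
    spec: ScenarioSpec, rep_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw latent scores for one repetition: (control, treatment) arms.

    The treatment arm is the second half of the common base sample with
    ``effect_x`` added post hoc, so the base draws are invariant to the
    effect size and the grid.
    """
    rng = latent_stream(spec.seed, spec.n, rep_index)
    base = rng.normal(spec.mu, spec.sigma, spec.n)
    half = spec.n // 2
    return base[:half], base[half:] + spec.effect_x


def clamp_and_discretise(values, grid: ScoreGrid):
    """Clamp to [0, 100], then snap onto the grid's discrete scores.

    Values in ``(edges[j-1], edges[j]]`` map to ``scores[j]`` with
    ``edges[-1] = -inf`` and ``edges[k-1] = +inf``; a value exactly on an
    edge maps to the lower score.  Scalar in, scalar out.
    """
    arr = np.asarray(values, dtype=float)
    clipped = np.clip(arr, 0.0, 100.0)
    idx = np.searchsorted(grid.edge_array, clipped, side="left")
    out = grid.score_array[idx]
    if arr.ndim == 0:
        return float(out)
    return out


def generate_trial(spec: ScenarioSpec, rep_index: int) -> TrialDataset:
    """Assemble one simulated trial: draw, shift, clamp, discretise.

    Deterministic given (seed, rep_index, n, mu, sigma, effect_x, grid);
    changing only the grid changes ``observed`` but not ``latent``.
    """
    control, treatment = generate_latent(spec, rep_index)
    half = spec.n // 2
    latent = np.concatenate([control, treatment])
    arm = np.repeat([0, 1], half)
    clamped = np.clip(latent, 0.0, 100.0)
    observed = clamp_and_discretise(latent, spec.grid)
    return TrialDataset(
        arm=arm,
        latent=latent,
        clamped=clamped,
        observed=observed,
        rep_index=rep_index,
    )
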