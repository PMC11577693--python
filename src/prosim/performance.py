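"""Performance measures for a scenario's collection of fit results.

Standard simulation-study summaries of the repeated estimates
``x_hat_i`` against the predefined latent truth ``x``: bias, empirical
standard error, mean squared error, CI coverage and the rejection rate
of the two-sided Wald/t test (Type I error when x=0, power otherwise),
each with its Monte Carlo standard error.

Non-converged fits are excluded listwise: every measure is computed over
the ``n_valid`` converged repetitions and the missing count is reported
alongside.  Performance is always assessed against the latent-scale
truth even though discretisation makes that truth unobservable for
non-zero effects, so part of the reported "bias" is a discretisation
artefact by design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .estimators import FitResult

__all__ = [
    "PerformanceRow",
    "bias",
    "empirical_se",
    "mse",
    "coverage",
    "rejection_rate",
    "monte_carlo_ses",
    "summarise_fits",
]


def bias(estimates: Sequence[float], true_x: float) -> float:
    """Mean estimate minus the predefined truth."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("bias undefined for an empty estimate vector")
    return float(est.mean() - true_x)


def empirical_se(estimates: Sequence[float]) -> float:
    """Sample SD of the estimates across repetitions (n-1 divisor)."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("empirical SE needs at least 2 estimates")
    return float(est.std(ddof=1))


def mse(estimates: Sequence[float], true_x: float) -> float:
    """Mean squared deviation from the truth (1/n divisor)."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("MSE undefined for an empty estimate vector")
    return float(((est - true_x) ** 2).mean())


def coverage(
    ci_lows: Sequence[float], ci_upps: Sequence[float], true_x: float
) -> float:
    """Fraction of closed intervals [low, upp] containing the truth."""
    lo = np.asarray(ci_lows, dtype=float)
    up = np.asarray(ci_upps, dtype=float)
    if lo.shape != up.shape:
        raise ValueError("CI bound vectors must have equal length")
    if lo.size == 0:
        raise ValueError("coverage undefined for empty CI vectors")
    return float(np.mean((lo <= true_x) & (true_x <= up)))


def rejection_rate(p_values: Sequence[float], alpha: float) -> float:
    """Fraction of repetitions with p <= alpha (inclusive)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("rejection rate undefined for an empty p vector")
    if np.any((p < 0.0) | (p > 1.0) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return float(np.mean(p <= alpha))


@dataclass(frozen=True)
class PerformanceRow:
    """One (scenario x method) summary row."""

    scenario_id: str
    method: str
    n_valid: int
    n_missing: int
    mean_estimate: float
    bias: float
    emp_se: float
    mse: float
    coverage: float
    rejection_rate: float
    mcse_bias: float = np.nan
    mcse_emp_se: float = np.nan
    mcse_coverage: float = np.nan
    mcse_rejection: float = np.nan


def monte_carlo_ses(row: PerformanceRow) -> PerformanceRow:
    """Fill in the Monte Carlo SEs of a summary row.

    mcse(bias) = EmpSE/sqrt(n); mcse(EmpSE) = EmpSE/sqrt(2(n-1));
    mcse(rate) = sqrt(rate*(1-rate)/n) for coverage and rejection.
    """
    n = row.n_valid
    if n < 2:
        return row
    return replace(
        row,
        mcse_bias=row.emp_se / np.sqrt(n),
        mcse_emp_se=row.emp_se / np.sqrt(2.0 * (n - 1)),
        mcse_coverage=float(np.sqrt(row.coverage * (1.0 - row.coverage) / n)),
        mcse_rejection=float(
            np.sqrt(row.rejection_rate * (1.0 - row.rejection_rate) / n)
        ),
    )


def summarise_fits(
    fits: Sequence[FitResult],
    true_x: float,
    alpha: float,
    scenario_id: str = "",
    method: str = "",
) -> PerformanceRow:
    """Summarise one method's repeated fits into a performance row.

    ``len(fits)`` is taken as nsim; non-converged entries count as
    missing and are excluded from every measure.  With fewer than 2
    valid fits the spread/rate measures are NaN (insufficient data).
    """
    ok = [f for f in fits if f.converged]
    n_valid = len(ok)
    n_missing = len(fits) - n_valid
    if not method and fits:
        method = fits[0].method
    if n_valid == 0:
        nan = float("nan")
        return PerformanceRow(
            scenario_id, method, 0, n_missing, nan, nan, nan, nan, nan, nan
        )
    est = np.array([f.estimate for f in ok], dtype=float)
    row = PerformanceRow(
        scenario_id=scenario_id,
        method=method,
        n_valid=n_valid,
        n_missing=n_missing,
        mean_estimate=float(est.mean()),
        bias=bias(est, true_x),
        emp_se=empirical_se(est) if n_valid >= 2 else float("nan"),
        mse=mse(est, true_x),
        coverage=coverage(
            [f.ci_low for f in ok], [f.ci_upp for f in ok], true_x
        ),
        rejection_rate=rejection_rate([f.p_value for f in ok], alpha),
    )
    return monte_carlo_ses(row)
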