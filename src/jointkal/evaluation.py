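"""Accuracy metrics for corrected joint trajectories.

The accuracy of a processed trajectory against the known ground-truth arc is
measured in the (x, z) plane only — the protocol fixes the y coordinate, so
planar error is the meaningful quantity:

    E = (1/n) * sum_i sqrt((x(i) - x0(i))^2 + (z(i) - z0(i))^2)

Runs are summarized per method as mean +/- sample standard deviation, and
methods are compared by their relative improvement in mean error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["ErrorReport", "mean_planar_error", "improvement_pct", "summarize_runs"]


@dataclass
class ErrorReport:
    """Per-run planar errors of one method plus their mean and sample SD."""

    method_name: str
    per_run_error: list[float]
    mean: float
    sd: float
    single_run: bool = False


def mean_planar_error(est: np.ndarray, truth: np.ndarray) -> float:
    """Mean Euclidean distance in the (x, z) plane; the y coordinate is ignored."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape or est.ndim != 2 or est.shape[1] != 3:
        raise ValidationError("estimate and truth must share shape (n, 3)")
    if est.shape[0] < 1:
        raise ValidationError("need at least one frame")
    dx = est[:, 0] - truth[:, 0]
    dz = est[:, 2] - truth[:, 2]
    return float(np.mean(np.hypot(dx, dz)))


def improvement_pct(e_base: float, e_new: float) -> float:
    """Relative accuracy improvement (e_base - e_new) / e_base * 100 (percent)."""
    if not e_base > 0:
        raise ValidationError("baseline error must be > 0")
    return (e_base - e_new) / e_base * 100.0


def summarize_runs(per_run_errors: dict[str, list[float]]) -> list[ErrorReport]:
    """Per-method mean and sample (n-1) standard deviation of run errors.

    A single-run method gets SD = 0 with ``single_run`` flagged, since the
    sample SD is undefined there.
    """
    reports = []
    for method, errors in per_run_errors.items():
        errors = [float(e) for e in errors]
        if not errors:
            raise ValidationError(f"method {method!r} has no runs")
        single = len(errors) == 1
        sd = 0.0 if single else float(np.std(errors, ddof=1))
        reports.append(ErrorReport(method_name=method, per_run_error=errors,
                                   mean=float(np.mean(errors)), sd=sd,
                                   single_run=single))
    return reports


def summary_table(reports: list[ErrorReport], decimals: int = 3) -> pd.DataFrame:
    """Display table (method, mean, sd, n_runs), rounded for presentation."""
    return pd.DataFrame({
        "method": [r.method_name for r in reports],
        "mean_error_m": [round(r.mean, decimals) for r in reports],
        "sd_m": [round(r.sd, decimals) for r in reports],
        "n_runs": [len(r.per_run_error) for r in reports],
    })
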