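"""Reconstruction-quality metrics: SNR, matching rate, RMSE.

All three derive from the relative L2 error rho = ||x - x_hat|| / ||x||:
SNR = -20 log10(rho) in dB, MR = 1 - rho, RMSE = ||x - x_hat|| / sqrt(N);
hence SNR = -20 log10(1 - MR) and RMSE = (1 - MR) ||x|| / sqrt(N) exactly.
A perfect reconstruction reports SNR = +inf (a sentinel, never an exception,
so batch tables aggregate cleanly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedMetricError


@dataclass(frozen=True)
class QualityReport:
    """Per-reconstruction metric bundle."""

    snr_db: float
    mr: float
    rmse: float
    max_abs_residual: float


def _pair(x, x_hat) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape or x.ndim != 1:
        raise ParameterError(f"x and x_hat must be equal-length vectors, got {x.shape} vs {x_hat.shape}")
    return x, x_hat


def _rel_error(x: np.ndarray, x_hat: np.ndarray) -> float:
    x_norm = float(np.linalg.norm(x))
    if x_norm == 0.0:
        raise UndefinedMetricError("reference signal has zero norm")
    return float(np.linalg.norm(x - x_hat)) / x_norm


def snr(x, x_hat) -> float:
    """Reconstruction SNR in dB, -20 log10(||x - x_hat|| / ||x||); +inf when equal."""
    x, x_hat = _pair(x, x_hat)
    rho = _rel_error(x, x_hat)
    return math.inf if rho == 0.0 else -20.0 * math.log10(rho)


def matching_rate(x, x_hat) -> float:
    """Matching rate MR = 1 - ||x - x_hat|| / ||x|| (1 means identical)."""
    x, x_hat = _pair(x, x_hat)
    return 1.0 - _rel_error(x, x_hat)


def rmse(x, x_hat) -> float:
    """Root mean squared pointwise error."""
    x, x_hat = _pair(x, x_hat)
    return float(np.sqrt(np.mean((x - x_hat) ** 2)))


def report(x, x_hat) -> QualityReport:
    """All metrics for one reconstruction."""
    x, x_hat = _pair(x, x_hat)
    return QualityReport(
        snr_db=snr(x, x_hat),
        mr=matching_rate(x, x_hat),
        rmse=rmse(x, x_hat),
        max_abs_residual=float(np.max(np.abs(x - x_hat))),
    )


def summarize(reports: list[QualityReport]) -> pd.DataFrame:
    """Mean and standard deviation per metric over repeated runs."""
    if not reports:
        raise ParameterError("no reports to summarize")
    df = pd.DataFrame([r.__dict__ for r in reports])
    return df.agg(["mean", "std"])
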