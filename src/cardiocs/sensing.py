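"""Gaussian measurement ensembles and compressed observations.

Sensing is y = Phi @ x with Phi an M x N matrix of i.i.d. N(0, 1/M) entries,
M = round(compression_ratio * N).  The 1/M variance makes the column norms of
Phi @ D concentrate near 1 for unit-norm atoms, so correlation thresholds in
the recovery stage compare atoms on a common scale.  Ensembles are never
persisted: the (N, compression_ratio, seed) triple regenerates them exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .sparse_domain import SparseDomain


@dataclass
class MeasurementEnsemble:
    """M x N Gaussian sensing matrix plus the parameters that regenerate it."""

    phi: np.ndarray
    compression_ratio: float
    seed: int

    @property
    def m(self) -> int:
        return self.phi.shape[0]

    @property
    def n(self) -> int:
        return self.phi.shape[1]


@dataclass
class Observation:
    """Compressed measurement vector with references to its provenance."""

    y: np.ndarray
    ensemble: MeasurementEnsemble
    domain: SparseDomain | None = None


def measurement_count(n: int, compression_ratio: float) -> int:
    """M = round(CR * N), rounding half away from zero."""
    return int(math.floor(compression_ratio * n + 0.5))


def gaussian_ensemble(
    n: int, compression_ratio: float, seed: int = 0, unit_variance: bool = False
) -> MeasurementEnsemble:
    """Draw the M x N Gaussian measurement matrix.

    Entries are i.i.d. normal with variance 1/M (or 1 when ``unit_variance``),
    M = round(compression_ratio * N).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not 0 < compression_ratio <= 1:
        raise ParameterError(
            f"compression_ratio must be in (0, 1], got {compression_ratio}"
        )
    m = measurement_count(n, compression_ratio)
    if m < 1:
        raise ParameterError("compression_ratio too small: no measurement rows")
    rng = np.random.default_rng(seed)
    scale = 1.0 if unit_variance else 1.0 / math.sqrt(m)
    phi = rng.normal(0.0, scale, size=(m, n))
    return MeasurementEnsemble(phi=phi, compression_ratio=compression_ratio, seed=seed)


def sense(
    ensemble: MeasurementEnsemble, x: np.ndarray, domain: SparseDomain | None = None
) -> Observation:
    """Observe y = Phi @ x."""
    x = np.asarray(x, dtype=float)
    if x.shape != (ensemble.n,):
        raise ParameterError(f"signal length {x.shape} does not match N={ensemble.n}")
    return Observation(y=ensemble.phi @ x, ensemble=ensemble, domain=domain)


def effective_matrix(
    ensemble: MeasurementEnsemble, domain: SparseDomain | None = None, normalize: bool = True
) -> np.ndarray:
    """A = Phi @ D, the matrix whose columns the greedy solvers correlate with.

    ``domain=None`` means the identity domain (A = Phi).  With ``normalize``
    (default) the columns are rescaled to unit norm so the weak-selection
    threshold compares inner products fairly; the recovered coefficients must
    then be divided by the same column norms, which
    :func:`cardiocs.recovery.reconstruct_signal` handles via the returned
    ``column_norms``.
    """
    a = ensemble.phi if domain is None else ensemble.phi @ domain.atoms
    if not normalize:
        return a, np.ones(a.shape[1])
    norms = np.linalg.norm(a, axis=0)
    norms = np.where(norms > 1e-300, norms, 1.0)
    return a / norms, norms
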