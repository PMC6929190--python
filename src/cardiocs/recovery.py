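"""Greedy sparse recovery: OMP, SWOMP, and the staged adaptive SWAMP solver.

All three solvers share the same loop skeleton: correlate the residual with
the columns of A, select one or more atoms, re-fit the coefficients on the
selected support by least squares, and update the residual.  They differ only
in the selection rule:

* **OMP** takes the single best-correlated atom per iteration and needs the
  sparsity k (or a residual tolerance) up front.
* **SWOMP** ("stagewise weak" OMP) takes *every* atom whose correlation
  reaches a fraction ``alpha`` of the current maximum, stopping on support
  stagnation or an iteration cap.
* **SWAMP** removes both a-priori inputs.  A restricted-isometry argument
  yields an initial sparsity estimate k0 (grow k0 until the energy captured by
  the top-k0 correlations of y exceeds sqrt((1-delta_k)/(1+delta_k))*||y||),
  the weak threshold is auto-corrected so the first selection has between k0
  and Smax candidates, and subsequent stages add at most L = stage * L0 atoms
  above the threshold, sorted by correlation.  The support may never exceed
  Smax = floor(M/2); termination is by residual tolerance, support cap, or
  stagnation.

Least-squares fits use a rank-revealing factorization (``numpy.linalg.lstsq``)
which returns the minimum-norm solution on rank-deficient supports (with a
warning).  After every fit the residual is orthogonal to the selected columns,
so residual norms are non-increasing and supports are nested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ParameterError
from .sparse_domain import SparseDomain

__all__ = [
    "RecoveryResult",
    "SwampConfig",
    "omp",
    "swomp",
    "estimate_initial_sparsity",
    "swamp",
    "reconstruct_signal",
]


@dataclass
class RecoveryResult:
    """Outcome of a greedy recovery run.

    ``theta_hat`` lives in the coordinates of the (possibly column-normalized)
    matrix A that was passed to the solver; ``stage_trace`` rows are
    (stage, step L, support size, residual norm).
    """

    theta_hat: np.ndarray
    support: list[int]
    residual_norm: float
    iterations: int
    stage_trace: list[tuple[int, int, int, float]] = field(default_factory=list)
    terminated_by: str = "max_iter"


@dataclass(frozen=True)
class SwampConfig:
    """Tunable parameters of the SWAMP solver.

    alpha : weak-selection threshold weight, 0 < alpha <= 1.
    l0 : initial step size (atoms added per stage grows as stage * l0).
    delta_k : restricted-isometry constant used by the sparsity pre-estimate.
    smax_fraction : support cap as a fraction of M (cap = floor(fraction * M)).
    eps1 : residual-norm termination tolerance; absolute unless
        ``eps_relative`` makes it a fraction of ||y||.
    alpha_adjust : multiplicative threshold correction factor in (0, 1).
    max_stages : hard cap on the number of staged passes.
    compound_step : grow the step as L = stage * L_prev instead of stage * l0.
    """

    alpha: float = 0.83
    l0: int = 5
    delta_k: float = 0.3
    smax_fraction: float = 0.5
    eps1: float = 1e-3
    eps_relative: bool = False
    alpha_adjust: float = 0.95
    max_stages: int = 500
    compound_step: bool = False

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ParameterError("alpha must satisfy 0 < alpha <= 1")
        if self.l0 < 1:
            raise ParameterError("initial step l0 must be >= 1")
        if not 0 <= self.delta_k < 1:
            raise ParameterError("delta_k must be in [0, 1)")
        if not 0 < self.smax_fraction <= 1:
            raise ParameterError("smax_fraction must be in (0, 1]")
        if not 0 < self.alpha_adjust < 1:
            raise ParameterError("alpha_adjust must be in (0, 1)")


def _check_inputs(y: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or y.ndim != 1 or a.shape[0] != y.size:
        raise ParameterError(f"shape mismatch: y has {y.shape}, A has {a.shape}")
    return y, a


def _least_squares(a_sub: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares fit on the support; minimum-norm + warning when rank-deficient."""
    coef, _, rank, _ = np.linalg.lstsq(a_sub, y, rcond=None)
    if rank < a_sub.shape[1]:
        warnings.warn(
            f"rank-deficient support matrix (rank {rank} < {a_sub.shape[1]});"
            " using the minimum-norm solution"
        )
    return coef


def _result(a, y, support, trace, iterations, terminated_by) -> RecoveryResult:
    theta = np.zeros(a.shape[1])
    if support:
        coef = _least_squares(a[:, support], y)
        theta[support] = coef
        r = y - a[:, support] @ coef
    else:
        r = y.copy()
    return RecoveryResult(
        theta_hat=theta,
        support=list(support),
        residual_norm=float(np.linalg.norm(r)),
        iterations=iterations,
        stage_trace=trace,
        terminated_by=terminated_by,
    )


def omp(
    y: np.ndarray,
    a: np.ndarray,
    sparsity: int | None = None,
    tol: float | None = None,
) -> RecoveryResult:
    """Orthogonal matching pursuit: one best-correlated atom per iteration.

    Runs for ``sparsity`` iterations, or until the residual norm drops below
    ``tol`` if a tolerance is given instead.  Ties in the correlation argmax
    break toward the lower index.
    """
    y, a = _check_inputs(y, a)
    m, n = a.shape
    if sparsity is None and tol is None:
        raise ParameterError("omp needs sparsity or tol")
    k_max = min(sparsity if sparsity is not None else m, m, n)
    support: list[int] = []
    in_support = np.zeros(n, dtype=bool)
    r = y.copy()
    trace: list[tuple[int, int, int, float]] = []
    it = 0
    terminated = "max_iter"
    zero_guard = 1e-14 * max(float(np.linalg.norm(y)), 1.0)
    while it < k_max:
        r_norm = float(np.linalg.norm(r))
        if tol is not None and r_norm <= tol:
            terminated = "residual_tol"
            break
        if r_norm <= zero_guard:
            terminated = "residual_tol"
            break
        u = np.abs(a.T @ r)
        u[in_support] = -1.0
        best = int(np.argmax(u))  # argmax returns the lowest index on ties
        if u[best] <= 0:
            terminated = "stagnation"
            break
        support.append(best)
        in_support[best] = True
        coef = _least_squares(a[:, support], y)
        r = y - a[:, support] @ coef
        it += 1
        trace.append((it, 1, len(support), float(np.linalg.norm(r))))
    if tol is not None and float(np.linalg.norm(r)) <= tol:
        terminated = "residual_tol"
    return _result(a, y, support, trace, it, terminated)


def swomp(
    y: np.ndarray,
    a: np.ndarray,
    alpha: float = 0.83,
    max_iterations: int = 20,
    tol: float = 0.0,
) -> RecoveryResult:
    """Stagewise weak OMP: select every atom with |<r, a_i>| >= alpha * max.

    Stops when the support stagnates (no new atom passes the threshold), when
    the iteration budget ``max_iterations`` is exhausted, or — as a numerical
    guard — when the residual norm falls to ``tol`` (default exact zero).
    """
    y, a = _check_inputs(y, a)
    if not 0 < alpha <= 1:
        raise ParameterError("alpha must satisfy 0 < alpha <= 1")
    if max_iterations < 1:
        raise ParameterError("max_iterations must be >= 1")
    n = a.shape[1]
    support: list[int] = []
    in_support = np.zeros(n, dtype=bool)
    r = y.copy()
    trace: list[tuple[int, int, int, float]] = []
    terminated = "max_iter"
    it = 0
    for it in range(1, max_iterations + 1):
        if np.linalg.norm(r) <= max(tol, 1e-12 * max(np.linalg.norm(y), 1.0)):
            terminated = "residual_tol" if tol > 0 else "stagnation"
            it -= 1
            break
        u = np.abs(a.T @ r)
        th = alpha * float(u.max())
        new = np.flatnonzero((u >= th) & ~in_support)
        if new.size == 0:
            terminated = "stagnation"
            it -= 1
            break
        support.extend(int(i) for i in new)
        in_support[new] = True
        coef = _least_squares(a[:, support], y)
        r = y - a[:, support] @ coef
        trace.append((it, len(new), len(support), float(np.linalg.norm(r))))
        if len(support) >= min(a.shape):
            terminated = "support_cap"
            break
    return _result(a, y, support, trace, it, terminated)


def estimate_initial_sparsity(
    y: np.ndarray,
    a: np.ndarray,
    l0: int = 5,
    delta_k: float = 0.3,
    cap: int | None = None,
) -> int:
    """Initial sparsity estimate k0 from the restricted-isometry test.

    Starting at k0 = 1 with Lambda0 the indices of the k0 largest |A^T y|,
    increment k0 by ``l0`` while ||A_Lambda0^T y|| <= sqrt((1-dk)/(1+dk)) ||y||;
    the first k0 that passes is returned (an under-estimate of the true
    sparsity under the restricted isometry property).  y = 0 gives 0; the
    estimate is capped at ``cap`` (with a warning when the cap binds).
    """
    y, a = _check_inputs(y, a)
    if not 0 <= delta_k < 1:
        raise ParameterError("delta_k must be in [0, 1)")
    if l0 < 1:
        raise ParameterError("l0 must be >= 1")
    y_norm = float(np.linalg.norm(y))
    if y_norm == 0.0:
        return 0
    n = a.shape[1]
    cap = n if cap is None else min(cap, n)
    threshold = np.sqrt((1.0 - delta_k) / (1.0 + delta_k)) * y_norm
    u = np.abs(a.T @ y)
    # the test only ever looks at the sorted correlation prefix, so the whole
    # k0 loop collapses to one sort + cumulative sum
    cum = np.sqrt(np.cumsum(np.sort(u)[::-1] ** 2))
    k0 = 1
    while cum[min(k0, n) - 1] <= threshold:
        if k0 >= cap:
            warnings.warn(f"initial-sparsity estimate hit the cap {cap}")
            return cap
        k0 += l0
    return min(k0, cap)


def _select_descending(u: np.ndarray, mask_available: np.ndarray, th: float) -> np.ndarray:
    """Indices with u >= th among available atoms, sorted by descending u
    (ties toward the lower index)."""
    cand = np.flatnonzero((u >= th) & mask_available)
    if cand.size == 0:
        return cand
    order = np.argsort(-u[cand], kind="stable")
    return cand[order]


def swamp(y: np.ndarray, a: np.ndarray, config: SwampConfig | None = None) -> RecoveryResult:
    """Sparsity-adaptive weak matching pursuit (staged SWOMP refinement).

    See the module docstring for the algorithm.  The support never exceeds
    Smax = floor(smax_fraction * M); when a stage's union would exceed it the
    solver terminates with the previous support's estimate
    (``terminated_by="support_cap"``).
    """
    y, a = _check_inputs(y, a)
    cfg = config if config is not None else SwampConfig()
    m, n = a.shape
    smax = max(1, int(np.floor(cfg.smax_fraction * m)))
    eps = cfg.eps1 * (np.linalg.norm(y) if cfg.eps_relative else 1.0)

    if float(np.linalg.norm(y)) == 0.0:
        return _result(a, y, [], [], 0, "stagnation")

    # --- initial sparsity estimate (restricted-isometry test) ---
    k0 = estimate_initial_sparsity(y, a, l0=cfg.l0, delta_k=cfg.delta_k, cap=smax)
    k0 = max(1, k0)

    # --- threshold correction: first selection must offer in [k0, Smax] atoms ---
    alpha = cfg.alpha
    u = np.abs(a.T @ y)
    u_max = float(u.max())
    for _ in range(100):
        t = int(np.count_nonzero(u >= alpha * u_max))
        if t < k0:
            alpha *= cfg.alpha_adjust
        elif t > smax:
            alpha = min(1.0, alpha / cfg.alpha_adjust)
            if alpha == 1.0 and int(np.count_nonzero(u >= u_max)) > smax:
                break  # degenerate ties; give up bracketing
        else:
            break
    else:
        raise ConfigurationError(
            f"threshold correction failed to bracket [{k0}, {smax}] candidates"
            f" within 100 adjustments (M={m}, N={n}, alpha0={cfg.alpha})"
        )

    available = np.ones(n, dtype=bool)
    first = _select_descending(u, available, alpha * u_max)[:k0]
    support = [int(i) for i in first]
    available[first] = False
    coef = _least_squares(a[:, support], y)
    r = y - a[:, support] @ coef
    trace: list[tuple[int, int, int, float]] = [
        (0, k0, len(support), float(np.linalg.norm(r)))
    ]

    terminated = "max_iter"
    stage = 1
    step = cfg.l0
    iterations = 1
    while True:
        if np.linalg.norm(r) <= eps:
            terminated = "residual_tol"
            break
        if stage > cfg.max_stages:
            terminated = "max_iter"
            break
        u = np.abs(a.T @ r)
        if not available.any() or float(u[available].max()) <= 1e-300:
            terminated = "stagnation"
            break
        th = alpha * float(u[available].max())
        selected = _select_descending(u, available, th)[:step]
        if selected.size == 0:
            terminated = "stagnation"
            break
        if len(support) + selected.size > smax:
            terminated = "support_cap"
            break
        support.extend(int(i) for i in selected)
        available[selected] = False
        coef = _least_squares(a[:, support], y)
        r = y - a[:, support] @ coef
        iterations += 1
        trace.append((stage, int(step), len(support), float(np.linalg.norm(r))))
        stage += 1
        step = stage * step if cfg.compound_step else stage * cfg.l0
    return _result(a, y, support, trace, iterations, terminated)


def reconstruct_signal(
    result: RecoveryResult,
    domain: SparseDomain | None = None,
    column_norms: np.ndarray | None = None,
) -> np.ndarray:
    """Signal-space reconstruction x_hat = D @ theta_hat.

    ``column_norms`` are the norms that :func:`cardiocs.sensing.effective_matrix`
    divided out of A's columns; passing them maps theta back to the domain's
    own coordinates.  ``domain=None`` means the identity domain.
    """
    theta = result.theta_hat
    if column_norms is not None:
        theta = theta / np.asarray(column_norms, dtype=float)
    if domain is None:
        return theta.copy()
    return domain.atoms @ theta
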