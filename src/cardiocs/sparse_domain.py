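"""Sparse representations: orthonormal DCT basis and K-SVD redundant dictionary.

A :class:`SparseDomain` is an N x K matrix whose unit-norm columns (atoms)
span the representation; for the DCT basis K = N and the matrix is orthogonal,
for a learned dictionary K may exceed N.  K-SVD alternates OMP sparse coding of
all training segments with per-atom rank-1 SVD updates of the residual, which
drives the mean squared representation error monotonically down.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.fft

from .errors import DataError, ParameterError
from .signal import Signal


@dataclass
class SparseDomain:
    """N x K atom matrix with unit-norm columns.

    ``kind`` is "dct" (orthonormal, K = N) or "ksvd" (learned, possibly
    redundant).  ``meta`` records training provenance.
    """

    atoms: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 2:
            raise ParameterError("atoms must be a 2-D matrix")
        norms = np.linalg.norm(self.atoms, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ParameterError("every atom must have unit Euclidean norm")
        if self.kind not in ("dct", "ksvd"):
            raise ParameterError(f"kind must be 'dct' or 'ksvd', got {self.kind!r}")
        if self.kind == "dct":
            n, k = self.atoms.shape
            if n != k or not np.allclose(self.atoms @ self.atoms.T, np.eye(n), atol=1e-9):
                raise ParameterError("dct domain must be square orthonormal")

    @property
    def n(self) -> int:
        """Signal dimension (atom length)."""
        return self.atoms.shape[0]

    @property
    def k(self) -> int:
        """Number of atoms."""
        return self.atoms.shape[1]


@dataclass
class TrainingCorpus:
    """Length-N windows cut from a concatenated sample set."""

    segments: np.ndarray  # shape (n_segments, N)

    def __post_init__(self):
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=float))

    def __len__(self) -> int:
        return 0 if self.segments.size == 0 else self.segments.shape[0]


def dct_domain(n: int) -> SparseDomain:
    """Orthonormal type-II DCT basis of size n x n.

    Columns are the DCT-II basis vectors, so ``analyze`` is the forward DCT
    and ``synthesize`` the inverse.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    # x = D @ theta with theta = DCT-II(x)  =>  D = C^T for orthonormal C
    atoms = scipy.fft.idct(np.eye(n), norm="ortho", axis=0)
    return SparseDomain(atoms=atoms, kind="dct", meta={"n": n})


def segment_corpus(signal: Signal | np.ndarray, n: int) -> TrainingCorpus:
    """Cut non-overlapping consecutive length-``n`` windows; the trailing
    remainder is dropped (with a warning if nothing remains)."""
    samples = signal.samples if isinstance(signal, Signal) else np.asarray(signal, dtype=float)
    if n < 1:
        raise ParameterError("window length must be >= 1")
    n_seg = samples.size // n
    if n_seg == 0:
        warnings.warn(f"signal of {samples.size} samples yields no length-{n} segment")
        return TrainingCorpus(segments=np.empty((0, n)))
    return TrainingCorpus(segments=samples[: n_seg * n].reshape(n_seg, n).copy())


def _omp_code(atoms: np.ndarray, x: np.ndarray, k: int) -> np.ndarray:
    """OMP sparse code of one segment at sparsity ``k`` (internal to K-SVD)."""
    # local import keeps recovery -> sparse_domain dependency one-way
    from .recovery import omp

    return omp(x, atoms, sparsity=k).theta_hat


def _canonical_sign(atom: np.ndarray, code_row: np.ndarray):
    """Make the first nonzero atom entry non-negative, flipping codes to match."""
    nz = np.flatnonzero(np.abs(atom) > 1e-12)
    if nz.size and atom[nz[0]] < 0:
        return -atom, -code_row
    return atom, code_row


def ksvd_train(
    corpus: TrainingCorpus,
    k_atoms: int,
    coding_sparsity: int | None = None,
    iterations: int = 30,
    seed: int = 0,
) -> SparseDomain:
    """Learn a redundant dictionary by K-SVD.

    Initialization draws ``k_atoms`` distinct training segments (seeded).
    Each iteration sparse-codes every segment with OMP against the current
    atoms, then updates each atom (and its codes) by a rank-1 SVD of the
    residual restricted to the segments that use it; atoms used by no segment
    are replaced by the currently worst-represented segment.  The mean squared
    representation error recorded in ``meta['errors']`` is non-increasing.
    """
    if len(corpus) == 0:
        raise DataError("cannot train on an empty corpus")
    if k_atoms < 1:
        raise ParameterError("k_atoms must be >= 1")
    X = corpus.segments.T  # (N, n_segments)
    n, n_seg = X.shape
    if coding_sparsity is None:
        coding_sparsity = max(1, int(np.ceil(n / 20)))
    coding_sparsity = min(coding_sparsity, n)

    rng = np.random.default_rng(seed)
    if k_atoms <= n_seg:
        init_idx = rng.choice(n_seg, size=k_atoms, replace=False)
        D = X[:, init_idx].astype(float).copy()
    else:
        D = np.concatenate([X, rng.standard_normal((n, k_atoms - n_seg))], axis=1)
    # guard all-zero init columns before normalization
    norms = np.linalg.norm(D, axis=0)
    dead = norms < 1e-12
    if dead.any():
        D[:, dead] = rng.standard_normal((n, int(dead.sum())))
        norms = np.linalg.norm(D, axis=0)
    D /= norms

    errors = []
    for _ in range(iterations):
        codes = np.column_stack([_omp_code(D, X[:, j], coding_sparsity) for j in range(n_seg)])
        for j in range(k_atoms):
            users = np.flatnonzero(np.abs(codes[j]) > 1e-12)
            if users.size == 0:
                resid = X - D @ codes
                worst = int(np.argmax(np.sum(resid**2, axis=0)))
                col = X[:, worst]
                if np.linalg.norm(col) < 1e-12:
                    col = rng.standard_normal(n)
                D[:, j] = col / np.linalg.norm(col)
                continue
            E = X[:, users] - D @ codes[:, users] + np.outer(D[:, j], codes[j, users])
            u, s, vt = np.linalg.svd(E, full_matrices=False)
            atom, code_row = _canonical_sign(u[:, 0], s[0] * vt[0])
            D[:, j] = atom
            codes[j, users] = code_row
        errors.append(float(np.mean((X - D @ codes) ** 2)))

    meta = {
        "iterations": iterations,
        "coding_sparsity": int(coding_sparsity),
        "seed": seed,
        "errors": errors,
        "n_segments": int(n_seg),
    }
    return SparseDomain(atoms=D, kind="ksvd", meta=meta)


def analyze(domain: SparseDomain, x: np.ndarray, sparsity: int | None = None) -> np.ndarray:
    """Coefficients of ``x`` in the domain.

    Exact (transpose) for the orthonormal DCT; for a learned dictionary this
    is OMP at ``sparsity`` (default: the training coding sparsity) and only an
    approximate inverse of :func:`synthesize` is promised.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (domain.n,):
        raise ParameterError(f"signal length {x.shape} does not match domain n={domain.n}")
    if domain.kind == "dct":
        return domain.atoms.T @ x
    if sparsity is None:
        sparsity = domain.meta.get("coding_sparsity", max(1, domain.n // 20))
    return _omp_code(domain.atoms, x, sparsity)


def synthesize(domain: SparseDomain, theta: np.ndarray) -> np.ndarray:
    """Signal-space vector D @ theta."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (domain.k,):
        raise ParameterError(f"coefficient length {theta.shape} does not match K={domain.k}")
    return domain.atoms @ theta


def save_domain(domain: SparseDomain, path: str | Path) -> None:
    """Persist the atom matrix as delimited text plus a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, domain.atoms, delimiter=",")
    meta = {"kind": domain.kind, "n": domain.n, "k": domain.k}
    meta.update({k: v for k, v in domain.meta.items() if k != "errors"})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_domain(path: str | Path) -> SparseDomain:
    """Load a dictionary saved by :func:`save_domain`."""
    path = Path(path)
    atoms = np.loadtxt(path, delimiter=",", ndmin=2)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    kind = meta.pop("kind", "ksvd")
    meta.pop("n", None), meta.pop("k", None)
    return SparseDomain(atoms=atoms, kind=kind, meta=meta)
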