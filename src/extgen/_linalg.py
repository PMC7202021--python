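"""Shared linear-algebra helpers for covariance-like matrices."""

from __future__ import annotations

import numpy as np

__all__ = ["is_symmetric", "symmetrize", "bend_psd", "sample_mvn"]


def is_symmetric(a: np.ndarray, tol: float = 1e-8) -> bool:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        return False
    scale = max(1.0, float(np.abs(a).max(initial=0.0)))
    return bool(np.all(np.abs(a - a.T) <= tol * scale))


def symmetrize(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return 0.5 * (a + a.T)


def bend_psd(a: np.ndarray, floor_factor: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Clip eigenvalues of a symmetric matrix to a small positive floor.

    Pairwise-complete similarity estimates (and rank-deficient cross-product
    matrices) can have slightly negative eigenvalues; mixed-model fitting and
    multivariate-normal sampling need a valid covariance.  The floor is
    ``floor_factor`` times the mean positive eigenvalue.

    Returns the (possibly) adjusted matrix and a flag telling whether any
    eigenvalue was actually raised.
    """
    a = symmetrize(a)
    vals, vecs = np.linalg.eigh(a)
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("matrix has no positive eigenvalue; cannot bend to PSD")
    floor = floor_factor * float(pos.mean())
    if vals.min() >= floor:
        return a, False
    bent = (vecs * np.maximum(vals, floor)) @ vecs.T
    return symmetrize(bent), True


def sample_mvn(rng: np.random.Generator, cov: np.ndarray, size: int = 1) -> np.ndarray:
    """Draw from N(0, cov) via eigendecomposition (tolerates singular cov)."""
    cov = symmetrize(cov)
    vals, vecs = np.linalg.eigh(cov)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((size, cov.shape[0]))
    draws = z @ root.T
    return draws[0] if size == 1 else draws
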