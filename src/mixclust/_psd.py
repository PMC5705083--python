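"""Nearest positive-semidefinite correlation matrix (Higham 2002).

Alternating projections between the PSD cone and the set of symmetric
unit-diagonal matrices, with Dykstra's correction, followed by a final
eigenvalue floor and diagonal renormalization.  The result is PSD (up to
float round-off), has an exact unit diagonal and entries in [-1, 1].
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["nearest_psd_correlation"]


def _proj_psd(a: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(0.5 * (a + a.T))
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def nearest_psd_correlation(
    s: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 100,
) -> np.ndarray:
    """Return the unit-diagonal PSD matrix closest to ``s`` (Frobenius).

    If ``s`` is already PSD within ``-1e-8`` on its smallest eigenvalue
    it is returned unchanged.
    """
    s = np.asarray(s, dtype=float)
    if np.linalg.eigvalsh(0.5 * (s + s.T)).min() >= -1e-8:
        return s
    x = s.copy()
    correction = np.zeros_like(x)
    converged = False
    for _ in range(max_iter):
        r = x - correction
        y = _proj_psd(r)
        correction = y - r
        x = y.copy()
        np.fill_diagonal(x, 1.0)
        if np.linalg.eigvalsh(x).min() >= -tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"nearest-PSD projection did not converge in {max_iter} iterations; "
            "returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    # final repair: floor eigenvalues at 0, renormalize diagonal to 1
    x = _proj_psd(x)
    d = np.sqrt(np.clip(np.diag(x), 1e-300, None))
    x = x / np.outer(d, d)
    x = 0.5 * (x + x.T)
    np.clip(x, -1.0, 1.0, out=x)
    np.fill_diagonal(x, 1.0)
    return x
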