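"""Non-negative least squares by the Lawson-Hanson active-set algorithm.

Solves ``min ||A x - b||^2  subject to  x >= 0``.  The coefficients here are
component contributions to a fecal marker profile, which cannot be negative,
so the constraint is structural rather than a regularisation device.

The active-set method maintains a passive set P of coefficients allowed to be
positive.  Each outer iteration moves the variable with the largest positive
dual (gradient of the residual) into P, solves the unconstrained least
squares problem on P, and, if that solution leaves the feasible region, backs
up along the line segment to the boundary and demotes the variables that hit
zero.  At convergence the KKT conditions hold: the dual is ~0 on P and
<= tol off P.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import SolverError, ValidationError

__all__ = ["nnls_solve"]


def nnls_solve(
    design: np.ndarray,
    target: np.ndarray,
    tol: float = 1e-10,
    max_iter: int | None = None,
) -> tuple[np.ndarray, float]:
    """Minimise ``||design @ x - target||^2`` subject to ``x >= 0``.

    Parameters
    ----------
    design
        (m, n) matrix, one column per dietary component, one row per marker.
    target
        (m,) corrected fecal concentration vector.
    tol
        Dual-feasibility tolerance, scaled by ``max(|A^T b|, 1)`` so it is
        meaningful across problem scales.
    max_iter
        Outer iteration cap; defaults to ``3 * n`` columns.

    Returns
    -------
    x, residual_ss
        The non-negative minimiser and its squared residual norm.

    Raises
    ------
    ValidationError
        On non-finite input or an empty design.
    SolverError
        On failure to converge within ``max_iter`` (carries the last iterate).
    """
    A = np.atleast_2d(np.asarray(design, dtype=float))
    b = np.asarray(target, dtype=float).ravel()
    m, n = A.shape
    if n == 0:
        raise ValidationError("design matrix has no columns")
    if b.shape[0] != m:
        raise ValidationError(f"design has {m} rows but target has {b.shape[0]}")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
        raise ValidationError("non-finite values in NNLS input")
    if m < n:
        warnings.warn(
            f"underdetermined NNLS system ({m} markers for {n} components)",
            stacklevel=2,
        )
    if max_iter is None:
        max_iter = max(3 * n, 3)

    # Dual tolerance on the scale of the gradient at x = 0.
    scale = max(float(np.max(np.abs(A.T @ b), initial=0.0)), 1.0)
    dual_tol = tol * scale

    x = np.zeros(n)
    passive = np.zeros(n, dtype=bool)
    w = A.T @ b  # dual at x = 0

    for _ in range(max_iter):
        candidates = ~passive & (w > dual_tol)
        if not candidates.any():
            break
        # Entering variable: largest dual; np.argmax takes the lowest index
        # on ties, which fixes a deterministic order.
        w_masked = np.where(candidates, w, -np.inf)
        j = int(np.argmax(w_masked))
        passive[j] = True

        while True:
            idx = np.flatnonzero(passive)
            z = np.zeros(n)
            z[idx] = np.linalg.lstsq(A[:, idx], b, rcond=None)[0]
            if np.all(z[idx] > 0):
                x = z
                break
            # Back up to the feasibility boundary and demote variables at 0.
            neg = idx[z[idx] <= 0]
            alpha = np.min(x[neg] / (x[neg] - z[neg]))
            x = x + alpha * (z - x)
            passive[idx[x[idx] <= tol * scale]] = False
            x[~passive] = 0.0
        w = A.T @ (b - A @ x)
    else:
        raise SolverError(
            f"NNLS did not converge within {max_iter} iterations", last_x=x
        )

    residual = b - A @ x
    return x, float(residual @ residual)
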