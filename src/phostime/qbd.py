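"""Block-tridiagonal (QBD) linear algebra.

Levels are eliminated sequentially, exploiting the quasi-birth-and-death
structure of the generators: a block Thomas sweep for the absorbing
first-passage systems, and top-down level censoring for the stationary
distribution.  Blocks are handled dense (per-level phase counts are
small even when the full chain is large); every routine has a generic
sparse counterpart elsewhere in the package used for cross-checking.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import lu_factor, lu_solve


def solve_block_tridiagonal(diag, up, down, rhs_blocks):
    """Solve ``T x = r`` where T is block tridiagonal.

    Parameters
    ----------
    diag, up, down : sequences of ndarray
        ``diag[l]`` the diagonal block of level ``l``; ``up[l]`` couples
        level ``l`` to ``l+1`` (``None`` for the last level); ``down[l]``
        couples ``l`` to ``l-1`` (``None`` for level 0).
    rhs_blocks : sequence of ndarray
        Right-hand side, one (possibly multi-column) block per level.

    Returns
    -------
    list of ndarray
        Solution blocks, one per level.

    Notes
    -----
    Forward elimination ascends through the levels (level 0 first); the
    back-substitution then descends.  No pivoting across levels is done,
    which is safe here because the Schur complements of (minus) a
    transient sub-generator are M-matrices.
    """
    J = len(diag)
    if not (len(up) == len(down) == len(rhs_blocks) == J):
        raise ValueError("inconsistent number of level blocks")
    schur_lu = []
    z = []
    for l in range(J):
        C = np.array(diag[l], dtype=float)
        r = np.array(rhs_blocks[l], dtype=float)
        if l > 0:
            C = C - down[l] @ lu_solve(schur_lu[l - 1], up[l - 1])
            r = r - down[l] @ lu_solve(schur_lu[l - 1], z[l - 1])
        schur_lu.append(lu_factor(C))
        z.append(r)
    x = [None] * J
    x[J - 1] = lu_solve(schur_lu[J - 1], z[J - 1])
    for l in range(J - 2, -1, -1):
        x[l] = lu_solve(schur_lu[l], z[l] - up[l] @ x[l + 1])
    return x


def censored_stationary(diag, up, down):
    """Stationary vector of a finite, irreducible QBD generator.

    Linear level reduction, censoring the lowest level first: with
    ``T_0 = A_0`` (the first diagonal block), the generator of the chain
    observed on levels ``l..J`` has first-level block

        ``T_l = A_l + D_l (-T_{l-1})^{-1} U_{l-1}``,

    where ``D_l`` is the down-block of level ``l`` and ``U_{l-1}`` the
    up-block of level ``l-1``.  The top-level stationary vector solves
    ``pi_{J-1} T_{J-1} = 0`` and lower levels follow from
    ``pi_l = pi_{l+1} D_{l+1} (-T_l)^{-1}``.

    Censoring upward keeps every intermediate quantity bounded by the
    sojourn times *below* the current level, which stay moderate for the
    chains built here even when the stationary mass concentrates at the
    top levels (the reverse sweep is catastrophically ill-conditioned in
    that regime).

    Returns the concatenated, normalized stationary probability vector
    (level-major order matching the block order).
    """
    J = len(diag)
    T = [None] * J
    T[0] = np.array(diag[0], dtype=float)
    factors = [None] * J
    for l in range(1, J):
        factors[l - 1] = lu_factor(-T[l - 1])
        T[l] = diag[l] + down[l] @ lu_solve(factors[l - 1], up[l - 1])
    # pi_{J-1} solves pi T = 0 on the top censored block; replace the
    # last column with ones to pin the scale.
    M = T[J - 1].copy()
    M[:, -1] = 1.0
    e = np.zeros(M.shape[0])
    e[-1] = 1.0
    pieces = [None] * J
    pieces[J - 1] = np.linalg.solve(M.T, e)
    for l in range(J - 2, -1, -1):
        # pi_l = (pi_{l+1} D_{l+1}) (-T_l)^{-1}, via the transposed factor
        pieces[l] = lu_solve(factors[l], pieces[l + 1] @ down[l + 1], trans=1)
    pi = np.concatenate(pieces)
    total = pi.sum()
    if total <= 0:
        raise ArithmeticError("censoring produced a non-positive mass")
    return pi / total
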