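"""Cell-centred finite-volume core on masked structured grids.

One assembly routine serves both solvers: the depth-averaged pressure
equation (pure diffusion of pressure with transmissibility h³/12μ) and
the depth-averaged oxygen advection–diffusion equation.  Two-point flux
approximation on the uniform grid (square cells, so face length / centre
distance = 1 and the conductance is a single scalar per face), optional
first-order upwind or central advection from prescribed face fluxes.

Sign conventions: ``qx[i, j]`` is the advective flux through the face
between cells ``(i-1, j)`` and ``(i, j)``, positive in +x; likewise
``qy`` in +y.  Boundary faces of interior cells carry prescribed total
fluxes via the right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["FvProblem", "assemble", "solve_cells"]


class SolverError(RuntimeError):
    """Linear solve failed to reach the requested residual."""


@dataclass
class FvProblem:
    """Assembled sparse system restricted to interior cells."""

    matrix: sp.csr_matrix
    rhs: np.ndarray
    index: np.ndarray  # (nx, ny) int, -1 outside interior
    constrained: bool  # True when a mean-zero Lagrange multiplier row is appended


def interior_index(interior: np.ndarray) -> np.ndarray:
    index = np.full(interior.shape, -1, dtype=np.int64)
    index[interior] = np.arange(int(interior.sum()))
    return index


def assemble(
    interior: np.ndarray,
    conductance: float,
    *,
    qx: np.ndarray | None = None,
    qy: np.ndarray | None = None,
    scheme: str = "upwind",
    rhs: np.ndarray | None = None,
    diag_extra: np.ndarray | None = None,
    dirichlet: list[tuple[int, int, float, float]] | None = None,
    constrain_mean: bool = False,
) -> FvProblem:
    """Assemble the steady FV system  A c = b  over interior cells.

    Parameters
    ----------
    interior : (nx, ny) bool mask of solved cells.
    conductance : scalar face conductance g (flux = g·(c_a − c_b)).
    qx, qy : optional advective face-flux arrays, shapes (nx+1, ny) and
        (nx, ny+1); only faces between two interior cells are used.
    scheme : "upwind" or "central" advection discretization.
    rhs : (nx, ny) per-cell source (prescribed boundary fluxes, sinks,
        manufactured sources); positive adds to the cell.
    diag_extra : (nx, ny) extra diagonal terms (e.g. advective outflow q_out).
    dirichlet : list of (i, j, g_d, value) ghost couplings adding
        ``g_d·(value − c_ij)`` to cell (i, j).
    constrain_mean : append a Lagrange row enforcing Σc = 0 (pure-Neumann
        problems); keeps every cell balance intact.
    """
    index = interior_index(interior)
    n = int(interior.sum())
    if n == 0:
        raise ValueError("no interior cells to solve on")

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r: np.ndarray, c: np.ndarray, v: np.ndarray) -> None:
        rows.append(np.asarray(r, dtype=np.int64))
        cols.append(np.asarray(c, dtype=np.int64))
        vals.append(np.asarray(v, dtype=float))

    for axis in (0, 1):
        if axis == 0:
            a, b = index[:-1, :], index[1:, :]
            q = None if qx is None else qx[1:-1, :]
        else:
            a, b = index[:, :-1], index[:, 1:]
            q = None if qy is None else qy[:, 1:-1]
        both = (a >= 0) & (b >= 0)
        ia, ib = a[both], b[both]
        g = np.full(ia.shape, conductance)
        # diffusion: flux a→b = g (c_a − c_b)
        add(ia, ia, g)
        add(ib, ib, g)
        add(ia, ib, -g)
        add(ib, ia, -g)
        if q is not None:
            qf = q[both]
            if scheme == "upwind":
                qp = np.maximum(qf, 0.0)  # carries c_a
                qm = np.minimum(qf, 0.0)  # carries c_b
                add(ia, ia, qp)
                add(ib, ia, -qp)
                add(ia, ib, qm)
                add(ib, ib, -qm)
            elif scheme == "central":
                half = 0.5 * qf
                add(ia, ia, half)
                add(ia, ib, half)
                add(ib, ia, -half)
                add(ib, ib, -half)
            else:
                raise ValueError(f"unknown advection scheme {scheme!r}")

    b_vec = np.zeros(n)
    if rhs is not None:
        b_vec += rhs[interior]
    if diag_extra is not None:
        d = diag_extra[interior]
        nz = np.nonzero(d)[0]
        add(nz, nz, d[nz])
    if dirichlet:
        for i, j, gd, val in dirichlet:
            k = index[i, j]
            if k < 0:
                raise ValueError(f"dirichlet cell ({i}, {j}) is not interior")
            add(np.array([k]), np.array([k]), np.array([gd]))
            b_vec[k] += gd * val

    r = np.concatenate(rows)
    c = np.concatenate(cols)
    v = np.concatenate(vals)
    if constrain_mean:
        # pure-Neumann nullspace: replace the balance row of cell 0 by p₀ = 0.
        # With compatible data the dropped row is minus the sum of the others,
        # so every cell balance still holds exactly; the level is re-gauged
        # downstream (outlet mean = 0).
        keep = r != 0
        r, c, v = r[keep], c[keep], v[keep]
        r = np.concatenate([r, [0]])
        c = np.concatenate([c, [0]])
        v = np.concatenate([v, [1.0]])
        b_vec[0] = 0.0
    A = sp.coo_matrix((v, (r, c)), shape=(n, n)).tocsr()
    return FvProblem(matrix=A, rhs=b_vec, index=index, constrained=constrain_mean)


def solve_cells(problem: FvProblem, *, rtol: float = 1e-10) -> tuple[np.ndarray, dict]:
    """Solve the assembled system; returns (field with NaN outside, diagnostics).

    Direct sparse LU first; on failure or poor residual, GMRES with ILU
    preconditioning as a fallback at relative tolerance ``rtol``.
    """
    A, b = problem.matrix, problem.rhs
    n = b.size
    x = None
    method = "splu"
    try:
        x = spla.spsolve(A.tocsc(), b)
    except Exception:
        x = None
    bnorm = float(np.linalg.norm(b))
    if x is not None and bnorm > 0:
        res = float(np.linalg.norm(A @ x - b)) / bnorm
    elif x is not None:
        res = float(np.linalg.norm(A @ x - b))
    else:
        res = np.inf
    if x is None or not np.isfinite(res) or res > max(rtol, 1e-9):
        method = "gmres+ilu"
        try:
            ilu = spla.spilu(A.tocsc(), drop_tol=1e-6, fill_factor=20)
            M = spla.LinearOperator((n, n), ilu.solve)
        except Exception:
            M = None
        x, info = spla.gmres(A, b, M=M, rtol=rtol, atol=0.0, maxiter=5000)
        res = float(np.linalg.norm(A @ x - b)) / bnorm if bnorm > 0 else float(np.linalg.norm(A @ x - b))
        if info != 0 or not np.isfinite(res) or res > 1e-6:
            raise SolverError(f"linear solve did not converge (relative residual {res:.3e})")

    interior = problem.index >= 0
    ncell = int(interior.sum())
    sol = x[:ncell]
    if problem.constrained:
        sol = sol - sol.mean()  # gauge: zero mean; callers may re-gauge
    field = np.full(problem.index.shape, np.nan)
    field[interior] = sol
    diagnostics = {"relative_residual": res, "method": method, "unknowns": ncell}
    return field, diagnostics
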