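"""Steady-state reaction-diffusion nutrient fields.

Nutrients diffuse much faster than cells move, so each extracellular
species is held at the quasi-static solution of a Helmholtz problem on the
periodic grid:

    D lap(C) - eps C + alpha(x) - sink(x) = 0

``alpha`` is uniform secretion by the stromal compartment and/or epithelial
band (per species), balanced as alpha = eps * G so the tumor-free field
equals the physiological baseline G everywhere.  Tumor uptake enters as a
linearized sink conductance g(x) placed at each cell's center-of-mass site
(sink = g * C), which keeps the operator an M-matrix and the solution
non-negative; one-off sources (necrotic lactate bursts, tumor lactate
export) enter the right-hand side for a single solve.

The operator is discretized with the 5-point finite-difference Laplacian
and solved with conjugate gradients (warm-started between Monte Carlo
steps); a dense direct solve is available as the oracle path for small
grids.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from .params import CellType, FieldConfig

logger = logging.getLogger(__name__)


def baseline_secretion(epsilon: float, G: float) -> float:
    """Secretion rate alpha = eps * G that fixes the no-tumor steady state at G."""
    if epsilon < 0 or G < 0:
        raise ValueError("epsilon and G must be non-negative")
    return epsilon * G


def periodic_laplacian(height: int, width: int) -> sparse.csr_matrix:
    """5-point Laplacian with periodic wrap, as a sparse matrix on H*W sites."""

    def ring(n: int) -> sparse.csr_matrix:
        main = -2.0 * np.ones(n)
        off = np.ones(n - 1)
        L = sparse.diags([off, main, off], [-1, 0, 1], format="lil")
        L[0, n - 1] += 1.0
        L[n - 1, 0] += 1.0
        return L.tocsr()

    Iy = sparse.identity(height, format="csr")
    Ix = sparse.identity(width, format="csr")
    return sparse.kron(Iy, ring(width)) + sparse.kron(ring(height), Ix)


class NutrientField:
    """One extracellular species on the lattice grid."""

    def __init__(self, cfg: FieldConfig, height: int, width: int):
        self.cfg = cfg
        self.height = height
        self.width = width
        self.C = np.full((height, width), cfg.G_baseline, dtype=float)
        #: one-shot sources (fmol/voxel/MCS), cleared after each solve
        self.transient_source = np.zeros((height, width))
        #: linearized uptake conductances (1/MCS), set by the driver per MCS
        self.sink_g = np.zeros((height, width))
        self._A0 = (
            -cfg.D * periodic_laplacian(height, width)
            + cfg.epsilon * sparse.identity(height * width, format="csr")
        ).tocsr()
        self._A0_lu = None  # lazy LU of the sink-free operator (preconditioner)

    def _preconditioner(self):
        from scipy.sparse.linalg import LinearOperator, splu

        if self._A0_lu is None:
            self._A0_lu = splu(self._A0.tocsc())
        n = self._A0.shape[0]
        return LinearOperator((n, n), matvec=self._A0_lu.solve)

    # ------------------------------------------------------------------
    def secretion_map(self, type_map: np.ndarray) -> np.ndarray:
        """Per-site secretion alpha(x) given the current cell-type map."""
        alpha = baseline_secretion(self.cfg.epsilon, self.cfg.G_baseline)
        src = np.zeros((self.height, self.width))
        if alpha == 0.0:
            return src
        if self.cfg.secreted_by_stroma:
            src[type_map == int(CellType.MEDIUM)] = alpha
        if self.cfg.secreted_by_epithelium:
            src[(type_map == int(CellType.ECM)) | (type_map == int(CellType.BASAL))] = alpha
        return src

    def solve(self, type_map: np.ndarray, method: str = "cg",
              rtol: float = 1e-8, maxiter: int = 2000) -> np.ndarray:
        """Solve the steady-state problem and update ``self.C`` in place."""
        b = (self.secretion_map(type_map) + self.transient_source).ravel()
        A = self._A0
        if self.sink_g.any():
            A = A + sparse.diags(self.sink_g.ravel())
        if method == "dense":
            sol = np.linalg.solve(A.toarray(), b)
        elif method == "cg":
            sol, info = cg(A, b, x0=self.C.ravel(), rtol=rtol, atol=0.0,
                           maxiter=maxiter, M=self._preconditioner())
            if info != 0:
                res = np.linalg.norm(A @ sol - b)
                raise RuntimeError(
                    f"field solver for {self.cfg.species} did not converge "
                    f"(info={info}, residual={res:.3e})"
                )
        else:
            raise ValueError(f"unknown solver method {method!r}")
        neg = sol < 0
        if neg.any():
            logger.debug(
                "clipped %d negative sites in %s field (min %.3e)",
                int(neg.sum()), self.cfg.species, float(sol.min()),
            )
            sol = np.clip(sol, 0.0, None)
        self.C = sol.reshape(self.height, self.width)
        self.transient_source[:] = 0.0
        return self.C


def solve_steady_state(field: NutrientField, lattice, method: str = "cg") -> NutrientField:
    """Solve ``field`` to steady state against the lattice's current type map."""
    type_map = lattice.ctype[lattice.owner]
    field.solve(type_map, method=method)
    return field


def sample_at_center_of_mass(C: np.ndarray, lattice, cid: int) -> float:
    """Field value at the cell's site nearest its center of mass.

    The center of mass of a ring-shaped or seam-straddling cell can fall on
    a site the cell does not own, so the sample is taken at the nearest
    owned site under the periodic metric.
    """
    sites = lattice.cell_sites(cid)
    if len(sites) == 0:
        raise ValueError(f"cell {cid} has no sites")
    cy, cx = lattice.com(cid)
    dy = sites[:, 0] - cy
    dy -= lattice.height * np.round(dy / lattice.height)
    dx = sites[:, 1] - cx
    dx -= lattice.width * np.round(dx / lattice.width)
    k = int(np.argmin(dy * dy + dx * dx))
    return float(C[sites[k, 0], sites[k, 1]])


def deposit_lactate_burst(field: NutrientField, lattice, cid: int,
                          lactate_index: int) -> float:
    """Transfer a dying cell's intracellular lactate to the field.

    The cell's lactate amount (concentration x volume, fmol) is split evenly
    over its occupied sites and added to the lactate source term for the
    next solve; the intracellular pool is zeroed.  Returns the amount moved.
    """
    conc = lattice.conc[cid, lactate_index]
    vol = int(lattice.volume[cid])
    if conc <= 0.0 or vol == 0:
        lattice.conc[cid, lactate_index] = 0.0
        return 0.0
    amount = conc * vol
    sites = lattice.cell_sites(cid)
    per_site = amount / len(sites)
    field.transient_source[sites[:, 0], sites[:, 1]] += per_site
    lattice.conc[cid, lactate_index] = 0.0
    return amount
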