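"""Cellular Potts (Glazier-Graner-Hogeweg) engine.

The lattice is a periodic 2-D map ``site -> cell id`` (id 0 = the continuous
stromal Medium).  Cells evolve by Metropolis voxel-copy attempts: a source
site is drawn uniformly, one of its 8 Moore neighbors is the target, and the
source's identity is copied onto the target with probability

    P = 1                      if dH <= 0
    P = exp(-dH / Tm)          if dH >  0

where dH collects adhesion, volume/surface-constraint, chemotaxis and (for
epithelial cells) focal-point-plasticity link energies.

Two equivalent implementations are provided: plain-Python single attempts
(:func:`attempt_voxel_copy`, used by tests and oracles) and a numba kernel
(:func:`monte_carlo_step`) that performs one full Monte Carlo step.  Both
consume the same pre-drawn random streams, so the kernel is replayable
attempt-for-attempt against the Python path.

Conventions (configurable where noted): Moore (8-)neighborhood for copy
candidates and adhesion pairs; surface measured as exposed edge count in the
von Neumann (4-)neighborhood; one MCS = width*height copy attempts; no
connectivity constraint (fragmented cells are permitted but can be counted).
"""

from __future__ import annotations

import logging
import math

import numpy as np
from numba import njit

from .params import (
    CellType,
    EnergyConfig,
    EPITHELIAL_TYPES,
    N_TYPES,
    PROLIFERATING_TYPES,
)

logger = logging.getLogger(__name__)

# Moore neighborhood offsets (dy, dx); the first four are the von Neumann set
MOORE = np.array(
    [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)],
    dtype=np.int64,
)
VON_NEUMANN = MOORE[:4]


def acceptance_probability(delta_H: float, Tm: float) -> float:
    """Metropolis acceptance probability for one voxel-copy attempt."""
    if Tm <= 0:
        raise ValueError(f"Tm must be > 0, got {Tm}")
    if delta_H <= 0:
        return 1.0
    return math.exp(-delta_H / Tm)


class Lattice:
    """Periodic site->cell map plus the per-cell bookkeeping table.

    All per-cell quantities (type, cached volume/surface, geometric targets,
    behavioral attributes, intracellular state) live in flat numpy arrays
    indexed by cell id; row 0 is reserved for Medium.
    """

    def __init__(self, width: int, height: int, capacity: int = 256):
        self.width = int(width)
        self.height = int(height)
        self.owner = np.zeros((self.height, self.width), dtype=np.int32)
        self._cap = int(capacity)
        self.n_cells = 1  # id 0 = Medium
        c = self._cap
        self.ctype = np.zeros(c, dtype=np.int8)
        self.volume = np.zeros(c, dtype=np.int64)
        self.surface = np.zeros(c, dtype=np.int64)
        self.target_volume = np.zeros(c, dtype=np.float64)
        self.target_surface = np.zeros(c, dtype=np.float64)
        self.sum_x = np.zeros(c, dtype=np.float64)  # unwrapped coordinate sums
        self.sum_y = np.zeros(c, dtype=np.float64)
        self.alive = np.zeros(c, dtype=bool)
        # behavioral attributes (cell_decisions layer)
        self.health = np.zeros(c)
        self.starvation = np.zeros(c)
        self.acidity = np.zeros(c)
        self.stress = np.zeros(c)
        self.divisions = np.zeros(c, dtype=np.int32)
        self.temp = np.zeros(c, dtype=np.int32)       # senescence limit
        self.at_periphery = np.zeros(c, dtype=bool)   # set at necrosis time
        self.conc: np.ndarray | None = None           # per-cell metabolic state
        # focal-point plasticity links: parallel lists (a, b, lam, L)
        self.links: list[list[float]] = []

    # -- construction --------------------------------------------------
    def _ensure_capacity(self, n: int) -> None:
        if n <= self._cap:
            return
        new_cap = max(n, self._cap * 2)
        for name in ("ctype", "volume", "surface", "target_volume",
                     "target_surface", "sum_x", "sum_y", "alive", "health",
                     "starvation", "acidity", "stress", "divisions", "temp",
                     "at_periphery"):
            old = getattr(self, name)
            new = np.zeros(new_cap, dtype=old.dtype)
            new[: self._cap] = old[: self._cap]
            setattr(self, name, new)
        if self.conc is not None:
            new = np.zeros((new_cap, self.conc.shape[1]))
            new[: self._cap] = self.conc[: self._cap]
            self.conc = new
        self._cap = new_cap

    def new_cell(self, ctype: CellType, target_volume: float,
                 target_surface: float, temp: int = 0) -> int:
        cid = self.n_cells
        self._ensure_capacity(cid + 1)
        self.n_cells += 1
        self.ctype[cid] = int(ctype)
        self.target_volume[cid] = target_volume
        self.target_surface[cid] = target_surface
        self.alive[cid] = True
        self.temp[cid] = temp
        return cid

    def attach_metabolism(self, base_state: np.ndarray) -> None:
        """Allocate per-cell concentration storage seeded with ``base_state``."""
        n_species = len(base_state)
        self.conc = np.zeros((self._cap, n_species))
        self.conc[: self.n_cells] = base_state

    def place_block(self, cid: int, y0: int, x0: int, h: int, w: int) -> None:
        """Assign a rectangular block of sites to ``cid`` (construction only)."""
        ys = np.arange(y0, y0 + h) % self.height
        xs = np.arange(x0, x0 + w) % self.width
        self.owner[np.ix_(ys, xs)] = cid

    # -- cached-state maintenance --------------------------------------
    def recount(self) -> None:
        """Rebuild volume, surface and center-of-mass caches from the owner map."""
        cap = self._cap
        self.volume[:] = 0
        counts = np.bincount(self.owner.ravel(), minlength=cap)
        self.volume[: len(counts)] = counts
        # exposed edges in the 4-neighborhood
        surf = np.zeros(cap, dtype=np.int64)
        for dy, dx in VON_NEUMANN:
            nb = np.roll(self.owner, (int(dy), int(dx)), axis=(0, 1))
            edge = self.owner[self.owner != nb]
            if edge.size:
                surf += np.bincount(edge, minlength=cap)[:cap]
        self.surface[:] = surf
        # unwrapped coordinate sums: unwrap each cell around its first site
        self.sum_x[:] = 0.0
        self.sum_y[:] = 0.0
        ys, xs = np.nonzero(self.owner)
        ids = self.owner[ys, xs]
        order = np.argsort(ids, kind="stable")
        ys, xs, ids = ys[order], xs[order], ids[order]
        bounds = np.searchsorted(ids, np.arange(1, self.n_cells + 1))
        start = 0
        for cid in range(1, self.n_cells):
            stop = bounds[cid] if cid < self.n_cells else len(ids)
            stop = np.searchsorted(ids, cid + 1)
            if stop <= start:
                start = stop
                continue
            cy, cx = ys[start:stop].astype(float), xs[start:stop].astype(float)
            ry, rx = cy[0], cx[0]
            dy = cy - ry
            dy -= self.height * np.round(dy / self.height)
            dx = cx - rx
            dx -= self.width * np.round(dx / self.width)
            self.sum_y[cid] = np.sum(ry + dy)
            self.sum_x[cid] = np.sum(rx + dx)
            start = stop
        self.surface[0] = 0
        self.volume[0] = self.width * self.height - int(
            self.volume[1 : self.n_cells].sum()
        )

    def com(self, cid: int) -> tuple[float, float]:
        """Center of mass (y, x), wrapped into the lattice."""
        v = self.volume[cid]
        if v <= 0:
            raise ValueError(f"cell {cid} has no sites")
        return (
            (self.sum_y[cid] / v) % self.height,
            (self.sum_x[cid] / v) % self.width,
        )

    def cell_sites(self, cid: int) -> np.ndarray:
        """(n, 2) array of (y, x) sites owned by ``cid``."""
        ys, xs = np.nonzero(self.owner == cid)
        return np.stack([ys, xs], axis=1)

    def medium_volume(self) -> int:
        return self.width * self.height - int(self.volume[1 : self.n_cells].sum())

    def com_sites(self, ids: np.ndarray) -> np.ndarray:
        """(len(ids), 2) array of each cell's owned site nearest its center
        of mass (periodic metric), computed in one pass over the lattice."""
        ys, xs = np.nonzero(self.owner)
        owners = self.owner[ys, xs]
        order = np.argsort(owners, kind="stable")
        ys, xs, owners = ys[order], xs[order], owners[order]
        out = np.full((len(ids), 2), -1, dtype=np.int64)
        starts = np.searchsorted(owners, ids, side="left")
        stops = np.searchsorted(owners, ids, side="right")
        for k, (a, b) in enumerate(zip(starts, stops)):
            if b <= a:
                continue
            cid = ids[k]
            cy, cx = self.com(cid)
            dy = ys[a:b] - cy
            dy -= self.height * np.round(dy / self.height)
            dx = xs[a:b] - cx
            dx -= self.width * np.round(dx / self.width)
            j = int(np.argmin(dy * dy + dx * dx))
            out[k, 0] = ys[a + j]
            out[k, 1] = xs[a + j]
        return out

    # -- queries used by the decision layer ----------------------------
    def neighbor_counts(self) -> np.ndarray:
        """Distinct adjacent cells per cell id (Moore adjacency, Medium excluded)."""
        pairs = []
        for dy, dx in MOORE:
            nb = np.roll(self.owner, (int(dy), int(dx)), axis=(0, 1))
            mask = (self.owner != nb) & (self.owner != 0) & (nb != 0)
            if mask.any():
                pairs.append(np.stack([self.owner[mask], nb[mask]], axis=1))
        counts = np.zeros(self._cap, dtype=np.int64)
        if pairs:
            uniq = np.unique(np.concatenate(pairs, axis=0), axis=0)
            cnt = np.bincount(uniq[:, 0], minlength=self._cap)
            counts[: len(cnt)] = cnt
        return counts

    def touches_medium(self, cid: int) -> bool:
        """Whether the cell has a boundary site adjacent to Medium (Moore)."""
        for dy, dx in MOORE:
            nb = np.roll(self.owner, (int(dy), int(dx)), axis=(0, 1))
            if np.any((self.owner == cid) & (nb == 0)):
                return True
        return False

    def remove_cell(self, cid: int) -> None:
        """Clear the cell's sites to Medium and retire the id."""
        self.owner[self.owner == cid] = 0
        self.alive[cid] = False
        self.volume[cid] = 0
        self.surface[cid] = 0
        self.links = [ln for ln in self.links if cid not in (int(ln[0]), int(ln[1]))]
        self.recount()

    def fragmented_cells(self) -> list[int]:
        """Ids of cells whose sites form more than one 8-connected component.

        Fragmentation is permitted (no connectivity constraint) but worth
        logging as a diagnostic.  Periodic wrap is handled by doubling.
        """
        from scipy import ndimage

        frag = []
        tiled = np.tile(self.owner, (2, 2))
        structure = np.ones((3, 3), dtype=bool)
        for cid in range(1, self.n_cells):
            if not self.alive[cid] or self.volume[cid] == 0:
                continue
            mask = tiled == cid
            n_lab = ndimage.label(mask, structure=structure)[1]
            # a compact cell appears as 4 translated copies
            if n_lab > 4:
                frag.append(cid)
        if frag:
            logger.debug("fragmented cells: %s", frag)
        return frag


# ----------------------------------------------------------------------
# Energy deltas (reference implementations)


def adhesion_delta(lat: Lattice, source_site, target_site, J: np.ndarray) -> float:
    """Change in total contact energy if the source id were copied onto target.

    Pairs of neighboring sites belonging to the same cell contribute 0; all
    other Moore pairs contribute J(tau_i, tau_j).  Only pairs involving the
    target site change.
    """
    sy, sx = source_site
    ty, tx = target_site
    src = lat.owner[sy, sx]
    tgt = lat.owner[ty, tx]
    d = 0.0
    for dy, dx in MOORE:
        ny, nx = (ty + dy) % lat.height, (tx + dx) % lat.width
        nb = lat.owner[ny, nx]
        tn = lat.ctype[nb]
        if nb != src:
            d += J[lat.ctype[src], tn]
        if nb != tgt:
            d -= J[lat.ctype[tgt], tn]
    return d


def _vol_term(lam: float, V: float, Vt: float, quadratic: bool) -> float:
    dev = V - Vt
    return lam * (dev * dev if quadratic else dev)


def volume_surface_delta(
    lat: Lattice,
    cell_gaining: int,
    cell_losing: int,
    target_site,
    cfg: EnergyConfig,
) -> float:
    """Volume+surface constraint energy change for one voxel copy.

    Medium (id 0) carries no constraint.  Surface changes are derived from
    the 4-neighborhood of the target site.
    """
    ty, tx = target_site
    quad = cfg.volume_form == "quadratic"
    d = 0.0
    cnt4 = {cell_gaining: 0, cell_losing: 0}
    for dy, dx in VON_NEUMANN:
        nb = lat.owner[(ty + dy) % lat.height, (tx + dx) % lat.width]
        if nb in cnt4:
            cnt4[nb] += 1
    if cell_gaining != 0:
        t = lat.ctype[cell_gaining]
        V, Vt = lat.volume[cell_gaining], lat.target_volume[cell_gaining]
        S, St = lat.surface[cell_gaining], lat.target_surface[cell_gaining]
        dS = 4 - 2 * cnt4[cell_gaining]
        d += _vol_term(cfg.lambda_v[t], V + 1, Vt, quad) - _vol_term(cfg.lambda_v[t], V, Vt, quad)
        d += _vol_term(cfg.lambda_s[t], S + dS, St, quad) - _vol_term(cfg.lambda_s[t], S, St, quad)
    if cell_losing != 0:
        t = lat.ctype[cell_losing]
        V, Vt = lat.volume[cell_losing], lat.target_volume[cell_losing]
        S, St = lat.surface[cell_losing], lat.target_surface[cell_losing]
        dS = 2 * cnt4[cell_losing] - 4
        d += _vol_term(cfg.lambda_v[t], V - 1, Vt, quad) - _vol_term(cfg.lambda_v[t], V, Vt, quad)
        d += _vol_term(cfg.lambda_s[t], S + dS, St, quad) - _vol_term(cfg.lambda_s[t], S, St, quad)
    return d


def chemotaxis_delta(fields, source_site, target_site, lambda_chem: float) -> float:
    """-lambda * sum_fields (C(dest) - C(src)); negative when moving up-gradient.

    ``fields`` is an iterable of 2-D concentration arrays (or a single array).
    """
    if isinstance(fields, np.ndarray) and fields.ndim == 2:
        fields = [fields]
    sy, sx = source_site
    ty, tx = target_site
    d = 0.0
    for C in fields:
        d -= lambda_chem * (C[ty, tx] - C[sy, sx])
    return d


def periodic_distance(ay, ax, by, bx, height, width) -> float:
    """Minimal-image Euclidean distance between two points."""
    dy = ay - by
    dy -= height * round(dy / height)
    dx = ax - bx
    dx -= width * round(dx / width)
    return math.hypot(dy, dx)


def focal_point_delta(
    linked_pairs,
    positions_before: dict[int, tuple[float, float]],
    positions_after: dict[int, tuple[float, float]],
    height: int,
    width: int,
) -> float:
    """Change in sum lam_ij (l_ij - L_ij)^2 for the given links.

    ``linked_pairs`` is an iterable of (a, b, lam, L).  Positions (y, x) are
    taken from ``positions_after`` where present, else ``positions_before``.
    """
    d = 0.0
    for a, b, lam, L in linked_pairs:
        a, b = int(a), int(b)
        pa0 = positions_before[a]
        pb0 = positions_before[b]
        pa1 = positions_after.get(a, pa0)
        pb1 = positions_after.get(b, pb0)
        l0 = periodic_distance(pa0[0], pa0[1], pb0[0], pb0[1], height, width)
        l1 = periodic_distance(pa1[0], pa1[1], pb1[0], pb1[1], height, width)
        d += lam * ((l1 - L) ** 2 - (l0 - L) ** 2)
    return d


def _rep_coord(x: float, ref: float, period: int) -> float:
    """Representative of x (mod period) closest to ref."""
    d = x - ref
    d -= period * round(d / period)
    return ref + d


def _fpp_delta_for_copy(lat: Lattice, gain: int, lose: int, target_site,
                        cfg: EnergyConfig) -> float:
    """FPP energy change when ``target_site`` flips from ``lose`` to ``gain``."""
    ep = {int(CellType.ECM), int(CellType.BASAL)}
    affected = [c for c in (gain, lose)
                if c != 0 and int(lat.ctype[c]) in ep and lat.volume[c] > 0]
    if not affected or not lat.links:
        return 0.0
    ty, tx = target_site
    before: dict[int, tuple[float, float]] = {}
    after: dict[int, tuple[float, float]] = {}
    relevant = [ln for ln in lat.links
                if int(ln[0]) in (gain, lose) or int(ln[1]) in (gain, lose)]
    if not relevant:
        return 0.0
    for ln in relevant:
        for c in (int(ln[0]), int(ln[1])):
            if c not in before and lat.volume[c] > 0:
                before[c] = lat.com(c)
    for c in affected:
        cy, cx = lat.com(c)
        ry = _rep_coord(ty, cy, lat.height)
        rx = _rep_coord(tx, cx, lat.width)
        if c == gain:
            v = lat.volume[c]
            after[c] = (
                ((lat.sum_y[c] + ry) / (v + 1)) % lat.height,
                ((lat.sum_x[c] + rx) / (v + 1)) % lat.width,
            )
        else:
            v = lat.volume[c]
            if v <= 1:
                continue
            after[c] = (
                ((lat.sum_y[c] - ry) / (v - 1)) % lat.height,
                ((lat.sum_x[c] - rx) / (v - 1)) % lat.width,
            )
    keep = [ln for ln in relevant if int(ln[0]) in before and int(ln[1]) in before]
    return focal_point_delta(keep, before, after, lat.height, lat.width)


def update_links(lat: Lattice, cfg: EnergyConfig) -> None:
    """Break over-stretched links and re-form broken ones.

    A link whose length exceeds ``fpp_max_distance`` is removed.  An
    epithelial cell with fewer than two links may re-link to its nearest
    unlinked epithelial neighbor within range.
    """
    ep_ids = [c for c in range(1, lat.n_cells)
              if lat.alive[c] and int(lat.ctype[c]) in
              (int(CellType.ECM), int(CellType.BASAL)) and lat.volume[c] > 0]
    if not ep_ids:
        return
    coms = {c: lat.com(c) for c in ep_ids}
    kept = []
    for a, b, lam, L in lat.links:
        a, b = int(a), int(b)
        if a not in coms or b not in coms:
            continue
        l = periodic_distance(*coms[a], *coms[b], lat.height, lat.width)
        if l <= cfg.fpp_max_distance:
            kept.append([a, b, lam, L])
    lat.links = kept
    degree = {c: 0 for c in ep_ids}
    linked = set()
    for a, b, _, _ in lat.links:
        degree[int(a)] += 1
        degree[int(b)] += 1
        linked.add((int(a), int(b)))
        linked.add((int(b), int(a)))
    for c in ep_ids:
        if degree[c] >= 2:
            continue
        best, best_d = None, cfg.fpp_max_distance
        for o in ep_ids:
            if o == c or (c, o) in linked or int(lat.ctype[o]) != int(lat.ctype[c]):
                continue
            d = periodic_distance(*coms[c], *coms[o], lat.height, lat.width)
            if d < best_d:
                best, best_d = o, d
        if best is not None:
            lat.links.append([c, best, cfg.lambda_fpp, cfg.fpp_target_length])
            linked.add((c, best))
            linked.add((best, c))
            degree[c] += 1
            degree[best] += 1


# ----------------------------------------------------------------------
# Single voxel-copy attempt (reference path)


def _apply_copy(lat: Lattice, gain: int, lose: int, target_site) -> None:
    ty, tx = target_site
    cnt4 = {gain: 0, lose: 0}
    for dy, dx in VON_NEUMANN:
        nb = lat.owner[(ty + dy) % lat.height, (tx + dx) % lat.width]
        if nb in cnt4:
            cnt4[nb] += 1
    lat.owner[ty, tx] = gain
    if gain == 0:
        lat.volume[0] += 1
    if lose == 0:
        lat.volume[0] -= 1
    if gain != 0:
        cy, cx = lat.com(gain)
        lat.sum_y[gain] += _rep_coord(ty, cy, lat.height)
        lat.sum_x[gain] += _rep_coord(tx, cx, lat.width)
        lat.volume[gain] += 1
        lat.surface[gain] += 4 - 2 * cnt4[gain]
    if lose != 0:
        cy, cx = lat.com(lose)
        lat.sum_y[lose] -= _rep_coord(ty, cy, lat.height)
        lat.sum_x[lose] -= _rep_coord(tx, cx, lat.width)
        lat.volume[lose] -= 1
        lat.surface[lose] += 2 * cnt4[lose] - 4
        if lat.volume[lose] == 0:
            lat.surface[lose] = 0
            lat.sum_x[lose] = 0.0
            lat.sum_y[lose] = 0.0


def attempt_voxel_copy(
    lat: Lattice,
    chemo_potential: np.ndarray | None,
    cfg: EnergyConfig,
    rng: np.random.Generator | None = None,
    *,
    site: int | None = None,
    neigh: int | None = None,
    u: float | None = None,
    apply: bool = True,
) -> bool:
    """One Metropolis voxel-copy attempt; returns whether it was accepted.

    ``chemo_potential`` is the pre-summed chemoattractant field (glucose +
    glutamine + oxygen); chemotaxis applies only when the gaining (moving)
    cell is of a proliferating type.  Randomness may be supplied explicitly
    (``site``, ``neigh``, ``u``) for replay against the compiled kernel.
    """
    H, W = lat.height, lat.width
    if site is None:
        site = int(rng.integers(0, H * W))
    if neigh is None:
        neigh = int(rng.integers(0, 8))
    if u is None:
        u = float(rng.random())
    sy, sx = divmod(site, W)
    dy, dx = MOORE[neigh]
    ty, tx = (sy + int(dy)) % H, (sx + int(dx)) % W
    src = int(lat.owner[sy, sx])
    tgt = int(lat.owner[ty, tx])
    if src == tgt:
        return False
    dH = adhesion_delta(lat, (sy, sx), (ty, tx), cfg.J)
    dH += volume_surface_delta(lat, src, tgt, (ty, tx), cfg)
    if chemo_potential is not None and src != 0 and int(lat.ctype[src]) in (
        int(CellType.PCANCER), int(CellType.PSTEM)
    ):
        dH += chemotaxis_delta(chemo_potential, (sy, sx), (ty, tx), cfg.lambda_chem)
    dH += _fpp_delta_for_copy(lat, src, tgt, (ty, tx), cfg)
    if dH > 0 and u >= math.exp(-dH / cfg.Tm):
        return False
    if apply:
        _apply_copy(lat, src, tgt, (ty, tx))
    return True


# ----------------------------------------------------------------------
# Compiled Monte Carlo step


@njit(cache=True)
def _pdist(ay, ax, by, bx, H, W):
    dy = ay - by
    dy -= H * round(dy / H)
    dx = ax - bx
    dx -= W * round(dx / W)
    return math.sqrt(dy * dy + dx * dx)


@njit(cache=True)
def _rep(x, ref, period):
    d = x - ref
    d -= period * round(d / period)
    return ref + d


@njit(cache=True)
def _mcs_kernel(
    owner, ctype, volume, surface, tvol, tsurf, sumx, sumy,
    lam_v, lam_s, J, chemo_type, lam_chem, chemo, Tm, quadratic,
    ep_type, link_indptr, link_partner, link_lam, link_L,
    rand_site, rand_neigh, rand_u, moore,
):
    H, W = owner.shape
    accepted = 0
    n = rand_site.shape[0]
    for a in range(n):
        s = rand_site[a]
        sy = s // W
        sx = s - sy * W
        k = rand_neigh[a]
        ty = (sy + moore[k, 0]) % H
        tx = (sx + moore[k, 1]) % W
        src = owner[sy, sx]
        tgt = owner[ty, tx]
        if src == tgt:
            continue
        ts = ctype[src]
        tt = ctype[tgt]
        # adhesion over the Moore neighborhood of the target site
        dH = 0.0
        c4_src = 0
        c4_tgt = 0
        for m in range(8):
            ny = (ty + moore[m, 0]) % H
            nx = (tx + moore[m, 1]) % W
            nb = owner[ny, nx]
            tn = ctype[nb]
            if nb != src:
                dH += J[ts, tn]
            if nb != tgt:
                dH -= J[tt, tn]
            if m < 4:
                if nb == src:
                    c4_src += 1
                if nb == tgt:
                    c4_tgt += 1
        # volume / surface constraints
        if src != 0:
            V = volume[src]
            S = surface[src]
            dS = 4 - 2 * c4_src
            if quadratic:
                dH += lam_v[ts] * ((V + 1 - tvol[src]) ** 2 - (V - tvol[src]) ** 2)
                dH += lam_s[ts] * ((S + dS - tsurf[src]) ** 2 - (S - tsurf[src]) ** 2)
            else:
                dH += lam_v[ts] + lam_s[ts] * dS
        if tgt != 0:
            V = volume[tgt]
            S = surface[tgt]
            dS = 2 * c4_tgt - 4
            if quadratic:
                dH += lam_v[tt] * ((V - 1 - tvol[tgt]) ** 2 - (V - tvol[tgt]) ** 2)
                dH += lam_s[tt] * ((S + dS - tsurf[tgt]) ** 2 - (S - tsurf[tgt]) ** 2)
            else:
                dH += -lam_v[tt] + lam_s[tt] * dS
        # chemotaxis for the moving (gaining) cell
        if src != 0 and chemo_type[ts]:
            dH += -lam_chem * (chemo[ty, tx] - chemo[sy, sx])
        # focal-point plasticity for epithelial cells
        gy_new = 0.0
        gx_new = 0.0
        ly_new = 0.0
        lx_new = 0.0
        g_ep = src != 0 and ep_type[ts]
        l_ep = tgt != 0 and ep_type[tt]
        if g_ep or l_ep:
            if g_ep:
                v = volume[src]
                cy = sumy[src] / v
                cx = sumx[src] / v
                ry = _rep(ty, cy, H)
                rx = _rep(tx, cx, W)
                gy_new = (sumy[src] + ry) / (v + 1)
                gx_new = (sumx[src] + rx) / (v + 1)
            if l_ep and volume[tgt] > 1:
                v = volume[tgt]
                cy = sumy[tgt] / v
                cx = sumx[tgt] / v
                ry = _rep(ty, cy, H)
                rx = _rep(tx, cx, W)
                ly_new = (sumy[tgt] - ry) / (v - 1)
                lx_new = (sumx[tgt] - rx) / (v - 1)
            else:
                l_ep = l_ep and False
            for who in range(2):
                cell = src if who == 0 else tgt
                is_ep = g_ep if who == 0 else l_ep
                if not is_ep:
                    continue
                my_new_y = gy_new if who == 0 else ly_new
                my_new_x = gx_new if who == 0 else lx_new
                my_old_y = sumy[cell] / volume[cell]
                my_old_x = sumx[cell] / volume[cell]
                for li in range(link_indptr[cell], link_indptr[cell + 1]):
                    p = link_partner[li]
                    if who == 1 and p == src:
                        continue  # the src-tgt link was handled from src's side
                    if volume[p] == 0:
                        continue
                    if p == tgt and who == 0 and l_ep:
                        py_old = sumy[p] / volume[p]
                        px_old = sumx[p] / volume[p]
                        py_new = ly_new
                        px_new = lx_new
                    elif p == src and who == 1:
                        continue
                    else:
                        py_old = sumy[p] / volume[p]
                        px_old = sumx[p] / volume[p]
                        py_new = py_old
                        px_new = px_old
                    l0 = _pdist(my_old_y, my_old_x, py_old, px_old, H, W)
                    l1 = _pdist(my_new_y, my_new_x, py_new, px_new, H, W)
                    lam = link_lam[li]
                    L0 = link_L[li]
                    dH += lam * ((l1 - L0) ** 2 - (l0 - L0) ** 2)
        # Metropolis rule
        if dH > 0.0 and rand_u[a] >= math.exp(-dH / Tm):
            continue
        # apply the copy, maintaining caches incrementally
        owner[ty, tx] = src
        if src == 0:
            volume[0] += 1
        if tgt == 0:
            volume[0] -= 1
        if src != 0:
            v = volume[src]
            cy = sumy[src] / v
            cx = sumx[src] / v
            sumy[src] += _rep(ty, cy, H)
            sumx[src] += _rep(tx, cx, W)
            volume[src] = v + 1
            surface[src] += 4 - 2 * c4_src
        if tgt != 0:
            v = volume[tgt]
            cy = sumy[tgt] / v
            cx = sumx[tgt] / v
            sumy[tgt] -= _rep(ty, cy, H)
            sumx[tgt] -= _rep(tx, cx, W)
            volume[tgt] = v - 1
            surface[tgt] += 2 * c4_tgt - 4
            if volume[tgt] == 0:
                surface[tgt] = 0
                sumy[tgt] = 0.0
                sumx[tgt] = 0.0
        accepted += 1
    return accepted


def _links_csr(lat: Lattice):
    """Per-cell CSR view of the (symmetric) link list for the kernel."""
    cap = lat._cap
    per_cell: list[list[tuple[int, float, float]]] = [[] for _ in range(cap)]
    for a, b, lam, L in lat.links:
        a, b = int(a), int(b)
        per_cell[a].append((b, lam, L))
        per_cell[b].append((a, lam, L))
    indptr = np.zeros(cap + 1, dtype=np.int64)
    for c in range(cap):
        indptr[c + 1] = indptr[c] + len(per_cell[c])
    n = indptr[-1]
    partner = np.zeros(n, dtype=np.int64)
    lam_arr = np.zeros(n)
    L_arr = np.zeros(n)
    i = 0
    for c in range(cap):
        for p, lam, L in per_cell[c]:
            partner[i] = p
            lam_arr[i] = lam
            L_arr[i] = L
            i += 1
    return indptr, partner, lam_arr, L_arr


_CHEMO_TYPE = np.zeros(N_TYPES, dtype=np.bool_)
for _t in PROLIFERATING_TYPES:
    _CHEMO_TYPE[int(_t)] = True
_EP_TYPE = np.zeros(N_TYPES, dtype=np.bool_)
for _t in EPITHELIAL_TYPES:
    _EP_TYPE[int(_t)] = True


def monte_carlo_step(
    lat: Lattice,
    chemo_potential: np.ndarray | None,
    cfg: EnergyConfig,
    rng: np.random.Generator,
    n_attempts: int | None = None,
) -> int:
    """One Monte Carlo step: width*height voxel-copy attempts (compiled).

    Returns the number of accepted copies.  All randomness is drawn from
    ``rng`` up-front, so a run is fully determined by (config, seed).
    """
    H, W = lat.height, lat.width
    if n_attempts is None:
        n_attempts = H * W
    rand_site = rng.integers(0, H * W, size=n_attempts)
    rand_neigh = rng.integers(0, 8, size=n_attempts)
    rand_u = rng.random(n_attempts)
    if chemo_potential is None:
        chemo_potential = np.zeros((H, W))
    indptr, partner, lam_arr, L_arr = _links_csr(lat)
    accepted = _mcs_kernel(
        lat.owner, lat.ctype, lat.volume, lat.surface,
        lat.target_volume, lat.target_surface, lat.sum_x, lat.sum_y,
        cfg.lambda_v, cfg.lambda_s, cfg.J, _CHEMO_TYPE, cfg.lambda_chem,
        np.ascontiguousarray(chemo_potential), cfg.Tm,
        cfg.volume_form == "quadratic",
        _EP_TYPE, indptr, partner, lam_arr, L_arr,
        rand_site, rand_neigh, rand_u, MOORE,
    )
    return int(accepted)


# ----------------------------------------------------------------------
# Snapshot writer


def write_snapshot(lat: Lattice, path_prefix: str, image: bool = False) -> None:
    """Write the integer owner and type maps as delimited text (and PNG)."""
    np.savetxt(path_prefix + "_owner.txt", lat.owner, fmt="%d")
    type_map = lat.ctype[lat.owner]
    np.savetxt(path_prefix + "_type.txt", type_map, fmt="%d")
    if image:
        import imageio.v3 as iio

        palette = np.array(
            [
                [240, 240, 240],  # Medium
                [233, 150, 180],  # ECM
                [40, 60, 140],    # Basal
                [60, 220, 60],    # PCancer
                [10, 120, 10],    # PStem
                [140, 200, 255],  # QCancer
                [40, 80, 200],    # QStem
                [220, 40, 40],    # Necrotic
            ],
            dtype=np.uint8,
        )
        iio.imwrite(path_prefix + "_type.png", palette[type_map])
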