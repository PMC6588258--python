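"""Shared fixtures: small lattices, baseline parameters, oracle helpers."""

import numpy as np
import pytest

from spheromet.cpm import MOORE, VON_NEUMANN, Lattice, periodic_distance
from spheromet.params import CellType, EnergyConfig, SimulationParameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def energy_cfg():
    cfg = EnergyConfig()
    cfg.validate()
    return cfg


def make_random_lattice(width, height, n_cells, rng, cfg=None,
                        types=(CellType.PCANCER, CellType.QCANCER,
                               CellType.NECROTIC)):
    """Small lattice with randomly grown blob cells, caches rebuilt."""
    lat = Lattice(width, height)
    for i in range(n_cells):
        t = types[i % len(types)]
        cid = lat.new_cell(t, target_volume=4.0, target_surface=8.0)
        y, x = int(rng.integers(height)), int(rng.integers(width))
        lat.owner[y, x] = cid
        for _ in range(int(rng.integers(2, 6))):
            dy, dx = MOORE[int(rng.integers(8))]
            y, x = (y + int(dy)) % height, (x + int(dx)) % width
            lat.owner[y, x] = cid
    lat.recount()
    return lat


def brute_force_hamiltonian(lat, cfg):
    """Independent total-energy computation from the raw owner map.

    Sums adhesion over unordered Moore pairs (same-cell pairs contribute
    zero), the quadratic volume/surface constraints for every non-Medium
    cell (volume and surface recounted from scratch), and the focal-point
    link energies.  Deliberately O(N^2)-naive; used only on tiny lattices.
    """
    H, W = lat.height, lat.width
    owner = lat.owner
    e = 0.0
    # each unordered Moore pair exactly once
    half = [(0, 1), (1, 0), (1, 1), (1, -1)]
    for y in range(H):
        for x in range(W):
            a = owner[y, x]
            for dy, dx in half:
                b = owner[(y + dy) % H, (x + dx) % W]
                if a != b:
                    e += cfg.J[lat.ctype[a], lat.ctype[b]]
    for cid in range(1, lat.n_cells):
        # a cell squeezed to zero volume still pays its constraint energy
        vol = int((owner == cid).sum())
        surf = 0
        ys, xs = np.nonzero(owner == cid)
        for y, x in zip(ys, xs):
            for dy, dx in VON_NEUMANN:
                if owner[(y + dy) % H, (x + dx) % W] != cid:
                    surf += 1
        t = lat.ctype[cid]
        quad = cfg.volume_form == "quadratic"
        dv = vol - lat.target_volume[cid]
        ds = surf - lat.target_surface[cid]
        if quad:
            e += cfg.lambda_v[t] * dv * dv + cfg.lambda_s[t] * ds * ds
        else:
            e += cfg.lambda_v[t] * dv + cfg.lambda_s[t] * ds
    for a, b, lam, L in lat.links:
        a, b = int(a), int(b)
        va = int((owner == a).sum())
        vb = int((owner == b).sum())
        if va == 0 or vb == 0:
            continue
        ca = lat.com(a)
        cb = lat.com(b)
        ell = periodic_distance(ca[0], ca[1], cb[0], cb[1], H, W)
        e += lam * (ell - L) ** 2
    return e


@pytest.fixture(scope="session")
def desk_params():
    return SimulationParameters.desk(width=60, total_mcs=300)
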