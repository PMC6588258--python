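"""Simulation orchestration: world construction, the multiscale step, metrics.

One Monte Carlo step (MCS) represents 6 minutes.  Within each MCS the
driver (1) re-solves the quasi-static nutrient fields against the current
uptake sinks, (2) samples each viable cell's extracellular concentrations
at its center of mass, (3) integrates each cell's metabolic ODEs for 6
minutes, and (4) performs one lattice Monte Carlo step; every 50 MCS
(5 hours) the cell-decision rules run (attribute accrual, growth or
shrinkage, stress, state transitions, mitosis).  A run of 6000 MCS
corresponds to 25 days of spheroid growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decisions as dec
from .cpm import Lattice, monte_carlo_step, update_links
from .fields import NutrientField, deposit_lactate_burst, sample_at_center_of_mass
from .metabolism import (
    EXT_IDX,
    IDX,
    MetabolicNetwork,
    base_state_vector,
    integrate_population,
    network_from_config,
)
from .params import (
    PROLIFERATING_TYPES,
    SPECIES,
    TUMOR_TYPES,
    VIABLE_TYPES,
    CellType,
    SimulationParameters,
)

SCENARIO_TYPES = {
    "I": (CellType.PCANCER, CellType.PSTEM, CellType.QCANCER, CellType.QSTEM),
    "II": (CellType.PCANCER, CellType.PSTEM),
    "III": (CellType.QCANCER, CellType.QSTEM),
    "IV": (CellType.PCANCER,),
    "V": (CellType.PSTEM,),
}


@dataclass
class Clock:
    """Simulation clock: 6 min per MCS, decisions every 50 MCS."""

    mcs: int = 0
    minutes_per_mcs: float = 6.0
    decision_interval_mcs: int = 50
    total_mcs: int = 6000

    @property
    def day(self) -> float:
        return self.mcs * self.minutes_per_mcs / 1440.0

    @property
    def n_decision_steps(self) -> int:
        return self.total_mcs // self.decision_interval_mcs


def _split(total: int, target: int) -> list[tuple[int, int]]:
    """Partition [0, total) into nearly equal chunks of about ``target``."""
    n = max(1, round(total / target))
    bounds = np.linspace(0, total, n + 1).astype(int)
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(n)]


class World:
    """Mutable simulation state for one run."""

    def __init__(self, params: SimulationParameters, lattice: Lattice,
                 fields: dict[str, NutrientField], network: MetabolicNetwork,
                 rng: np.random.Generator, seed: int | None = None):
        self.params = params
        self.lat = lattice
        self.fields = fields
        self.network = network
        self.rng = rng
        self.seed = seed
        ck = params.clock
        self.clock = Clock(0, ck.minutes_per_mcs, ck.decision_interval_mcs,
                           ck.total_mcs)
        self.day0_volume: float | None = None
        self.records: list[dict] = []
        self._pending_knockdowns = sorted(
            params.metabolism.knockdowns, key=lambda k: k.day
        )
        self.knockdown_log: list[dict] = []
        self._last_uptake: dict[int, np.ndarray] = {}

    # -- bookkeeping ---------------------------------------------------
    def viable_cells(self) -> np.ndarray:
        lat = self.lat
        ids = np.arange(1, lat.n_cells)
        mask = lat.alive[1:lat.n_cells] & np.isin(
            lat.ctype[1:lat.n_cells], [int(t) for t in VIABLE_TYPES]
        ) & (lat.volume[1:lat.n_cells] > 0)
        return ids[mask]

    def tumor_cells(self) -> np.ndarray:
        lat = self.lat
        ids = np.arange(1, lat.n_cells)
        mask = lat.alive[1:lat.n_cells] & np.isin(
            lat.ctype[1:lat.n_cells], [int(t) for t in TUMOR_TYPES]
        ) & (lat.volume[1:lat.n_cells] > 0)
        return ids[mask]

    def tumor_volume(self) -> int:
        return int(self.lat.volume[self.tumor_cells()].sum())

    def chemo_potential(self) -> np.ndarray:
        return (self.fields["glucose"].C + self.fields["glutamine"].C
                + self.fields["oxygen"].C)

    # -- the multiscale step -------------------------------------------
    def _apply_scheduled_knockdowns(self) -> None:
        from .metabolism import apply_knockdown

        mcs_per_day = self.params.clock.mcs_per_day
        while self._pending_knockdowns and (
            self.clock.mcs >= self._pending_knockdowns[0].day * mcs_per_day
        ):
            kd = self._pending_knockdowns.pop(0)
            self.network = apply_knockdown(
                self.network, kd.reaction, kd.mode, self.rng,
                mean=self.params.metabolism.partial_mean,
                sd=self.params.metabolism.partial_sd,
            )
            self.knockdown_log.append({
                "mcs": self.clock.mcs, "reaction": kd.reaction,
                "mode": kd.mode,
                "factor": self.network.knockdown_draws[kd.reaction],
            })

    def _solve_fields(self) -> None:
        lat = self.lat
        type_map = lat.ctype[lat.owner]
        # linearized uptake sinks at each viable cell's center-of-mass site
        for f in self.fields.values():
            f.sink_g[:] = 0.0
        ids = np.array([c for c in self._last_uptake
                        if lat.alive[c] and lat.volume[c] > 0], dtype=np.int64)
        if len(ids):
            sites = lat.com_sites(ids)
            for k, cid in enumerate(ids):
                sy, sx = int(sites[k, 0]), int(sites[k, 1])
                uptake = self._last_uptake[int(cid)]
                for ei, sp in enumerate(SPECIES):
                    amt = uptake[ei]
                    f = self.fields[sp]
                    if amt > 0.0:
                        f.sink_g[sy, sx] += amt / (f.C[sy, sx] + 1e-9)
                    elif amt < 0.0:
                        f.transient_source[sy, sx] += -amt
        for f in self.fields.values():
            f.solve(type_map)

    def step(self) -> None:
        """Advance the world by one MCS."""
        if self.clock.mcs >= self.clock.total_mcs:
            raise RuntimeError("simulation horizon reached")
        p = self.params
        lat = self.lat
        self._apply_scheduled_knockdowns()
        if self.clock.mcs % p.field_refresh_cadence == 0:
            self._solve_fields()
        # sample and integrate intracellular dynamics
        viable = self.viable_cells()
        self._last_uptake = {}
        if len(viable):
            ext_mat = np.zeros((lat._cap, len(SPECIES)))
            active = np.zeros(lat._cap, dtype=np.bool_)
            sites = lat.com_sites(viable)
            for ei, sp in enumerate(SPECIES):
                ext_mat[viable, ei] = self.fields[sp].C[sites[:, 0], sites[:, 1]]
            active[viable] = True
            arrays = self.network.compile()
            (vf, sub_idx, sub_km, ext_idx, ext_km, inh_idx, inh_ki,
             stoich, ext_st, gate) = arrays
            exch = integrate_population(
                lat.conc, ext_mat, active, self.clock.minutes_per_mcs,
                p.metabolism.dt_substep_min, vf, sub_idx, sub_km, ext_idx,
                ext_km, inh_idx, inh_ki, stoich, ext_st, gate,
                EXT_IDX["glucose"],
            )
            for cid in viable:
                # fmol exchanged with the environment this MCS (+ = uptake)
                self._last_uptake[int(cid)] = -exch[cid] * lat.volume[cid]
        # lattice dynamics
        monte_carlo_step(lat, self.chemo_potential(), p.energy, self.rng)
        self.clock.mcs += 1
        if self.clock.mcs % self.clock.decision_interval_mcs == 0:
            self._decision_step()
            self.measure()

    def _decision_step(self) -> None:
        p = self.params.decisions
        lat = self.lat
        update_links(lat, self.params.energy)
        neigh = lat.neighbor_counts()
        for cid in list(self.viable_cells()):
            atp = lat.conc[cid, IDX["ATP"]]
            ext_lac = sample_at_center_of_mass(self.fields["lactate"].C, lat, cid)
            dec.accumulate_attributes(lat, cid, atp, ext_lac, p)
            dec.stress_update(lat, cid, int(neigh[cid]), p)
            t = CellType(lat.ctype[cid])
            if t in PROLIFERATING_TYPES:
                gsum = (lat.conc[cid, IDX["ATP"]]
                        + lat.conc[cid, IDX["Glc_in"]]
                        + lat.conc[cid, IDX["Gln_in"]])
                dec.growth_update(lat, cid, gsum, p)
            new = dec.evaluate_transitions(lat, cid, p)
            if new == CellType.NECROTIC:
                deposit_lactate_burst(self.fields["lactate"], lat, cid,
                                      IDX["Lac_in"])
        # necrotic shrinkage / clearance
        for cid in range(1, lat.n_cells):
            if (lat.alive[cid]
                    and CellType(lat.ctype[cid]) == CellType.NECROTIC
                    and lat.volume[cid] > 0):
                dec.necrotic_shrink(lat, cid, p)
        # mitosis checks
        for cid in list(self.viable_cells()):
            t = CellType(lat.ctype[cid])
            if t not in PROLIFERATING_TYPES:
                continue
            vmax_mit = p.Pvolmaxmit if t == CellType.PCANCER else p.Svolmaxmit
            if (lat.volume[cid] >= vmax_mit
                    and lat.health[cid] >= dec.proliferation_threshold(p)):
                did = dec.mitosis(lat, cid, self.rng, p)
                if did is None and CellType(lat.ctype[cid]) == CellType.NECROTIC:
                    deposit_lactate_burst(self.fields["lactate"], lat, cid,
                                          IDX["Lac_in"])

    # -- metrics --------------------------------------------------------
    def measure(self) -> dict:
        """Record tumor volume, fold-change, per-type counts and totals."""
        lat = self.lat
        vol = self.tumor_volume()
        if self.day0_volume is None:
            self.day0_volume = float(vol) if vol > 0 else 1.0
        rec = {
            "mcs": self.clock.mcs,
            "day": self.clock.day,
            "tumor_volume": vol,
            "fold_change": vol / self.day0_volume,
        }
        ids = self.tumor_cells()
        types = lat.ctype[ids]
        n_tot = max(len(ids), 1)
        for t in TUMOR_TYPES:
            n = int((types == int(t)).sum())
            rec[f"n_{t.name.lower()}"] = n
            rec[f"frac_{t.name.lower()}"] = n / n_tot
        rec["n_cells"] = len(ids)
        if self.params.record_metabolites and lat.conc is not None:
            viable = self.viable_cells()
            if len(viable):
                totals = (lat.conc[viable].T * lat.volume[viable]).sum(axis=1)
            else:
                totals = np.zeros(lat.conc.shape[1])
            for i, s in enumerate(self.network.species):
                rec[f"total_{s}"] = float(totals[i])
        self.records.append(rec)
        return rec

    def metabolite_slices(self) -> pd.DataFrame:
        """Per-lattice-row totals of each intracellular metabolite.

        Each cell's amount (concentration x volume) is distributed over the
        rows it occupies, proportionally to its per-row voxel counts; the
        slice sums over all rows therefore equal the spatial aggregate.
        """
        lat = self.lat
        rows = []
        for cid in self.viable_cells():
            sites = lat.cell_sites(cid)
            counts = np.bincount(sites[:, 0], minlength=lat.height)
            occupied = np.nonzero(counts)[0]
            for y in occupied:
                w = counts[y]
                for i, s in enumerate(self.network.species):
                    rows.append({
                        "row": int(y), "species": s,
                        "amount": float(lat.conc[cid, i] * w),
                    })
        if not rows:
            return pd.DataFrame(columns=["row", "species", "amount"])
        df = pd.DataFrame(rows)
        return df.groupby(["row", "species"], as_index=False)["amount"].sum()

    def layering(self) -> dict[str, float]:
        """Mean periodic distance from the tumor centroid, per cell class."""
        lat = self.lat
        ids = self.tumor_cells()
        if len(ids) == 0:
            return {}
        coms = np.array([lat.com(c) for c in ids])
        vols = lat.volume[ids].astype(float)
        # centroid via circular mean on each axis
        out = {}
        ang_y = coms[:, 0] / lat.height * 2 * np.pi
        ang_x = coms[:, 1] / lat.width * 2 * np.pi
        cy = (np.arctan2(np.average(np.sin(ang_y), weights=vols),
                         np.average(np.cos(ang_y), weights=vols))
              % (2 * np.pi)) / (2 * np.pi) * lat.height
        cx = (np.arctan2(np.average(np.sin(ang_x), weights=vols),
                         np.average(np.cos(ang_x), weights=vols))
              % (2 * np.pi)) / (2 * np.pi) * lat.width
        dy = coms[:, 0] - cy
        dy -= lat.height * np.round(dy / lat.height)
        dx = coms[:, 1] - cx
        dx -= lat.width * np.round(dx / lat.width)
        dist = np.hypot(dy, dx)
        types = lat.ctype[ids]
        for label, tset in (
            ("necrotic", (CellType.NECROTIC,)),
            ("proliferating", PROLIFERATING_TYPES),
            ("quiescent", (CellType.QCANCER, CellType.QSTEM)),
        ):
            m = np.isin(types, [int(t) for t in tset])
            if m.any():
                out[label] = float(dist[m].mean())
        return out

    def trajectory(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records)
        df.attrs["seed"] = self.seed
        df.attrs["config_hash"] = self.params.config_hash()
        return df


# ----------------------------------------------------------------------
# Construction


def build_world(params: SimulationParameters,
                rng: np.random.Generator | int | None = None,
                network: MetabolicNetwork | None = None,
                initial_states: list[np.ndarray] | None = None) -> World:
    """Construct the lattice, epithelial bands, nutrient fields and tumor seed.

    The fields are pre-solved to their tumor-free steady state (uniform at
    each species' baseline) before the nine-cell cluster is placed at the
    lattice center with types drawn from the configured scenario.
    """
    params.validate()
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = int(rng) if rng is not None else 0
        rng = np.random.default_rng(seed)
    g = params.geometry
    lat = Lattice(g.width, g.height)
    dparams = params.decisions

    # epithelial bands: ECM along the lower edge, Basal along the upper
    band = g.band_depth
    if band > 0:
        for band_type, y0 in ((CellType.ECM, 0), (CellType.BASAL, g.height - band)):
            row_chunks = _split(band, g.epithelial_cell_size)
            col_chunks = _split(g.width, g.epithelial_cell_size)
            for (ry0, ry1) in row_chunks:
                for (cx0, cx1) in col_chunks:
                    h, w = ry1 - ry0, cx1 - cx0
                    cid = lat.new_cell(band_type, target_volume=h * w,
                                       target_surface=2 * (h + w))
                    lat.place_block(cid, y0 + ry0, cx0, h, w)

    # fields: tumor-free steady state before any tumor cells exist
    fields = {sp: NutrientField(cfg, g.height, g.width)
              for sp, cfg in params.fields.items()}
    lat.recount()
    type_map = lat.ctype[lat.owner]
    for f in fields.values():
        f.solve(type_map)

    # nine-cell cluster at the lattice center
    allowed = SCENARIO_TYPES[g.scenario]
    side = int(np.ceil(np.sqrt(dparams.V_normal)))
    grid = int(np.ceil(np.sqrt(g.n_initial_cells)))
    extent = grid * side
    y0 = g.height // 2 - extent // 2
    x0 = g.width // 2 - extent // 2
    if y0 < band or y0 + extent > g.height - band:
        raise ValueError("initial cluster would overlap the epithelial bands")
    placed = 0
    for gy in range(grid):
        for gx in range(grid):
            if placed >= g.n_initial_cells:
                break
            t = allowed[int(rng.integers(0, len(allowed)))]
            cid = lat.new_cell(t, target_volume=dparams.V_normal,
                               target_surface=4 * side,
                               temp=dec.draw_temp(rng, dparams))
            lat.place_block(cid, y0 + gy * side, x0 + gx * side, side, side)
            placed += 1
    lat.recount()

    if network is None:
        network = network_from_config(params.metabolism)
    base = base_state_vector() if network.source == "surrogate" else np.zeros(
        network.n_species
    )
    if network.source != "surrogate":
        base[: len(base_state_vector())] = base_state_vector()[
            : network.n_species
        ]
    lat.attach_metabolism(base)
    if initial_states is not None:
        tumor = [c for c in range(1, lat.n_cells)
                 if lat.ctype[c] in [int(t) for t in TUMOR_TYPES]]
        for cid, st in zip(tumor, initial_states):
            lat.conc[cid] = st

    # epithelial focal-point links
    update_links(lat, params.energy)

    world = World(params, lat, fields, network, rng, seed=seed)
    world.measure()  # day-0 record, fold-change 1
    return world


def run_simulation(params: SimulationParameters,
                   seed: int | np.random.Generator = 0,
                   network: MetabolicNetwork | None = None,
                   initial_states: list[np.ndarray] | None = None,
                   progress: bool = False) -> World:
    """Build a world and run it to its configured horizon."""
    world = build_world(params, seed, network=network,
                        initial_states=initial_states)
    it = range(params.clock.total_mcs)
    if progress:
        from tqdm import tqdm

        it = tqdm(it, desc="MCS")
    for _ in it:
        world.step()
    return world


def run_manifest(world: World) -> dict:
    """Provenance manifest for one completed run."""
    import spheromet

    return {
        "seed": world.seed,
        "config_hash": world.params.config_hash(),
        "version": spheromet.__version__,
        "mcs": world.clock.mcs,
        "knockdowns": world.knockdown_log,
        "n_cells_final": int(len(world.tumor_cells())),
    }
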