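"""Cell-decision layer: attribute accumulation, growth, death, transitions.

Every 5 simulated hours (50 MCS) each tumor cell is evaluated:

* it accrues **Health** while its ATP level is at or above the starvation
  gate ``atpD``, otherwise **Starvation**; over-exposure to extracellular
  lactate (> ``LacDeath``) accrues **Acidity**; persistently having more
  than ``N`` distinct neighbors accrues **Stress** linearly;
* accruals follow the saturating fitness factor
  F(x, Vmax, k) = Vmax * x^a / (x^a + k^a), with the Health increment
  scaled by exp(C) (an ATP-utilization coefficient) and quiescent cells
  running at 75% amplitude;
* quiescent cells whose Health reaches the threshold QCPThr (= QSSThr)
  wake to the proliferating state; any viable cell whose Starvation,
  Acidity or Stress crosses its respective threshold becomes necrotic —
  an irreversible transition that dumps the cell's lactate into the
  microenvironment;
* proliferating cells above their growth threshold enlarge their target
  volume; at doubling volume they divide (daughters inherit the parent's
  metabolic concentrations; all attributes reset), subject to a senescence
  limit drawn once per cell; necrotic cells shrink, to a quarter-volume
  floor in the core or to clearance at the periphery.
"""

from __future__ import annotations

import numpy as np

from .cpm import Lattice, _rep_coord
from .params import CellType, DecisionParameters


# ----------------------------------------------------------------------
# Fitness factor and thresholds


def fitness_factor(x: float, Vmax: float, k: float, a: float = 1.0) -> float:
    """Saturating accrual increment F(x, Vmax, k) = Vmax x^a / (x^a + k^a)."""
    if k <= 0:
        raise ValueError(f"Michaelis constant k must be > 0, got {k}")
    if x < 0 or Vmax < 0:
        raise ValueError("x and Vmax must be non-negative")
    if a < 1:
        raise ValueError("Hill exponent a must be >= 1")
    if x == 0.0:
        return 0.0
    xa = x ** a
    return Vmax * xa / (xa + k ** a)


def proliferation_threshold(p: DecisionParameters) -> float:
    """QCPThr = QSSThr: Health needed for a quiescent cell to wake.

    Saturates in Pos_conc (the reference glucose+glutamine+lactate level)
    with amplitude Total_time * V_atpmax.
    """
    return p.Total_time * p.V_atpmax * p.Pos_conc / (p.Pos_conc + p.atpK)


def necrosis_threshold_atp(p: DecisionParameters, quiescent: bool = False) -> float:
    """Starvation level at which a cell becomes necrotic (PNeThr).

    Quiescent and stem cells take longer to die and carry a higher
    threshold (configurable multiplier).
    """
    thr = p.Total_time * p.V_atpmax * p.Neg_concATP / (p.Neg_concATP + p.atpK)
    return thr * p.quiescent_thr_multiplier if quiescent else thr


def necrosis_threshold_acid(p: DecisionParameters, quiescent: bool = False) -> float:
    """Acidity level at which a cell becomes necrotic (PNeThra)."""
    thr = p.Total_timelac * p.V_lacmax * p.Pos_concLac / (p.Pos_concLac + p.LacK)
    return thr * p.quiescent_thr_multiplier if quiescent else thr


# ----------------------------------------------------------------------
# Attribute accumulation


def accumulate_attributes(lat: Lattice, cid: int, atp: float,
                          ext_lactate: float, p: DecisionParameters) -> None:
    """One decision step of Health / Starvation / Acidity accrual."""
    from .metabolism import perceived_vmax

    t = CellType(lat.ctype[cid])
    amp = perceived_vmax(t)
    if atp >= p.atpD:
        lat.health[cid] += np.exp(p.C) * fitness_factor(
            atp, p.V_atpmax * amp, p.atpK, p.hill_a
        )
    else:
        lat.starvation[cid] += fitness_factor(
            atp, p.V_atpmax * amp, p.atpK, p.hill_a
        )
    if ext_lactate > p.LacDeath:
        lat.acidity[cid] += fitness_factor(
            ext_lactate, p.V_lacmax * amp, p.LacK, p.hill_a
        )


def stress_update(lat: Lattice, cid: int, neighbor_count: int,
                  p: DecisionParameters) -> None:
    """Linear stress accrual while the cell has more than N neighbors.

    With ``stress_reset_on_relief`` the accumulated stress resets whenever
    the crowding condition is not met, so only *consecutive* crowded steps
    count.
    """
    if neighbor_count > p.N:
        lat.stress[cid] += p.StressIncrement
    elif p.stress_reset_on_relief:
        lat.stress[cid] = 0.0


# ----------------------------------------------------------------------
# Growth and shrinkage


def growth_update(lat: Lattice, cid: int, growth_sum: float,
                  p: DecisionParameters) -> None:
    """Increment a proliferating cell's target volume.

    ``growth_sum`` is the intracellular ATP + glucose + glutamine; growth
    only occurs strictly above the type's threshold.
    """
    t = CellType(lat.ctype[cid])
    if t == CellType.PCANCER:
        thr = p.PGrThr
    elif t == CellType.PSTEM:
        thr = p.SGrThr
    else:
        return  # growth is limited to proliferating cells
    if growth_sum > thr:
        lat.target_volume[cid] += p.incvol * (growth_sum - thr)


def necrotic_shrink(lat: Lattice, cid: int, p: DecisionParameters) -> bool:
    """Shrink a necrotic cell's target volume; returns True if removed.

    Periphery cells (flagged at transition time) shrink to zero and are
    cleared; core cells floor at a quarter of the normal cell volume.
    """
    if CellType(lat.ctype[cid]) != CellType.NECROTIC:
        raise ValueError(f"cell {cid} is not necrotic")
    floor = 0.0 if lat.at_periphery[cid] else (
        p.necrotic_core_floor_fraction * p.V_normal
    )
    lat.target_volume[cid] = max(lat.target_volume[cid] - p.decvol, floor)
    if lat.at_periphery[cid] and (
        lat.target_volume[cid] <= 0.0 or lat.volume[cid] == 0
    ):
        lat.remove_cell(cid)
        return True
    if lat.volume[cid] == 0:
        lat.alive[cid] = False
        return True
    return False


# ----------------------------------------------------------------------
# State transitions


def _reset_attributes(lat: Lattice, cid: int) -> None:
    lat.health[cid] = 0.0
    lat.starvation[cid] = 0.0
    lat.acidity[cid] = 0.0
    lat.stress[cid] = 0.0


def evaluate_transitions(lat: Lattice, cid: int, p: DecisionParameters) -> CellType:
    """Apply the state-transition rules to one cell; returns its new type.

    Quiescent cells wake when Health crosses QCPThr/QSSThr; any viable
    cell turns necrotic when Starvation, Acidity or Stress crosses its
    threshold.  Necrosis is irreversible; attributes reset on any change.
    """
    t = CellType(lat.ctype[cid])
    if t == CellType.NECROTIC:
        return t
    quiescent = t in (CellType.QCANCER, CellType.QSTEM)
    if (
        lat.starvation[cid] >= necrosis_threshold_atp(p, quiescent)
        or lat.acidity[cid] >= necrosis_threshold_acid(p, quiescent)
        or lat.stress[cid] > p.StressThr
    ):
        new = CellType.NECROTIC
    elif t == CellType.QCANCER and lat.health[cid] >= proliferation_threshold(p):
        new = CellType.PCANCER
    elif t == CellType.QSTEM and lat.health[cid] >= proliferation_threshold(p):
        new = CellType.PSTEM
    else:
        return t
    lat.ctype[cid] = int(new)
    _reset_attributes(lat, cid)
    if new == CellType.NECROTIC:
        lat.at_periphery[cid] = lat.touches_medium(cid)
    return new


def draw_temp(rng: np.random.Generator, p: DecisionParameters) -> int:
    """Senescence limit: one integerized Gaussian(maxdiv, temp_sd) draw."""
    return int(round(rng.normal(p.maxdiv, p.temp_sd)))


def mitosis(lat: Lattice, cid: int, rng: np.random.Generator,
            p: DecisionParameters) -> int | None:
    """Divide a proliferating cell; returns the daughter id (None if senescent).

    The cell's voxels are split into two equal halves (plus/minus one voxel)
    by a random plane through the center of mass.  The daughter inherits the
    parent's metabolic concentrations; both cells become quiescent (a PStem
    parent's daughter is QStem with probability probstem, else QCancer); all
    attributes reset.  A cell that has exhausted its division budget
    (divisions >= temp) becomes necrotic instead of dividing.
    """
    t = CellType(lat.ctype[cid])
    if t not in (CellType.PCANCER, CellType.PSTEM):
        raise ValueError(f"mitosis attempted on non-proliferating cell {cid} ({t.name})")
    if lat.divisions[cid] >= lat.temp[cid]:
        # senescence: mitosis arrested, the cell dies
        lat.ctype[cid] = int(CellType.NECROTIC)
        _reset_attributes(lat, cid)
        lat.at_periphery[cid] = lat.touches_medium(cid)
        return None
    sites = lat.cell_sites(cid)
    n = len(sites)
    if n < 2:
        return None
    cy, cx = lat.com(cid)
    # random division plane through the center of mass
    theta = rng.uniform(0.0, np.pi)
    uy, ux = np.sin(theta), np.cos(theta)
    dy = sites[:, 0] - cy
    dy -= lat.height * np.round(dy / lat.height)
    dx = sites[:, 1] - cx
    dx -= lat.width * np.round(dx / lat.width)
    proj = dy * uy + dx * ux
    order = np.argsort(proj, kind="stable")
    half = n // 2
    daughter_sites = sites[order[half:]] if n % 2 == 0 else sites[order[half + 1:]]
    # keep the extra voxel (odd n) with the parent
    if t == CellType.PCANCER:
        parent_type, daughter_type = CellType.QCANCER, CellType.QCANCER
    else:
        parent_type = CellType.QSTEM
        daughter_type = (CellType.QSTEM if rng.random() <= p.probstem
                         else CellType.QCANCER)
    did = lat.new_cell(daughter_type, target_volume=p.V_normal,
                       target_surface=lat.target_surface[cid],
                       temp=draw_temp(rng, p))
    if lat.conc is not None:
        lat.conc[did] = lat.conc[cid]
    lat.owner[daughter_sites[:, 0], daughter_sites[:, 1]] = did
    lat.divisions[cid] += 1
    lat.divisions[did] = lat.divisions[cid]
    lat.ctype[cid] = int(parent_type)
    lat.target_volume[cid] = p.V_normal
    _reset_attributes(lat, cid)
    _reset_attributes(lat, did)
    lat.recount()
    return did
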