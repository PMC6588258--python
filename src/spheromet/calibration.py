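"""Latin-hypercube calibration harness.

The cell-decision parameters are sampled within their calibration ranges (100 sets
by default) and each candidate set is screened against the selection
criteria: a roughly 10-fold tumor-volume change by day 15, significant
necrosis, an appropriate mix of proliferating / quiescent / necrotic cells
at the end of the run, and the ordering constraints
Neg_concATP < atpD < Pos_conc and Pos_concLac > LacDeath.  Candidates
failing the ordering constraints are rejected without simulation.

"Significant necrosis" and "appropriate distribution" are inherently
qualitative criteria; they are configurable floors here (defaults: necrotic fraction
>= 10%, all three viability classes present), reported per candidate so
users can re-threshold without re-simulating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .params import CellType, SimulationParameters

#: sampling ranges (one printed pair arrives inverted and is normalized
#: here) and the calibrated baseline values
TABLE1_RANGES: dict[str, tuple[float, float]] = {
    "incvol": (10.0, 50.0),
    "decvol": (0.001, 0.1),
    "PGrThr": (0.0032, 0.192),
    "SGrThr": (0.0032, 0.192),
    "StressIncrement": (0.25, 1.0),
    "StressThr": (20.0, 100.0),
    "N": (7.0, 10.0),
    "V_atpmax": (1.68e-3, 4.2),
    "atpD": (0.032, 0.064),   # printed min/max inverted; normalized
    "Total_time": (50.0, 240.0),
    "Neg_concATP": (0.0001, 0.015),
    "Pos_conc": (0.0064, 0.192),
    "V_lacmax": (1.11e-2, 27.75),
    "LacDeath": (0.1256, 2.75),
    "Pos_concLac": (0.1256, 2.75),
    "Total_timelac": (50.0, 240.0),
    "maxdiv": (4.0, 10.0),
    "probstem": (0.1, 0.8),
    "C": (6.0, 11.0),
}

INTEGER_PARAMS = ("N", "maxdiv")


@dataclass
class ParameterRange:
    name: str
    min: float
    max: float

    def __post_init__(self):
        if self.min > self.max:
            self.min, self.max = self.max, self.min


def default_ranges() -> list[ParameterRange]:
    return [ParameterRange(k, lo, hi) for k, (lo, hi) in TABLE1_RANGES.items()]


@dataclass
class CandidateResult:
    params: dict[str, float]
    constraint_flags: dict[str, bool]
    fold_change_day15: float | None = None
    necrotic_fraction: float | None = None
    has_significant_necrosis: bool | None = None
    type_distribution_ok: bool | None = None
    accepted: bool = False
    n_simulations: int = 0


def lhs_sample(ranges: list[ParameterRange], n: int, seed: int) -> pd.DataFrame:
    """Latin hypercube design: n sets, one sample per equal-probability stratum."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=len(ranges), seed=seed)
    unit = sampler.random(n)
    lo = np.array([r.min for r in ranges])
    hi = np.array([r.max for r in ranges])
    degenerate = lo == hi
    if degenerate.any():
        import warnings

        names = [r.name for r, d in zip(ranges, degenerate) if d]
        warnings.warn(f"degenerate (constant) ranges: {names}")
    vals = lo + unit * (hi - lo)  # affine scaling; degenerate columns constant
    df = pd.DataFrame(vals, columns=[r.name for r in ranges])
    for p in INTEGER_PARAMS:
        if p in df:
            df[p] = df[p].round().astype(int)
    return df


def check_constraints(paramset: dict[str, float]) -> dict[str, bool]:
    """The three strict ordering constraints a candidate must satisfy."""
    try:
        return {
            "neg_lt_atpD": paramset["Neg_concATP"] < paramset["atpD"],
            "pos_gt_atpD": paramset["Pos_conc"] > paramset["atpD"],
            "poslac_gt_lacdeath": paramset["Pos_concLac"] > paramset["LacDeath"],
        }
    except KeyError as e:
        raise KeyError(f"parameter set missing {e.args[0]!r}") from None


def _apply_paramset(base: SimulationParameters,
                    paramset: dict[str, float]) -> SimulationParameters:
    p = base.copy()
    for k, v in paramset.items():
        if not hasattr(p.decisions, k):
            raise KeyError(f"unknown decision parameter {k!r}")
        setattr(p.decisions, k, int(v) if k in INTEGER_PARAMS else float(v))
    return p


def evaluate_candidate(
    paramset: dict[str, float],
    n_replicates: int = 3,
    base_params: SimulationParameters | None = None,
    seed: int = 0,
    fold_band: tuple[float, float] = (8.0, 12.0),
    necrosis_floor: float = 0.10,
    fold_day: float = 15.0,
) -> CandidateResult:
    """Simulate one candidate parameter set and score the selection criteria.

    Candidates failing the ordering constraints are rejected with zero
    simulations.  Otherwise ``n_replicates`` runs are averaged: the
    fold-change at ``fold_day``, the necrotic fraction and the class mix
    at the end of the run.
    """
    from .driver import run_simulation

    flags = check_constraints(paramset)
    result = CandidateResult(params=dict(paramset), constraint_flags=flags)
    if not all(flags.values()):
        return result
    params = _apply_paramset(base_params or SimulationParameters.default(),
                             paramset)
    folds = []
    necro = []
    dist_ok = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        world = run_simulation(params, seed=rep_seed)
        df = world.trajectory()
        i = int((df["day"] - fold_day).abs().idxmin())
        folds.append(float(df["fold_change"].iloc[i]))
        last = df.iloc[-1]
        n = max(last["n_cells"], 1)
        necro.append(float(last["n_necrotic"] / n))
        prolif = last["n_pcancer"] + last["n_pstem"]
        quies = last["n_qcancer"] + last["n_qstem"]
        dist_ok.append(bool(prolif > 0 and quies > 0 and last["n_necrotic"] > 0))
        result.n_simulations += 1
    result.fold_change_day15 = float(np.mean(folds))
    result.necrotic_fraction = float(np.mean(necro))
    result.has_significant_necrosis = result.necrotic_fraction >= necrosis_floor
    result.type_distribution_ok = bool(np.mean(dist_ok) >= 0.5)
    result.accepted = (
        fold_band[0] <= result.fold_change_day15 <= fold_band[1]
        and result.has_significant_necrosis
        and result.type_distribution_ok
    )
    return result


def calibrate(
    n_candidates: int = 100,
    n_replicates: int = 3,
    seed: int = 0,
    base_params: SimulationParameters | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Full screening pass: LHS design, constraint gate, candidate scoring.

    Returns one row per candidate with all criteria values; rerunning with
    the same seeds yields an identical table.
    """
    design = lhs_sample(default_ranges(), n_candidates, seed)
    rows = []
    for i, paramset in design.iterrows():
        res = evaluate_candidate(
            paramset.to_dict(), n_replicates=n_replicates,
            base_params=base_params, seed=seed * 100003 + int(i), **kwargs,
        )
        row = dict(res.params)
        row.update({f"flag_{k}": v for k, v in res.constraint_flags.items()})
        row.update({
            "candidate": int(i),
            "fold_change_day15": res.fold_change_day15,
            "necrotic_fraction": res.necrotic_fraction,
            "has_significant_necrosis": res.has_significant_necrosis,
            "type_distribution_ok": res.type_distribution_ok,
            "accepted": res.accepted,
            "n_simulations": res.n_simulations,
        })
        rows.append(row)
    return pd.DataFrame(rows)
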