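"""Experiment protocols: knockdown screens, sensitivity sweep, heterogeneity.

All experiments derive per-replicate seeds from one master seed, and the
control and treatment arms of an experiment share per-replicate seeds
(common random numbers) so that arm differences are treatment-driven.
Result tables carry the replicate seed and config hash for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metabolism import INTERNAL_SPECIES, base_state_vector
from .params import KnockdownEntry, SimulationParameters

KNOCKDOWN_TARGETS = ("GAPDH", "OXPHOS", "ASCT2")
KNOCKDOWN_DAYS = (0, 5, 10, 20)


@dataclass
class ExperimentSpec:
    """Declarative description of one experiment."""

    kind: str = "baseline"          # baseline|sensitivity_sweep|heterogeneity|knockdown
    replicates: int = 10            # 10 for sensitivity, 30 for knockdowns
    knockdown_reaction: str | None = None
    knockdown_mode: str = "complete"
    knockdown_day: int = 0
    sweep_multipliers: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    n_sets: int = 90                # heterogeneity pool size
    sd_fraction: float = 0.10

    def validate(self, horizon_days: float) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.kind == "knockdown":
            if self.knockdown_reaction not in KNOCKDOWN_TARGETS:
                raise ValueError(
                    f"knockdown target must be one of {KNOCKDOWN_TARGETS}"
                )
            if self.knockdown_day > horizon_days:
                raise ValueError("knockdown day is beyond the simulation horizon")


def _replicate_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _run_arm(params: SimulationParameters, seeds: list[int],
             label: str) -> pd.DataFrame:
    from .driver import run_simulation

    frames = []
    for s in seeds:
        world = run_simulation(params, seed=s)
        df = world.trajectory()
        df["arm"] = label
        df["seed"] = s
        df["config_hash"] = params.config_hash()
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def aggregate_fold_change(runs: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of fold-change per decision step and arm.

    With a single replicate the std column is 0 and flagged.
    """
    g = runs.groupby(["arm", "mcs"], as_index=False).agg(
        day=("day", "first"),
        fold_mean=("fold_change", "mean"),
        fold_std=("fold_change", "std"),
        n=("fold_change", "size"),
    )
    g["fold_std"] = g["fold_std"].fillna(0.0)
    g["std_undefined"] = g["n"] < 2
    return g


def run_experiment(spec: ExperimentSpec, params: SimulationParameters,
                   master_seed: int = 0) -> dict[str, pd.DataFrame]:
    """Run one experiment with a control arm; returns runs and aggregates."""
    spec.validate(params.clock.total_mcs / params.clock.mcs_per_day)
    seeds = _replicate_seeds(master_seed, spec.replicates)
    control = _run_arm(params, seeds, "control")
    frames = [control]
    if spec.kind == "knockdown":
        p = params.copy()
        p.metabolism.knockdowns = [KnockdownEntry(
            reaction=spec.knockdown_reaction, mode=spec.knockdown_mode,
            day=spec.knockdown_day,
        )]
        label = (f"{spec.knockdown_reaction}_{spec.knockdown_mode}"
                 f"_day{spec.knockdown_day}")
        frames.append(_run_arm(p, seeds, label))
    elif spec.kind == "heterogeneity":
        rng = np.random.default_rng(master_seed)
        pool = heterogeneous_initial_conditions(
            base_state_vector(), spec.n_sets, spec.sd_fraction, rng
        )
        het_frames = []
        from .driver import run_simulation

        for s in seeds:
            pick = rng.choice(spec.n_sets, size=params.geometry.n_initial_cells,
                              replace=False)
            world = run_simulation(params, seed=s,
                                   initial_states=[pool[i] for i in pick])
            df = world.trajectory()
            df["arm"] = "heterogeneous"
            df["seed"] = s
            df["config_hash"] = params.config_hash()
            het_frames.append(df)
        frames.append(pd.concat(het_frames, ignore_index=True))
    elif spec.kind != "baseline":
        raise ValueError(f"unknown experiment kind {spec.kind!r}")
    runs = pd.concat(frames, ignore_index=True)
    return {"runs": runs, "aggregate": aggregate_fold_change(runs)}


def heterogeneous_initial_conditions(base_state: np.ndarray, n_sets: int,
                                     sd_fraction: float,
                                     rng: np.random.Generator) -> list[np.ndarray]:
    """Pool of initial metabolite vectors with ~10% Gaussian spread.

    Every species of every set is the base value times an independent
    Normal(1, sd_fraction) draw, truncated at zero (negative draws are
    clipped and counted).
    """
    base_state = np.asarray(base_state, dtype=float)
    if (base_state < 0).any() or sd_fraction < 0:
        raise ValueError("base state and sd_fraction must be non-negative")
    sets = []
    n_clipped = 0
    for _ in range(n_sets):
        mult = rng.normal(1.0, sd_fraction, size=base_state.shape)
        n_clipped += int((mult < 0).sum())
        sets.append(base_state * np.clip(mult, 0.0, None))
    if n_clipped:
        import logging

        logging.getLogger(__name__).info(
            "heterogeneous initial conditions: clipped %d negative draws",
            n_clipped,
        )
    return sets


def sensitivity_sweep(params: SimulationParameters,
                      atpD_multipliers=(0.1, 1.0, 10.0),
                      lacD_multipliers=(0.1, 1.0, 10.0),
                      replicates: int = 5,
                      master_seed: int = 0) -> pd.DataFrame:
    """Grid sweep of the atpD and LacDeath thresholds.

    For each (atpD multiplier, lacD multiplier) grid point the model runs
    ``replicates`` times (common random numbers across grid points) and the
    mean end-of-run fold-change is reported, one row per grid point.
    """
    seeds = _replicate_seeds(master_seed, replicates)
    from .driver import run_simulation

    base_atpD = params.decisions.atpD
    base_lacD = params.decisions.LacDeath
    rows = []
    for ma in atpD_multipliers:
        for ml in lacD_multipliers:
            p = params.copy()
            p.decisions.atpD = base_atpD * ma
            p.decisions.LacDeath = base_lacD * ml
            folds = []
            for s in seeds:
                world = run_simulation(p, seed=s)
                folds.append(float(world.trajectory()["fold_change"].iloc[-1]))
            rows.append({
                "atpD_multiplier": ma,
                "lacD_multiplier": ml,
                "atpD": p.decisions.atpD,
                "LacDeath": p.decisions.LacDeath,
                "fold_change_mean": float(np.mean(folds)),
                "fold_change_std": float(np.std(folds, ddof=1)) if len(folds) > 1 else 0.0,
                "replicates": replicates,
                "seeds": ",".join(map(str, seeds)),
                "config_hash": p.config_hash(),
            })
    return pd.DataFrame(rows)
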