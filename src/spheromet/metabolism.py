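"""Per-cell intracellular metabolic network.

Each viable tumor cell carries a concentration vector (fmol/voxel) advanced
every Monte Carlo step by 6 minutes of ODE time.  The default network is a
reduced surrogate for a detailed kinetic model of pancreatic-cancer
central carbon metabolism: it keeps the pathway skeleton (glucose uptake, lumped glycolysis,
lactate exchange, pentose phosphate pathway, glutamine uptake and
glutaminolysis, TCA chain, oxidative phosphorylation, ATP maintenance) and
the regulatory couplings needed for the observed compensation behaviors:

* glycolysis (GAPDH step) is inhibited by ATP, so respiration failure
  up-regulates glycolytic flux (Pasteur/Warburg-style response: PEP and
  lactate rise when OXPHOS is blocked);
* the TCA steps are product-inhibited by malate and glutaminolysis by
  alpha-ketoglutarate, so an OXPHOS block backs the chain up and
  intracellular glutamine accumulates;
* lactate import (and its oxidation) is gated strictly on extracellular
  glucose exhaustion — at normal glucose the lactate uptake flux is null.

Rate laws are irreversible Michaelis-Menten products over substrates with
optional hyperbolic inhibition terms:

    v = Vf * kd * prod_s C_s/(C_s+Km_s) * prod_e E_e/(E_e+Km_e)
             * prod_i Ki_i/(Ki_i+C_i)

where kd is the knockdown multiplier (1 = unperturbed, 0 = complete
knockdown).  All parameters are surrogate values and are configurable.

Networks can also be loaded from SBML; models written by
:func:`save_sbml_network` round-trip exactly, and foreign kinetic laws are
compiled from the SBML math AST into generic rate callables (integrated on
the scipy path).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .params import CellType, MetabolismConfig, SPECIES

#: intracellular state vector layout
INTERNAL_SPECIES = (
    "Glc_in", "Gln_in", "ATP", "Lac_in", "PEP",
    "Fum", "Mal", "aKG", "R5P", "S7P",
)
#: extracellular inputs, same order as the nutrient fields
EXTERNAL_SPECIES = SPECIES  # glucose, glutamine, oxygen, lactate

IDX = {name: i for i, name in enumerate(INTERNAL_SPECIES)}
EXT_IDX = {name: i for i, name in enumerate(EXTERNAL_SPECIES)}

GLUCOSE_ZERO = 1e-6  # fmol/voxel; "no glucose" gate for lactate uptake


@dataclass
class Reaction:
    """One reaction: stoichiometry plus Michaelis-Menten rate-law parameters.

    ``stoich`` maps internal species to signed coefficients; ``ext_stoich``
    maps extracellular species to signed coefficients (negative = uptake
    from the field, positive = export to it).  ``km`` holds one Km per
    substrate (internal or external name); ``inhibitors`` maps internal
    species to Ki.  ``gate`` may be ``"no_glucose"``.
    """

    name: str
    stoich: dict[str, float] = field(default_factory=dict)
    ext_stoich: dict[str, float] = field(default_factory=dict)
    Vf: float = 0.0                 # fmol/voxel/min
    km: dict[str, float] = field(default_factory=dict)
    inhibitors: dict[str, float] = field(default_factory=dict)
    gate: str | None = None
    knockdown_factor: float = 1.0
    rate_callable: object | None = None  # generic (C, ext) -> v, for SBML imports

    def __post_init__(self) -> None:
        if self.Vf < 0 or self.knockdown_factor < 0:
            raise ValueError(f"{self.name}: Vf and knockdown_factor must be >= 0")

    def substrates(self) -> list[str]:
        subs = [s for s, c in self.stoich.items() if c < 0]
        subs += [s for s, c in self.ext_stoich.items() if c < 0]
        return subs


class MetabolicNetwork:
    """Reaction set shared by all viable cells in a run."""

    def __init__(self, reactions: list[Reaction], source: str = "surrogate",
                 species: tuple[str, ...] = INTERNAL_SPECIES):
        self.reactions = list(reactions)
        self.source = source
        self.species = tuple(species)
        self.knockdown_draws: dict[str, float] = {}
        self._validate()
        self._arrays = None

    def _validate(self) -> None:
        known = set(self.species)
        for r in self.reactions:
            for s in r.stoich:
                if s not in known:
                    raise ValueError(f"reaction {r.name}: unknown species {s!r}")
            for e in r.ext_stoich:
                if e not in EXT_IDX:
                    raise ValueError(f"reaction {r.name}: unknown external {e!r}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def reaction(self, name: str) -> Reaction:
        for r in self.reactions:
            if r.name == name:
                return r
        raise KeyError(f"no reaction named {name!r} in network")

    def has_generic_rates(self) -> bool:
        return any(r.rate_callable is not None for r in self.reactions)

    def copy(self) -> "MetabolicNetwork":
        net = MetabolicNetwork(
            [replace(r, stoich=dict(r.stoich), ext_stoich=dict(r.ext_stoich),
                     km=dict(r.km), inhibitors=dict(r.inhibitors))
             for r in self.reactions],
            source=self.source, species=self.species,
        )
        net.knockdown_draws = dict(self.knockdown_draws)
        return net

    # -- compiled representation for the fast integrator ----------------
    def compile(self):
        if self._arrays is not None:
            return self._arrays
        if self.has_generic_rates():
            raise ValueError(
                "network contains generic (SBML-AST) rate laws; "
                "use the scipy integration path"
            )
        R = len(self.reactions)
        S = self.n_species
        E = len(EXTERNAL_SPECIES)
        sidx = {s: i for i, s in enumerate(self.species)}
        max_sub = max((sum(1 for s, c in r.stoich.items() if c < 0) for r in self.reactions), default=1) or 1
        max_ext = max((sum(1 for s, c in r.ext_stoich.items() if c < 0) for r in self.reactions), default=1) or 1
        max_inh = max((len(r.inhibitors) for r in self.reactions), default=1) or 1
        vf = np.zeros(R)
        sub_idx = -np.ones((R, max_sub), dtype=np.int64)
        sub_km = np.zeros((R, max_sub))
        ext_idx = -np.ones((R, max_ext), dtype=np.int64)
        ext_km = np.zeros((R, max_ext))
        inh_idx = -np.ones((R, max_inh), dtype=np.int64)
        inh_ki = np.zeros((R, max_inh))
        stoich = np.zeros((R, S))
        ext_st = np.zeros((R, E))
        gate = np.zeros(R, dtype=np.int8)
        for ri, r in enumerate(self.reactions):
            vf[ri] = r.Vf * r.knockdown_factor
            j = 0
            for s, c in r.stoich.items():
                stoich[ri, sidx[s]] = c
                if c < 0:
                    if s not in r.km:
                        raise ValueError(f"reaction {r.name}: missing Km for {s}")
                    sub_idx[ri, j] = sidx[s]
                    sub_km[ri, j] = r.km[s]
                    j += 1
            j = 0
            for e, c in r.ext_stoich.items():
                ext_st[ri, EXT_IDX[e]] = c
                if c < 0:
                    if e not in r.km:
                        raise ValueError(f"reaction {r.name}: missing Km for {e}")
                    ext_idx[ri, j] = EXT_IDX[e]
                    ext_km[ri, j] = r.km[e]
                    j += 1
            for j, (s, ki) in enumerate(r.inhibitors.items()):
                inh_idx[ri, j] = sidx[s]
                inh_ki[ri, j] = ki
            if r.gate == "no_glucose":
                gate[ri] = 1
        self._arrays = (vf, sub_idx, sub_km, ext_idx, ext_km, inh_idx, inh_ki,
                        stoich, ext_st, gate)
        return self._arrays

    def invalidate(self) -> None:
        self._arrays = None


# ----------------------------------------------------------------------
# Surrogate network definition

#: default rate parameters (fmol/voxel/min and fmol/voxel); surrogates for
#: a fully fitted kinetic model, tuned so the control steady state supports
#: growth (ATP well above the starvation gate) while single knockdowns of
#: OXPHOS or ASCT2 drive ATP below it.
SURROGATE_PARAMS: dict[str, dict[str, float]] = {
    "GLUT1":      {"Vf": 0.01125, "Km_glucose": 0.2, "Ki_Glc_in": 0.02},
    "GAPDH":      {"Vf": 0.01125, "Km_Glc_in": 0.01, "Ki_ATP": 0.30},
    "LDH":        {"Vf": 0.01875, "Km_PEP": 0.10},
    "MCT":        {"Vf": 0.01875, "Km_Lac_in": 0.10},
    "MCT_uptake": {"Vf": 0.0015, "Km_lactate": 0.5},
    "LDH_rev":    {"Vf": 0.0015, "Km_Lac_in": 0.1},
    "PPP_in":     {"Vf": 0.00225, "Km_Glc_in": 0.01},
    "PPP_ret":    {"Vf": 0.00525, "Km_R5P": 0.05},
    "PPP_out":    {"Vf": 0.00525, "Km_S7P": 0.05},
    "ASCT2":      {"Vf": 0.001875, "Km_glutamine": 0.008, "Ki_Gln_in": 0.15},
    "GLS":        {"Vf": 0.005, "Km_Gln_in": 0.30, "Ki_aKG": 0.30},
    "TCA_a":      {"Vf": 0.0001125, "Km_PEP": 0.10, "Ki_Mal": 0.30},
    "TCA_b":      {"Vf": 0.001875, "Km_aKG": 0.05, "Ki_Mal": 0.30},
    "TCA_c":      {"Vf": 0.001875, "Km_Fum": 0.05},
    "OXPHOS":     {"Vf": 0.0015, "Km_Mal": 0.05, "Km_oxygen": 0.004},
    "ATPase":     {"Vf": 0.035, "Km_ATP": 0.05},
}

#: ATP yield of the lumped OXPHOS step, per malate oxidized
OXPHOS_ATP_YIELD = 30.0

#: baseline initial intracellular concentrations, fmol/voxel (near the
#: control steady state of the surrogate at physiological nutrients)
BASE_STATE = {
    "Glc_in": 0.0095, "Gln_in": 0.2217, "ATP": 0.1575, "Lac_in": 0.0998,
    "PEP": 0.0998, "Fum": 0.0263, "Mal": 0.5125, "aKG": 0.7068,
    "R5P": 0.0359, "S7P": 0.0359,
}


def base_state_vector() -> np.ndarray:
    return np.array([BASE_STATE[s] for s in INTERNAL_SPECIES])


def _p(name: str, overrides_vf: dict, overrides_km: dict) -> dict[str, float]:
    d = dict(SURROGATE_PARAMS[name])
    if name in overrides_vf:
        d["Vf"] = overrides_vf[name]
    for k, v in overrides_km.items():
        # km_overrides keyed "REACTION.Km_species"
        if k.startswith(name + "."):
            d[k.split(".", 1)[1]] = v
    return d


def surrogate_network(vf_overrides: dict[str, float] | None = None,
                      km_overrides: dict[str, float] | None = None) -> MetabolicNetwork:
    """Build the reduced surrogate metabolic network."""
    ov = vf_overrides or {}
    ok = km_overrides or {}

    def mk(name, stoich, ext_stoich=None, inhibitors=None, gate=None):
        p = _p(name, ov, ok)
        km = {}
        inh = {}
        for k, v in p.items():
            if k.startswith("Km_"):
                km[k[3:]] = v
            elif k.startswith("Ki_"):
                inh[k[3:]] = v
        if inhibitors:
            inh.update(inhibitors)
        return Reaction(name=name, stoich=stoich, ext_stoich=ext_stoich or {},
                        Vf=p["Vf"], km=km, inhibitors=inh, gate=gate)

    y = OXPHOS_ATP_YIELD
    rxns = [
        mk("GLUT1", {"Glc_in": +1}, {"glucose": -1}),
        mk("GAPDH", {"Glc_in": -1, "PEP": +2, "ATP": +2}),
        mk("LDH", {"PEP": -1, "Lac_in": +1}),
        mk("MCT", {"Lac_in": -1}, {"lactate": +1}),
        mk("MCT_uptake", {"Lac_in": +1}, {"lactate": -1}, gate="no_glucose"),
        mk("LDH_rev", {"Lac_in": -1, "PEP": +1}, gate="no_glucose"),
        mk("PPP_in", {"Glc_in": -1, "R5P": +2}),
        mk("PPP_ret", {"R5P": -1, "S7P": +1}),
        mk("PPP_out", {"S7P": -1, "PEP": +1}),
        mk("ASCT2", {"Gln_in": +1}, {"glutamine": -1}),
        mk("GLS", {"Gln_in": -1, "aKG": +1}),
        mk("TCA_a", {"PEP": -1, "aKG": +1}),
        mk("TCA_b", {"aKG": -1, "Fum": +1}),
        mk("TCA_c", {"Fum": -1, "Mal": +1}),
        mk("OXPHOS", {"Mal": -1, "ATP": +y}, {"oxygen": -0.25}),
        mk("ATPase", {"ATP": -1}),
    ]
    return MetabolicNetwork(rxns, source="surrogate")


# ----------------------------------------------------------------------
# Integration


@njit(cache=True)
def _rates(C, ext, vf, sub_idx, sub_km, ext_idx, ext_km, inh_idx, inh_ki,
           gate, glc_i):
    R = vf.shape[0]
    v = np.empty(R)
    for r in range(R):
        x = vf[r]
        if x > 0.0 and gate[r] == 1 and ext[glc_i] >= GLUCOSE_ZERO:
            x = 0.0
        if x > 0.0:
            for j in range(sub_idx.shape[1]):
                i = sub_idx[r, j]
                if i < 0:
                    break
                c = C[i]
                if c <= 0.0:
                    x = 0.0
                    break
                x *= c / (c + sub_km[r, j])
            for j in range(ext_idx.shape[1]):
                i = ext_idx[r, j]
                if i < 0:
                    break
                e = ext[i]
                if e <= 0.0:
                    x = 0.0
                    break
                x *= e / (e + ext_km[r, j])
            for j in range(inh_idx.shape[1]):
                i = inh_idx[r, j]
                if i < 0:
                    break
                x *= inh_ki[r, j] / (inh_ki[r, j] + C[i])
        v[r] = x
    return v


@njit(cache=True)
def _rk4_integrate(C0, ext, dt_total, dt_sub, vf, sub_idx, sub_km, ext_idx,
                   ext_km, inh_idx, inh_ki, stoich, ext_st, gate, glc_i):
    """Adaptive-substep RK4 with non-negativity clipping.

    The nominal substep ``dt_sub`` is shortened whenever a pool would lose
    more than ~90% of its content within one step (small fast pools such as
    intracellular glucose become stiff near depletion); a floor on the step
    size plus clipping keeps the cost bounded.  Returns the final state and
    the cumulative external exchange (fmol/voxel; negative = net uptake
    from the environment).
    """
    S = C0.shape[0]
    E = ext.shape[0]
    C = C0.copy()
    exch = np.zeros(E)
    t = 0.0
    h_min = dt_sub / 64.0
    max_iter = 80 * int(math.ceil(dt_total / dt_sub))
    it = 0
    while t < dt_total - 1e-12 and it < max_iter:
        it += 1
        v1 = _rates(C, ext, vf, sub_idx, sub_km, ext_idx, ext_km, inh_idx,
                    inh_ki, gate, glc_i)
        k1 = stoich.T @ v1
        h = min(dt_sub, dt_total - t)
        for i in range(S):
            if k1[i] < 0.0 and C[i] > 1e-12:
                lim = 0.9 * C[i] / (-k1[i])
                if lim < h:
                    h = lim
        if h < h_min:
            h = min(h_min, dt_total - t)
        C2 = np.maximum(C + 0.5 * h * k1, 0.0)
        v2 = _rates(C2, ext, vf, sub_idx, sub_km, ext_idx, ext_km, inh_idx,
                    inh_ki, gate, glc_i)
        k2 = stoich.T @ v2
        C3 = np.maximum(C + 0.5 * h * k2, 0.0)
        v3 = _rates(C3, ext, vf, sub_idx, sub_km, ext_idx, ext_km, inh_idx,
                    inh_ki, gate, glc_i)
        k3 = stoich.T @ v3
        C4 = np.maximum(C + h * k3, 0.0)
        v4 = _rates(C4, ext, vf, sub_idx, sub_km, ext_idx, ext_km, inh_idx,
                    inh_ki, gate, glc_i)
        k4 = stoich.T @ v4
        C = np.maximum(C + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
        vbar = (v1 + 2 * v2 + 2 * v3 + v4) / 6.0
        exch += h * (ext_st.T @ vbar)
        t += h
    return C, exch


@njit(cache=True)
def integrate_population(conc, ext_mat, active, dt_total, dt_sub, vf, sub_idx,
                         sub_km, ext_idx, ext_km, inh_idx, inh_ki, stoich,
                         ext_st, gate, glc_i):
    """Advance every active cell independently; returns exchange matrix."""
    n = conc.shape[0]
    exch = np.zeros((n, ext_mat.shape[1]))
    for c in range(n):
        if not active[c]:
            continue
        Cf, ex = _rk4_integrate(conc[c], ext_mat[c], dt_total, dt_sub, vf,
                                sub_idx, sub_km, ext_idx, ext_km, inh_idx,
                                inh_ki, stoich, ext_st, gate, glc_i)
        conc[c] = Cf
        exch[c] = ex
    return exch


def _generic_rhs(network: MetabolicNetwork, ext: np.ndarray):
    """Python RHS supporting generic (SBML-AST) rate callables."""
    sidx = {s: i for i, s in enumerate(network.species)}

    def rhs(_t, C):
        dC = np.zeros(len(C))
        Cc = np.maximum(C, 0.0)
        for r in network.reactions:
            if r.rate_callable is not None:
                v = r.knockdown_factor * float(r.rate_callable(Cc, ext))
            else:
                v = r.Vf * r.knockdown_factor
                if r.gate == "no_glucose" and ext[EXT_IDX["glucose"]] >= GLUCOSE_ZERO:
                    v = 0.0
                if v > 0:
                    for s, c in r.stoich.items():
                        if c < 0:
                            x = Cc[sidx[s]]
                            v *= x / (x + r.km[s]) if x > 0 else 0.0
                    for e, c in r.ext_stoich.items():
                        if c < 0:
                            x = ext[EXT_IDX[e]]
                            v *= x / (x + r.km[e]) if x > 0 else 0.0
                    for s, ki in r.inhibitors.items():
                        v *= ki / (ki + Cc[sidx[s]])
            for s, c in r.stoich.items():
                dC[sidx[s]] += c * v
        return dC

    return rhs


def integrate_cell(state: np.ndarray, network: MetabolicNetwork,
                   ext: np.ndarray, dt: float, method: str = "rk4",
                   dt_sub: float = 0.5):
    """Advance one cell's intracellular state by ``dt`` minutes.

    Returns ``(new_state, exchange)`` where ``exchange`` is the cumulative
    external flux per species (fmol/voxel of cell; negative = uptake).
    The ``rk4`` path is the production integrator; ``bdf`` uses scipy's
    implicit solver and serves as the cross-check / fallback (it does not
    report exchange for generic-rate networks).
    """
    state = np.asarray(state, dtype=float)
    ext = np.asarray(ext, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if (ext < 0).any():
        raise ValueError("external concentrations must be non-negative")
    if method == "rk4":
        arrays = network.compile()
        (vf, sub_idx, sub_km, ext_idx, ext_km, inh_idx, inh_ki,
         stoich, ext_st, gate) = arrays
        return _rk4_integrate(state, ext, dt, dt_sub, vf, sub_idx, sub_km,
                              ext_idx, ext_km, inh_idx, inh_ki, stoich,
                              ext_st, gate, EXT_IDX["glucose"])
    if method == "bdf":
        from scipy.integrate import solve_ivp

        rhs = _generic_rhs(network, ext)
        sol = solve_ivp(rhs, (0.0, dt), state, method="BDF",
                        rtol=1e-8, atol=1e-9)
        if not sol.success:
            raise RuntimeError(f"stiff integration failed: {sol.message}")
        return np.maximum(sol.y[:, -1], 0.0), None
    raise ValueError(f"unknown integration method {method!r}")


# ----------------------------------------------------------------------
# Knockdowns


def apply_knockdown(network: MetabolicNetwork, reaction_name: str,
                    mode: str, rng: np.random.Generator | None = None,
                    mean: float = 0.1, sd: float = 0.2) -> MetabolicNetwork:
    """Return a copy of the network with the named reaction knocked down.

    ``complete`` sets the knockdown multiplier to zero.  ``partial`` draws
    the multiplier once from Normal(mean, sd) — nominally 10% residual
    activity with 20% spread — truncated at zero (a negative rate is
    unphysical); the draw is recorded in ``knockdown_draws``.
    """
    net = network.copy()
    rxn = net.reaction(reaction_name)  # raises KeyError if absent
    if mode == "complete":
        factor = 0.0
    elif mode == "partial":
        if rng is None:
            raise ValueError("partial knockdown requires an rng")
        raw = float(rng.normal(mean, sd))
        factor = max(raw, 0.0)
        net.knockdown_draws[reaction_name + "_raw"] = raw
    else:
        raise ValueError(f"unknown knockdown mode {mode!r}")
    rxn.knockdown_factor = factor
    net.knockdown_draws[reaction_name] = factor
    net.invalidate()
    return net


def perceived_vmax(cell_type: CellType) -> float:
    """Fitness-factor amplitude scale: quiescent cells run at 75%."""
    t = CellType(cell_type)
    if t in (CellType.PCANCER, CellType.PSTEM):
        return 1.0
    if t in (CellType.QCANCER, CellType.QSTEM):
        return 0.75
    raise ValueError(f"{t.name} cells have no metabolic amplitude")


def network_from_config(cfg: MetabolismConfig) -> MetabolicNetwork:
    if cfg.network == "surrogate":
        return surrogate_network(cfg.vf_overrides, cfg.km_overrides)
    return load_sbml_network(cfg.network)


# ----------------------------------------------------------------------
# SBML import / export


def save_sbml_network(network: MetabolicNetwork, path: str) -> None:
    """Write the network as SBML Level 3 with explicit MM kinetic laws."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId("spheromet_network")
    comp = model.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)
    for s in network.species:
        sp = model.createSpecies()
        sp.setId(s)
        sp.setCompartment("cell")
        sp.setInitialConcentration(float(BASE_STATE.get(s, 0.0)))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
    for e in EXTERNAL_SPECIES:
        sp = model.createSpecies()
        sp.setId("ext_" + e)
        sp.setCompartment("cell")
        sp.setInitialConcentration(0.0)
        sp.setConstant(False)
        sp.setBoundaryCondition(True)
        sp.setHasOnlySubstanceUnits(False)
    for r in network.reactions:
        rx = model.createReaction()
        rx.setId(r.name)
        rx.setReversible(False)
        terms = [f"Vf_{r.name}"]
        for s, c in list(r.stoich.items()) + [
            ("ext_" + e, c) for e, c in r.ext_stoich.items()
        ]:
            ref = rx.createReactant() if c < 0 else rx.createProduct()
            ref.setSpecies(s)
            ref.setStoichiometry(abs(float(c)))
            ref.setConstant(True)
        for s, c in r.stoich.items():
            if c < 0:
                terms.append(f"({s} / ({s} + Km_{r.name}_{s}))")
        for e, c in r.ext_stoich.items():
            if c < 0:
                terms.append(f"(ext_{e} / (ext_{e} + Km_{r.name}_{e}))")
        for s in r.inhibitors:
            terms.append(f"(Ki_{r.name}_{s} / (Ki_{r.name}_{s} + {s}))")
        kl = rx.createKineticLaw()
        formula = " * ".join(terms)
        kl.setMath(libsbml.parseL3Formula(formula))

        def _lp(pid, val):
            p = kl.createLocalParameter()
            p.setId(pid)
            p.setValue(float(val))

        _lp(f"Vf_{r.name}", r.Vf * r.knockdown_factor)
        for s, km in r.km.items():
            key = s if s in network.species else s
            pid = f"Km_{r.name}_{s}"
            _lp(pid, km)
        for s, ki in r.inhibitors.items():
            _lp(f"Ki_{r.name}_{s}", ki)
        if r.gate:
            rx.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                        f"gate={r.gate}</body>")
    libsbml.writeSBMLToFile(doc, path)


def _compile_ast(node, species_ids, param_values):
    """Compile a libsbml math AST into a closure over (C, ext)."""
    import libsbml

    t = node.getType()
    if t == libsbml.AST_REAL or t == libsbml.AST_INTEGER:
        v = node.getValue()
        return lambda C, ext: v
    if t == libsbml.AST_NAME:
        name = node.getName()
        if name in param_values:
            v = param_values[name]
            return lambda C, ext: v
        if name in species_ids:
            i = species_ids[name]
            if i >= 0:
                return lambda C, ext: C[i]
            j = -i - 1
            return lambda C, ext: ext[j]
        raise ValueError(f"unresolved symbol {name!r} in kinetic law")
    kids = [_compile_ast(node.getChild(i), species_ids, param_values)
            for i in range(node.getNumChildren())]
    if t == libsbml.AST_PLUS:
        return lambda C, ext: sum(k(C, ext) for k in kids)
    if t == libsbml.AST_TIMES:
        def prod(C, ext):
            out = 1.0
            for k in kids:
                out *= k(C, ext)
            return out
        return prod
    if t == libsbml.AST_MINUS:
        if len(kids) == 1:
            return lambda C, ext: -kids[0](C, ext)
        return lambda C, ext: kids[0](C, ext) - kids[1](C, ext)
    if t == libsbml.AST_DIVIDE:
        return lambda C, ext: kids[0](C, ext) / kids[1](C, ext)
    if t in (libsbml.AST_POWER, libsbml.AST_FUNCTION_POWER):
        return lambda C, ext: kids[0](C, ext) ** kids[1](C, ext)
    if t == libsbml.AST_FUNCTION_EXP:
        return lambda C, ext: math.exp(kids[0](C, ext))
    raise ValueError(f"unsupported AST node type {t} in kinetic law")


def load_sbml_network(path: str, alias: dict[str, str] | None = None) -> MetabolicNetwork:
    """Load a metabolic network from an SBML file.

    Species ids are reconciled to the canonical state-vector names via the
    optional ``alias`` table ({sbml_id: canonical_name}); species that map
    to no canonical name are carried as extra state entries.  Kinetic laws
    written by :func:`save_sbml_network` are recognized structurally and
    recovered as Michaelis-Menten reactions (fast path); any other kinetic
    law is compiled from its math AST into a generic rate callable.
    Reactions without kinetic laws, or an empty model, are an error.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ValueError(f"SBML parse error: {err.getMessage()}")
    model = doc.getModel()
    if model is None or model.getNumReactions() == 0:
        raise ValueError(f"{path}: empty SBML model (no reactions)")
    alias = alias or {}

    missing_kl = [model.getReaction(i).getId()
                  for i in range(model.getNumReactions())
                  if model.getReaction(i).getKineticLaw() is None]
    if missing_kl:
        raise ValueError(f"reactions without kinetic laws: {missing_kl}")

    # species bookkeeping: canonical internal names first, extras appended
    def canon(sid: str) -> str | None:
        if sid.startswith("ext_") and sid[4:] in EXT_IDX:
            return "ext:" + sid[4:]
        name = alias.get(sid, sid)
        if name in EXT_IDX and name not in IDX:
            return "ext:" + name
        return name

    species_order = list(INTERNAL_SPECIES)
    boundary = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        c = canon(sp.getId())
        if c is None:
            continue
        if c.startswith("ext:"):
            boundary[sp.getId()] = c[4:]
        elif c not in species_order:
            species_order.append(c)

    name_of = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        c = canon(sp.getId())
        name_of[sp.getId()] = c

    sidx_local = {s: i for i, s in enumerate(species_order)}

    reactions = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        rname = rx.getId()
        stoich: dict[str, float] = {}
        ext_stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            sid = ref.getSpecies()
            coef = -abs(ref.getStoichiometry())
            if sid in boundary:
                ext_stoich[boundary[sid]] = ext_stoich.get(boundary[sid], 0) + coef
            else:
                nm = name_of[sid]
                stoich[nm] = stoich.get(nm, 0) + coef
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            sid = ref.getSpecies()
            coef = abs(ref.getStoichiometry())
            if sid in boundary:
                ext_stoich[boundary[sid]] = ext_stoich.get(boundary[sid], 0) + coef
            else:
                nm = name_of[sid]
                stoich[nm] = stoich.get(nm, 0) + coef
        kl = rx.getKineticLaw()
        params = {}
        for j in range(kl.getNumLocalParameters()):
            p = kl.getLocalParameter(j)
            params[p.getId()] = p.getValue()
        for j in range(kl.getNumParameters()):
            p = kl.getParameter(j)
            params[p.getId()] = p.getValue()
        gate = None
        notes = rx.getNotesString() if rx.isSetNotes() else ""
        if "gate=no_glucose" in notes:
            gate = "no_glucose"
        # structural recognition of our own MM pattern
        vf_key = f"Vf_{rname}"
        if vf_key in params:
            km = {}
            inh = {}
            ok = True
            for pid, val in params.items():
                if pid == vf_key:
                    continue
                if pid.startswith(f"Km_{rname}_"):
                    km[pid[len(f"Km_{rname}_"):]] = val
                elif pid.startswith(f"Ki_{rname}_"):
                    inh[pid[len(f"Ki_{rname}_"):]] = val
                else:
                    ok = False
            if ok:
                reactions.append(Reaction(
                    name=rname, stoich=stoich, ext_stoich=ext_stoich,
                    Vf=params[vf_key], km=km, inhibitors=inh, gate=gate,
                ))
                continue
        # generic path: compile the AST
        ids = {}
        for sid, nm in name_of.items():
            if sid in boundary:
                ids[sid] = -(EXT_IDX[boundary[sid]] + 1)
            else:
                ids[sid] = sidx_local[nm]
        fn = _compile_ast(kl.getMath(), ids, params)
        reactions.append(Reaction(
            name=rname, stoich=stoich, ext_stoich=ext_stoich, Vf=1.0,
            gate=gate, rate_callable=fn,
        ))
    return MetabolicNetwork(reactions, source="sbml",
                            species=tuple(species_order))
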