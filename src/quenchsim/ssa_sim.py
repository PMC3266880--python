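"""Exact stochastic (RDME) simulation of the genetic circuit.

The deterministic model's Hill responses arise, under the law of mass
action and quasi-steady-state, from explicit elementary steps:
repressors dimerize, dimers bind enumerated promoter operator sites,
AHL binds LuxR, the LuxR-AHL complex homodimerizes and the homodimer
binds the lux promoter.  This module builds that elementary reaction
set per cubic cell compartment, adds AHL hop channels between adjacent
compartments (rate D/h² per molecule per direction), and samples the
reaction-diffusion master equation exactly with the next-reaction
method (indexed priority queue + per-channel dependency graph),
compiled with numba.

Equilibrium constants are split so that the fast-equilibrium limit of
the reaction set reproduces the deterministic rate laws: for each
repressor, K_dimer * K_operator = K_d², with the dimerization constant
chosen large (weak dimerization) so that monomer ~ total protein, the
regime in which the deterministic Hill form is exact.  Forward binding
rates default to documented fast values; the deterministic model only
constrains the equilibria.

Reported protein totals follow the monomer-equivalent convention:
a dimer counts 2, a promoter-bound dimer counts 2.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

import numpy as np
from numba import njit

from . import model_core as mc
from .model_core import AVOGADRO, GeneCircuitParams

__all__ = [
    "SSAConfig",
    "CompartmentModel",
    "StochasticTrajectory",
    "ObservableTrajectory",
    "molecules_from_concentration",
    "concentration_from_molecules",
    "diffusion_jump_rate",
    "build_reaction_set",
    "build_birth_death",
    "simulate_ssa",
    "aggregate_protein_totals",
    "mean_field_rates",
    "OBSERVABLE_SPECIES",
]

log = logging.getLogger("quenchsim.ssa")

# ---- per-cell species layout ---------------------------------------------
_SP = (
    "m_cI", "m_tetR_O", "m_tetR_Q", "m_lacI", "m_luxI",
    "cI", "cI_2", "TetR", "TetR_2", "LacI", "LacI_2", "LuxI",
    "AHL", "LuxR", "LuxR_AHL", "LuxR_AHL_2",
    "OcI_free", "OcI_bound", "OtetO_free", "OtetO_bound",
    "Olux_free", "Olux_bound", "OlacI_free", "OlacI_bound",
    "OluxI_free", "OluxI_bound",
)
N_SP = len(_SP)
_I = {name: i for i, name in enumerate(_SP)}

#: the ten observable species (totals over all molecular forms)
OBSERVABLE_SPECIES = mc.FULL_SPECIES


def molecules_from_concentration(conc: float, cell_volume: float) -> int:
    """nM -> molecule count in a cell of ``cell_volume`` litres
    (round to nearest; inverse conversion is exact on integers)."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if cell_volume <= 0:
        raise ValueError("volume must be > 0")
    return int(round(conc * 1e-9 * AVOGADRO * cell_volume))


def concentration_from_molecules(count: int, cell_volume: float) -> float:
    """Molecule count -> nM."""
    return count * 1e9 / (AVOGADRO * cell_volume)


def diffusion_jump_rate(D: float, h: float) -> float:
    """Per-molecule hop rate between adjacent cubic compartments,
    ``d = D / h²`` (1/hr for D in µm²/hr and h in µm)."""
    if D < 0:
        raise ValueError("D must be >= 0")
    if h <= 0:
        raise ValueError("h must be > 0")
    return D / h ** 2


@dataclass(frozen=True)
class SSAConfig:
    """Rate constants of the elementary steps the deterministic model
    collapses by QSSA.  Dissociation constants split the deterministic
    K_d² = K_dimer * K_operator; forward rates are documented fast
    defaults (1/nM/hr and 1/hr)."""

    K_dim_rep: float = 1.0e5     # repressor dimerization K (nM), weak
    K_dim_RA: float = 100.0      # LuxR-AHL complex dimerization K (nM)
    kr_dim: float = 1000.0       # dimer dissociation rate (1/hr)
    kon_op: float = 2000.0       # dimer-operator association (1/nM/hr)
    kon_RA: float = 200.0        # AHL-LuxR association (1/nM/hr)


@dataclass
class CompartmentModel:
    """A line of cubic compartments with mass-action channels.

    Reacting compartments carry the full per-cell species set; empty
    compartments (single-cell geometry) carry only diffusing AHL.
    """

    params: GeneCircuitParams
    config: SSAConfig
    n_compartments: int
    reacting: np.ndarray           # bool per compartment
    boundary: str                  # "reflecting" | "absorbing"
    volume_scale: float
    # channel arrays
    r1: np.ndarray
    r2: np.ndarray
    same: np.ndarray
    coef: np.ndarray
    stoich_ptr: np.ndarray
    stoich_sp: np.ndarray
    stoich_delta: np.ndarray
    dep_ptr: np.ndarray
    dep_idx: np.ndarray
    channel_names: list
    initial: np.ndarray            # molecule counts, len n_compartments*N_SP
    species_names: tuple = _SP

    @property
    def n_channels(self) -> int:
        return len(self.coef)

    @property
    def n_cells(self) -> int:
        return int(np.sum(self.reacting))

    def digest(self) -> str:
        h = hashlib.sha256()
        for a in (self.r1, self.r2, self.same, self.coef,
                  self.stoich_ptr, self.stoich_sp, self.stoich_delta,
                  self.initial):
            h.update(np.ascontiguousarray(a).tobytes())
        h.update(self.boundary.encode())
        return h.hexdigest()[:12]


@dataclass
class StochasticTrajectory:
    """Sample times x compartments x species, integer molecule counts."""

    times: np.ndarray
    counts: np.ndarray             # (T, n_compartments, N_SP) int64
    seed: int
    model_digest: str
    metadata: dict = field(default_factory=dict)
    species_names: tuple = _SP

    def raw_species(self, name: str) -> np.ndarray:
        return self.counts[:, :, _I[name]]


@dataclass
class ObservableTrajectory:
    """Aggregated totals (monomer equivalents) on the cell-centred grid;
    satisfies the trajectory interface used by the pattern metrics."""

    times: np.ndarray
    data: dict                     # name -> (T, n_cells)
    grid: str = "midpoint"

    def species(self, name: str) -> np.ndarray:
        return self.data[name]


# --------------------------------------------------------------------------
# Reaction-set construction
# --------------------------------------------------------------------------

class _Builder:
    def __init__(self, n_species_total: int):
        self.r1, self.r2, self.same, self.coef = [], [], [], []
        self.stoich = []
        self.names = []
        self.n = n_species_total

    def add(self, name: str, reactants: list, delta: dict, coef: float):
        """reactants: 1 or 2 global species indices (repeated index =
        homodimerization); delta: net change per firing."""
        if coef < 0:
            raise ValueError(f"negative rate constant for channel {name}")
        if coef == 0.0:
            return
        if len(reactants) == 1:
            self.r1.append(reactants[0]); self.r2.append(-1)
            self.same.append(0)
        else:
            a, b = reactants
            self.r1.append(a); self.r2.append(b)
            self.same.append(1 if a == b else 0)
        self.coef.append(coef)
        self.stoich.append({s: d for s, d in delta.items() if d != 0})
        self.names.append(name)

    def finalize(self):
        M = len(self.coef)
        ptr = np.zeros(M + 1, dtype=np.int64)
        sp, dl = [], []
        for i, st in enumerate(self.stoich):
            for s, d in sorted(st.items()):
                sp.append(s); dl.append(d)
            ptr[i + 1] = len(sp)
        # dependency graph: channels consuming/producing a species ->
        # channels whose propensity reads that species
        readers = {}
        for i in range(M):
            for s in (self.r1[i], self.r2[i]):
                if s >= 0:
                    readers.setdefault(s, set()).add(i)
        dep_ptr = np.zeros(M + 1, dtype=np.int64)
        dep = []
        for i, st in enumerate(self.stoich):
            ds = {i}
            for s in st:
                ds |= readers.get(s, set())
            dep.extend(sorted(ds))
            dep_ptr[i + 1] = len(dep)
        return (np.array(self.r1, dtype=np.int64),
                np.array(self.r2, dtype=np.int64),
                np.array(self.same, dtype=np.int64),
                np.array(self.coef, dtype=np.float64),
                ptr, np.array(sp, dtype=np.int64),
                np.array(dl, dtype=np.int64),
                dep_ptr, np.array(dep, dtype=np.int64))


def _split_operator_K(K_d: float, h: float, K_dim: float) -> float:
    """Operator dissociation constant from the deterministic K_d and the
    dimerization constant: K_op = K_d^h / K_dim (h = 2 throughout)."""
    if h != 2.0:
        raise mc.ConfigurationError(
            "the elementary reaction set realizes Hill coefficient 2 "
            f"(dimer binding); got h={h}")
    return K_d ** 2 / K_dim


def build_reaction_set(params: GeneCircuitParams, n_cells: int,
                       config: Optional[SSAConfig] = None, *,
                       geometry: str = "line",
                       n_empty_side: int = 25,
                       volume_scale: float = 1.0,
                       diffusion_on: bool = True,
                       initial_state: Optional[np.ndarray] = None,
                       ) -> CompartmentModel:
    """Build the compartmentalized mass-action model.

    ``geometry='line'``: ``n_cells`` adjacent reacting cells, reflecting
    (zero-flux) ends.  ``geometry='single_cell'``: one reacting cell
    centred in ``2*n_empty_side`` empty compartments with absorbing far
    ends (AHL diffuses away).  ``volume_scale`` inflates every
    compartment volume (and molecule counts) for law-of-large-numbers
    checks.  The initial condition is the deterministic steady state
    rounded to the nearest molecule.
    """
    if config is None:
        config = SSAConfig()
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    p = params
    C = p.C / volume_scale          # nM per molecule in a scaled cell
    if geometry == "line":
        n_comp = n_cells
        reacting = np.ones(n_comp, dtype=bool)
        boundary = "reflecting"
    elif geometry == "single_cell":
        if n_cells != 1:
            raise ValueError("single_cell geometry implies n_cells=1")
        n_comp = 2 * n_empty_side + 1
        reacting = np.zeros(n_comp, dtype=bool)
        reacting[n_empty_side] = True
        boundary = "absorbing"
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    # operator dissociation constants (K_d² = K_dim * K_op)
    K_op_C = _split_operator_K(p.K_C, p.h_C, config.K_dim_rep)
    K_op_T = _split_operator_K(p.K_T, p.h_T, config.K_dim_rep)
    K_op_L = _split_operator_K(p.K_L, p.h_L, config.K_dim_rep)
    K_op_Q = _split_operator_K(p.K_RA, p.h_RA, config.K_dim_RA)
    kf_dim = config.kr_dim / config.K_dim_rep     # 1/nM/hr
    kf_dimRA = config.kr_dim / config.K_dim_RA
    koff_RA = config.kon_RA * p.K_R

    b = _Builder(n_comp * N_SP)
    tx = [  # free-rate, bound-rate transcription per operator pair
        ("OcI", "m_cI", p.k_C / C, p.l_C * p.k_C / C),
        ("OtetO", "m_tetR_O", p.k_TO / C, p.l_TO * p.k_TO / C),
        ("Olux", "m_tetR_Q", p.l_TQ * p.k_TQ / C, p.k_TQ / C),  # activated
        ("OlacI", "m_lacI", p.k_L / C, p.l_L * p.k_L / C),
        ("OluxI", "m_luxI", p.k_I / C, p.l_I * p.k_I / C),
    ]
    deg_m = [("m_cI", p.g_mC), ("m_tetR_O", p.g_mTO), ("m_tetR_Q", p.g_mTQ),
             ("m_lacI", p.g_mL), ("m_luxI", p.g_mI)]
    translate = [("m_cI", "cI", p.a_C), ("m_tetR_O", "TetR", p.a_T),
                 ("m_tetR_Q", "TetR", p.a_T), ("m_lacI", "LacI", p.a_L),
                 ("m_luxI", "LuxI", p.a_I)]
    dimers = [("cI", "cI_2", p.g_pC), ("TetR", "TetR_2", p.g_pT),
              ("LacI", "LacI_2", p.g_pL)]
    operators = [  # operator, binder dimer, K_op, degradation of binder
        ("OcI", "TetR_2", K_op_T, p.g_pT),
        ("OluxI", "TetR_2", K_op_T, p.g_pT),
        ("OtetO", "LacI_2", K_op_L, p.g_pL),
        ("OlacI", "cI_2", K_op_C, p.g_pC),
    ]

    for c in range(n_comp):
        base = c * N_SP
        gi = lambda name: base + _I[name]
        if reacting[c]:
            # transcription (leak included via the bound/free split)
            for op, m, v_free, v_bound in tx:
                b.add(f"tx_{m}_free[{c}]", [gi(op + "_free")],
                      {gi(m): 1}, v_free)
                b.add(f"tx_{m}_bound[{c}]", [gi(op + "_bound")],
                      {gi(m): 1}, v_bound)
            for m, g in deg_m:
                b.add(f"deg_{m}[{c}]", [gi(m)], {gi(m): -1}, g)
            for m, prot, a in translate:
                b.add(f"tl_{m}[{c}]", [gi(m)], {gi(prot): 1}, a)
            # protein degradation: monomer, dimer (unit), promoter-bound
            for mono, dim, g in dimers:
                b.add(f"deg_{mono}[{c}]", [gi(mono)], {gi(mono): -1}, g)
                b.add(f"deg_{dim}[{c}]", [gi(dim)], {gi(dim): -1}, g)
            b.add(f"deg_LuxI[{c}]", [gi("LuxI")], {gi("LuxI"): -1}, p.g_pI)
            for op, dim, K_op, g in operators:
                b.add(f"deg_bound_{op}[{c}]", [gi(op + "_bound")],
                      {gi(op + "_bound"): -1, gi(op + "_free"): 1}, g)
            # dimerization
            for mono, dim, g in dimers:
                b.add(f"dim_{mono}[{c}]", [gi(mono), gi(mono)],
                      {gi(mono): -2, gi(dim): 1}, kf_dim * C)
                b.add(f"undim_{dim}[{c}]", [gi(dim)],
                      {gi(dim): -1, gi(mono): 2}, config.kr_dim)
            # operator binding
            for op, dim, K_op, g in operators:
                b.add(f"bind_{op}[{c}]", [gi(dim), gi(op + "_free")],
                      {gi(dim): -1, gi(op + "_free"): -1,
                       gi(op + "_bound"): 1}, config.kon_op * C)
                b.add(f"unbind_{op}[{c}]", [gi(op + "_bound")],
                      {gi(op + "_bound"): -1, gi(dim): 1,
                       gi(op + "_free"): 1}, config.kon_op * K_op)
            # AHL synthesis, degradation (all AHL-containing forms decay
            # at g_A with LuxR recycled, so total AHL obeys the PDE law
            # and total LuxR is conserved)
            b.add(f"syn_AHL[{c}]", [gi("LuxI")], {gi("AHL"): 1}, p.k_A)
            b.add(f"deg_AHL[{c}]", [gi("AHL")], {gi("AHL"): -1}, p.g_A)
            b.add(f"deg_LuxR_AHL[{c}]", [gi("LuxR_AHL")],
                  {gi("LuxR_AHL"): -1, gi("LuxR"): 1}, p.g_A)
            b.add(f"deg_LuxR_AHL_2[{c}]", [gi("LuxR_AHL_2")],
                  {gi("LuxR_AHL_2"): -1, gi("LuxR"): 2}, p.g_A)
            b.add(f"deg_bound_Olux[{c}]", [gi("Olux_bound")],
                  {gi("Olux_bound"): -1, gi("Olux_free"): 1,
                   gi("LuxR"): 2}, p.g_A)
            # LuxR-AHL binding, complex dimerization, lux operator
            b.add(f"bind_LuxR_AHL[{c}]", [gi("LuxR"), gi("AHL")],
                  {gi("LuxR"): -1, gi("AHL"): -1, gi("LuxR_AHL"): 1},
                  config.kon_RA * C)
            b.add(f"unbind_LuxR_AHL[{c}]", [gi("LuxR_AHL")],
                  {gi("LuxR_AHL"): -1, gi("LuxR"): 1, gi("AHL"): 1},
                  koff_RA)
            b.add(f"dim_LuxR_AHL[{c}]", [gi("LuxR_AHL"), gi("LuxR_AHL")],
                  {gi("LuxR_AHL"): -2, gi("LuxR_AHL_2"): 1}, kf_dimRA * C)
            b.add(f"undim_LuxR_AHL_2[{c}]", [gi("LuxR_AHL_2")],
                  {gi("LuxR_AHL_2"): -1, gi("LuxR_AHL"): 2}, config.kr_dim)
            b.add(f"bind_Olux[{c}]", [gi("LuxR_AHL_2"), gi("Olux_free")],
                  {gi("LuxR_AHL_2"): -1, gi("Olux_free"): -1,
                   gi("Olux_bound"): 1}, config.kon_op * C)
            b.add(f"unbind_Olux[{c}]", [gi("Olux_bound")],
                  {gi("Olux_bound"): -1, gi("LuxR_AHL_2"): 1,
                   gi("Olux_free"): 1}, config.kon_op * K_op_Q)
        else:
            # empty volume: AHL decays abiotically at the same rate
            b.add(f"deg_AHL[{c}]", [gi("AHL")], {gi("AHL"): -1}, p.g_A)

    # diffusion channels (AHL only)
    d = diffusion_jump_rate(p.D_A, p.cell_edge) if diffusion_on else 0.0
    if d > 0.0:
        for c in range(n_comp - 1):
            a_i = c * N_SP + _I["AHL"]
            a_j = (c + 1) * N_SP + _I["AHL"]
            b.add(f"hop_AHL[{c}->{c+1}]", [a_i], {a_i: -1, a_j: 1}, d)
            b.add(f"hop_AHL[{c+1}->{c}]", [a_j], {a_j: -1, a_i: 1}, d)
        if boundary == "absorbing":
            a0 = 0 * N_SP + _I["AHL"]
            aN = (n_comp - 1) * N_SP + _I["AHL"]
            b.add("hop_AHL[0->out]", [a0], {a0: -1}, d)
            b.add(f"hop_AHL[{n_comp-1}->out]", [aN], {aN: -1}, d)

    (r1, r2, same, coef, sptr, ssp, sdl, dptr, didx) = b.finalize()

    # validate stoichiometric invariants of each channel at build time
    _validate_conservation(b, n_comp, reacting)

    if initial_state is None:
        initial_state = _default_initial(params, n_comp, reacting,
                                         volume_scale)
    model = CompartmentModel(
        params=params, config=config, n_compartments=n_comp,
        reacting=reacting, boundary=boundary, volume_scale=volume_scale,
        r1=r1, r2=r2, same=same, coef=coef,
        stoich_ptr=sptr, stoich_sp=ssp, stoich_delta=sdl,
        dep_ptr=dptr, dep_idx=didx, channel_names=b.names,
        initial=np.asarray(initial_state, dtype=np.int64),
    )
    return model


def _validate_conservation(b: _Builder, n_comp: int, reacting) -> None:
    """Promoter sites and LuxR must be conserved by every channel."""
    for i, st in enumerate(b.stoich):
        per_op = {}
        luxr = 0
        for s, dlt in st.items():
            name = _SP[s % N_SP]
            if name.startswith("O"):
                op = name.rsplit("_", 1)[0]
                per_op[op] = per_op.get(op, 0) + dlt
            if name == "LuxR":
                luxr += dlt
            elif name == "LuxR_AHL":
                luxr += dlt
            elif name == "LuxR_AHL_2":
                luxr += 2 * dlt
            elif name == "Olux_bound":
                luxr += 2 * dlt
        bad = {k: v for k, v in per_op.items() if v != 0}
        if bad or luxr != 0:
            raise mc.ConfigurationError(
                f"channel {b.names[i]} violates conservation: "
                f"operators {bad}, LuxR {luxr}")


def _default_initial(params: GeneCircuitParams, n_comp: int, reacting,
                     volume_scale: float) -> np.ndarray:
    """Deterministic steady state rounded to the nearest molecule."""
    p = params
    ss = mc.find_steady_state("full", p)
    C = p.C / volume_scale
    RA = mc.lux_qssa_complex(ss["AHL"], p.R_T, p.K_R)
    x0 = np.zeros(n_comp * N_SP, dtype=np.int64)
    rnd = lambda conc: int(round(max(conc, 0.0) / C))
    for c in range(n_comp):
        base = c * N_SP
        if not reacting[c]:
            continue
        for m in ("m_cI", "m_tetR_O", "m_tetR_Q", "m_lacI", "m_luxI"):
            x0[base + _I[m]] = rnd(ss[m])
        x0[base + _I["cI"]] = rnd(ss["cI"])
        x0[base + _I["TetR"]] = rnd(ss["TetR"])
        x0[base + _I["LacI"]] = rnd(ss["LacI"])
        x0[base + _I["LuxI"]] = rnd(ss["LuxI"])
        x0[base + _I["AHL"]] = rnd(ss["AHL"] - RA)
        x0[base + _I["LuxR_AHL"]] = rnd(RA)
        x0[base + _I["LuxR"]] = rnd(p.R_T) - x0[base + _I["LuxR_AHL"]]
        for op, n in (("OcI", p.n_C), ("OtetO", p.n_TO), ("Olux", p.n_TQ),
                      ("OlacI", p.n_L), ("OluxI", p.n_I)):
            x0[base + _I[op + "_free"]] = int(round(n))
    return x0


def build_pure_diffusion(n_comp: int, D: float, h: float, n0: int,
                         start: Optional[int] = None,
                         boundary: str = "reflecting") -> CompartmentModel:
    """Diffusion-only model: ``n0`` molecules of a single species placed
    in one compartment, hopping at D/h² per direction.  Used to verify
    the RDME discretization against the diffusion kernel moments."""
    if n_comp < 2:
        raise ValueError("need at least 2 compartments")
    b = _Builder(n_comp * N_SP)
    d = diffusion_jump_rate(D, h)
    ai = lambda c: c * N_SP + _I["AHL"]
    for c in range(n_comp - 1):
        b.add(f"hop[{c}->{c+1}]", [ai(c)], {ai(c): -1, ai(c + 1): 1}, d)
        b.add(f"hop[{c+1}->{c}]", [ai(c + 1)], {ai(c + 1): -1, ai(c): 1}, d)
    if boundary == "absorbing":
        b.add("hop[0->out]", [ai(0)], {ai(0): -1}, d)
        b.add(f"hop[{n_comp-1}->out]", [ai(n_comp - 1)],
              {ai(n_comp - 1): -1}, d)
    (r1, r2, same, coef, sptr, ssp, sdl, dptr, didx) = b.finalize()
    init = np.zeros(n_comp * N_SP, dtype=np.int64)
    init[ai(n_comp // 2 if start is None else start)] = n0
    _m, params = mc.load_params("set2")
    return CompartmentModel(
        params=params, config=SSAConfig(), n_compartments=n_comp,
        reacting=np.zeros(n_comp, dtype=bool), boundary=boundary,
        volume_scale=1.0, r1=r1, r2=r2, same=same, coef=coef,
        stoich_ptr=sptr, stoich_sp=ssp, stoich_delta=sdl,
        dep_ptr=dptr, dep_idx=didx, channel_names=b.names, initial=init)


def build_birth_death(c_rate: float, g_rate: float, x0: int = 0,
                      ) -> CompartmentModel:
    """Minimal single-species birth-death model (production at ``c_rate``
    molecules/hr, first-order decay ``g_rate``) sharing the SSA kernel;
    used for exactness checks against the Poisson stationary law."""
    b = _Builder(N_SP)
    # reuse slot 0 as the species; a constant birth is modelled as a
    # first-order channel on an immutable dummy species with count 1
    dummy, spec = 1, 0
    b.add("birth", [dummy], {spec: 1}, c_rate)
    b.add("death", [spec], {spec: -1}, g_rate)
    (r1, r2, same, coef, sptr, ssp, sdl, dptr, didx) = b.finalize()
    init = np.zeros(N_SP, dtype=np.int64)
    init[spec] = x0
    init[dummy] = 1
    _m, params = mc.load_params("set2")
    return CompartmentModel(
        params=params, config=SSAConfig(), n_compartments=1,
        reacting=np.array([True]), boundary="reflecting", volume_scale=1.0,
        r1=r1, r2=r2, same=same, coef=coef,
        stoich_ptr=sptr, stoich_sp=ssp, stoich_delta=sdl,
        dep_ptr=dptr, dep_idx=didx, channel_names=b.names, initial=init)


# --------------------------------------------------------------------------
# Next-reaction kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _propensity(i, x, r1, r2, same, coef):
    if r2[i] < 0:
        return coef[i] * x[r1[i]]
    if same[i] == 1:
        n = x[r1[i]]
        return coef[i] * n * (n - 1)
    return coef[i] * x[r1[i]] * x[r2[i]]


@njit(cache=True)
def _heap_swap(heap, pos, a, b):
    ia, ib = heap[a], heap[b]
    heap[a], heap[b] = ib, ia
    pos[ia], pos[ib] = b, a


@njit(cache=True)
def _sift_up(keys, heap, pos, i):
    while i > 0:
        par = (i - 1) // 2
        if keys[heap[i]] < keys[heap[par]]:
            _heap_swap(heap, pos, i, par)
            i = par
        else:
            break


@njit(cache=True)
def _sift_down(keys, heap, pos, i, m):
    while True:
        l = 2 * i + 1
        r = l + 1
        small = i
        if l < m and keys[heap[l]] < keys[heap[small]]:
            small = l
        if r < m and keys[heap[r]] < keys[heap[small]]:
            small = r
        if small == i:
            break
        _heap_swap(heap, pos, i, small)
        i = small


@njit(cache=True)
def _nrm_core(x, r1, r2, same, coef, sptr, ssp, sdl, dptr, didx,
              rec_times, seed, max_events, event_log):
    np.random.seed(seed)
    M = len(coef)
    INF = np.inf
    a = np.empty(M)
    keys = np.empty(M)
    heap = np.empty(M, dtype=np.int64)
    pos = np.empty(M, dtype=np.int64)
    for i in range(M):
        a[i] = _propensity(i, x, r1, r2, same, coef)
        keys[i] = np.random.exponential(1.0) / a[i] if a[i] > 0.0 else INF
        heap[i] = i
        pos[i] = i
    for i in range(M // 2 - 1, -1, -1):
        _sift_down(keys, heap, pos, i, M)

    n_rec = len(rec_times)
    out = np.zeros((n_rec, len(x)), dtype=np.int64)
    rec_i = 0
    t_end = rec_times[n_rec - 1]
    n_events = 0
    while True:
        r = heap[0]
        tau = keys[r]
        t_next = tau if tau < t_end else t_end
        while rec_i < n_rec and rec_times[rec_i] <= t_next:
            for s in range(len(x)):
                out[rec_i, s] = x[s]
            rec_i += 1
        if tau >= t_end:
            break
        if n_events >= max_events:
            return out, -2, n_events, tau
        # fire channel r
        for k in range(sptr[r], sptr[r + 1]):
            x[ssp[k]] += sdl[k]
            if x[ssp[k]] < 0:
                return out, r, n_events, tau
        if n_events < len(event_log):
            event_log[n_events] = tau
        n_events += 1
        t = tau
        for k in range(dptr[r], dptr[r + 1]):
            j = didx[k]
            a_old = a[j]
            a_new = _propensity(j, x, r1, r2, same, coef)
            if not np.isfinite(a_new) or a_new < 0.0:
                return out, j, n_events, t
            a[j] = a_new
            if j == r or a_old == 0.0 or not np.isfinite(keys[j]):
                key = t + np.random.exponential(1.0) / a_new \
                    if a_new > 0.0 else INF
            else:
                key = t + (a_old / a_new) * (keys[j] - t) \
                    if a_new > 0.0 else INF
            old_key = keys[j]
            keys[j] = key
            if key < old_key:
                _sift_up(keys, heap, pos, pos[j])
            else:
                _sift_down(keys, heap, pos, pos[j], M)
    return out, -1, n_events, t_end


def simulate_ssa(model: CompartmentModel, t_end: float, seed: int,
                 record_dt: float = 0.1, *,
                 max_events: int = 2_000_000_000,
                 log_events: int = 0) -> StochasticTrajectory:
    """Exact next-reaction-method sample of the compartment model.

    ``seed`` fully determines the trajectory for a given model digest.
    Recording at fixed intervals does not perturb the dynamics.
    ``log_events`` > 0 additionally stores the first N event times in
    ``metadata['event_times']`` (waiting-time diagnostics).
    """
    if seed is None:
        raise ValueError("a seed is required; the SSA has no hidden entropy")
    if t_end <= 0 or record_dt <= 0:
        raise ValueError("t_end and record_dt must be positive")
    rec_times = np.arange(0.0, t_end + 0.5 * record_dt, record_dt)
    x = model.initial.copy()
    event_log = np.full(int(log_events), np.nan)
    out, status, n_events, t_reached = _nrm_core(
        x, model.r1, model.r2, model.same, model.coef,
        model.stoich_ptr, model.stoich_sp, model.stoich_delta,
        model.dep_ptr, model.dep_idx, rec_times, int(seed), max_events,
        event_log)
    if status == -2:
        raise mc.ConvergenceError(
            f"SSA exceeded {max_events} events at t={t_reached:.3f}")
    if status >= 0:
        raise RuntimeError(
            f"SSA propensity/stoichiometry error in channel "
            f"{model.channel_names[status]} at t={t_reached:.3f}")
    log.info("SSA: %d events to t=%.2f", n_events, t_end)
    counts = out.reshape(len(rec_times), model.n_compartments, N_SP)
    meta = {"n_events": int(n_events), "record_dt": record_dt,
            "boundary": model.boundary,
            "volume_scale": model.volume_scale}
    if log_events:
        meta["event_times"] = event_log[:min(int(log_events), n_events)]
    return StochasticTrajectory(
        times=rec_times, counts=counts, seed=int(seed),
        model_digest=model.digest(), metadata=meta)


# --------------------------------------------------------------------------
# Aggregation and mean-field cross-check
# --------------------------------------------------------------------------

_TOTALS = {
    "m_cI": {"m_cI": 1}, "m_tetR_O": {"m_tetR_O": 1},
    "m_tetR_Q": {"m_tetR_Q": 1}, "m_lacI": {"m_lacI": 1},
    "m_luxI": {"m_luxI": 1},
    "cI": {"cI": 1, "cI_2": 2, "OlacI_bound": 2},
    "TetR": {"TetR": 1, "TetR_2": 2, "OcI_bound": 2, "OluxI_bound": 2},
    "LacI": {"LacI": 1, "LacI_2": 2, "OtetO_bound": 2},
    "LuxI": {"LuxI": 1},
    "AHL": {"AHL": 1, "LuxR_AHL": 1, "LuxR_AHL_2": 2, "Olux_bound": 2},
    "LuxR": {"LuxR": 1, "LuxR_AHL": 1, "LuxR_AHL_2": 2, "Olux_bound": 2},
}


def aggregate_protein_totals(traj: StochasticTrajectory,
                             cells_only: bool = True,
                             reacting: Optional[np.ndarray] = None,
                             ) -> ObservableTrajectory:
    """Totals of all molecular forms per cell over time.

    Monomer-equivalent accounting: dimers contribute 2, promoter-bound
    dimers contribute 2; AHL totals include receptor-bound ligand.  The
    returned object exposes the ten observable species plus the
    (conserved) LuxR total.
    """
    counts = traj.counts
    if cells_only and reacting is not None:
        counts = counts[:, np.asarray(reacting, dtype=bool), :]
    data = {}
    for name, parts in _TOTALS.items():
        tot = np.zeros(counts.shape[:2], dtype=np.int64)
        for sp, w in parts.items():
            tot += w * counts[:, :, _I[sp]]
        data[name] = tot
    return ObservableTrajectory(times=traj.times, data=data)


def mean_field_rates(model: CompartmentModel, x: np.ndarray) -> np.ndarray:
    """Deterministic mass-action ODE right-hand side of the generated
    reaction set (molecule units; ``x(x-1) -> x²`` for homodimer
    channels).  The large-count limit of the SSA."""
    x = np.asarray(x, dtype=float)
    dx = np.zeros_like(x)
    for i in range(model.n_channels):
        if model.r2[i] < 0:
            a = model.coef[i] * x[model.r1[i]]
        elif model.same[i] == 1:
            a = model.coef[i] * x[model.r1[i]] ** 2
        else:
            a = model.coef[i] * x[model.r1[i]] * x[model.r2[i]]
        for k in range(model.stoich_ptr[i], model.stoich_ptr[i + 1]):
            dx[model.stoich_sp[k]] += model.stoich_delta[k] * a
    return dx
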