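"""Stochastic-sequence + ODE simulation of a PEGylation reaction.

The reaction model couples three ingredients:

1. **Gillespie-like site selection.**  Among the currently reactive
   amine sites, the next site to be modified is drawn with probability
   proportional to its predicted intrinsic reactivity, via a cumulative
   probability and a single uniform draw.

2. **Distance-cutoff shielding.**  Once a site carries a PEG chain,
   every still-reactive site within a radial distance cutoff (the
   radius of PEG coverage) of that site's amine nitrogen becomes
   permanently blocked.  Radii below ~11 Å — the smallest lysine–lysine
   spacing in a compact protein like lysozyme — impose no effective
   constraint.

3. **A deterministic ODE system** for the PEGmer populations.  With N
   effective PEGylation steps, the species are the j-PEGylated protein
   concentrations P_j (j = 0…N), the active reagent PEG, and its
   hydrolysis product PEG_d:

       dP_0/dt   = −ε·k_1·φ_1·PEG·P_0
       dP_j/dt   =  ε·k_j·φ_j·PEG·P_{j−1} − ε·k_{j+1}·φ_{j+1}·PEG·P_j
       dPEG/dt   = −k_d·PEG − Σ_j ε·k_j·φ_j·PEG·P_{j−1}
       dPEG_d/dt =  k_d·PEG

   k_j is the mean predicted reactivity over the reactive set at step j
   (k_j,avg), ε a reaction prefactor absorbing linker chemistry and
   conditions, φ_j a diffusional attenuation modifier governed by κ,
   and k_d the aqueous hydrolysis rate of the amine-reactive ester
   (0.21 min⁻¹ for mPEG-NHS, ~0.01 min⁻¹ for mPEG-SPA/SMB).

The default φ strategy attenuates each subsequent step by the PEG
surface coverage already in place: φ_j = exp(−κ·(j−1)·π·R²) with R the
shielding radius, so φ_1 = 1 and κ carries units of Å⁻².  The strategy
is pluggable (``phi_strategy``) because the functional form is a
modelling choice, not a law.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .reactivity import DEFAULT_CUTOFF, ReactivityModel
from .structure import AmineSite

__all__ = [
    "HYDROLYSIS_RATES",
    "ISO_REACTIVITY_PARAMETERS",
    "ShieldingState",
    "KineticParameters",
    "SimulationResult",
    "select_site",
    "apply_shielding",
    "reaction_sequence",
    "diffusion_modifier",
    "simulate",
    "pegmer_distribution",
    "rfd_ratio",
]

# Linker hydrolysis rate constants, min^-1 (literature values)
HYDROLYSIS_RATES = {"NHS": 0.21, "SPA": 0.01, "SMB": 0.01}

# Prior-work iso-reactivity fits (shielding mol/g, diffusion, reactivity);
# reference constants only — nothing in this package consumes them.
ISO_REACTIVITY_PARAMETERS = {
    "lysozyme": {"alpha": 3.1e-5, "kappa": 3.2e3, "k0": 10.7},
    "bche": {"alpha": 4.4e-4, "kappa": 7.2e3, "k0": 7.3},
}


@dataclass
class ShieldingState:
    """Partition of the site set into modified / blocked / reactive."""

    modified_sites: list[str]
    blocked_sites: set[str]
    reactive_sites: set[str]
    shield_radius: float

    @classmethod
    def initial(cls, site_ids: list[str], shield_radius: float) -> "ShieldingState":
        return cls(modified_sites=[], blocked_sites=set(),
                   reactive_sites=set(site_ids), shield_radius=shield_radius)

    def check_partition(self, all_ids: set[str]) -> None:
        parts = set(self.modified_sites) | self.blocked_sites | self.reactive_sites
        n = len(self.modified_sites) + len(self.blocked_sites) + len(self.reactive_sites)
        if parts != all_ids or n != len(all_ids):
            raise ValueError("shielding state does not partition the site set")


@dataclass
class KineticParameters:
    """Reaction-condition parameters of the kinetic model.

    Units: k_d min⁻¹; kappa Å⁻²; shield_radius Å; peg_mw kDa;
    concentrations mol·L⁻¹; cutoff_rate M⁻¹·min⁻¹.  epsilon is the
    dimensionless reaction prefactor.
    """

    k_d: float = HYDROLYSIS_RATES["NHS"]
    kappa: float = 0.0
    epsilon: float = 1.0
    shield_radius: float = 11.0
    peg_mw: float = 5.0
    protein0: float = 1e-5
    peg0: float = 1e-3
    cutoff_rate: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        for name in ("k_d", "kappa", "epsilon", "shield_radius", "peg_mw",
                     "protein0", "peg0", "cutoff_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def select_site(rates: dict[str, float], uniform_draw: float) -> str:
    """Gillespie-like selection: cumulative probability vs one draw.

    k_v = (cumulative rate up to site v) / (total rate); the first site
    whose cumulative value reaches the draw is returned, so a site is
    chosen with probability proportional to its reactivity.
    """
    if not 0 <= uniform_draw < 1:
        raise ValueError("uniform_draw must lie in [0, 1)")
    positive = [(s, r) for s, r in rates.items() if r > 0]
    if not positive:
        raise ValueError("no site with positive rate")
    total = sum(r for _s, r in positive)
    cum = 0.0
    for s, r in positive:
        cum += r / total
        if cum >= uniform_draw:
            return s
    return positive[-1][0]  # guard against floating-point undershoot


def apply_shielding(state: ShieldingState, chosen: str,
                    coords: dict[str, np.ndarray]) -> ShieldingState:
    """Modify ``chosen`` and block every reactive site within the radius.

    Distances are nitrogen-to-nitrogen Euclidean; blocking is permanent.
    Returns a new state; the input is not mutated.
    """
    if chosen not in state.reactive_sites:
        raise ValueError(f"site {chosen!r} is not in the reactive set")
    origin = np.asarray(coords[chosen], dtype=float)
    newly_blocked = {
        s for s in state.reactive_sites if s != chosen
        and np.linalg.norm(np.asarray(coords[s], dtype=float) - origin)
        <= state.shield_radius}
    return ShieldingState(
        modified_sites=state.modified_sites + [chosen],
        blocked_sites=state.blocked_sites | newly_blocked,
        reactive_sites=state.reactive_sites - newly_blocked - {chosen},
        shield_radius=state.shield_radius)


def reaction_sequence(sites: list[AmineSite], model: ReactivityModel,
                      shield_radius: float, seed: int | None = None,
                      cutoff_rate: float | None = None,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[list[str], list[float]]:
    """Draw one stochastic modification sequence with its per-step rates.

    Sites predicted below the reactivity cutoff are removed up front.
    At each step the averaged reactivity over the current reactive set
    (k_j,avg) is recorded, a site is selected Gillespie-style, and its
    shielding is applied; the loop ends when no reactive site remains.
    Returns ``(site_sequence, k_avg_per_step)``; both empty when no
    site clears the cutoff (a valid no-reaction outcome).
    """
    cutoff = model.cutoff if cutoff_rate is None else cutoff_rate
    rates = {s.site_id: model.predict(s) for s in sites}
    coords = {s.site_id: s.nitrogen_coords for s in sites}
    active = {sid: r for sid, r in rates.items() if r >= cutoff and r > 0}
    if not active:
        return [], []
    if rng is None:
        rng = np.random.default_rng(seed)
    state = ShieldingState.initial(list(active), shield_radius)
    sequence: list[str] = []
    k_avg: list[float] = []
    while state.reactive_sites:
        current = {sid: rates[sid] for sid in active if sid in state.reactive_sites}
        k_avg.append(float(np.mean(list(current.values()))))
        chosen = select_site(current, float(rng.random()))
        state = apply_shielding(state, chosen, coords)
        sequence.append(chosen)
    return sequence, k_avg


def diffusion_modifier(j: int, params: KineticParameters,
                       phi_strategy=None) -> float:
    """Diffusional attenuation φ_j for the j-th PEGylation step.

    Default covered-area strategy: φ_j = exp(−κ·(j−1)·π·R²), i.e. the
    first reaction is unmodified and each attached chain attenuates the
    next step in proportion to the surface area it covers.  Pass a
    callable ``phi_strategy(j, params)`` for an alternative form.
    """
    if j < 1:
        raise ValueError("step index j must be >= 1")
    if phi_strategy is not None:
        return float(phi_strategy(j, params))
    area = np.pi * params.shield_radius ** 2
    return float(np.exp(-params.kappa * (j - 1) * area))


@dataclass
class SimulationResult:
    """ODE trajectories of the PEGmer populations and the reagent.

    ``pegmer_conc`` has shape (N+1, n_times): row j is P_j(t) in
    mol·L⁻¹.  A dense interpolant is kept for distribution queries.
    """

    times: np.ndarray
    pegmer_conc: np.ndarray
    peg_conc: np.ndarray
    peg_hydrolyzed: np.ndarray
    site_sequence: list[str]
    k_avg_per_step: list[float]
    phi_per_step: list[float]
    params: KineticParameters
    _dense: object = field(default=None, repr=False)

    @property
    def n_steps(self) -> int:
        return len(self.k_avg_per_step)

    def relative(self) -> np.ndarray:
        """PEGmer concentrations normalized by the initial protein concentration."""
        return self.pegmer_conc / self.params.protein0

    def species_table(self) -> "dict[str, np.ndarray]":
        out = {"time_min": self.times}
        for j in range(self.pegmer_conc.shape[0]):
            out[f"P_{j}"] = self.pegmer_conc[j]
        out["PEG"] = self.peg_conc
        out["PEG_d"] = self.peg_hydrolyzed
        return out

    def to_text(self, sep: str = ",") -> str:
        table = self.species_table()
        keys = list(table)
        lines = [sep.join(keys)]
        for i in range(len(self.times)):
            lines.append(sep.join(f"{table[k][i]:.10g}" for k in keys))
        return "\n".join(lines) + "\n"


def simulate(params: KineticParameters, k_avg_per_step: list[float],
             t_grid: np.ndarray, phi_strategy=None,
             rtol: float = 1e-8) -> SimulationResult:
    """Integrate the N+3 ODE system over ``t_grid`` (minutes).

    The reagent undergoes first-order hydrolysis (k_d) in parallel with
    the PEGylation steps; each step j proceeds at the observed rate
    ε·k_j,avg·φ_j·PEG·P_{j−1}.  A stiff implicit integrator is used.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must increase from 0")
    n = len(k_avg_per_step)
    k = np.asarray(k_avg_per_step, dtype=float)
    if np.any(k < 0):
        raise ValueError("k_avg_per_step entries must be >= 0")
    phi = np.array([diffusion_modifier(j, params, phi_strategy)
                    for j in range(1, n + 1)])
    keff = params.epsilon * k * phi  # per-step observed rate constants

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        # tiny integrator undershoots below zero must not feed back as sources
        p = np.maximum(y[:n + 1], 0.0)
        peg = max(y[n + 1], 0.0)
        dy = np.zeros_like(y)
        flux = keff * peg * p[:n] if n else np.zeros(0)  # step j consumes P_{j-1}
        dy[:n] -= flux
        dy[1:n + 1] += flux
        dy[n + 1] = -params.k_d * peg - flux.sum()
        dy[n + 2] = params.k_d * peg
        return dy

    y0 = np.zeros(n + 3)
    y0[0] = params.protein0
    y0[n + 1] = params.peg0
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                    method="LSODA", rtol=rtol, atol=rtol * max(params.protein0, params.peg0, 1e-30) * 1e-3,
                    dense_output=True)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = sol.y
    if np.any(y < -1e-12):
        raise RuntimeError("integration produced significantly negative concentrations")
    return SimulationResult(
        times=sol.t, pegmer_conc=y[:n + 1], peg_conc=y[n + 1],
        peg_hydrolyzed=y[n + 2], site_sequence=[], k_avg_per_step=list(k),
        phi_per_step=list(phi), params=params, _dense=sol.sol)


def pegmer_distribution(result: SimulationResult, t: float) -> np.ndarray:
    """PEGmer fractions P_j(t)/ΣP_j(t) at time t (dense-output query)."""
    if not result.times[0] <= t <= result.times[-1]:
        raise ValueError(f"t={t} outside simulated range "
                         f"[{result.times[0]}, {result.times[-1]}]")
    n = result.pegmer_conc.shape[0] - 1
    y = result._dense(t) if result._dense is not None else None
    if y is None:  # fall back to nearest grid point
        idx = int(np.argmin(np.abs(result.times - t)))
        p = result.pegmer_conc[:, idx]
    else:
        p = y[:n + 1]
    total = p.sum()
    if total <= 0:
        raise ValueError("total protein concentration is zero")
    return p / total


# PEG monomer (ethylene oxide unit) molar mass, g/mol
_EO_MONOMER_MASS = 44.0
BRUSH_THRESHOLD = 2.0


def rfd_ratio(graft_sites: list[str], coords: dict[str, np.ndarray],
              peg_mw_kda: float, monomer_length: float = 3.5,
              ) -> tuple[float, str]:
    """Flory-radius-to-graft-spacing ratio and conformation class.

    R_f = a·N^(3/5) with a the monomer length and N the number of
    ethylene-oxide units; D is the mean nearest-neighbour
    nitrogen–nitrogen distance among the grafted sites.  Ratios above 2
    indicate a brush-like PEG layer, below a dumbbell conformation.
    """
    if len(graft_sites) < 2:
        raise ValueError("rfd_ratio needs at least 2 graft sites")
    n_monomers = 1000.0 * peg_mw_kda / _EO_MONOMER_MASS
    r_f = monomer_length * n_monomers ** 0.6
    xyz = np.array([np.asarray(coords[s], dtype=float) for s in graft_sites])
    dmat = np.sqrt(((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(dmat, np.inf)
    spacing = float(dmat.min(axis=1).mean())
    ratio = r_f / spacing
    return ratio, ("brush" if ratio > BRUSH_THRESHOLD else "dumbbell")
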