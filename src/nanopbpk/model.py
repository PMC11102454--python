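"""Whole-body PBPK ODE model of intravenously dosed nanoparticles.

Each organ holds three nanoparticle mass pools: intravascular (``M_vasc``),
extravascular tissue (``M_extra``) and, in organs of the mononuclear
phagocyte system (lung, liver, spleen, kidney), an intracellular phagocytic
pool (``M_phago``).  The pools exchange by convection with arterial/venous
blood, by passive permeation governed by the permeability–flow product
``PA`` and the tissue:plasma coefficient ``P``, by time-dependent
Hill-kinetic phagocytic uptake, first-order phagocytic release, and
clearance into bile (liver) or urine (kidney):

    dM_vasc/dt  = Q (M_in/V_in - M_vasc/V_vasc)
                  - PA (M_vasc/V_vasc - M_extra/(P V_extra)) + R_rel - R_up
    dM_extra/dt = PA (M_vasc/V_vasc - M_extra/(P V_extra)) - R_elim
    dM_phago/dt = R_up - R_rel

    R_up   = K_max t^n_H / (K_50^n_H + t^n_H) * M_vasc
    R_rel  = K_rel M_phago
    R_elim = K_elim M_extra/V_extra

The system is linear in nanoparticle mass (the Hill factor depends on time,
not on mass), so solutions scale exactly with the administered dose.  All
masses are in μg, volumes in mL, times in h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import OrganParameters, PBPKParameters
from .physiology import PORTAL_ORGANS, PhysiologyTable

DEFAULT_SOLVER_OPTS = {"method": "LSODA", "rtol": 1e-8, "atol": 1e-10}

#: default output grid: 0–48 h every 0.1 h
DEFAULT_T_GRID = np.round(np.arange(0, 480 + 1) * 0.1, 10)


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to converge."""


@dataclass(frozen=True)
class DoseSchedule:
    """An IV bolus of ``dose_mass`` μg into venous blood at ``admin_time``."""

    dose_mass: float  # μg
    admin_time: float = 0.0  # h

    def __post_init__(self) -> None:
        if self.dose_mass < 0:
            raise ValueError("dose_mass must be nonnegative")

    @classmethod
    def from_mg(cls, dose_mg: float) -> "DoseSchedule":
        return cls(dose_mass=dose_mg * 1e3)


@dataclass
class SystemState:
    """Nanoparticle mass (μg) in every pool at one instant."""

    M_art: float
    M_ven: float
    organs: dict[str, tuple[float, float, float]]  # organ -> (vasc, extra, phago)
    X_bile: float = 0.0
    X_urine: float = 0.0

    def total_mass(self) -> float:
        return (
            self.M_art
            + self.M_ven
            + sum(sum(pools) for pools in self.organs.values())
            + self.X_bile
            + self.X_urine
        )

    def to_vector(self, phys: PhysiologyTable) -> np.ndarray:
        y = [self.M_art, self.M_ven]
        for o in phys.organs:
            y.extend(self.organs[o])
        y.extend([self.X_bile, self.X_urine])
        return np.asarray(y, dtype=float)

    @classmethod
    def from_vector(cls, y: np.ndarray, phys: PhysiologyTable) -> "SystemState":
        organs = {}
        for i, o in enumerate(phys.organs):
            j = 2 + 3 * i
            organs[o] = (y[j], y[j + 1], y[j + 2])
        return cls(M_art=y[0], M_ven=y[1], organs=organs, X_bile=y[-2], X_urine=y[-1])


def hill_uptake_rate(t: float, M_vasc: float, p: OrganParameters) -> float:
    """Phagocytic uptake rate R_up (μg/h) at time ``t``.

    The Hill factor rises from 0 at t=0 to ``K_max`` with half-maximum time
    ``K_50``.  ``K_50 = 0`` means immediate saturation: the rate is
    ``K_max * M_vasc`` for any t > 0 and 0 at t = 0 (right-limit
    convention).
    """
    if t < 0 or M_vasc < 0:
        raise ValueError("t and M_vasc must be nonnegative")
    if p.K_max == 0 or t == 0:
        return 0.0
    tn = t**p.n_H
    return p.K_max * tn / (p.K_50**p.n_H + tn) * M_vasc


def organ_derivatives(
    state: SystemState,
    organ: str,
    params: PBPKParameters,
    phys: PhysiologyTable,
    t: float = 0.0,
) -> tuple[float, float, float, float]:
    """Mass-balance rates (dM_vasc/dt, dM_extra/dt, dM_phago/dt, dX_elim/dt)
    for one organ, in μg/h.  The four rates sum to the organ's net
    convective inflow minus outflow.  ``t`` enters only through the Hill
    uptake factor (default 0, i.e. uptake not yet switched on)."""
    p = params[organ]
    if p.PA > 0 and p.P == 0:
        raise ValueError("P must be positive when PA is nonzero")
    M_vasc, M_extra, M_phago = state.organs[organ]
    V_vasc, V_extra = phys.V_vasc[organ], phys.V_extra[organ]
    C_vasc = M_vasc / V_vasc
    C_extra = M_extra / V_extra

    # convective inflow: lung from the venous pool, liver from hepatic
    # artery + portal (splenic) outflow, everything else from the artery
    if organ == "lung":
        inflow = phys.cardiac_output * state.M_ven / phys.V_ven
        q_out = phys.cardiac_output
    elif organ == "liver":
        inflow = phys.Q[organ] * state.M_art / phys.V_art
        for po in PORTAL_ORGANS:
            inflow += phys.Q[po] * state.organs[po][0] / phys.V_vasc[po]
        q_out = phys.perfusion(organ)
    else:
        inflow = phys.Q[organ] * state.M_art / phys.V_art
        q_out = phys.Q[organ]

    flux = p.PA * (C_vasc - C_extra / p.P) if p.PA > 0 else 0.0
    R_up = hill_uptake_rate(t, M_vasc, p)
    R_rel = p.K_rel * M_phago
    R_elim = p.K_elim * C_extra

    dM_vasc = inflow - q_out * C_vasc - flux + R_rel - R_up
    dM_extra = flux - R_elim
    dM_phago = R_up - R_rel
    return dM_vasc, dM_extra, dM_phago, R_elim


def build_rhs(params: PBPKParameters, phys: PhysiologyTable):
    """Vectorized right-hand side f(t, y) of the whole-body system.

    State layout: ``[M_art, M_ven, (M_vasc, M_extra, M_phago) per organ in
    phys.organs order, X_bile, X_urine]``.
    """
    organs = phys.organs
    K = len(organs)
    idx = {o: i for i, o in enumerate(organs)}
    lung_i, liver_i = idx["lung"], idx["liver"]
    kidney_i = idx["kidney"]
    portal_i = np.array([idx[o] for o in PORTAL_ORGANS], dtype=int)

    Vv = np.array([phys.V_vasc[o] for o in organs])
    Ve = np.array([phys.V_extra[o] for o in organs])
    PA = np.array([params[o].PA for o in organs])
    P = np.array([params[o].P for o in organs])
    if np.any((PA > 0) & (P == 0)):
        raise ValueError("P must be positive wherever PA is nonzero")
    PA_over_P = np.where(PA > 0, PA / np.where(P > 0, P, 1.0), 0.0)
    K_max = np.array([params[o].K_max for o in organs])
    K_50 = np.array([params[o].K_50 for o in organs])
    n_H = np.array([params[o].n_H for o in organs])
    K_rel = np.array([params[o].K_rel for o in organs])
    K_elim = np.array([params[o].K_elim for o in organs])

    # arterial flow into each organ (lung slot unused), venous-side outflow
    Q_in = np.array([phys.Q[o] for o in organs])
    Q_out = Q_in.copy()
    Q_out[liver_i] = phys.perfusion("liver")
    co = phys.cardiac_output
    V_art, V_ven = phys.V_art, phys.V_ven
    # organs draining to the vein: all except lung (to artery) and portal
    to_vein = np.ones(K, dtype=bool)
    to_vein[lung_i] = False
    to_vein[portal_i] = False

    sl_v = slice(2, 2 + 3 * K, 3)
    sl_e = slice(3, 3 + 3 * K, 3)
    sl_p = slice(4, 4 + 3 * K, 3)
    hill_active = K_max > 0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        C_art = y[0] / V_art
        C_ven = y[1] / V_ven
        Mv = y[sl_v]
        Cv = Mv / Vv
        Ce = y[sl_e] / Ve

        hill = np.zeros(K)
        if t > 0:
            tn = t**n_H[hill_active]
            hill[hill_active] = (
                K_max[hill_active] * tn / (K_50[hill_active] ** n_H[hill_active] + tn)
            )
        R_up = hill * Mv
        R_rel = K_rel * y[sl_p]
        R_elim = K_elim * Ce
        flux = PA * Cv - PA_over_P * Ce

        inflow = Q_in * C_art
        inflow[lung_i] = co * C_ven
        inflow[liver_i] += np.sum(Q_in[portal_i] * Cv[portal_i])
        outflow = Q_out * Cv

        dy = np.empty_like(y)
        dy[0] = co * Cv[lung_i] - co * C_art
        dy[1] = np.sum(outflow[to_vein]) - co * C_ven
        dy[sl_v] = inflow - outflow - flux + R_rel - R_up
        dy[sl_e] = flux - R_elim
        dy[sl_p] = R_up - R_rel
        dy[-2] = R_elim[liver_i]
        dy[-1] = R_elim[kidney_i]
        return dy

    return rhs


def initial_state(dose: DoseSchedule, phys: PhysiologyTable) -> np.ndarray:
    """Bolus initial condition: the whole dose in the venous pool."""
    y0 = np.zeros(2 + 3 * len(phys.organs) + 2)
    y0[1] = dose.dose_mass
    return y0


@dataclass
class SimulationResult:
    """Trajectories of every mass pool plus derived concentrations."""

    t: np.ndarray  # h, strictly increasing
    y: np.ndarray  # (n_t, n_state) μg
    phys: PhysiologyTable
    dose_mass: float  # μg
    params: PBPKParameters | None = field(default=None, repr=False)

    @property
    def blood_concentration(self) -> np.ndarray:
        """(M_art + M_ven) / (V_art + V_ven), μg/mL (pooled blood)."""
        return (self.y[:, 0] + self.y[:, 1]) / self.phys.blood_volume

    def organ_mass(self, organ: str) -> np.ndarray:
        i = 2 + 3 * self.phys.organs.index(organ)
        return self.y[:, i : i + 3].sum(axis=1)

    def tissue_concentration(self, organ: str) -> np.ndarray:
        """Total organ NP mass over total organ volume, μg/mL."""
        return self.organ_mass(organ) / (
            self.phys.V_vasc[organ] + self.phys.V_extra[organ]
        )

    @property
    def X_bile(self) -> np.ndarray:
        return self.y[:, -2]

    @property
    def X_urine(self) -> np.ndarray:
        return self.y[:, -1]

    def state_at(self, i: int) -> SystemState:
        return SystemState.from_vector(self.y[i], self.phys)

    def total_mass(self) -> np.ndarray:
        return self.y.sum(axis=1)

    def mass_balance_error(self) -> float:
        """max_t |total mass + excreted - dose| / dose (dimensionless)."""
        if self.dose_mass == 0:
            return float(np.max(np.abs(self.total_mass())))
        return float(np.max(np.abs(self.total_mass() - self.dose_mass)) / self.dose_mass)

    def scaled(self, dose_mass: float) -> "SimulationResult":
        """Exact rescaling to another dose (the model is linear in mass)."""
        factor = dose_mass / self.dose_mass
        return SimulationResult(
            t=self.t, y=self.y * factor, phys=self.phys, dose_mass=dose_mass, params=self.params
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time, compartment, organ, mass, concentration)."""
        rows = []
        blood = self.blood_concentration
        for k, t in enumerate(self.t):
            rows.append((t, "arterial", "blood", self.y[k, 0], blood[k]))
            rows.append((t, "venous", "blood", self.y[k, 1], blood[k]))
            for i, o in enumerate(self.phys.organs):
                j = 2 + 3 * i
                conc = self.tissue_concentration(o)[k]
                for comp, col in (("vasc", j), ("extra", j + 1), ("phago", j + 2)):
                    rows.append((t, comp, o, self.y[k, col], conc))
            rows.append((t, "bile", "excreted", self.y[k, -2], np.nan))
            rows.append((t, "urine", "excreted", self.y[k, -1], np.nan))
        return pd.DataFrame(
            rows, columns=["time", "compartment", "organ", "mass", "concentration"]
        )


def simulate(
    params: PBPKParameters,
    phys: PhysiologyTable,
    dose: DoseSchedule | float,
    t_grid: np.ndarray | None = None,
    solver_opts: dict | None = None,
    y0: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the whole-body system from an IV bolus.

    ``dose`` may be a :class:`DoseSchedule` or a plain mass in μg.  ``y0``
    overrides the bolus initial condition (state-vector layout of
    :func:`build_rhs`); the dose is then taken as the total initial mass.
    """
    if not isinstance(dose, DoseSchedule):
        dose = DoseSchedule(dose_mass=float(dose))
    t_grid = DEFAULT_T_GRID if t_grid is None else np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0:
        raise ValueError("t_grid must start at 0 (bolus administration)")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    opts = dict(DEFAULT_SOLVER_OPTS)
    if solver_opts:
        opts.update(solver_opts)
    if opts["rtol"] <= 0 or opts["atol"] <= 0:
        raise ValueError("solver tolerances must be positive")

    rhs = build_rhs(params, phys)
    if t_grid.size == 1:
        y = initial_state(dose, phys) if y0 is None else np.asarray(y0, dtype=float)
        return SimulationResult(
            t=t_grid, y=y[None, :], phys=phys, dose_mass=dose.dose_mass, params=params
        )
    if y0 is None:
        y0 = initial_state(dose, phys)
    else:
        y0 = np.asarray(y0, dtype=float)
        dose = DoseSchedule(dose_mass=float(y0.sum()), admin_time=dose.admin_time)
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        t_eval=t_grid,
        method=opts["method"],
        rtol=opts["rtol"],
        atol=opts["atol"],
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE solver failed near t = {sol.t[-1] if sol.t.size else 0.0:.4g} h: "
            f"{sol.message}"
        )
    y = sol.y.T.copy()
    y[y < 0] = 0.0  # clamp solver-noise negatives
    return SimulationResult(t=t_grid, y=y, phys=phys, dose_mass=dose.dose_mass, params=params)


def blood_auc(result: SimulationResult, t_end: float) -> float:
    """Trapezoidal area under the blood concentration curve over [0, t_end],
    in μg·h/mL."""
    t, c = result.t, result.blood_concentration
    if t_end > t[-1] + 1e-12:
        raise ValueError("t_end exceeds the simulated time range")
    if t_end < t[0]:
        raise ValueError("t_end precedes the first grid point")
    if t.size < 2 or t_end == t[0]:
        return 0.0
    mask = t <= t_end
    tt, cc = t[mask], c[mask]
    if tt[-1] < t_end:
        tt = np.append(tt, t_end)
        cc = np.append(cc, np.interp(t_end, t, c))
    return float(np.trapezoid(cc, tt))


def np_count_from_dose(
    mass_mg: float, diameter_nm: float = 180.0, density_g_ml: float = 1.0
) -> float:
    """Number of particles in a dose, treating particles as spheres.

    count = mass / (density * pi/6 * diameter^3); 0.1 mg of 180 nm,
    1 g/mL particles is ~3.3e10 ("30 billion").
    """
    if mass_mg < 0:
        raise ValueError("mass must be nonnegative")
    if diameter_nm <= 0 or density_g_ml <= 0:
        raise ValueError("diameter and density must be positive")
    volume_ml = math.pi / 6.0 * (diameter_nm * 1e-7) ** 3  # nm -> cm; cm^3 == mL
    return (mass_mg * 1e-3) / (density_g_ml * volume_ml)
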