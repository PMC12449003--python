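"""Pulsatile 1D blood flow on vascular networks.

The model is the classical 1D theory of incompressible flow in deformable
vessels: mass and momentum balance

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q^2/A)/dx = -(A/rho) dP/dx - 8 pi mu Q / (rho A)

closed by a nonlinear viscoelastic tube law

    P = P0 + (pi r0 h / A) [ E_e eps + E_c eps_r ln(e^chi + 1)
                             + K_m/(2 sqrt(A A0)) dA/dt ]
    eps = A/A0 - 1,  chi = (eps - eps0)/eps_r

(elastin linear term, collagen recruitment softplus term, Kelvin–Voigt rate
term).  The wall rate term is recast into first-order form by substituting
the mass balance, ``dA/dt = -dQ/dx``, which turns the viscoelastic
contribution of the pressure gradient into a diffusion of ``Q``; that
diffusion is integrated implicitly in time (per vessel, tridiagonal) so the
admissible time step is set by the advective CFL condition alone.  With
``K_m = 0`` the elastic hyperbolic system is recovered identically.

The transport part is an explicit second-order finite-volume scheme (minmod
MUSCL reconstruction, midpoint evolution, Rusanov interface fluxes, pressure
gradient applied through interface pressures) with local time stepping on a
power-of-two hierarchy: each vessel advances with its own admissible step,
junction-adjacent vessels synchronize at common time levels, and junction
fluxes are buffered so that mass conservation is exact.  Junctions enforce
mass and total-pressure continuity plus one outgoing-characteristic
compatibility relation per vessel (Newton, analytic Jacobian, solved in
batch across junctions of equal degree); terminals carry 3-element
Windkessel models (purely resistive when C = 0) and the root a prescribed
periodic inflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from . import units
from .ccogen import VascularTree, ViscosityLaw

__all__ = [
    "WallLaw",
    "WindkesselBC",
    "InflowBC",
    "SolverConfig",
    "HemoParams",
    "tube_law_pressure",
    "wave_speed",
    "windkessel_update",
    "fv_step",
    "VesselState",
    "Simulator",
    "SimulationResult",
    "run_simulation",
    "build_walls",
    "calibrate_windkessels",
]


# ---------------------------------------------------------------------------
# constitutive laws (array-parameter kernels + dataclass API)
# ---------------------------------------------------------------------------

def _p_el(a, r0, h, ee, ec, e0, er, p0, a0):
    eps = a / a0 - 1.0
    chi = (eps - e0) / er
    g = ee * eps + ec * er * np.logaddexp(0.0, chi)
    return p0 + np.pi * r0 * h / a * g


def _dpda(a, r0, h, ee, ec, e0, er, a0):
    eps = a / a0 - 1.0
    chi = (eps - e0) / er
    g = ee * eps + ec * er * np.logaddexp(0.0, chi)
    gp = (ee + ec / (1.0 + np.exp(-chi))) / a0
    return np.pi * r0 * h * (gp / a - g / a ** 2)


def _phi(a, r0, h, km, a0):
    """Coefficient of -dQ/dx in the viscoelastic pressure contribution."""
    return (np.pi * r0 * h / a) * km / (2.0 * np.sqrt(a * a0))


@dataclass(frozen=True)
class WallLaw:
    """Viscoelastic tube-law parameters of one vessel (CGS units)."""

    r0: float  # reference radius, cm
    h: float  # wall thickness, cm
    e_e: float  # elastin effective modulus, dyn/cm^2
    e_c: float  # collagen effective modulus, dyn/cm^2
    eps0: float  # mean of the collagen recruitment distribution
    eps_r: float  # spread of the collagen recruitment distribution
    k_m: float  # viscoelastic coefficient, dyn s/cm^2
    p0: float  # reference pressure at A = A0, dyn/cm^2

    def __post_init__(self):
        if min(self.r0, self.h, self.e_e, self.eps_r) <= 0 or self.k_m < 0:
            raise ValueError("invalid wall parameters")

    @property
    def a0(self) -> float:
        return np.pi * self.r0 ** 2

    def _args(self):
        return (self.r0, self.h, self.e_e, self.e_c, self.eps0, self.eps_r,
                self.p0, self.a0)


def elastic_pressure(a, wall: WallLaw):
    """Elastic part of the tube law (no rate term)."""
    r0, h, ee, ec, e0, er, p0, a0 = wall._args()
    return _p_el(np.asarray(a, float), r0, h, ee, ec, e0, er, p0, a0)


def elastic_dpda(a, wall: WallLaw):
    r0, h, ee, ec, e0, er, p0, a0 = wall._args()
    return _dpda(np.asarray(a, float), r0, h, ee, ec, e0, er, a0)


def visco_phi(a, wall: WallLaw):
    return _phi(np.asarray(a, float), wall.r0, wall.h, wall.k_m, wall.a0)


def tube_law_pressure(a, dadt, wall: WallLaw):
    """Transmural pressure for lumen area ``a`` and area rate ``dadt``."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("lumen area must be positive")
    return elastic_pressure(a, wall) + visco_phi(a, wall) * np.asarray(dadt, float)


def wave_speed(a, wall: WallLaw, rho: float = 1.04):
    """Characteristic speed ``c = sqrt(A/rho * dP_el/dA)`` in cm/s."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("lumen area must be positive")
    c2 = a / rho * elastic_dpda(a, wall)
    if np.any(c2 <= 0):
        raise ValueError("non-physical wall parameters: dP/dA <= 0")
    return np.sqrt(c2)


@dataclass(frozen=True)
class WindkesselBC:
    """3-element Windkessel terminal model; ``c == 0`` is purely resistive."""

    r1: float  # dyn s / cm^5
    r2: float
    c: float  # cm^5 / dyn
    p_t: float  # reference (venous-side) pressure, dyn/cm^2

    def __post_init__(self):
        if self.r1 < 0 or self.r2 < 0 or self.c < 0:
            raise ValueError("Windkessel parameters must be non-negative")


def windkessel_update(bc: WindkesselBC, q_o: float, p_o: float, dt: float,
                      dq_dt: float = 0.0) -> float:
    """One explicit-Euler step of the Windkessel pressure ODE.

    For ``C = 0`` the ODE degenerates algebraically to
    ``P_o = P_t + (R1 + R2) Q_o`` and that relation is returned exactly.
    """
    if bc.c == 0.0:
        return bc.p_t + (bc.r1 + bc.r2) * q_o
    dpdt = bc.r1 * dq_dt + ((bc.r1 + bc.r2) * q_o - (p_o - bc.p_t)) / (
        bc.r2 * bc.c
    )
    return p_o + dt * dpdt


@dataclass(frozen=True)
class InflowBC:
    """Periodic prescribed flow at the network root."""

    q_func: object  # callable t -> Q (cm^3/s)
    period: float  # s
    q_mean: float = 0.0  # cm^3/s, informational

    def __call__(self, t):
        return self.q_func(t)


@dataclass(frozen=True)
class SolverConfig:
    dx_c: float = 1.0  # characteristic cell length, cm
    dt_max: float = 1.0e-3  # s
    cfl: float = 0.9
    rho: float = 1.04  # g/cm^3
    n_cycles: int = 10
    samples_per_cycle: int = 128
    include_friction: bool = True
    wall_model: str = "viscoelastic"  # "viscoelastic" | "elastic"
    uniform_level: bool = False  # force every vessel to the finest time level
    newton_tol: float = 1.0e-11
    newton_max: int = 50
    max_level: int = 30


# ---------------------------------------------------------------------------
# default material parameter set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HemoParams:
    """Named wall/material parameter set for pial vessels (CGS).

    The thickness-to-radius relation is the double-exponential fit
    ``h/r0 = 0.2802 exp(-5.053 r0) + 0.1324 exp(-0.1114 r0)`` commonly used
    for systemic arteries; for arteriolar radii it gives h/r0 ~ 0.4.
    """

    e_e: float = 2.0e6  # elastin modulus, dyn/cm^2 (200 kPa)
    e_c: float = 2.0e7  # collagen modulus, dyn/cm^2
    eps0: float = 0.25  # collagen recruitment mean strain
    eps_r: float = 0.07  # collagen recruitment spread
    k_m: float = 5.0e4  # wall viscosity coefficient, dyn s/cm^2 (~ (4/3) eta_wall)
    p0_mmhg: float = 75.0  # reference pressure at A0
    rho: float = 1.04
    a0_factor: float = 1.0  # scenario multiplier on reference lumen area
    h_factor: float = 1.0  # scenario multiplier on wall thickness
    viscosity: ViscosityLaw = field(default_factory=ViscosityLaw.pries)
    scenario: str = "normotensive"

    def wall_for_radius(self, r0: float) -> WallLaw:
        r_eff = r0 * np.sqrt(self.a0_factor)
        h = self.h_factor * r0 * (
            0.2802 * np.exp(-5.053 * r0) + 0.1324 * np.exp(-0.1114 * r0)
        )
        return WallLaw(
            r0=r_eff, h=h, e_e=self.e_e, e_c=self.e_c, eps0=self.eps0,
            eps_r=self.eps_r, k_m=self.k_m,
            p0=units.mmhg_to_cgs(self.p0_mmhg),
        )


def build_walls(tree: VascularTree, params: HemoParams) -> list[WallLaw]:
    """One wall law per tree segment, from its generated radius."""
    return [params.wall_for_radius(float(r)) for r in tree.radius]


def calibrate_windkessels(tree: VascularTree, params: HemoParams,
                          p_root_mean_mmhg: float = 90.0,
                          p_t_mmhg: float = 30.0,
                          r1_fraction: float = 0.2) -> dict[int, WindkesselBC]:
    """Purely resistive terminal Windkessels giving uniform outlet flow.

    The total terminal resistance of each outlet is the budget
    ``(P_root - P_t)/Q_t`` minus the Poiseuille resistance accumulated along
    its root path, so that under steady conditions every outlet discharges
    ``Q_inlet / N_T``.
    """
    from .ccogen import poiseuille_solve

    if not tree.solved:
        poiseuille_solve(tree)
    mu = np.asarray(params.viscosity(tree.radius), dtype=float)
    seg_r = 8.0 * mu * tree.lengths / (np.pi * tree.radius ** 4)
    budget = units.mmhg_to_cgs(p_root_mean_mmhg - p_t_mmhg)
    q_t = tree.q_inlet / tree.n_terminals
    bcs = {}
    for tid in tree.terminal_ids():
        r_path = sum(seg_r[s] for s in tree.path_to_root(int(tid)))
        r_tot = max(budget / q_t - r_path, 0.05 * budget / q_t)
        bcs[int(tid)] = WindkesselBC(
            r1=r1_fraction * r_tot, r2=(1 - r1_fraction) * r_tot, c=0.0,
            p_t=units.mmhg_to_cgs(p_t_mmhg),
        )
    return bcs


# ---------------------------------------------------------------------------
# finite-volume kernels
# ---------------------------------------------------------------------------

def _minmod(a, b):
    return np.where(a * b <= 0, 0.0, np.where(np.abs(a) < np.abs(b), a, b))


def _kernel_single(a, q, dx, dt, wp, mu, rho, end_l, end_r,
                   include_friction, km_on):
    """Batched update of single-cell vessels.

    ``a, q, dx, mu``: (g,) arrays; ``wp``: tuple of per-vessel wall arrays
    (r0, h, ee, ec, e0, er, p0, a0, km); ``end_*``: dicts of (g,) arrays.
    The viscoelastic Q-diffusion is implicit in the cell value.
    """
    r0, h, ee, ec, e0, er, p0, a0, km = wp
    a_new = a + dt / dx * (end_l["fm"] - end_r["fm"])
    rhs = (end_l["fmom"] - end_r["fmom"]) / dx \
        - a / rho * (end_r["p"] - end_l["p"]) / dx
    denom = np.ones_like(q)
    if km_on:
        phi = _phi(a, r0, h, km, a0)
        coef = 2.0 * a * phi / (rho * dx ** 2)
        rhs = rhs + coef * (end_l["q"] + end_r["q"])
        denom = denom + dt * 2.0 * coef
    if include_friction:
        denom = denom + dt * 8.0 * np.pi * mu / (rho * a)
    q_new = (q + dt * rhs) / denom
    return a_new, q_new


def _kernel_multi(a, q, dx, dt, wall_args, km, mu, rho, end_l, end_r,
                  include_friction, km_on):
    """MUSCL-Hancock update of one multi-cell vessel (scalar wall params)."""
    r0, h, ee, ec, e0, er, p0, a0 = wall_args
    nc = len(a)
    da = np.zeros(nc)
    dq = np.zeros(nc)
    da[1:-1] = _minmod(a[1:-1] - a[:-2], a[2:] - a[1:-1])
    dq[1:-1] = _minmod(q[1:-1] - q[:-2], q[2:] - q[1:-1])
    a_w, a_e = np.maximum(a - 0.5 * da, 1e-12), np.maximum(a + 0.5 * da, 1e-12)
    q_w, q_e = q - 0.5 * dq, q + 0.5 * dq
    p_w = _p_el(a_w, r0, h, ee, ec, e0, er, p0, a0)
    p_e = _p_el(a_e, r0, h, ee, ec, e0, er, p0, a0)
    inc_a = -0.5 * dt / dx * (q_e - q_w)
    inc_q = -0.5 * dt / dx * (
        (q_e ** 2 / a_e - q_w ** 2 / a_w) + a / rho * (p_e - p_w)
    )
    a_w, a_e = np.maximum(a_w + inc_a, 1e-12), np.maximum(a_e + inc_a, 1e-12)
    q_w, q_e = q_w + inc_q, q_e + inc_q

    al, ar = a_e[:-1], a_w[1:]
    ql, qr = q_e[:-1], q_w[1:]
    cl = np.sqrt(al / rho * _dpda(al, r0, h, ee, ec, e0, er, a0))
    cr = np.sqrt(ar / rho * _dpda(ar, r0, h, ee, ec, e0, er, a0))
    s = np.maximum(np.abs(ql / al) + cl, np.abs(qr / ar) + cr)
    fm = np.empty(nc + 1)
    fmom = np.empty(nc + 1)
    p_if = np.empty(nc + 1)
    fm[1:-1] = 0.5 * (ql + qr) - 0.5 * s * (ar - al)
    fmom[1:-1] = 0.5 * (ql ** 2 / al + qr ** 2 / ar) - 0.5 * s * (qr - ql)
    p_if[1:-1] = 0.5 * (_p_el(al, r0, h, ee, ec, e0, er, p0, a0)
                        + _p_el(ar, r0, h, ee, ec, e0, er, p0, a0))
    fm[0], fm[-1] = end_l["fm"], end_r["fm"]
    fmom[0], fmom[-1] = end_l["fmom"], end_r["fmom"]
    p_if[0], p_if[-1] = end_l["p"], end_r["p"]

    a_new = a + dt / dx * (fm[:-1] - fm[1:])
    rhs = (fmom[:-1] - fmom[1:]) / dx - a / rho * (p_if[1:] - p_if[:-1]) / dx
    fric = 8.0 * np.pi * mu / (rho * a) if include_friction else 0.0
    if km_on:
        phi_c = _phi(a, r0, h, km, a0)
        phi_if = np.empty(nc + 1)
        phi_if[1:-1] = 0.5 * (phi_c[:-1] + phi_c[1:])
        phi_if[0], phi_if[-1] = phi_c[0], phi_c[-1]
        alpha = a / rho / dx ** 2  # multiplies phi at interfaces
        lo = alpha * phi_if[:-1]  # coupling to q_{i-1}
        hi = alpha * phi_if[1:]  # coupling to q_{i+1}
        # boundary interfaces couple to known end flows at half spacing
        lo[0] *= 2.0
        hi[-1] *= 2.0
        rhs = rhs.copy()
        rhs[0] += lo[0] * end_l["q"]
        rhs[-1] += hi[-1] * end_r["q"]
        ab = np.zeros((3, nc))
        ab[1] = 1.0 + dt * (lo + hi) + dt * fric
        ab[0, 1:] = -dt * hi[:-1]
        ab[2, :-1] = -dt * lo[1:]
        q_new = solve_banded((1, 1), ab, q + dt * rhs)
    else:
        q_new = (q + dt * rhs) / (1.0 + dt * fric)
    return a_new, q_new


@dataclass
class VesselState:
    """Stand-alone single-vessel state for direct finite-volume stepping."""

    a: np.ndarray
    q: np.ndarray
    dx: float
    wall: WallLaw
    mu: float = 0.032
    rho: float = 1.04
    t: float = 0.0


def fv_step(state: VesselState, dt: float, end_l=None, end_r=None,
            include_friction: bool = True,
            wall_model: str = "viscoelastic", cfl: float = 0.9) -> VesselState:
    """Advance one vessel by ``dt`` with the second-order FV scheme.

    End data default to transmissive (zero-gradient) boundaries; a dict with
    keys ``fm, fmom, p, q`` prescribes interface data explicitly.  Raises on
    CFL violation and on loss of positivity.
    """
    w = state.wall
    c = wave_speed(state.a, w, state.rho)
    smax = float(np.max(np.abs(state.q / state.a) + c))
    if dt * smax / state.dx >= cfl:
        raise ValueError(
            f"CFL violation: dt*smax/dx = {dt * smax / state.dx:.3f} >= {cfl}"
        )

    def transmissive(i):
        return {
            "fm": state.q[i],
            "fmom": state.q[i] ** 2 / state.a[i],
            "p": float(elastic_pressure(state.a[i], w)),
            "q": state.q[i],
        }

    end_l = end_l or transmissive(0)
    end_r = end_r or transmissive(-1)
    km_on = wall_model == "viscoelastic" and w.k_m != 0.0
    if len(state.a) == 1:
        wp = (np.array([w.r0]), np.array([w.h]), np.array([w.e_e]),
              np.array([w.e_c]), np.array([w.eps0]), np.array([w.eps_r]),
              np.array([w.p0]), np.array([w.a0]), np.array([w.k_m]))
        el = {k: np.atleast_1d(np.float64(v)) for k, v in end_l.items()}
        er = {k: np.atleast_1d(np.float64(v)) for k, v in end_r.items()}
        a_new, q_new = _kernel_single(
            state.a, state.q, np.float64(state.dx), dt, wp,
            np.float64(state.mu), state.rho, el, er, include_friction, km_on
        )
    else:
        a_new, q_new = _kernel_multi(
            state.a, state.q, state.dx, dt, w._args(), w.k_m, state.mu,
            state.rho, end_l, end_r, include_friction, km_on
        )
    if np.any(a_new <= 0) or not np.all(np.isfinite(a_new)):
        bad = int(np.argmin(a_new))
        raise FloatingPointError(
            f"non-positive lumen area in cell {bad} after step at t={state.t}"
        )
    return VesselState(a=a_new, q=q_new, dx=state.dx, wall=state.wall,
                       mu=state.mu, rho=state.rho, t=state.t + dt)


# ---------------------------------------------------------------------------
# network simulator
# ---------------------------------------------------------------------------

class Simulator:
    """Explicit local-time-stepping solver on a vascular tree.

    Vessels are the tree segments; each junction couples a parent's distal
    end with its children's proximal ends; terminals carry Windkessels and
    the root a prescribed inflow.
    """

    def __init__(self, tree: VascularTree, walls: list[WallLaw],
                 terminal_bcs: dict[int, WindkesselBC], inflow: InflowBC,
                 config: SolverConfig = SolverConfig()):
        if tree.n == 0:
            raise ValueError("empty tree")
        self.tree = tree
        self.cfg = config
        self.walls = list(walls)
        nv = tree.n
        self.nv = nv
        if len(self.walls) != nv:
            raise ValueError("one wall law per segment required")
        # per-vessel wall parameter arrays
        def arr(f):
            return np.array([f(w) for w in self.walls])

        self.w_r0 = arr(lambda w: w.r0)
        self.w_h = arr(lambda w: w.h)
        self.w_ee = arr(lambda w: w.e_e)
        self.w_ec = arr(lambda w: w.e_c)
        self.w_e0 = arr(lambda w: w.eps0)
        self.w_er = arr(lambda w: w.eps_r)
        self.w_p0 = arr(lambda w: w.p0)
        self.w_a0 = arr(lambda w: w.a0)
        self.w_km = arr(lambda w: w.k_m)
        if config.wall_model == "elastic":
            self.w_km = np.zeros_like(self.w_km)

        lengths = tree.lengths
        self.ncell = np.maximum(1, np.round(lengths / config.dx_c).astype(int))
        self.dx = lengths / self.ncell
        self.offs = np.concatenate([[0], np.cumsum(self.ncell)])
        ntot = int(self.offs[-1])
        self.a = np.repeat(self.w_a0, self.ncell)
        self.q = np.zeros(ntot)
        self.mu = np.asarray(tree.viscosity(tree.radius), dtype=float)
        self.rho = config.rho
        self.cell_first = self.offs[:-1]
        self.cell_last = self.offs[1:] - 1
        self.sc = np.flatnonzero(self.ncell == 1)  # single-cell vessels
        self.mc = np.flatnonzero(self.ncell > 1)
        self._sc_wp = tuple(w[self.sc] for w in (
            self.w_r0, self.w_h, self.w_ee, self.w_ec, self.w_e0, self.w_er,
            self.w_p0, self.w_a0, self.w_km))

        # junction groups by degree
        junctions = []
        for v in range(nv):
            kids = [int(c) for c in tree.children[v] if c >= 0]
            if kids:
                junctions.append([(v, 1)] + [(k, 0) for k in kids])
        self.jn_groups = {}
        for ends in junctions:
            self.jn_groups.setdefault(len(ends), []).append(ends)
        self._jn = []
        for n_deg, group in sorted(self.jn_groups.items()):
            vid = np.array([[v for v, _ in ends] for ends in group])
            end = np.array([[e for _, e in ends] for ends in group])
            cell = np.where(end == 1, self.cell_last[vid], self.cell_first[vid])
            sgn = np.where(end == 1, 1.0, -1.0)
            wp = tuple(w[vid] for w in (
                self.w_r0, self.w_h, self.w_ee, self.w_ec, self.w_e0,
                self.w_er, self.w_p0, self.w_a0))
            self._jn.append({"n": n_deg, "vid": vid, "end": end, "cell": cell,
                             "sgn": sgn, "wp": wp})

        self.terminals = np.asarray(tree.terminal_ids(), dtype=np.int64)
        missing = [int(t) for t in self.terminals if int(t) not in terminal_bcs]
        if missing:
            raise ValueError(f"terminal segments without Windkessel: {missing}")
        bcl = [terminal_bcs[int(t)] for t in self.terminals]
        self.t_r1 = np.array([b.r1 for b in bcl])
        self.t_r2 = np.array([b.r2 for b in bcl])
        self.t_c = np.array([b.c for b in bcl])
        self.t_pt = np.array([b.p_t for b in bcl])
        self.t_cell = self.cell_last[self.terminals]
        self._t_wp = tuple(w[self.terminals] for w in (
            self.w_r0, self.w_h, self.w_ee, self.w_ec, self.w_e0, self.w_er,
            self.w_p0, self.w_a0))
        self.term_q_prev = np.zeros(len(self.terminals))
        self.term_pi = np.where(self.t_c > 0, units.mmhg_to_cgs(75.0),
                                self.t_pt)
        self.inflow = inflow
        self.t = 0.0
        # interface buffers: [vessel, end(0=prox,1=dist), (fm,fmom,p,q,tacc)]
        self.buf = np.zeros((nv, 2, 5))
        self.dt_stats = {"min": np.inf, "max": 0.0, "sum": 0.0, "n": 0}
        self.mass_in = 0.0
        self.mass_out = 0.0

    # -- helpers ------------------------------------------------------------
    def total_volume(self) -> float:
        return float((self.a * np.repeat(self.dx, self.ncell)).sum())

    def _wave_speed_cells(self, cells, vid):
        a = self.a[cells]
        c2 = a / self.rho * _dpda(
            a, self.w_r0[vid], self.w_h[vid], self.w_ee[vid], self.w_ec[vid],
            self.w_e0[vid], self.w_er[vid], self.w_a0[vid]
        )
        if np.any(c2 <= 0):
            raise FloatingPointError("dP/dA <= 0 encountered")
        return np.sqrt(c2)

    def _vessel_dt(self) -> np.ndarray:
        dts = np.empty(self.nv)
        if len(self.sc):
            cells = self.cell_first[self.sc]
            c = self._wave_speed_cells(cells, self.sc)
            smax = np.abs(self.q[cells] / self.a[cells]) + c
            dts[self.sc] = self.cfg.cfl * self.dx[self.sc] / smax
        for v in self.mc:
            sl = slice(self.offs[v], self.offs[v + 1])
            vid = np.full(self.ncell[v], v)
            c = self._wave_speed_cells(np.arange(self.offs[v], self.offs[v + 1]),
                                       vid)
            smax = float(np.max(np.abs(self.q[sl] / self.a[sl]) + c))
            dts[v] = self.cfg.cfl * self.dx[v] / smax
        return np.minimum(dts, self.cfg.dt_max)

    # -- boundary solves ----------------------------------------------------
    def _solve_junction_group(self, grp, sel):
        """Batched Newton for the junctions ``sel`` of one degree group."""
        n = grp["n"]
        cell = grp["cell"][sel]
        sgn = grp["sgn"][sel]
        wp = tuple(w[sel] for w in grp["wp"])
        r0, h, ee, ec, e0, er, p0, a0 = wp
        a_b = self.a[cell]
        u_b = self.q[cell] / a_b
        c_b = np.sqrt(a_b / self.rho * _dpda(a_b, r0, h, ee, ec, e0, er, a0))
        g = len(a_b)
        av = a_b.copy()
        uv = u_b.copy()
        p_scale = self.rho * np.max(c_b, axis=1) ** 2  # (g,)
        q_scale = np.max(a_b * (np.abs(u_b) + c_b), axis=1)
        tol = self.cfg.newton_tol

        def residual(av, uv):
            p = _p_el(av, r0, h, ee, ec, e0, er, p0, a0)
            r = np.empty((g, 2 * n))
            r[:, 0] = (sgn * av * uv).sum(axis=1) / q_scale
            tot = p + 0.5 * self.rho * uv ** 2
            r[:, 1:n] = (tot[:, 1:] - tot[:, :1]) / p_scale[:, None]
            r[:, n:] = (uv - u_b + sgn * (c_b / a_b) * (av - a_b)) / c_b
            return r

        for it in range(self.cfg.newton_max):
            r = residual(av, uv)
            bad = np.max(np.abs(r), axis=1) >= tol
            if not bad.any():
                break
            jac = np.zeros((g, 2 * n, 2 * n))
            dp = _dpda(av, r0, h, ee, ec, e0, er, a0)
            jac[:, 0, :n] = sgn * uv / q_scale[:, None]
            jac[:, 0, n:] = sgn * av / q_scale[:, None]
            for e in range(1, n):
                jac[:, e, e] = dp[:, e] / p_scale
                jac[:, e, 0] = -dp[:, 0] / p_scale
                jac[:, e, n + e] = self.rho * uv[:, e] / p_scale
                jac[:, e, n] = -self.rho * uv[:, 0] / p_scale
            for e in range(n):
                jac[:, n + e, e] = sgn[:, e] / a_b[:, e]
                jac[:, n + e, n + e] = 1.0 / c_b[:, e]
            try:
                dxv = np.linalg.solve(jac[bad], -r[bad][..., None])[..., 0]
            except np.linalg.LinAlgError as exc:
                raise FloatingPointError(f"junction Jacobian singular: {exc}")
            av[bad] = np.maximum(av[bad] + dxv[:, :n], 1e-12)
            uv[bad] = uv[bad] + dxv[:, n:]
        else:
            raise FloatingPointError(
                "junction Newton did not converge; max residual %.3e"
                % float(np.max(np.abs(r)))
            )
        fm = av * uv
        fmom = av * uv ** 2
        p_if = _p_el(av, r0, h, ee, ec, e0, er, p0, a0)
        return fm, fmom, p_if

    def _solve_inflow(self, t_eval):
        v = self.tree.root
        i = self.cell_first[v]
        a_b = self.a[i]
        u_b = self.q[i] / a_b
        c_b = float(self._wave_speed_cells(np.array([i]), np.array([v]))[0])
        q_in = float(self.inflow(t_eval))
        w = self.walls[v]
        av = a_b
        for _ in range(self.cfg.newton_max):
            uv = u_b + (c_b / a_b) * (av - a_b)
            gres = av * uv - q_in
            if abs(gres) < self.cfg.newton_tol * max(abs(q_in), a_b * c_b):
                break
            av = max(av - gres / (uv + av * c_b / a_b), 1e-12)
        uv = u_b + (c_b / a_b) * (av - a_b)
        return q_in, av * uv ** 2, float(elastic_pressure(av, w))

    def _solve_terminals(self, sel, dtj):
        """Batched terminal Windkessel coupling for the terminals ``sel``."""
        r0, h, ee, ec, e0, er, p0, a0 = tuple(w[sel] for w in self._t_wp)
        cell = self.t_cell[sel]
        a_b = self.a[cell]
        u_b = self.q[cell] / a_b
        c_b = np.sqrt(a_b / self.rho * _dpda(a_b, r0, h, ee, ec, e0, er, a0))
        r1, r2, cc, pt = (self.t_r1[sel], self.t_r2[sel], self.t_c[sel],
                          self.t_pt[sel])
        has_c = cc > 0
        if has_c.any():
            # explicit-Euler capacitor update using the previous outflow
            pi = self.term_pi[sel]
            pi = np.where(
                has_c,
                pi + dtj * (self.term_q_prev[sel]
                            - (pi - pt) / r2) / np.where(has_c, cc, 1.0),
                pi,
            )
            self.term_pi[sel] = pi
        p_ref = np.where(has_c, self.term_pi[sel], pt)
        r_eff = np.where(has_c, r1, r1 + r2)
        av = a_b.copy()
        scale = self.rho * c_b ** 2
        for _ in range(self.cfg.newton_max):
            uv = u_b - (c_b / a_b) * (av - a_b)
            f = _p_el(av, r0, h, ee, ec, e0, er, p0, a0) \
                - (p_ref + r_eff * av * uv)
            bad = np.abs(f) >= self.cfg.newton_tol * scale
            if not bad.any():
                break
            fp = _dpda(av, r0, h, ee, ec, e0, er, a0) \
                - r_eff * (uv - av * c_b / a_b)
            av = np.where(bad, np.maximum(av - f / fp, 1e-12), av)
        uv = u_b - (c_b / a_b) * (av - a_b)
        self.term_q_prev[sel] = av * uv
        p_if = _p_el(av, r0, h, ee, ec, e0, er, p0, a0)
        return av * uv, av * uv ** 2, p_if

    # -- time advance -------------------------------------------------------
    def advance(self, t_target: float):
        """Local-time-stepping advance to exactly ``t_target``."""
        cfg = self.cfg
        while self.t < t_target - 1e-13:
            dt_sync = min(cfg.dt_max, t_target - self.t)
            dts = self._vessel_dt()
            lev = np.ceil(np.log2(np.maximum(dt_sync / dts, 1.0))).astype(int)
            lev = np.minimum(lev, cfg.max_level)
            if cfg.uniform_level:
                lev[:] = lev.max()  # global time stepping at the finest step
            m_max = int(lev.max())
            dt_v = dt_sync / 2.0 ** lev
            if np.any(dt_v < 1e-10):
                raise FloatingPointError("time step underflow (< 1e-10 s)")
            st = self.dt_stats
            st["min"] = min(st["min"], float(dt_v.min()))
            st["max"] = max(st["max"], float(dt_v.max()))
            st["sum"] += float(dt_v.sum())
            st["n"] += self.nv
            nsub = 2 ** m_max
            stride_v = 2 ** (m_max - lev)
            jn_sched = []
            for grp in self._jn:
                m_j = lev[grp["vid"]].max(axis=1)
                jn_sched.append((2 ** (m_max - m_j), dt_sync / 2.0 ** m_j))
            t_stride = stride_v[self.terminals]
            t_dt = dt_v[self.terminals]
            root = self.tree.root
            self.buf[:] = 0.0
            for s in range(nsub):
                for grp, (strd, dtj) in zip(self._jn, jn_sched):
                    sel = np.flatnonzero(s % strd == 0)
                    if not len(sel):
                        continue
                    fm, fmom, p_if = self._solve_junction_group(grp, sel)
                    vid = grp["vid"][sel].ravel()
                    end = grp["end"][sel].ravel()
                    wdt = np.broadcast_to(dtj[sel][:, None], fm.shape).ravel()
                    self.buf[vid, end, 0] += fm.ravel() * wdt
                    self.buf[vid, end, 1] += fmom.ravel() * wdt
                    self.buf[vid, end, 2] += p_if.ravel() * wdt
                    self.buf[vid, end, 3] += fm.ravel() * wdt
                    self.buf[vid, end, 4] += wdt
                if s % stride_v[root] == 0:
                    dtj = float(dt_v[root])
                    fm, fmom, p_if = self._solve_inflow(
                        self.t + s / nsub * dt_sync + 0.5 * dtj
                    )
                    b = self.buf[root, 0]
                    b[:4] += np.array([fm, fmom, p_if, fm]) * dtj
                    b[4] += dtj
                    self.mass_in += fm * dtj
                sel_t = np.flatnonzero(s % t_stride == 0)
                if len(sel_t):
                    dtj = t_dt[sel_t]
                    fm, fmom, p_if = self._solve_terminals(sel_t, dtj)
                    vid = self.terminals[sel_t]
                    self.buf[vid, 1, 0] += fm * dtj
                    self.buf[vid, 1, 1] += fmom * dtj
                    self.buf[vid, 1, 2] += p_if * dtj
                    self.buf[vid, 1, 3] += fm * dtj
                    self.buf[vid, 1, 4] += dtj
                    self.mass_out += float((fm * dtj).sum())
                # vessel steps completing at substep s
                done = (s + 1) % stride_v == 0
                sc_act = self.sc[done[self.sc]]
                if len(sc_act):
                    self._step_single(sc_act, dt_v[sc_act])
                for v in self.mc[done[self.mc]]:
                    self._step_multi(int(v), float(dt_v[v]))
            self.t += dt_sync

    def _ends_from_buf(self, vids):
        out = []
        for end in (0, 1):
            b = self.buf[vids, end]
            tacc = b[..., 4]
            if np.any(tacc <= 0):
                raise FloatingPointError("missing buffered interface data")
            out.append({"fm": b[..., 0] / tacc, "fmom": b[..., 1] / tacc,
                        "p": b[..., 2] / tacc, "q": b[..., 3] / tacc})
            self.buf[vids, end] = 0.0
        return out

    def _step_single(self, vids, dt):
        sel = np.searchsorted(self.sc, vids)
        wp = tuple(w[sel] for w in self._sc_wp)
        cells = self.cell_first[vids]
        end_l, end_r = self._ends_from_buf(vids)
        a_new, q_new = _kernel_single(
            self.a[cells], self.q[cells], self.dx[vids], dt, wp,
            self.mu[vids], self.rho, end_l, end_r,
            self.cfg.include_friction, bool(np.any(wp[8] > 0)),
        )
        if np.any(a_new <= 0) or not np.all(np.isfinite(a_new)):
            bad = int(vids[int(np.argmin(a_new))])
            raise FloatingPointError(
                f"solver blow-up in vessel {bad} at t={self.t:.6f}s"
            )
        self.a[cells] = a_new
        self.q[cells] = q_new

    def _step_multi(self, v, dt):
        sl = slice(self.offs[v], self.offs[v + 1])
        end_l, end_r = self._ends_from_buf(np.array([v]))
        end_l = {k: float(x[0]) for k, x in end_l.items()}
        end_r = {k: float(x[0]) for k, x in end_r.items()}
        args = (self.w_r0[v], self.w_h[v], self.w_ee[v], self.w_ec[v],
                self.w_e0[v], self.w_er[v], self.w_p0[v], self.w_a0[v])
        a_new, q_new = _kernel_multi(
            self.a[sl], self.q[sl], float(self.dx[v]), dt, args,
            float(self.w_km[v]), float(self.mu[v]), self.rho, end_l, end_r,
            self.cfg.include_friction, self.w_km[v] > 0,
        )
        if np.any(a_new <= 0) or not np.all(np.isfinite(a_new)):
            raise FloatingPointError(
                f"solver blow-up in vessel {v} at t={self.t:.6f}s"
            )
        self.a[sl] = a_new
        self.q[sl] = q_new

    # -- probing ------------------------------------------------------------
    def probe(self):
        """Per-vessel elastic pressure/flow/area at distal and proximal cells."""
        args = (self.w_r0, self.w_h, self.w_ee, self.w_ec, self.w_e0,
                self.w_er, self.w_p0, self.w_a0)
        p = _p_el(self.a[self.cell_last], *args)
        p0 = _p_el(self.a[self.cell_first], *args)
        return (p, self.q[self.cell_last].copy(), self.a[self.cell_last].copy(),
                p0, self.q[self.cell_first].copy())


@dataclass
class SimulationResult:
    t: np.ndarray  # sample times, all cycles
    p: np.ndarray  # (n_samples, n_vessels) distal elastic pressure, dyn/cm^2
    q: np.ndarray  # (n_samples, n_vessels) distal flow, cm^3/s
    a: np.ndarray  # (n_samples, n_vessels) distal area, cm^2
    p_prox: np.ndarray  # (n_samples, n_vessels) proximal-cell pressure
    q_prox: np.ndarray  # (n_samples, n_vessels) proximal-cell flow
    period: float
    n_cycles: int
    samples_per_cycle: int
    dt_stats: dict
    periodicity_residual: float

    def last_cycle(self):
        """(t, P, Q) of the final cycle, t relative to the cycle start."""
        spc = self.samples_per_cycle
        sl = slice(len(self.t) - spc, len(self.t))
        return (self.t[sl] - self.t[sl][0], self.p[sl], self.q[sl])


def run_simulation(tree: VascularTree, walls, terminal_bcs, inflow: InflowBC,
                   config: SolverConfig = SolverConfig()) -> SimulationResult:
    """Simulate ``config.n_cycles`` cardiac cycles and sample every vessel.

    Returns waveforms at every vessel's distal end; the cycle-to-cycle
    periodicity residual is the maximum relative change of the pressure
    field between the last two cycles.
    """
    sim = Simulator(tree, walls, terminal_bcs, inflow, config)
    spc = config.samples_per_cycle
    n_samp = config.n_cycles * spc
    t_samples = np.arange(1, n_samp + 1) * (inflow.period / spc)
    p = np.empty((n_samp, sim.nv))
    q = np.empty((n_samp, sim.nv))
    a = np.empty((n_samp, sim.nv))
    pp = np.empty((n_samp, sim.nv))
    qp = np.empty((n_samp, sim.nv))
    for i, ts in enumerate(t_samples):
        sim.advance(ts)
        p[i], q[i], a[i], pp[i], qp[i] = sim.probe()
    if config.n_cycles >= 2:
        last = p[-spc:]
        prev = p[-2 * spc: -spc]
        residual = float(np.max(np.abs(last - prev))
                         / max(np.max(np.abs(last)), 1e-300))
    else:
        residual = float("nan")
    st = sim.dt_stats
    return SimulationResult(
        t=t_samples, p=p, q=q, a=a, p_prox=pp, q_prox=qp,
        period=inflow.period, n_cycles=config.n_cycles,
        samples_per_cycle=spc,
        dt_stats={"min": st["min"], "max": st["max"],
                  "avg": st["sum"] / max(st["n"], 1)},
        periodicity_residual=residual,
    )
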