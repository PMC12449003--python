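"""Deterministic synthetic inputs and analytic oracles.

Everything needed to exercise the generator and the 1D solver without any
external data: folded cortical patches, seed feeder stubs, toy networks
(single vessel, series, bifurcation, symmetric trees, small CCO patches),
smooth periodic inflow waveforms standing in for the upstream arterial
circulation, and closed-form reference values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .ccogen import (
    GeoConstraints,
    OptParams,
    CostSpec,
    StageConfig,
    VascularTree,
    ViscosityLaw,
    grow_stage,
    poiseuille_solve,
)
from .flow1d import (
    HemoParams,
    InflowBC,
    WindkesselBC,
    build_walls,
    calibrate_windkessels,
)
from .geometry import build_shell, make_synthetic_cortex_patch
from ._meshq import TriangleQuery

__all__ = [
    "ToyNetworkSpec",
    "ToyCase",
    "make_toy_network",
    "make_inflow_waveform",
    "analytic_oracles",
    "standard_patch_shell",
    "standard_patch_tree",
    "seed_feeder_tree",
    "PATCH_EXTENT",
    "TERMINAL_FLOW_ML_MIN",
]

# The standard demo patch: a 4 x 4 cm folded cortical square.  The full-scale
# design density is 1.2 terminals/mm^2; the demo uses a reduced density so the
# default networks stay at a few hundred vessels.  The flow per terminal is
# kept at its physiological value (inlet flow / terminal count of the MCA
# territory, ~1.85e-3 ml/min per penetrating arteriole), so that desk-scale
# vessels see realistic per-vessel flows and radii.
PATCH_EXTENT = 4.0  # cm
PATCH_WAVELENGTH = 2.0  # cm
PATCH_AMPLITUDE = 0.25  # cm
TERMINAL_FLOW_ML_MIN = 125.0 / 51595.0  # MCA inlet flow / MCA S3 terminals
XI_INLET = 1847.0  # Murray constant of the equalization reference territory


def standard_patch_shell(seed: int = 3, thickness: float = 0.2,
                         outward_fraction: float = 0.75):
    patch = make_synthetic_cortex_patch(
        PATCH_EXTENT, PATCH_WAVELENGTH, PATCH_AMPLITUDE, seed=seed
    )
    return build_shell(patch, thickness, outward_fraction)


def seed_feeder_tree(shell, n_terminals_target: int,
                     viscosity: ViscosityLaw | None = None,
                     gamma: float = 3.0) -> VascularTree:
    """Single feeder stub on the median surface of the patch shell.

    The inlet flow scales with the targeted terminal count at fixed
    per-terminal flow; the inlet radius follows Murray's law,
    ``r = (Q/xi)**(1/3)``, with the reference Murray constant.
    """
    q_inlet = n_terminals_target * TERMINAL_FLOW_ML_MIN
    r_root = (units.mlmin_to_cgs(q_inlet) / XI_INLET) ** (1.0 / 3.0)
    tree = VascularTree(
        q_inlet_ml_min=q_inlet, root_radius=r_root, gamma=gamma,
        viscosity=viscosity or ViscosityLaw.pries(),
    )
    med = np.asarray(shell.base.vertices) + (
        0.5 * (shell.t_out - shell.t_in)
    ) * shell.normals
    tq = TriangleQuery(med, shell.base.faces)
    c = np.asarray(shell.base.vertices).mean(axis=0)
    p0, _, _ = tq.closest(np.array([c + [-0.2, 0.0, 0.0]]))
    p1, _, _ = tq.closest(np.array([c + [0.2, 0.0, 0.0]]))
    tree.add_root(p0[0], p1[0])
    return tree


def standard_patch_tree(n_terminals: int = 30, seed: int = 7,
                        shell=None, min_length: float = 0.1,
                        viscosity: ViscosityLaw | None = None) -> VascularTree:
    """Volumetric-cost CCO tree on the standard patch (seeded, deterministic)."""
    shell = shell or standard_patch_shell()
    tree = seed_feeder_tree(shell, n_terminals, viscosity=viscosity)
    stage = StageConfig(
        label=1,
        q_inlet_ml_min=units.cgs_to_mlmin(tree.q_inlet),
        n_term_target=n_terminals,
        geo=GeoConstraints(gamma=3.0, delta=0.0, theta_min_deg=20.0),
        opt=OptParams(min_length=min_length),
        cost=CostSpec(kind="volumetric"),
        seed=seed,
    )
    return grow_stage(tree, stage, shell)


def make_inflow_waveform(mean_flow_ml_min: float, pulsatility: float,
                         period: float = 1.0) -> InflowBC:
    """Smooth two-harmonic periodic inflow with exact mean and pulsatility.

    The emitted waveform has period-mean equal to ``mean_flow_ml_min`` and
    ``(Q_s - Q_d)/Q_m`` equal to ``pulsatility`` (both to the resolution of
    the dense grid used to locate the extrema of the base shape).
    """
    if mean_flow_ml_min <= 0 or period <= 0:
        raise ValueError("mean flow and period must be positive")
    if pulsatility < 0:
        raise ValueError("pulsatility must be non-negative")
    qm = units.mlmin_to_cgs(mean_flow_ml_min)

    def shape(t):
        x = 2 * np.pi * t / period
        return np.sin(x) + 0.3 * np.sin(2 * x + 0.6)

    tt = np.linspace(0.0, period, 1 << 16, endpoint=False)
    w = shape(tt)
    span = float(w.max() - w.min())
    beta = pulsatility / span if pulsatility > 0 else 0.0
    if 1.0 + beta * float(w.min()) <= 0:
        raise ValueError("requested pulsatility implies negative flow")

    def q_func(t):
        return qm * (1.0 + beta * shape(np.asarray(t, dtype=float)))

    return InflowBC(q_func=q_func, period=period, q_mean=qm)


@dataclass(frozen=True)
class ToyNetworkSpec:
    kind: str = "single"  # single | series | bifurcation | symmetric_tree | cco_patch
    depth: int = 3  # symmetric_tree
    n_segments: int = 3  # series
    n_terminals: int = 30  # cco_patch
    seed: int = 7
    radius: float = 0.02  # cm, root radius of hand-built networks
    length: float = 1.0  # cm, segment length of hand-built networks
    q_mean_ml_min: float | None = None
    pulsatility: float = 0.9
    period: float = 1.0
    params: HemoParams = field(default_factory=HemoParams)
    p_root_mean_mmhg: float = 90.0
    p_t_mmhg: float = 30.0


@dataclass
class ToyCase:
    """A fully parameterized, simulatable network."""

    tree: VascularTree
    walls: list
    terminal_bcs: dict
    inflow: InflowBC
    params: HemoParams


def _hand_tree(spec: ToyNetworkSpec) -> VascularTree:
    n_term = {"single": 1, "series": 1, "bifurcation": 2,
              "symmetric_tree": 2 ** spec.depth}[spec.kind]
    q = spec.q_mean_ml_min
    if q is None:
        q = n_term * TERMINAL_FLOW_ML_MIN * 50  # keep hand nets at easy flows
    tree = VascularTree(q_inlet_ml_min=q, root_radius=spec.radius,
                        viscosity=spec.params.viscosity)
    ell = spec.length
    if spec.kind == "single":
        tree.add_root([0, 0, 0], [ell, 0, 0])
    elif spec.kind == "series":
        tree.add_root([0, 0, 0], [ell, 0, 0])
        prev = tree.root
        for i in range(1, spec.n_segments):
            prev = tree.add_child(prev, [(i + 1) * ell, 0, 0])
    elif spec.kind == "bifurcation":
        tree.add_root([0, 0, 0], [ell, 0, 0])
        tree.add_child(tree.root, [2 * ell, 0.5 * ell, 0])
        tree.add_child(tree.root, [2 * ell, -0.5 * ell, 0])
    else:  # symmetric binary tree
        tree.add_root([0, 0, 0], [ell, 0, 0])
        frontier = [(tree.root, np.array([ell, 0.0, 0.0]), 2.0)]
        for level in range(spec.depth):
            nxt = []
            for parent, tip, spread in frontier:
                for sgn in (+1.0, -1.0):
                    new_tip = tip + np.array([ell, sgn * ell / spread, 0.0])
                    cid = tree.add_child(parent, new_tip)
                    nxt.append((cid, new_tip, spread * 2.0))
            frontier = nxt
    return tree


def make_toy_network(spec: ToyNetworkSpec) -> ToyCase:
    """Build a simulatable toy network with walls, Windkessels and inflow."""
    if spec.kind == "cco_patch":
        tree = standard_patch_tree(
            n_terminals=spec.n_terminals, seed=spec.seed,
            viscosity=spec.params.viscosity,
        )
    elif spec.kind in ("single", "series", "bifurcation", "symmetric_tree"):
        tree = _hand_tree(spec)
    else:
        raise ValueError(f"unknown toy network kind {spec.kind!r}")
    poiseuille_solve(tree)
    walls = build_walls(tree, spec.params)
    bcs = calibrate_windkessels(
        tree, spec.params, p_root_mean_mmhg=spec.p_root_mean_mmhg,
        p_t_mmhg=spec.p_t_mmhg,
    )
    inflow = make_inflow_waveform(
        units.cgs_to_mlmin(tree.q_inlet), spec.pulsatility, spec.period
    )
    return ToyCase(tree=tree, walls=walls, terminal_bcs=bcs, inflow=inflow,
                   params=spec.params)


def analytic_oracles() -> dict:
    """Closed-form reference relations used across the test-suite."""

    def poiseuille_dp(mu, length, q, r):
        return 8.0 * mu * length * q / (np.pi * r ** 4)

    def windkessel_steady(r1, r2, p_t, q):
        return p_t + (r1 + r2) * q

    def rc_decay(p0, p_t, r2, c, t):
        return p_t + (p0 - p_t) * np.exp(-t / (r2 * c))

    def murray_xi_ref(q_ml_min, r_um):
        return (q_ml_min / 60.0) / (r_um * 1e-4) ** 3

    def sphere_shell_volume(r_in, r_out):
        return 4.0 * np.pi / 3.0 * (r_out ** 3 - r_in ** 3)

    return {
        "poiseuille_dp": poiseuille_dp,
        "windkessel_steady": windkessel_steady,
        "rc_decay": rc_decay,
        "murray_xi": murray_xi_ref,
        "sphere_shell_volume": sphere_shell_volume,
    }
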