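"""Constrained constructive optimization (CCO) growth of arterial trees.

A tree is grown inside a shell domain by repeatedly sampling a candidate
terminal location, connecting it to a nearby segment through a new
bifurcation whose position is optimized over a discretized triangle, and
committing the connection of least cost that satisfies the geometric
constraints (branching angles, radius symmetry, and — for distribution
vessels — full containment in the domain).

Hemodynamics during generation are steady Poiseuille flow with uniform
terminal outflow: every terminal discharges ``Q_inlet / N_T``.  Radii follow
the bifurcation power law ``r_p^gamma = sum r_c^gamma`` anchored at the
inlet radius, which is the Murray relation ``Q = xi * r^gamma`` with ``xi``
fixed by the inlet pair ``(Q_inlet, r_inlet)``; with ``gamma = 3`` this is
the classical uniform-wall-shear rule.  Blood rheology enters through a
radius-dependent viscosity (Pries et al. in-vitro fit) when computing
segment resistances and hence the pressure field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from . import units
from ._meshq import point_segment_distance

__all__ = [
    "ViscosityLaw",
    "viscosity_of_radius",
    "VascularTree",
    "poiseuille_solve",
    "murray_xi",
    "GeoConstraints",
    "OptParams",
    "CostSpec",
    "StageConfig",
    "cost_of",
    "add_terminal",
    "grow_stage",
    "decompose_and_grow",
    "check_tree",
    "partition_subdomains",
]


# ---------------------------------------------------------------------------
# blood rheology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViscosityLaw:
    """Blood viscosity as a function of vessel radius.

    ``newtonian`` is a constant; ``pries`` is the in-vitro relative-viscosity
    fit of Pries et al. at the given discharge hematocrit, multiplied by the
    plasma viscosity.  The plasma viscosity default (0.01 P) makes the
    large-diameter limit equal the Newtonian value 0.032 P.
    """

    kind: str = "newtonian"  # "newtonian" | "pries"
    mu_newton: float = 0.032  # poise
    hematocrit: float = 0.45
    mu_plasma: float = 0.01  # poise

    @classmethod
    def newtonian(cls, mu: float = 0.032) -> "ViscosityLaw":
        return cls(kind="newtonian", mu_newton=mu)

    @classmethod
    def pries(cls, hematocrit: float = 0.45,
              mu_plasma: float = 0.01) -> "ViscosityLaw":
        return cls(kind="pries", hematocrit=hematocrit, mu_plasma=mu_plasma)

    def __call__(self, r_cm):
        r = np.asarray(r_cm, dtype=float)
        if np.any(r <= 0):
            raise ValueError("radius must be positive")
        if self.kind == "newtonian":
            return np.broadcast_to(np.float64(self.mu_newton), r.shape).copy() \
                if r.shape else float(self.mu_newton)
        d_um = 2.0 * r * 1.0e4
        mu45 = 220.0 * np.exp(-1.3 * d_um) + 3.2 - 2.44 * np.exp(
            -0.06 * d_um ** 0.645
        )
        shape = 1.0 / (1.0 + 1.0e-11 * d_um ** 12)
        c = (0.8 + np.exp(-0.075 * d_um)) * (-1.0 + shape) + shape
        h = self.hematocrit
        rel = 1.0 + (mu45 - 1.0) * (((1.0 - h) ** c - 1.0)
                                    / ((1.0 - 0.45) ** c - 1.0))
        out = rel * self.mu_plasma
        return out if out.shape else float(out)


def viscosity_of_radius(law: ViscosityLaw, r_cm) -> float:
    """Dynamic blood viscosity (poise) at vessel radius ``r_cm``."""
    return law(r_cm)


def murray_xi(q_ml_min: float, r_um: float) -> float:
    """Murray proportionality constant ``xi = Q / r^3`` in 1/s.

    ``Q`` is given in ml/min and ``r`` in micrometres; both are converted to
    CGS before forming the ratio.
    """
    if q_ml_min <= 0 or r_um <= 0:
        raise ValueError("flow and radius must be positive")
    q = units.mlmin_to_cgs(q_ml_min)
    r = units.um_to_cm(r_um)
    return q / r ** 3


# ---------------------------------------------------------------------------
# tree container
# ---------------------------------------------------------------------------

class VascularTree:
    """Rooted binary-branching network of straight vessel segments.

    Segment ids are stable row indices; splitting a segment keeps the
    proximal fragment under the original id and appends new rows for the
    distal fragment and the new terminal.
    """

    TYPE_DISTRIBUTION = 0
    TYPE_TERMINAL = 1

    def __init__(self, q_inlet_ml_min: float, root_radius: float,
                 gamma: float = 3.0, inlet_pressure_mmhg: float = 80.0,
                 viscosity: ViscosityLaw | None = None):
        self.q_inlet = units.mlmin_to_cgs(q_inlet_ml_min)
        self.root_radius = float(root_radius)
        self.gamma = float(gamma)
        self.inlet_pressure = units.mmhg_to_cgs(inlet_pressure_mmhg)
        self.viscosity = viscosity or ViscosityLaw.newtonian()
        cap = 16
        self._prox = np.zeros((cap, 3))
        self._dist = np.zeros((cap, 3))
        self._parent = np.full(cap, -1, dtype=np.int64)
        self._child = np.full((cap, 2), -1, dtype=np.int64)
        self._stage = np.zeros(cap, dtype=np.int64)
        self._vtype = np.zeros(cap, dtype=np.int64)
        self._radius = np.zeros(cap)
        self._flow = np.zeros(cap)
        self._p_dist = np.zeros(cap)
        self._n_term = np.zeros(cap, dtype=np.int64)
        self.n = 0
        self.root = -1
        self.solved = False
        self.journal: list = []

    # -- array views --------------------------------------------------------
    @property
    def proximal(self):
        return self._prox[: self.n]

    @property
    def distal(self):
        return self._dist[: self.n]

    @property
    def parent(self):
        return self._parent[: self.n]

    @property
    def children(self):
        return self._child[: self.n]

    @property
    def stage(self):
        return self._stage[: self.n]

    @property
    def vtype(self):
        return self._vtype[: self.n]

    @property
    def radius(self):
        return self._radius[: self.n]

    @property
    def flow(self):
        return self._flow[: self.n]

    @property
    def pressure_distal(self):
        return self._p_dist[: self.n]

    @property
    def n_term_per_segment(self):
        return self._n_term[: self.n]

    @property
    def lengths(self):
        return np.linalg.norm(self.distal - self.proximal, axis=1)

    @property
    def n_segments(self):
        return self.n

    def terminal_ids(self):
        return np.flatnonzero(self.children[:, 0] < 0)

    @property
    def n_terminals(self):
        return int((self.children[:, 0] < 0).sum())

    # -- construction -------------------------------------------------------
    def _grow_arrays(self):
        cap = len(self._parent)
        if self.n < cap:
            return
        new = 2 * cap
        for name in ("_prox", "_dist", "_child"):
            arr = getattr(self, name)
            pad = np.full((new - cap,) + arr.shape[1:],
                          -1 if arr.dtype.kind == "i" else 0.0, dtype=arr.dtype)
            setattr(self, name, np.vstack([arr, pad]))
        for name in ("_parent", "_stage", "_vtype", "_n_term"):
            arr = getattr(self, name)
            pad = np.full(new - cap, -1 if name == "_parent" else 0,
                          dtype=arr.dtype)
            setattr(self, name, np.concatenate([arr, pad]))
        for name in ("_radius", "_flow", "_p_dist"):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate([arr, np.zeros(new - cap)]))

    def _append(self, prox, dist, parent, stage, vtype) -> int:
        self._grow_arrays()
        i = self.n
        self._prox[i] = prox
        self._dist[i] = dist
        self._parent[i] = parent
        self._child[i] = -1
        self._stage[i] = stage
        self._vtype[i] = vtype
        self.n += 1
        return i

    def add_root(self, prox, dist, stage: int = 0,
                 vtype: int = 0) -> int:
        if self.root >= 0:
            raise ValueError("tree already has a root")
        self.root = self._append(prox, dist, -1, stage, vtype)
        self.solved = False
        return self.root

    def add_child(self, parent: int, dist_point, stage: int = 0,
                  vtype: int = 0) -> int:
        slots = self._child[parent]
        if slots[1] >= 0:
            raise ValueError(f"segment {parent} already has two children")
        i = self._append(self._dist[parent], dist_point, parent, stage, vtype)
        if slots[0] < 0:
            self._child[parent, 0] = i
        else:
            self._child[parent, 1] = i
        self.solved = False
        return i

    def split_insert(self, seg: int, bifurcation_point, terminal_point,
                     stage: int = 0, vtype: int = 0) -> tuple[int, int]:
        """Split ``seg`` at ``bifurcation_point`` and sprout a new terminal.

        Returns ``(distal_fragment_id, terminal_id)``.  The proximal
        fragment keeps id ``seg``; the distal fragment inherits the split
        segment's children, stage and type.
        """
        xb = np.asarray(bifurcation_point, dtype=float)
        tp = np.asarray(terminal_point, dtype=float)
        old_dist = self._dist[seg].copy()
        old_children = self._child[seg].copy()
        nd = self._append(xb, old_dist, seg, self._stage[seg], self._vtype[seg])
        nt = self._append(xb, tp, seg, stage, vtype)
        self._dist[seg] = xb
        self._child[seg] = (nd, nt)
        self._child[nd] = old_children
        for c in old_children:
            if c >= 0:
                self._parent[c] = nd
        self.solved = False
        return nd, nt

    def set_coordinates(self, proximal, distal):
        self._prox[: self.n] = proximal
        self._dist[: self.n] = distal
        self.solved = False

    def copy(self) -> "VascularTree":
        out = VascularTree.__new__(VascularTree)
        out.__dict__.update(
            {
                k: (v.copy() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()
                if k != "journal"
            }
        )
        out.journal = list(self.journal)
        return out

    # -- traversal ----------------------------------------------------------
    def topological_order(self) -> np.ndarray:
        """Segment ids ordered root-first (parents before children)."""
        order = np.empty(self.n, dtype=np.int64)
        stack = [self.root]
        k = 0
        while stack:
            i = stack.pop()
            order[k] = i
            k += 1
            for c in self._child[i]:
                if c >= 0:
                    stack.append(c)
        if k != self.n:
            raise ValueError("tree is disconnected")
        return order

    def path_to_root(self, seg: int) -> list[int]:
        path = []
        while seg >= 0:
            path.append(seg)
            seg = int(self._parent[seg])
        return path

    def total_volume(self) -> float:
        return float(np.sum(np.pi * self.radius ** 2 * self.lengths))


def poiseuille_solve(tree: VascularTree) -> VascularTree:
    """Steady Poiseuille solve with uniform terminal outflow.

    Terminal counts propagate bottom-up, giving exact flow conservation;
    radii follow the power law anchored at the inlet radius; pressures
    accumulate ``R * Q`` drops from the root, with
    ``R = 8 mu(r) L / (pi r^4)``.
    """
    if tree.root < 0 or tree.n == 0:
        raise ValueError("tree has no root")
    order = tree.topological_order()
    n_term = tree._n_term
    child = tree._child
    for i in order[::-1]:
        c0, c1 = child[i]
        if c0 < 0:
            n_term[i] = 1
        else:
            n_term[i] = n_term[c0] + (n_term[c1] if c1 >= 0 else 0)
    nt_total = int(n_term[tree.root])
    n = tree.n
    frac = n_term[:n] / nt_total
    tree._flow[:n] = tree.q_inlet * frac
    tree._radius[:n] = tree.root_radius * frac ** (1.0 / tree.gamma)
    lengths = tree.lengths
    if np.any(lengths <= 0):
        raise ValueError("zero-length segment encountered")
    mu = tree.viscosity(tree._radius[:n])
    resist = 8.0 * mu * lengths / (np.pi * tree._radius[:n] ** 4)
    drop = resist * tree._flow[:n]
    p = tree._p_dist
    parent = tree._parent
    for i in order:
        upstream = tree.inlet_pressure if parent[i] < 0 else p[parent[i]]
        p[i] = upstream - drop[i]
    tree.solved = True
    return tree


# ---------------------------------------------------------------------------
# stage configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeoConstraints:
    gamma: float = 3.0
    delta: float = 0.0  # minimum child-radius symmetry ratio
    theta_min_deg: float = 20.0  # minimum angle between the two children
    phi_min_deg: float = 0.0  # minimum out-of-plane opening angle

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0 <= self.delta < 1:
            raise ValueError("delta must be in [0, 1)")
        if not (0 <= self.theta_min_deg < 180 and 0 <= self.phi_min_deg < 180):
            raise ValueError("angles must be in [0, 180) degrees")


@dataclass(frozen=True)
class OptParams:
    nu: float = 0.01  # perfusion-area factor for the distance criterion
    f_r: float = 0.9  # relaxation of the distance criterion
    f_n: int = 100  # number of nearest segments tested
    dv: int = 7  # points per triangle edge in the connection search
    max_failures: int = 2000  # consecutive rejections before relaxing
    min_length: float = 0.01  # cm, shortest admissible new segment

    def __post_init__(self):
        if not 0 < self.f_r <= 1:
            raise ValueError("f_r must be in (0, 1]")
        if self.f_n < 1 or self.dv < 2:
            raise ValueError("f_n >= 1 and dv >= 2 required")


@dataclass(frozen=True)
class CostSpec:
    kind: str = "volumetric"  # "volumetric" | "sprouting"
    c_v: float = 1.0e4
    c_p: float = 0.5
    c_d: float = 1.0

    def __post_init__(self):
        if self.kind not in ("volumetric", "sprouting"):
            raise ValueError(f"unknown cost kind {self.kind!r}")
        if min(self.c_v, self.c_p, self.c_d) < 0:
            raise ValueError("cost coefficients must be non-negative")


@dataclass(frozen=True)
class StageConfig:
    label: int
    q_inlet_ml_min: float
    n_term_target: int
    geo: GeoConstraints = field(default_factory=GeoConstraints)
    opt: OptParams = field(default_factory=OptParams)
    cost: CostSpec = field(default_factory=CostSpec)
    vessel_type: str = "distribution"
    seed: int = 0


# ---------------------------------------------------------------------------
# connection search
# ---------------------------------------------------------------------------

def _triangle_grid(p0, p1, p2, dv):
    """Barycentric lattice with ``dv`` points per edge, vertices excluded."""
    pts = []
    m = dv - 1
    for i in range(dv):
        for j in range(dv - i):
            k = m - i - j
            if (i == m) or (j == m) or (k == m):
                continue  # triangle vertices are degenerate bifurcations
            pts.append((i / m, j / m, k / m))
    w = np.asarray(pts)
    return w[:, 0:1] * p0 + w[:, 1:2] * p1 + w[:, 2:3] * p2


def _tentative_volume(tree, seg, grid, n_term_root_path, nt_new):
    """Total tree volume after tentatively inserting at each grid point."""
    gamma = tree.gamma
    rr = tree.root_radius
    n = tree.n_term_per_segment.astype(float)
    n_after = n + n_term_root_path  # +1 along the root path of `seg`
    r2 = rr ** 2 * (n_after / nt_new) ** (2.0 / gamma)
    lengths = tree.lengths
    keep = np.ones(tree.n, dtype=bool)
    keep[seg] = False
    const = float(np.sum(np.pi * r2[keep] * lengths[keep]))
    p_j = tree.proximal[seg]
    d_j = tree.distal[seg]
    n_j = tree.n_term_per_segment[seg]
    l1 = np.linalg.norm(grid - p_j, axis=1)
    l2 = np.linalg.norm(d_j - grid, axis=1)
    r2_prox = rr ** 2 * ((n_j + 1) / nt_new) ** (2.0 / gamma)
    r2_dist = rr ** 2 * (n_j / nt_new) ** (2.0 / gamma)
    r2_term = rr ** 2 * (1.0 / nt_new) ** (2.0 / gamma)
    return const, l1, l2, r2_prox, r2_dist, r2_term

def _candidate_costs(tree, seg, grid, candidate, spec):
    """Cost of connecting ``candidate`` through each grid bifurcation point."""
    nt_new = tree.n_terminals + 1
    path = tree.path_to_root(seg)
    on_path = np.zeros(tree.n, dtype=np.int64)
    on_path[path] = 1
    const, l1, l2, r2_prox, r2_dist, r2_term = _tentative_volume(
        tree, seg, grid, on_path, nt_new
    )
    l3 = np.linalg.norm(candidate - grid, axis=1)
    vol = const + np.pi * (r2_prox * l1 + r2_dist * l2 + r2_term * l3)
    if spec.kind == "volumetric":
        cost = vol
    else:
        d_root = np.linalg.norm(grid - tree.proximal[tree.root], axis=1)
        cost = spec.c_v * vol + spec.c_p * d_root + spec.c_d * l3
    return cost, l1, l2, l3


def cost_of(tree: VascularTree, spec: CostSpec, candidate_connection) -> float:
    """Cost of one candidate connection ``(segment_id, bifurcation, terminal)``."""
    seg, xb, term = candidate_connection
    grid = np.atleast_2d(np.asarray(xb, dtype=float))
    cost, _, _, _ = _candidate_costs(tree, int(seg),
                                     grid, np.asarray(term, dtype=float), spec)
    return float(cost[0])


def _geometry_feasible(tree, seg, grid, candidate, geo, min_length,
                       l1, l2, l3):
    ok = (l1 >= min_length) & (l2 >= min_length) & (l3 >= min_length)
    d_j = tree.distal[seg]
    u1 = d_j - grid
    u2 = candidate - grid
    n1 = np.linalg.norm(u1, axis=1)
    n2 = np.linalg.norm(u2, axis=1)
    denom = np.where((n1 > 0) & (n2 > 0), n1 * n2, 1.0)
    cosang = np.einsum("ij,ij->i", u1, u2) / denom
    ok &= np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= geo.theta_min_deg
    if geo.delta > 0:
        n_j = tree.n_term_per_segment[seg]
        hi = max(n_j, 1)
        ratio = (min(n_j, 1) / hi) ** (1.0 / geo.gamma)
        if ratio < geo.delta:
            ok &= False
    if geo.phi_min_deg > 0:
        up = grid - tree.proximal[seg]
        nrm = np.cross(u1, up)
        nn = np.linalg.norm(nrm, axis=1)
        planar = nn < 1e-12
        sin_phi = np.abs(np.einsum("ij,ij->i", u2,
                                   nrm / np.where(planar, 1.0, nn)[:, None]))
        sin_phi = sin_phi / np.where(n2 > 0, n2, 1.0)
        ok &= planar | (np.degrees(np.arcsin(np.clip(sin_phi, 0, 1)))
                        >= geo.phi_min_deg)
    return ok


def add_terminal(tree: VascularTree, stage: StageConfig, domain,
                 rng: np.random.Generator, state: dict | None = None,
                 sample_faces=None, containment_domain=None):
    """Add one terminal (and its bifurcation) to the tree.

    Candidate locations are sampled uniformly in the domain subject to the
    perfusion-area distance criterion ``nu * sqrt(area / N_T)``; after
    ``max_failures`` consecutive rejections the criterion is relaxed by the
    factor ``f_r`` (per-stage counter, reset on success).  For each of the
    ``f_n`` nearest segments the bifurcation point is optimized over a
    triangle lattice with ``dv`` points per edge; the cheapest connection
    that satisfies the branching-angle, symmetry and containment constraints
    is committed and the tree re-solved.

    ``containment_domain`` (default: ``domain``) is the domain against which
    the distribution-vessel containment constraint is checked; during
    sub-domain growth candidates are sampled in the sub-domain while the
    vessels themselves only need to stay inside the full shell, so that
    connections near sub-domain interfaces remain admissible.
    """
    if state is None:
        state = {"relax": 1.0, "failures": 0}
    if containment_domain is None:
        containment_domain = domain
    opt, geo, spec = stage.opt, stage.geo, stage.cost
    if not tree.solved:
        poiseuille_solve(tree)
    vtype = (VascularTree.TYPE_DISTRIBUTION
             if stage.vessel_type == "distribution"
             else VascularTree.TYPE_TERMINAL)
    max_attempts = 10 * opt.max_failures
    for _ in range(max_attempts):
        p = domain.sample(1, rng, faces=sample_faces)[0]
        dists = point_segment_distance(p[None], tree.proximal, tree.distal)[0]
        d_thr = opt.nu * np.sqrt(domain.area / max(tree.n_terminals, 1))
        if dists.min() < d_thr * state["relax"]:
            _register_failure(state, opt)
            continue
        nearest = np.argsort(dists, kind="stable")[: opt.f_n]
        seg_all, grid_all, cost_all, ok_all, gidx_all = [], [], [], [], []
        for seg in nearest:
            seg = int(seg)
            grid = _triangle_grid(tree.proximal[seg], tree.distal[seg], p,
                                  opt.dv)
            cost, l1, l2, l3 = _candidate_costs(tree, seg, grid, p, spec)
            ok = _geometry_feasible(tree, seg, grid, p, geo, opt.min_length,
                                    l1, l2, l3)
            m = len(grid)
            seg_all.append(np.full(m, seg))
            grid_all.append(grid)
            cost_all.append(cost)
            ok_all.append(ok)
            gidx_all.append(np.arange(m))
        seg_arr = np.concatenate(seg_all)
        grid_arr = np.vstack(grid_all)
        cost_arr = np.concatenate(cost_all)
        ok_arr = np.concatenate(ok_all)
        gidx_arr = np.concatenate(gidx_all)
        order = np.lexsort((gidx_arr, seg_arr, cost_arr))
        order = order[ok_arr[order]]
        # containment screening in cost order, batched; a candidate location
        # whose cheapest connections all leave the domain is abandoned
        max_checked = 256
        order = order[:max_checked]
        chosen = -1
        if vtype == VascularTree.TYPE_DISTRIBUTION:
            ts = np.linspace(0.0, 1.0, opt.dv)[:, None]
            for lo in range(0, len(order), 64):
                chunk = order[lo: lo + 64]
                segs = seg_arr[chunk]
                xbs = grid_arr[chunk]
                frag = np.concatenate([
                    tree.proximal[segs][:, None, :] * (1 - ts) + xbs[:, None, :] * ts,
                    xbs[:, None, :] * (1 - ts) + tree.distal[segs][:, None, :] * ts,
                ], axis=1)
                term = xbs[:, None, :] * (1 - ts) + p[None, None, :] * ts
                pts = np.concatenate([frag, term], axis=1)
                feas = containment_domain.contains(
                    pts.reshape(-1, 3)).reshape(len(chunk), -1).all(axis=1)
                if feas.any():
                    chosen = int(chunk[int(np.argmax(feas))])
                    break
        elif len(order):
            chosen = int(order[0])
        if chosen >= 0:
            seg = int(seg_arr[chosen])
            xb = grid_arr[chosen]
            rec_prox = tree.proximal[seg].copy()
            rec_dist = tree.distal[seg].copy()
            nd, nt = tree.split_insert(seg, xb, p, stage.label, vtype)
            tree.journal.append(
                (seg, rec_prox, rec_dist, xb.copy(), p.copy(), stage.label,
                 vtype, nd, nt)
            )
            poiseuille_solve(tree)
            state["failures"] = 0
            return nd, nt
        _register_failure(state, opt)
    raise RuntimeError(
        "stage aborted: no feasible connection found after "
        f"{max_attempts} candidate attempts (relaxation {state['relax']:.3g})"
    )


def _register_failure(state, opt):
    state["failures"] += 1
    if state["failures"] >= opt.max_failures:
        state["relax"] *= opt.f_r
        state["failures"] = 0


def grow_stage(tree: VascularTree, stage: StageConfig, domain,
               sample_faces=None, containment_domain=None) -> VascularTree:
    """Grow the tree until it has ``stage.n_term_target`` terminals."""
    if stage.n_term_target <= tree.n_terminals:
        raise ValueError("stage target must exceed the current terminal count")
    tree.gamma = stage.geo.gamma
    tree.q_inlet = units.mlmin_to_cgs(stage.q_inlet_ml_min)
    rng = np.random.default_rng(stage.seed)
    poiseuille_solve(tree)
    state = {"relax": 1.0, "failures": 0}
    while tree.n_terminals < stage.n_term_target:
        add_terminal(tree, stage, domain, rng, state,
                     sample_faces=sample_faces,
                     containment_domain=containment_domain)
    return tree


# ---------------------------------------------------------------------------
# domain-decomposed growth (PDCCO)
# ---------------------------------------------------------------------------

def partition_subdomains(shell, k: int) -> list[np.ndarray]:
    """Balanced contiguous partition of the base-surface triangles.

    Farthest-point seeding on the triangle adjacency graph followed by a
    multi-source geodesic (Dijkstra) assignment.
    """
    mesh = shell.base
    nf = len(mesh.faces)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return [np.arange(nf)]
    adj = mesh.face_adjacency
    cent = mesh.triangles_center
    w = np.linalg.norm(cent[adj[:, 0]] - cent[adj[:, 1]], axis=1)
    g = coo_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([adj[:, 0], adj[:, 1]]),
          np.concatenate([adj[:, 1], adj[:, 0]]))),
        shape=(nf, nf),
    ).tocsr()
    seeds = [int(np.argmin(((cent - cent.mean(0)) ** 2).sum(1)))]
    d_all = dijkstra(g, indices=seeds[0])
    for _ in range(k - 1):
        seeds.append(int(np.argmax(d_all)))
        d_new = dijkstra(g, indices=seeds[-1])
        d_all = np.minimum(d_all, d_new)
    dmat = dijkstra(g, indices=seeds)
    label = np.argmin(dmat, axis=0)
    parts = [np.flatnonzero(label == i) for i in range(k)]
    if any(len(pt) == 0 for pt in parts):
        raise ValueError("empty sub-domain in partition")
    return parts


def _nearest_fragment(tree, frag_ids, xb):
    d = point_segment_distance(
        xb[None], tree.proximal[frag_ids], tree.distal[frag_ids]
    )[0]
    return int(frag_ids[int(np.argmin(d))])


def decompose_and_grow(tree: VascularTree, shell, k: int,
                       stage: StageConfig) -> VascularTree:
    """Grow a stage concurrently over ``k`` sub-domains and merge.

    The shell is split into ``k`` contiguous sub-domains; each sub-domain
    independently grows its share of the terminal budget (apportioned by
    area, with per-sub-domain seeds spawned from the stage seed) on a
    private copy of the baseline tree, adding vessels only inside its
    sub-domain.  The private growth journals are then replayed onto the
    baseline to form the merged network, and a global Poiseuille solve
    restores the power-law radii and balance laws everywhere.  ``k == 1``
    reduces exactly to :func:`grow_stage`.
    """
    if k == 1:
        return grow_stage(tree, stage, shell)
    parts = partition_subdomains(shell, k)
    areas = np.array([shell.base.area_faces[p].sum() for p in parts])
    n_add_total = stage.n_term_target - tree.n_terminals
    if n_add_total <= 0:
        raise ValueError("stage target must exceed the current terminal count")
    shares = areas / areas.sum() * n_add_total
    n_add = np.floor(shares).astype(int)
    rema = np.argsort(-(shares - n_add), kind="stable")
    for i in range(n_add_total - n_add.sum()):
        n_add[rema[i % k]] += 1
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(stage.seed).spawn(k)]

    poiseuille_solve(tree)
    n_base = tree.n_segments
    journals = []
    for i, (part, na, seed_i) in enumerate(zip(parts, n_add, child_seeds)):
        if na == 0:
            journals.append([])
            continue
        sub = shell.subset(part)
        private = tree.copy()
        private.journal = []
        st = replace(stage, n_term_target=private.n_terminals + na,
                     seed=seed_i)
        grow_stage(private, st, sub, containment_domain=shell)
        journals.append(private.journal)

    merged = tree.copy()
    merged.journal = []
    frags = {b: [b] for b in range(n_base)}
    owner = {b: b for b in range(n_base)}
    for journal in journals:
        m = {}
        for (pid, rec_prox, rec_dist, xb, term, st_label, vtype,
             priv_nd, priv_nt) in journal:
            if pid < n_base:
                cands = frags[pid]
                target = None
                for c in cands:
                    if (np.array_equal(merged.proximal[c], rec_prox)
                            and np.array_equal(merged.distal[c], rec_dist)):
                        target = c
                        break
                if target is None:
                    # conflict: another sub-domain already split this
                    # baseline segment; attach to the nearest fragment,
                    # nudging the bifurcation to its midpoint if it would
                    # coincide with a fragment endpoint (zero-length split)
                    target = _nearest_fragment(merged, np.asarray(cands), xb)
                    eps = 1e-9
                    if (np.linalg.norm(xb - merged.proximal[target]) < eps
                            or np.linalg.norm(xb - merged.distal[target]) < eps):
                        xb = 0.5 * (merged.proximal[target]
                                    + merged.distal[target])
            else:
                target = m[pid]
            nd, nt = merged.split_insert(target, xb, term, st_label, vtype)
            merged.journal.append(
                (target, merged.proximal[target].copy(), rec_dist, xb, term,
                 st_label, vtype, nd, nt)
            )
            b = owner.get(target)
            if b is not None:
                frags[b].append(nd)
                owner[nd] = b
            m[priv_nd] = nd
            m[priv_nt] = nt
    merged.gamma = stage.geo.gamma
    merged.q_inlet = units.mlmin_to_cgs(stage.q_inlet_ml_min)
    poiseuille_solve(merged)
    return merged


# ---------------------------------------------------------------------------
# invariant checking
# ---------------------------------------------------------------------------

def check_tree(tree: VascularTree, domain=None, dv: int = 7) -> dict:
    """Residuals of the structural and hemodynamic tree invariants.

    Returns a dict with the maximum relative flow-conservation residual, the
    maximum relative power-law (Murray) residual over bifurcations, the
    maximum relative deviation of terminal flows from ``Q_inlet / N_T``, the
    number of segments with non-monotone pressure, and — when a domain is
    given — the number of distribution segments not fully contained in it.
    """
    if not tree.solved:
        poiseuille_solve(tree)
    res = {}
    child = tree.children
    has2 = child[:, 1] >= 0
    q = tree.flow
    r = tree.radius
    gamma = tree.gamma
    internal = child[:, 0] >= 0
    qc = np.where(internal, q[np.maximum(child[:, 0], 0)], 0.0) + np.where(
        has2, q[np.maximum(child[:, 1], 0)], 0.0
    )
    cons = np.abs(q[internal] - qc[internal]) / np.abs(q[internal])
    res["flow_conservation"] = float(cons.max()) if cons.size else 0.0
    rp = r[has2] ** gamma
    rc = r[child[has2, 0]] ** gamma + r[child[has2, 1]] ** gamma
    murr = np.abs(rp - rc) / rp
    res["murray_residual"] = float(murr.max()) if murr.size else 0.0
    term = tree.terminal_ids()
    qt = tree.q_inlet / len(term)
    res["terminal_flow_uniformity"] = float(
        np.abs(q[term] - qt).max() / qt
    )
    pprox = np.where(tree.parent >= 0,
                     tree.pressure_distal[np.maximum(tree.parent, 0)],
                     tree.inlet_pressure)
    res["non_monotone_pressure"] = int((tree.pressure_distal > pprox).sum())
    if domain is not None:
        dist_mask = tree.vtype == VascularTree.TYPE_DISTRIBUTION
        ids = np.flatnonzero(dist_mask)
        ts = np.linspace(0, 1, dv)
        bad = 0
        for i in ids:
            pts = tree.proximal[i] * (1 - ts)[:, None] + tree.distal[i] * ts[:, None]
            if not domain.contains(pts).all():
                bad += 1
        res["containment_violations"] = bad
    return res
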