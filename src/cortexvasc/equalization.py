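"""Inter-territorial pressure-distribution equalization.

Territories generated from different feeder vessels inherit inlet radii that
are not calibrated against their inlet flows, so the steady (Poiseuille)
pressure distributions of the grown networks disagree across territories.
Equalization finds, per territory, a single scaling factor ``f_S`` applied
to every vessel diameter such that the quadratic error between the
territory's pressure histogram and a reference territory's histogram is
minimized.  Histograms use the distal-node pressure of every segment, with
the inlet pressure shifted to 80 mmHg, binned into 1000 uniform bins on
[0, 80] mmHg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import units
from .ccogen import VascularTree, murray_xi, poiseuille_solve

__all__ = [
    "PressureHistogram",
    "EqualizationResult",
    "pressure_histogram",
    "find_scaling_factor",
    "apply_diameter_scaling",
]

N_BINS = 1000
P_RANGE = (0.0, 80.0)  # mmHg
INLET_SHIFT_MMHG = 80.0


@dataclass
class PressureHistogram:
    edges: np.ndarray  # mmHg, 1001 edges
    frequencies: np.ndarray  # normalized, sum 1
    inlet_shift: float = INLET_SHIFT_MMHG


def _shifted_pressures_mmhg(tree: VascularTree, sample: str) -> np.ndarray:
    drop = tree.inlet_pressure - tree.pressure_distal
    if sample == "midpoint":
        pprox = np.where(
            tree.parent >= 0,
            tree.pressure_distal[np.maximum(tree.parent, 0)],
            tree.inlet_pressure,
        )
        drop = tree.inlet_pressure - 0.5 * (pprox + tree.pressure_distal)
    return INLET_SHIFT_MMHG - units.cgs_to_mmhg(drop)


def pressure_histogram(tree: VascularTree,
                       sample: str = "distal") -> PressureHistogram:
    """Histogram of segment pressures with the inlet shifted to 80 mmHg.

    ``sample`` selects the per-segment sampling point (``distal`` default,
    or ``midpoint``).  Pressures below 0 mmHg are clipped into the first bin
    with a warning.
    """
    if not tree.solved:
        raise ValueError("tree must be solved (poiseuille_solve) first")
    p = _shifted_pressures_mmhg(tree, sample)
    if (p < P_RANGE[0]).any():
        warnings.warn(
            "%d pressures below 0 mmHg clipped into the first bin"
            % int((p < P_RANGE[0]).sum()),
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.clip(p, P_RANGE[0], None)
    freq, edges = np.histogram(p, bins=N_BINS, range=P_RANGE)
    freq = freq / freq.sum()
    return PressureHistogram(edges=edges, frequencies=freq)


@dataclass
class EqualizationResult:
    f_s: float
    error: float
    inlet_radius_um: float
    xi_before: float
    xi_after: float


def apply_diameter_scaling(tree: VascularTree, f_s: float) -> VascularTree:
    """Return a copy of the tree with every diameter multiplied by ``f_s``.

    With the power-law radii anchored at the inlet, scaling the inlet radius
    scales every radius by exactly ``f_s``; the copy is re-solved so that
    pressure drops reflect the new resistances (``f_s**-4`` at fixed flows
    for a radius-independent viscosity).
    """
    if f_s <= 0:
        raise ValueError("f_s must be positive")
    out = tree.copy()
    out.root_radius = tree.root_radius * f_s
    poiseuille_solve(out)
    return out


def _histogram_error(tree, f_s, reference, sample):
    scaled = apply_diameter_scaling(tree, f_s)
    with warnings.catch_warnings():
        # sub-physiological trial scalings legitimately push pressures
        # below the histogram range; clipping is part of the objective
        warnings.simplefilter("ignore", RuntimeWarning)
        h = pressure_histogram(scaled, sample=sample)
    return float(np.sum((h.frequencies - reference.frequencies) ** 2))


def find_scaling_factor(tree: VascularTree, reference: PressureHistogram,
                        lo: float = 0.5, hi: float = 1.5, tol: float = 1e-4,
                        sample: str = "distal") -> EqualizationResult:
    """Optimal diameter scaling factor ``f_S`` against a reference histogram.

    The quadratic histogram error is scanned on a coarse grid over
    ``[lo, hi]`` and refined to ``tol`` with a nested grid (the error is
    piecewise constant in ``f_S`` because of binning, so derivative-based
    refinement is not used).  Raises if the optimum sits at the search
    boundary (no interior bracket).
    """
    if not tree.solved:
        poiseuille_solve(tree)
    coarse = np.arange(lo, hi + 1e-12, 1e-2)
    errs = np.array([_histogram_error(tree, f, reference, sample)
                     for f in coarse])
    i = int(np.argmin(errs))
    if i == 0 or i == len(coarse) - 1:
        raise ValueError(
            "no interior bracket for f_S in [%g, %g]: end-point errors %g / %g"
            % (lo, hi, errs[0], errs[-1])
        )
    fine = np.arange(coarse[i - 1], coarse[i + 1] + tol / 2, tol)
    errs_f = np.array([_histogram_error(tree, f, reference, sample)
                       for f in fine])
    j = int(np.argmin(errs_f))
    f_best = float(fine[j])
    q_ml_min = units.cgs_to_mlmin(tree.q_inlet)
    r_um = units.cm_to_um(tree.root_radius)
    return EqualizationResult(
        f_s=f_best,
        error=float(errs_f[j]),
        inlet_radius_um=r_um * f_best,
        xi_before=murray_xi(q_ml_min, r_um),
        xi_after=murray_xi(q_ml_min, r_um * f_best),
    )
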