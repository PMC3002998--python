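"""Placement of the non-spatial MT length distribution onto the fixed mesh
and the Pom1 convection velocity field it generates.

All microtubules are nucleated between the two central mesh nodes and grow
antiparallel toward the two cell tips; each length class is split equally
between the half-cells and mirrored.  Cytosolic Pom1 (carrying the lumped
Tea1) is transported tip-ward by "riding" on growing MT plus-ends and by
"walking" along MT polymers as motor cargo; the local velocity saturates
with the number of available tracks and is bounded by the carrier speeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import COPIES_PER_NM_UM3, CellGeometry, Mesh
from .microtubules import MTParams, MTState


@dataclass(frozen=True)
class CouplingParams:
    """Parameters of the MT-to-velocity coupling.

    ``v_walk`` is the speed (µm/min) of the Tea2 motor along a polymer;
    ``K_occ`` is the MT count at which the saturating occupancy factor
    ``m/(m + K_occ)`` reaches one half; ``v_refresh`` is the interval (min)
    at which the velocity field is recomputed from the MT subsystem.
    """

    v_walk: float = 3.0
    K_occ: float = 0.05
    v_refresh: float = 0.1


@dataclass
class PlacedMTs:
    """Expected per-mesh-point MT copy numbers (both half-cells, mirrored)."""

    growing_count: np.ndarray  # growing MTs whose span covers the point
    total_count: np.ndarray    # all MTs whose span covers the point
    tip_count: np.ndarray      # growing plus-ends located at the point


@dataclass
class VelocityField:
    """Signed convection velocity (µm/min) per mesh point.

    Positive values point toward the right-hand tip; by the antiparallel
    construction the field is antisymmetric about the cell centre and
    vanishes at the central face.
    """

    v: np.ndarray


def normalize_subunits(i, L: float, mesh: Mesh, delta_d: float):
    """Number of fixed-mesh intervals covered by a polymer of ``i`` subunits.

    ``ni = ceil(i * delta_d / (L / n_points))`` — the polymer's physical
    length divided by the physical length represented by one mesh interval,
    rounded up (a polymer poking into an interval counts as covering it).
    A small tolerance keeps exact multiples from rounding up spuriously.
    """
    i = np.asarray(i)
    if np.any(i < 1):
        raise ValueError("subunit index must be >= 1")
    increment = L / mesh.n_points
    ni = np.ceil(i * delta_d / increment - 1e-12).astype(int)
    return ni if ni.ndim else int(ni)


def place_mts(state: MTState, geom: CellGeometry, t: float, mesh: Mesh,
              params: MTParams) -> PlacedMTs:
    """Map MT length classes to expected copy numbers on the mesh.

    Each class is converted to copies per cell at the current volume, split
    equally between the two half-cells, anchored at the central pair and
    extended ``ni`` intervals toward its tip, then mirrored.  Spans are
    clipped at the half-mesh (polymers reach at most the cell tip).
    """
    n = mesh.n_points
    half = n // 2
    L = float(geom.length_at(t))
    to_copies = COPIES_PER_NM_UM3 * float(geom.volume_at(t))

    growing = np.zeros(n)
    total = np.zeros(n)
    tips = np.zeros(n)
    if state.N == 0:
        return PlacedMTs(growing, total, tips)

    ni = np.minimum(normalize_subunits(np.arange(1, state.N + 1), L, mesh,
                                       params.delta_d), half)
    g_copies = state.grow * to_copies
    s_copies = state.shrink * to_copies

    # coverage at distance d (1..half) from the centre = sum of classes with ni >= d
    g_by_ni = np.bincount(ni, weights=g_copies, minlength=half + 1)
    a_by_ni = np.bincount(ni, weights=g_copies + s_copies, minlength=half + 1)
    g_cov = np.cumsum(g_by_ni[::-1])[::-1][1:half + 1]   # index d-1
    a_cov = np.cumsum(a_by_ni[::-1])[::-1][1:half + 1]

    # right half-cell: mesh points half..n-1 are distances 1..half from centre
    growing[half:] = 0.5 * g_cov
    total[half:] = 0.5 * a_cov
    tips[half:] = 0.5 * g_by_ni[1:half + 1]
    # mirrored left half-cell
    growing[:half] = growing[half:][::-1]
    total[:half] = total[half:][::-1]
    tips[:half] = tips[half:][::-1]
    return PlacedMTs(growing, total, tips)


def occupancy(m: np.ndarray, K_occ: float) -> np.ndarray:
    """Saturating track-occupancy factor ``m / (m + K_occ)`` in [0, 1)."""
    m = np.asarray(m, dtype=float)
    return m / (m + K_occ)


def convection_velocity(placed: PlacedMTs, mt_params: MTParams,
                        params: CouplingParams) -> VelocityField:
    """Pom1 convection velocity from riding and walking transport.

    ``v(x) = v_el * f(growing(x)) + v_walk * f(total(x))`` with the
    saturating occupancy ``f``; directed toward the nearer tip (positive on
    the right half, negative on the left), so cargo speed never exceeds
    ``v_el + v_walk`` however many tracks are present.
    """
    if np.any(placed.growing_count < 0) or np.any(placed.total_count < 0):
        raise ValueError("MT counts must be non-negative")
    speed = (mt_params.v_el * occupancy(placed.growing_count, params.K_occ)
             + params.v_walk * occupancy(placed.total_count, params.K_occ))
    n = speed.size
    sign = np.where(np.arange(n) >= n // 2, 1.0, -1.0)
    return VelocityField(v=sign * speed)
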