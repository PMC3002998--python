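"""Synthetic initial concentration profiles for Pom1 and Cdr2.

The published initial distributions were digitized fluorescence data that
are not machine-readable; these generators emulate their described shape: a
tip-peaked, symmetric Pom1 gradient and a midcell-peaked Cdr2 distribution
in a 7 µm newborn cell, normalized to exact total copy numbers (2000 Pom1,
1855 Cdr2), plus an asymmetric "newborn" variant in which both proteins
start biased toward one cell end, and a uniform variant for solver tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import COPIES_PER_NM_UM3, CellGeometry, Mesh
from .pde import FieldState, PDEParams


@dataclass(frozen=True)
class ProfileParams:
    """Shape parameters of the synthetic initial profiles.

    ``lam`` is the normalized decay length of the Pom1 tip gradient;
    ``sigma`` the normalized width of the Cdr2 midcell peak; ``w`` the
    Pom1 tip asymmetry weight of the newborn variant (w:1 new end:old end)
    and ``cdr2_shift`` the normalized off-centre displacement of newborn
    Cdr2.  Membrane fractions set how the initial pools are split between
    membrane-bound and cytosolic forms.
    """

    lam: float = 0.12
    sigma: float = 0.10
    w: float = 3.0
    cdr2_shift: float = 0.15
    pom1_membrane_frac: float = 0.8
    cdr2_membrane_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.sigma <= 0 or self.w < 1:
            raise ValueError("invalid profile shape parameters")
        for f in (self.pom1_membrane_frac, self.cdr2_membrane_frac):
            if not 0 <= f <= 1:
                raise ValueError("membrane fractions must lie in [0, 1]")


def make_initial_profiles(kind: str, copies_pom1: float, copies_cdr2: float,
                          geom: CellGeometry, mesh: Mesh,
                          params: ProfileParams = ProfileParams(),
                          n_sites: int = 10,
                          pom1_oe_factor: float = 1.0,
                          kinetics: PDEParams | None = None) -> FieldState:
    """Build the t = 0 field state for a scenario.

    ``kind`` is one of ``"symmetric"`` (tip-peaked Pom1, midcell Cdr2),
    ``"newborn"`` (both biased toward one end, mimicking a cell right after
    division) or ``"uniform"`` (flat fields for solver fixtures).  Fields
    are scaled so that the spatially integrated copy numbers match the
    requested totals exactly; Pom1 overexpression multiplies the Pom1
    copies by ``pom1_oe_factor``.

    The membrane Cdr2 pool is the shaped (midcell-peaked) component while
    cytosolic Cdr2 starts spatially uniform (fast cytosolic diffusion).  If
    ``kinetics`` is given, the membrane pool is distributed across the
    phosphoforms according to the local steady chain ratio
    ``r(x) = k_phos * P_m(x) / k_dephos`` (weights ``r^j``), so that
    Pom1-driven expulsion is active from t = 0 instead of waiting for the
    chain to fill.
    """
    if copies_pom1 <= 0 or copies_cdr2 <= 0:
        raise ValueError("copy numbers must be positive")
    x = mesh.xbar
    if kind == "symmetric":
        pom1 = np.exp(-x / params.lam) + np.exp(-(1.0 - x) / params.lam)
        cdr2 = np.exp(-0.5 * ((x - 0.5) / params.sigma) ** 2)
    elif kind == "newborn":
        pom1 = (params.w * np.exp(-x / params.lam)
                + np.exp(-(1.0 - x) / params.lam))
        c = 0.5 + params.cdr2_shift
        cdr2 = np.exp(-0.5 * ((x - c) / params.sigma) ** 2)
    elif kind == "uniform":
        pom1 = np.ones_like(x)
        cdr2 = np.ones_like(x)
    else:
        raise ValueError(f"unknown profile kind {kind!r}")

    V0 = float(geom.volume_at(0.0))

    def normalize(shape: np.ndarray, copies: float) -> np.ndarray:
        # mean over mesh midpoints equals the integral over [0, 1]
        return shape * (copies / (shape.mean() * COPIES_PER_NM_UM3 * V0))

    pom1 = normalize(pom1, copies_pom1 * pom1_oe_factor)
    mem_copies = params.cdr2_membrane_frac * copies_cdr2
    cyt_copies = copies_cdr2 - mem_copies
    cdr2_mem = normalize(cdr2, mem_copies) if mem_copies > 0 else np.zeros_like(x)
    cdr2_cyt = normalize(np.ones_like(x), cyt_copies) if cyt_copies > 0 \
        else np.zeros_like(x)

    P_m = params.pom1_membrane_frac * pom1
    C_m = np.zeros((n_sites + 1, mesh.n_points))
    if kinetics is not None and n_sites > 0 and kinetics.k_dephos > 0:
        r = kinetics.k_phos * P_m / kinetics.k_dephos
        j = np.arange(n_sites + 1)[:, None]
        logw = j * np.log(np.maximum(r[None, :], 1e-300))
        w = np.exp(logw - logw.max(axis=0, keepdims=True))
        C_m[:] = cdr2_mem[None, :] * w / w.sum(axis=0, keepdims=True)
    else:
        C_m[0] = cdr2_mem
    return FieldState(
        P_c=(1.0 - params.pom1_membrane_frac) * pom1,
        P_m=P_m,
        C_c=cdr2_cyt,
        C_m=C_m,
        t=0.0,
    )
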