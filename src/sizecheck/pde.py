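"""Reaction-diffusion-convection system for Pom1 and Cdr2 on the growing cell.

Species: cytosolic and membrane Pom1 (``P_c``, ``P_m``), cytosolic Cdr2
(``C_c``) and a chain of membrane Cdr2 phosphoforms ``C_m^(0..n)``.  Pom1
partitions reversibly between cytosol and membrane; cytosolic Cdr2 inserts
into the membrane, where membrane Pom1 phosphorylates it on ``n`` sites in
an ordered distributive chain opposed by a constant implicit phosphatase;
the fully phosphorylated form is expelled to the cytosol and simultaneously
dephosphorylated.  With ``n_sites = 0`` the model degenerates to the
single-step variant in which membrane Pom1 catalyses direct expulsion of
unphosphorylated membrane Cdr2.

The equations are solved on the fixed normalized mesh ``xbar = x/L(t)``:

    du/dt = (D/L²) u_xx  -  (1/L) (v(xbar) u)_x  -  alpha*u  +  R(u)

with no-flux boundaries.  Per step, a Strang-like splitting applies a half
step of reactions+dilution (classical RK4), one implicit step of transport
(Crank-Nicolson diffusion; first-order upwind convection, folded into the
same tridiagonal system, for ``P_c`` only), and a second reaction half step.
The finite-volume flux form makes transport conserve total copies exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .coupling import VelocityField
from .geometry import COPIES_PER_NM_UM3, CellGeometry, Mesh


@dataclass(frozen=True)
class PDEParams:
    """Kinetics of the Pom1:Cdr2 subsystem.

    Diffusion coefficients in µm²/min, first-order constants in min⁻¹,
    ``k_phos`` in nM⁻¹·min⁻¹ (per site, catalysed by membrane Pom1), feeds
    in nM/min.  Surface-to-volume normalization of the interfacial reactions
    is absorbed into the on/off constants.  ``n_sites = 0`` selects the
    single-step expulsion variant (``k_expel_single``, nM⁻¹·min⁻¹).
    """

    D_c: float = 6.0
    D_m: float = 0.06
    k_P_on: float = 1.0
    k_P_off: float = 2.0
    k_C_on: float = 1.0
    k_phos: float = 4.5
    k_dephos: float = 1.0
    k_expel: float = 5.0
    k_expel_single: float = 0.4
    feed_P: float = 0.0
    feed_C: float = 0.0
    n_sites: int = 10
    pom1_oe_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.D_m >= self.D_c:
            raise ValueError("membrane diffusion must be slower than cytosolic")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")


@dataclass
class FieldState:
    """Spatial concentration fields (nM) on the mesh at time ``t`` (min)."""

    P_c: np.ndarray
    P_m: np.ndarray
    C_c: np.ndarray
    C_m: np.ndarray      # shape (n_sites + 1, n_points), phosphoforms 0..n
    t: float = 0.0

    def copy(self) -> "FieldState":
        return FieldState(self.P_c.copy(), self.P_m.copy(), self.C_c.copy(),
                          self.C_m.copy(), self.t)

    @property
    def membrane_cdr2(self) -> np.ndarray:
        """Total membrane Cdr2 (sum over phosphoforms) per mesh point."""
        return self.C_m.sum(axis=0)

    @property
    def total_pom1(self) -> np.ndarray:
        return self.P_c + self.P_m

    @property
    def total_cdr2(self) -> np.ndarray:
        return self.C_c + self.membrane_cdr2


def reaction_terms(fields: FieldState, params: PDEParams):
    """Pure reaction rates (no transport, no dilution) for each species.

    Returns ``(dP_c, dP_m, dC_c, dC_m)``.  The phosphorylation chain is
    ordered and distributive: each step ``C_m^(j) -> C_m^(j+1)`` proceeds at
    ``k_phos * P_m * C_m^(j)``, opposed by ``k_dephos * C_m^(j)`` steps down
    the chain; expulsion returns the top form, fully dephosphorylated, to
    the cytosol.  Summing the chain, the only net source of total Cdr2 is
    ``feed_C`` (all internal fluxes telescope).
    """
    if min(fields.P_c.min(), fields.P_m.min(), fields.C_c.min(),
           fields.C_m.min()) < 0:
        raise ValueError("negative concentrations in reaction input")
    return _reaction_rates(fields.P_c, fields.P_m, fields.C_c, fields.C_m, params)


def _reaction_rates(P_c, P_m, C_c, C_m, params: PDEParams):
    part = params.k_P_on * P_c - params.k_P_off * P_m
    dP_c = params.feed_P - part
    dP_m = part

    insert = params.k_C_on * C_c
    dC_m = np.zeros_like(C_m)
    n = params.n_sites
    if n == 0:
        expel = params.k_expel_single * P_m * C_m[0]
        dC_m[0] = insert - expel
    else:
        phos = params.k_phos * P_m * C_m[:-1]          # j -> j+1, j = 0..n-1
        dephos = params.k_dephos * C_m[1:]             # j -> j-1, j = 1..n
        expel = params.k_expel * C_m[n]
        dC_m[:-1] -= phos
        dC_m[1:] += phos
        dC_m[1:] -= dephos
        dC_m[:-1] += dephos
        dC_m[0] += insert
        dC_m[n] -= expel
    dC_c = params.feed_C - insert + expel
    return dP_c, dP_m, dC_c, dC_m


class Pom1Cdr2Solver:
    """Strang-split Crank-Nicolson integrator for the field system."""

    def __init__(self, geom: CellGeometry, mesh: Mesh, params: PDEParams,
                 dt: float = 0.01) -> None:
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.geom = geom
        self.mesh = mesh
        self.params = params
        self.dt = dt

    # -- reaction + dilution half step (classical RK4) -------------------
    def _react(self, fields: FieldState, h: float) -> None:
        a = self.geom.alpha
        p = self.params

        def rhs(Pc, Pm, Cc, Cm):
            dPc, dPm, dCc, dCm = _reaction_rates(Pc, Pm, Cc, Cm, p)
            return (dPc - a * Pc, dPm - a * Pm, dCc - a * Cc, dCm - a * Cm)

        # the phosphorylation chain can be stiff where membrane Pom1 is
        # high (cell tips); substep so the fastest first-order rate stays
        # well inside the RK4 stability region
        fastest = max(p.k_phos * float(fields.P_m.max()),
                      p.k_expel_single * float(fields.P_m.max()),
                      p.k_expel, p.k_dephos, p.k_P_on, p.k_P_off, p.k_C_on)
        nsub = max(1, int(np.ceil(fastest * h / 0.5)))
        hs = h / nsub

        y = (fields.P_c, fields.P_m, fields.C_c, fields.C_m)
        for _ in range(nsub):
            k1 = rhs(*y)
            k2 = rhs(*(u + 0.5 * hs * k for u, k in zip(y, k1)))
            k3 = rhs(*(u + 0.5 * hs * k for u, k in zip(y, k2)))
            k4 = rhs(*(u + hs * k for u, k in zip(y, k3)))
            y = tuple(u + (hs / 6.0) * (a1 + 2 * a2 + 2 * a3 + a4)
                      for u, a1, a2, a3, a4 in zip(y, k1, k2, k3, k4))
        fields.P_c, fields.P_m, fields.C_c, fields.C_m = y

    # -- implicit transport step -----------------------------------------
    @staticmethod
    def _laplacian_times(u: np.ndarray, r: float) -> np.ndarray:
        """(I + r*Lap) u for the no-flux finite-volume Laplacian (dx = 1 unit
        absorbed into r)."""
        out = u.copy()
        out[..., :-1] += r * (u[..., 1:] - u[..., :-1])
        out[..., 1:] += r * (u[..., :-1] - u[..., 1:])
        return out

    @staticmethod
    def _banded_identity_minus(r: float, n: int) -> np.ndarray:
        """Banded form (3, n) of I - r*Lap."""
        ab = np.zeros((3, n))
        ab[1, :] = 1.0 + 2.0 * r
        ab[1, 0] = ab[1, -1] = 1.0 + r
        ab[0, 1:] = -r
        ab[2, :-1] = -r
        return ab

    def step(self, fields: FieldState, velocity: VelocityField,
             dt: float | None = None) -> FieldState:
        """Advance the fields by one time step."""
        h = self.dt if dt is None else dt
        self._check(fields)
        mesh = self.mesh
        n = mesh.n_points
        dx = mesh.dx
        L = float(self.geom.length_at(fields.t + 0.5 * h))
        p = self.params

        out = fields.copy()
        self._react(out, 0.5 * h)

        # diffusion ratios r = D/L^2 * h/2 / dx^2
        r_c = p.D_c / L**2 * 0.5 * h / dx**2
        r_m = p.D_m / L**2 * 0.5 * h / dx**2

        # cytosolic Cdr2: pure Crank-Nicolson diffusion
        ab_c = self._banded_identity_minus(r_c, n)
        out.C_c = solve_banded((1, 1), ab_c, self._laplacian_times(out.C_c, r_c))

        # membrane species: shared matrix, multiple right-hand sides
        ab_m = self._banded_identity_minus(r_m, n)
        rhs_m = self._laplacian_times(
            np.vstack([out.P_m[None, :], out.C_m]), r_m)
        sol = solve_banded((1, 1), ab_m, rhs_m.T)
        out.P_m = sol[:, 0]
        out.C_m = sol[:, 1:].T

        # cytosolic Pom1: CN diffusion + implicit upwind convection
        w = np.zeros(n + 1)                       # face velocities, normalized
        w[1:-1] = 0.5 * (velocity.v[:-1] + velocity.v[1:]) / L
        wp, wm = np.maximum(w, 0.0), np.minimum(w, 0.0)
        cu = h / dx
        ab = self._banded_identity_minus(r_c, n)
        ab[1, :] += cu * (wp[1:] - wm[:-1])       # diagonal
        ab[0, 1:] += cu * wm[1:-1]                # super-diagonal (u_{j+1})
        ab[2, :-1] -= cu * wp[1:-1]               # sub-diagonal (u_{j-1})
        out.P_c = solve_banded((1, 1), ab, self._laplacian_times(out.P_c, r_c))

        self._react(out, 0.5 * h)
        out.t = fields.t + h

        self._check(out)
        return out

    def _check(self, fields: FieldState) -> None:
        for name in ("P_c", "P_m", "C_c", "C_m"):
            u = getattr(fields, name)
            if np.any(np.isnan(u)) or u.min() < -0.1:
                raise FloatingPointError(
                    f"instability in species {name} at t={fields.t:.3f} min "
                    f"(min={u.min():.3g})")


def midcell_membrane_cdr2(fields: FieldState, mesh: Mesh,
                          window: tuple[float, float] = (0.4, 0.6)) -> float:
    """Mean total membrane Cdr2 (nM) over the normalized midcell window."""
    lo, hi = window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("window must be a non-empty subinterval of [0, 1]")
    mask = (mesh.xbar >= lo) & (mesh.xbar <= hi)
    if not mask.any():
        raise ValueError("window contains no mesh points")
    return float(fields.membrane_cdr2[mask].mean())


def total_copies(fields: FieldState, species: str, geom: CellGeometry,
                 t: float | None = None) -> float:
    """Spatially integrated copy number of a species at time ``t``.

    ``species`` is one of ``"pom1"``, ``"cdr2"``, ``"P_c"``, ``"P_m"``,
    ``"C_c"``, ``"C_m"``.  The mesh-point mean equals the integral over the
    unit interval, so copies = mean(conc) * V(t) * N_A.
    """
    if t is None:
        t = fields.t
    profiles = {
        "pom1": fields.total_pom1, "cdr2": fields.total_cdr2,
        "P_c": fields.P_c, "P_m": fields.P_m, "C_c": fields.C_c,
        "C_m": fields.membrane_cdr2,
    }
    try:
        u = profiles[species]
    except KeyError:
        raise ValueError(f"unknown species {species!r}") from None
    return float(u.mean()) * COPIES_PER_NM_UM3 * float(geom.volume_at(t))


def fwhm(xbar: np.ndarray, profile: np.ndarray) -> float:
    """Full width at half maximum (normalized units) of a single-peaked
    profile, measured above its minimum with linear interpolation."""
    u = np.asarray(profile, float)
    base = u.min()
    half = base + 0.5 * (u.max() - base)
    above = u >= half
    if not above.any():
        return 0.0
    i0, i1 = np.nonzero(above)[0][[0, -1]]
    x_left = xbar[i0]
    if i0 > 0:
        x_left = np.interp(half, [u[i0 - 1], u[i0]], [xbar[i0 - 1], xbar[i0]])
    x_right = xbar[i1]
    if i1 < u.size - 1:
        x_right = np.interp(half, [u[i1 + 1], u[i1]], [xbar[i1 + 1], xbar[i1]])
    return float(x_right - x_left)
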