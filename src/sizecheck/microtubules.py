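"""Non-spatial microtubule dynamic-instability ODE subsystem.

Microtubules (MTs) are discretized into length classes of ``delta_d`` µm
(one "subunit" = ``Ns * delta_d`` tubulin monomers).  Free tubulin exists as
a GDP-bound pool ``T_D`` and a GTP-bound, polymerization-competent pool
``T_T``; an implicit nucleation site converts ``T_T`` reversibly into the
shortest growing polymer.  Growing polymers of class ``i`` elongate to class
``i+1`` (first order in ``T_T``, not raised to the subunit stoichiometry),
switch irreversibly to shrinking polymers at a position-dependent catastrophe
rate, and shrinking polymers lose one subunit at a time, releasing ``T_D``.
Every species is diluted at the cell growth rate ``alpha``.

As the cell lengthens, new (zero-concentration) length classes are appended
so that polymers may span up to half the cell: ``N`` runs from 50 in a 7 µm
newborn to 100 when the volume has doubled.

Rate constants are derived from measured elongation/shrinkage velocities;
nucleation and catastrophe constants are calibration parameters constrained
by the observed average of 3.6 tip-touching MTs per cell and an apparent
steady state within 10 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .geometry import COPIES_PER_NM_UM3, CellGeometry


@dataclass(frozen=True)
class MTParams:
    """Kinetic parameters of the microtubule subsystem.

    Velocities are in µm/min, first-order constants in min⁻¹, bimolecular
    constants in nM⁻¹·min⁻¹ and feeds in nM/min.  ``T_T_ref`` is the
    reference GTP-tubulin concentration at which a growing polymer elongates
    at exactly ``v_el``.
    """

    Ns: float = 1625.0            # tubulin monomers per µm of polymer
    delta_d: float = 0.07         # µm per discretized subunit
    v_el: float = 2.0             # average elongation velocity
    v_dp: float = 8.0             # average shrinkage velocity
    T_T_ref: float = 7500.0       # nM, reference T_T for velocity calibration
    Vc_ref: float = 74.0          # µm³, average cell volume used in derivations
    k_ex: float = 5.0             # GDP->GTP exchange, first order in T_D
    k_nuc1: float = 2.062e-5      # nucleation forward, first order in T_T
    k_nuc2: float = 1.0           # nucleation reverse, first order in MT_1^g
    kcat_a: float = 0.1385        # catastrophe prefactor (min⁻¹)
    kcat_b: float = 1.5           # catastrophe position-exponent
    mbc_factor: float = 1.0       # catastrophe multiplier (5 under MBC)
    feed_T: float = 70.6          # constant tubulin production into T_D
    feed_GTP: float = 2400.0      # constant GTP production
    mbc_onset: float = 0.0        # time (min) at which mbc_factor switches on

    @property
    def monomers_per_subunit(self) -> float:
        """Tubulin monomers per polymerized MT subunit (Ns·delta_d = 113.75)."""
        return self.Ns * self.delta_d

    @property
    def k_el(self) -> float:
        """Elongation rate constant (nM⁻¹·min⁻¹)."""
        return k_el_from_velocity(self.v_el, self.Ns, self.delta_d,
                                  self.Vc_ref, self.T_T_ref)

    @property
    def k_dep(self) -> float:
        """Depolymerization rate constant (min⁻¹)."""
        return k_dep_from_velocity(self.v_dp, self.Ns, self.delta_d, self.Vc_ref)


def k_el_from_velocity(v_el: float, Ns: float, delta_d: float,
                       Vc: float = 74.0, T_T_ref: float = 7500.0) -> float:
    """Elongation rate constant from the measured elongation velocity.

    One polymer adds ``v_el * Ns`` monomers per minute, i.e. ``v_el/delta_d``
    discretized subunits per minute.  Equating this per-polymer event rate,
    expressed as a concentration rate for one molecule in the reference cell
    volume ``Vc`` and normalized by the ``Ns*delta_d`` monomers per subunit,
    with the mass-action law ``k_el * [MT_i^g] * [T_T]`` at the reference
    concentration ``T_T_ref`` makes the ``N_A * Vc`` factors cancel, leaving

        k_el = v_el / (delta_d * T_T_ref).
    """
    if min(Ns, delta_d, Vc, T_T_ref) <= 0:
        raise ValueError("MT parameters must be positive")
    if v_el < 0:
        raise ValueError("elongation velocity must be non-negative")
    return v_el / (delta_d * T_T_ref)


def k_dep_from_velocity(v_dp: float, Ns: float, delta_d: float,
                        Vc: float = 74.0) -> float:
    """Depolymerization rate constant from the measured shrinkage velocity.

    Shrinkage is first order in the shrinking polymer alone, so the
    per-polymer subunit-loss rate is the rate constant itself:
    ``k_dep = v_dp / delta_d`` (min⁻¹).  Each loss event releases
    ``Ns * delta_d`` monomers of GDP-tubulin.
    """
    if min(Ns, delta_d, Vc) <= 0:
        raise ValueError("MT parameters must be positive")
    if v_dp < 0:
        raise ValueError("shrinkage velocity must be non-negative")
    return v_dp / delta_d


def k_cat(i, N: int, params: MTParams) -> np.ndarray | float:
    """Catastrophe rate (min⁻¹) for length class ``i`` of a maximum ``N``.

    An exponential function of polymer extent normalized to cell length,
    ``kcat_a * exp(kcat_b * i/N)``, strictly increasing toward the cell tips,
    times the drug multiplier ``mbc_factor``.
    """
    i_arr = np.asarray(i)
    if np.any(i_arr < 1) or np.any(i_arr > N):
        raise ValueError(f"length class out of range 1..{N}")
    out = params.kcat_a * np.exp(params.kcat_b * i_arr / N) * params.mbc_factor
    return out if out.ndim else float(out)


@dataclass
class MTState:
    """Concentrations (nM) of tubulin pools and MT length classes."""

    T_D: float
    T_T: float
    GTP: float
    grow: np.ndarray      # MT_i^g, i = 1..N
    shrink: np.ndarray    # MT_i^s, i = 1..N

    def __post_init__(self) -> None:
        self.grow = np.asarray(self.grow, dtype=float)
        self.shrink = np.asarray(self.shrink, dtype=float)
        if self.grow.shape != self.shrink.shape or self.grow.ndim != 1:
            raise ValueError("grow and shrink must be 1-D arrays of equal length")

    @property
    def N(self) -> int:
        """Current number of length classes."""
        return self.grow.size

    def to_vector(self) -> np.ndarray:
        return np.concatenate(([self.T_D, self.T_T, self.GTP], self.grow, self.shrink))

    @classmethod
    def from_vector(cls, y: np.ndarray, N: int) -> "MTState":
        return cls(T_D=y[0], T_T=y[1], GTP=y[2],
                   grow=y[3:3 + N].copy(), shrink=y[3 + N:3 + 2 * N].copy())

    @classmethod
    def initial(cls, N: int, T_T: float = 7500.0, T_D: float = 500.0,
                GTP: float = 340_000.0) -> "MTState":
        """Polymer-free initial state (concentrations in nM)."""
        return cls(T_D=T_D, T_T=T_T, GTP=GTP,
                   grow=np.zeros(N), shrink=np.zeros(N))


def max_classes(L: float, delta_d: float) -> int:
    """Number of length classes for cell length ``L``: polymers span at most
    half the cell, so ``N = floor((L/2)/delta_d)`` (50 at 7 µm, 100 at 14 µm)."""
    return int(np.floor(L / (2.0 * delta_d) + 1e-9))


def extend_system(state: MTState, L_new: float, params: MTParams) -> MTState:
    """Append zero-concentration length classes so that ``N`` tracks the
    grown cell length.  Shrinking the system is rejected."""
    N_new = max_classes(L_new, params.delta_d)
    if N_new < state.N:
        raise ValueError("cell length implies fewer classes than present")
    if N_new == state.N:
        return state
    pad = N_new - state.N
    return MTState(T_D=state.T_D, T_T=state.T_T, GTP=state.GTP,
                   grow=np.concatenate([state.grow, np.zeros(pad)]),
                   shrink=np.concatenate([state.shrink, np.zeros(pad)]))


def ode_rhs(t: float, y: np.ndarray, params: MTParams, geom: CellGeometry,
            N: int) -> np.ndarray:
    """Time derivatives of ``[T_D, T_T, GTP, grow(1..N), shrink(1..N)]``.

    Reactions: constant tubulin feed into ``T_D``; irreversible nucleotide
    exchange ``k_ex*T_D`` (consumes GTP); reversible nucleation
    ``T_T <-> MT_1^g``; elongation ``MT_i^g + T_T -> MT_{i+1}^g`` (the top
    class cannot elongate); catastrophe ``MT_i^g -> MT_i^s`` at ``k_cat(i)``;
    depolymerization ``MT_i^s -> MT_{i-1}^s + T_D`` (class 1 dissolves
    entirely); and ``-alpha*u`` dilution on every species.  Tubulin
    consumption/release is weighted by the ``Ns*delta_d`` monomers per
    polymerized subunit, so total tubulin mass obeys
    ``d(mass)/dt = feed_T - alpha*mass`` exactly.
    """
    if np.any(np.isnan(y)):
        raise FloatingPointError(f"NaN in MT state at t={t:.4f} min")
    T_D, T_T, GTP = y[0], y[1], y[2]
    g = y[3:3 + N]
    s = y[3 + N:3 + 2 * N]
    alpha = geom.alpha
    m = params.monomers_per_subunit

    mbc = params.mbc_factor if t >= params.mbc_onset else 1.0
    idx = np.arange(1, N + 1)
    kcat = params.kcat_a * np.exp(params.kcat_b * idx / N) * mbc

    k_elTT = params.k_el * T_T
    elong = k_elTT * g            # elong[i-1]: class i -> i+1
    elong[-1] = 0.0               # tip-capped at the half-cell
    nuc = params.k_nuc1 * T_T - params.k_nuc2 * g[0]
    cat = kcat * g
    dep = params.k_dep * s        # dep[i-1]: class i -> i-1

    dg = -elong - cat - alpha * g
    dg[0] += nuc
    dg[1:] += elong[:-1]

    ds = cat - dep - alpha * s
    ds[:-1] += dep[1:]

    exch = params.k_ex * T_D
    dT_T = exch - m * (nuc + elong.sum()) - alpha * T_T
    dT_D = params.feed_T - exch + m * dep.sum() - alpha * T_D
    dGTP = params.feed_GTP - exch - alpha * GTP

    return np.concatenate(([dT_D, dT_T, dGTP], dg, ds))


def tip_classes(N: int, L: float, params: MTParams, mesh_points: int = 100) -> np.ndarray:
    """Boolean mask over classes 1..N of polymers touching the cell tip.

    A polymer of class ``i`` covers ``ceil(i*delta_d / (L/mesh_points))``
    fixed-mesh intervals from the cell centre; it touches the tip when that
    count reaches the half-mesh (``mesh_points/2``), i.e. when its physical
    length exceeds ``(mesh_points/2 - 1)/mesh_points * L``.
    """
    i = np.arange(1, N + 1)
    half = mesh_points // 2
    covered = np.ceil(i * params.delta_d / (L / mesh_points) - 1e-12)
    return np.minimum(covered, half) >= half


def count_full_length(state: MTState, geom: CellGeometry, t: float,
                      params: MTParams, mesh_points: int = 100) -> float:
    """Expected number of MTs touching the cell tips (both tips combined).

    Sums the concentrations of all length classes whose normalized extent
    reaches the end of the half-mesh and converts to copies per cell at the
    current volume.  At t = 0 this is exactly the longest class ``N``.
    """
    L = float(geom.length_at(t))
    mask = tip_classes(state.N, L, params, mesh_points)
    conc = (state.grow + state.shrink)[mask].sum()
    return conc * COPIES_PER_NM_UM3 * float(geom.volume_at(t))


@dataclass
class MTTrajectory:
    """Sampled solution of the MT subsystem on a uniform time grid."""

    t: np.ndarray
    states: list[MTState]
    params: MTParams
    geom: CellGeometry

    def full_length_counts(self, mesh_points: int = 100) -> np.ndarray:
        return np.array([
            count_full_length(s, self.geom, ti, self.params, mesh_points)
            for ti, s in zip(self.t, self.states)
        ])

    def total_polymer_concentration(self) -> np.ndarray:
        return np.array([s.grow.sum() + s.shrink.sum() for s in self.states])


def _extension_times(geom: CellGeometry, params: MTParams, t_end: float) -> np.ndarray:
    """Times at which the class count N increments by one."""
    N0 = max_classes(geom.L0, params.delta_d)
    N_end = max_classes(float(geom.length_at(t_end)), params.delta_d)
    if N_end <= N0 or geom.alpha == 0:
        return np.empty(0)
    ks = np.arange(N0 + 1, N_end + 1)
    return np.log(2.0 * params.delta_d * ks / geom.L0) / geom.alpha


def simulate_mt(params: MTParams, geom: CellGeometry,
                t_end: float | None = None, sample_dt: float = 0.1,
                state0: MTState | None = None,
                rtol: float = 1e-8, atol: float = 1e-12) -> MTTrajectory:
    """Integrate the MT subsystem over ``[0, t_end]``.

    The stiff system is integrated piecewise between class-extension events;
    at each event the state is padded with a zero-concentration class.
    States are sampled every ``sample_dt`` minutes.
    """
    if t_end is None:
        t_end = geom.t_end
    if state0 is None:
        state0 = MTState.initial(max_classes(geom.L0, params.delta_d))

    events = _extension_times(geom, params, t_end)
    breaks = np.concatenate(([0.0], events[(events > 0) & (events < t_end)], [t_end]))
    samples = np.round(np.arange(0.0, t_end + 0.5 * sample_dt, sample_dt), 9)

    t_out: list[float] = []
    states_out: list[MTState] = []
    state = state0
    for a, b in zip(breaks[:-1], breaks[1:]):
        state = extend_system(state, float(geom.length_at(a)) * (1 + 1e-12), params)
        N = state.N
        seg_samples = samples[(samples >= a) & (samples < b)] if b < t_end else \
            samples[(samples >= a) & (samples <= b)]
        t_eval = np.unique(np.concatenate([seg_samples, [b]]))
        sol = solve_ivp(
            ode_rhs, (a, b), state.to_vector(), method="LSODA", t_eval=t_eval,
            args=(params, geom, N), rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"MT integration failed on [{a:.3f}, {b:.3f}]: {sol.message}")
        in_samples = np.isin(sol.t, seg_samples)
        for ti, yi in zip(sol.t[in_samples], sol.y[:, in_samples].T):
            t_out.append(float(ti))
            states_out.append(MTState.from_vector(yi, N))
        state = MTState.from_vector(sol.y[:, -1], N)  # carry across the break

    return MTTrajectory(t=np.array(t_out), states=states_out, params=params, geom=geom)


def settling_time(t: np.ndarray, counts: np.ndarray, tol: float = 0.05) -> float:
    """Earliest time after which ``counts`` stays within ``tol`` of its
    subsequent running mean (mean over the remaining horizon).

    Returns ``inf`` if the series never settles.
    """
    t = np.asarray(t, float)
    c = np.asarray(counts, float)
    # reverse cumulative mean: m[k] = mean(c[k:])
    m = np.cumsum(c[::-1])[::-1] / np.arange(c.size, 0, -1)
    ok = np.abs(c - m) <= tol * np.abs(m)
    bad = np.nonzero(~ok)[0]
    if bad.size == 0:
        return float(t[0])
    if bad[-1] == c.size - 1:
        return float("inf")
    return float(t[bad[-1] + 1])


def calibrate_nucleation(params: MTParams, geom: CellGeometry,
                         target: float = 3.6, t_start: float = 10.0,
                         t_end: float = 100.0, iterations: int = 3) -> MTParams:
    """Scale ``k_nuc1`` so the time-averaged tip-touching MT count over
    ``[t_start, t_end]`` hits ``target`` (the polymer sector is nearly linear
    in the nucleation rate, so a few multiplicative updates converge)."""
    p = params
    for _ in range(iterations):
        traj = simulate_mt(p, geom, t_end=t_end, sample_dt=0.5)
        counts = traj.full_length_counts()
        mean = counts[traj.t >= t_start].mean()
        if mean <= 0:
            raise RuntimeError("no tip-touching polymers; cannot calibrate")
        p = replace(p, k_nuc1=p.k_nuc1 * target / mean)
        if abs(mean - target) / target < 1e-3:
            break
    return p
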