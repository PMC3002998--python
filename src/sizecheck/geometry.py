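"""Growth law, cylindrical volume bookkeeping, and the fixed normalized mesh.

The cell is a cylinder of constant radius that elongates exponentially and
uniformly, ``L(t) = L0 * exp(alpha * t)``.  All spatial fields live on a fixed
mesh of ``n_points`` equal-width intervals of the normalized coordinate
``xbar = x / L(t)``; each mesh point is the midpoint of its interval and
represents a physical region of the cell that grows with it.

Unit conventions used throughout the package: time in minutes, lengths in
micrometres, volumes in cubic micrometres, concentrations in nanomolar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AVOGADRO = 6.02214076e23

#: copies of a species present per nM of concentration per µm³ of volume
#: (1e-9 mol/L * N_A * 1e-15 L/µm³)
COPIES_PER_NM_UM3 = AVOGADRO * 1e-9 * 1e-15


@dataclass(frozen=True)
class CellGeometry:
    """Exponentially growing cylindrical cell.

    Parameters
    ----------
    L0 : float
        Newborn cell length (µm).
    radius : float
        Cell radius (µm), constant: fission yeast grows only lengthwise.
    alpha : float
        Specific growth rate (min⁻¹); ``ln(2)/doubling_time``.
    t_end : float
        Simulation horizon (min).
    """

    L0: float = 7.0
    radius: float = 1.5
    alpha: float = np.log(2.0) / 100.0
    t_end: float = 100.0

    def __post_init__(self) -> None:
        if self.L0 <= 0 or self.radius <= 0:
            raise ValueError("cell dimensions must be positive")
        if self.alpha < 0:
            raise ValueError("growth rate must be non-negative")

    @classmethod
    def from_doubling_time(
        cls,
        doubling_time: float,
        L0: float = 7.0,
        radius: float = 1.5,
        t_end: float = 100.0,
    ) -> "CellGeometry":
        """Build a geometry from a volume-doubling time in minutes."""
        if doubling_time <= 0:
            raise ValueError("doubling time must be positive")
        return cls(L0=L0, radius=radius, alpha=np.log(2.0) / doubling_time, t_end=t_end)

    def length_at(self, t) -> np.ndarray | float:
        """Cell length L(t) = L0·exp(alpha·t) in µm; ``t`` may be an array."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        out = self.L0 * np.exp(self.alpha * t)
        return out if out.ndim else float(out)

    def volume_at(self, t) -> np.ndarray | float:
        """Cell volume π·r²·L(t) in µm³."""
        return cylinder_volume(self.length_at(t), self.radius)


def cylinder_volume(length, radius: float):
    """Volume of a cylindrical cell in µm³."""
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0) or radius <= 0:
        raise ValueError("cylinder dimensions must be positive")
    out = np.pi * radius**2 * length
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Mesh:
    """Fixed normalized spatial mesh of equal-width interval midpoints.

    ``n_points`` intervals of width ``1/n_points`` tile [0, 1]; mesh point
    ``j`` (0-based) sits at ``(j + 1/2)/n_points``.  ``n_points`` must be even
    so that a central pair of nodes exists, between which microtubules are
    nucleated.
    """

    n_points: int = 100
    xbar: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_points < 2 or self.n_points % 2:
            raise ValueError("n_points must be an even integer >= 2")
        x = (np.arange(self.n_points) + 0.5) / self.n_points
        x.setflags(write=False)
        object.__setattr__(self, "xbar", x)

    @property
    def dx(self) -> float:
        """Normalized interval width."""
        return 1.0 / self.n_points

    @property
    def center_pair(self) -> tuple[int, int]:
        """0-based indices of the two central nodes (49, 50 for 100 points)."""
        return (self.n_points // 2 - 1, self.n_points // 2)

    def real_increment(self, geom: CellGeometry, t: float) -> float:
        """Physical length (µm) represented by one mesh interval at time t."""
        return float(geom.length_at(t)) / self.n_points


def copies_to_concentration(copies: float, volume: float) -> float:
    """Convert a molecule count in a volume (µm³) to a concentration in nM."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    if copies < 0:
        raise ValueError("copies must be non-negative")
    return copies / (COPIES_PER_NM_UM3 * volume)


def concentration_to_copies(conc_nM: float, volume: float) -> float:
    """Convert a concentration in nM to a molecule count in a volume (µm³)."""
    return conc_nM * COPIES_PER_NM_UM3 * volume
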