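"""Mitotic trigger: a zeroth-order ultrasensitive Goldbeter-Koshland switch.

The signalling cascade downstream of Cdr2 (Cdr1, Wee1, Cdc25, Cdc2) is
collapsed into a single covalent-modification cycle operating in the
zeroth-order regime.  The activation rate is proportional to the mean
membrane Cdr2 concentration in the midcell region; the opposing
inactivation rate is constant.  Because the saturation constants are small,
the steady-state active fraction of Cdc2 switches sharply from ~0 to ~1 as
the activation rate crosses the inactivation rate, converting the gradual
midcell Cdr2 increase of a lengthening cell into an all-or-none mitotic
commitment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CellGeometry, cylinder_volume


@dataclass(frozen=True)
class TriggerParams:
    """Goldbeter-Koshland switch parameters.

    ``gain`` (nM⁻¹·min⁻¹-equivalent scale) maps midcell membrane Cdr2 to
    the activation rate ``u``; ``v_inact`` is the constant opposing rate.
    ``J1``/``J2`` are the Michaelis constants of the two converter enzymes
    relative to total substrate; values << 1 give zeroth-order
    ultrasensitivity.  ``threshold`` is the active fraction defining
    commitment to mitosis.
    """

    J1: float = 0.01
    J2: float = 0.01
    v_inact: float = 1.0
    gain: float = 0.017216769779633247
    threshold: float = 0.5
    midcell_window: tuple[float, float] = (0.4, 0.6)

    def __post_init__(self) -> None:
        if self.J1 <= 0 or self.J2 <= 0:
            raise ValueError("J1 and J2 must be positive")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


def goldbeter_koshland(u, v, J1: float, J2: float):
    """Steady-state active fraction of a covalent-modification cycle.

    The standard closed form

        G(u, v, J1, J2) = 2 u J2 / (B + sqrt(B^2 - 4 (v - u) u J2)),
        B = v - u + v J1 + u J2,

    continuous and increasing in the activation rate ``u``, decreasing in
    the inactivation rate ``v``; lies in [0, 1].
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("rates must be non-negative")
    if J1 <= 0 or J2 <= 0:
        raise ValueError("J1 and J2 must be positive")
    B = v - u + v * J1 + u * J2
    disc = B * B - 4.0 * (v - u) * u * J2
    out = np.where(u > 0,
                   2.0 * u * J2 / (B + np.sqrt(np.maximum(disc, 0.0))), 0.0)
    return out if out.ndim else float(out)


def cdc2_series(midcell_cdr2: np.ndarray, params: TriggerParams) -> np.ndarray:
    """Cdc2 active fraction over time, driven memorylessly by midcell Cdr2."""
    u = params.gain * np.asarray(midcell_cdr2, dtype=float)
    return goldbeter_koshland(u, params.v_inact, params.J1, params.J2)


@dataclass(frozen=True)
class TriggerReport:
    """Outcome of trigger detection; ``triggered`` False means the activity
    never crossed the threshold within the simulated horizon."""

    triggered: bool
    t_trigger: float = float("nan")
    L_trigger: float = float("nan")
    V_trigger: float = float("nan")


def detect_trigger(t: np.ndarray, activity: np.ndarray, geom: CellGeometry,
                   params: TriggerParams) -> TriggerReport:
    """First upward threshold crossing of the Cdc2 activity series.

    The crossing time is linearly interpolated between samples; the
    corresponding cell length and cylinder volume are evaluated at that
    time.  Total microtubule disruption, for example, keeps the activity at
    zero and yields a "not triggered" report.
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(activity, dtype=float)
    if t.shape != a.shape:
        raise ValueError("time and activity series must be aligned")
    thr = params.threshold
    above = a >= thr
    cross = np.nonzero(~above[:-1] & above[1:])[0]
    if above[0]:
        t_star = float(t[0])
    elif cross.size:
        i = cross[0]
        t_star = float(np.interp(thr, [a[i], a[i + 1]], [t[i], t[i + 1]]))
    else:
        return TriggerReport(triggered=False)
    L = float(geom.length_at(t_star))
    return TriggerReport(True, t_star, L, cylinder_volume(L, geom.radius))
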