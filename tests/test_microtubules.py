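"""Microtubule subsystem: rate derivations, ODE structure, growth coupling."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sizecheck.geometry import COPIES_PER_NM_UM3, CellGeometry
from sizecheck.microtubules import (MTParams, MTState, count_full_length,
                                    extend_system, k_cat, k_dep_from_velocity,
                                    k_el_from_velocity, max_classes, ode_rhs,
                                    settling_time, simulate_mt)


def _quiet_params(**kw):
    """Parameters with nucleation, catastrophe and feeds off."""
    defaults = dict(k_nuc1=0.0, k_nuc2=0.0, kcat_a=0.0, feed_T=0.0,
                    feed_GTP=0.0)
    defaults.update(kw)
    return MTParams(**defaults)


class TestVelocityDerivedRates:
    def test_elongation_speed_back_substitution(self):
        """A single polymer integrated through the actual ODE must advance
        its tip at the configured velocity when T_T sits at the reference
        concentration."""
        p = _quiet_params()
        geom = CellGeometry(alpha=0.0)
        N = 100
        state = MTState.initial(N, T_T=p.T_T_ref, T_D=0.0)
        state.grow[0] = 1e-6          # one seed polymer, too dilute to
                                      # deplete the tubulin pool
        sol = solve_ivp(ode_rhs, (0.0, 1.5), state.to_vector(),
                        t_eval=[0.5, 1.5], args=(p, geom, N),
                        method="LSODA", rtol=1e-10, atol=1e-16)
        speeds = []
        for y in sol.y.T:
            g = y[3:3 + N]
            speeds.append((g * np.arange(1, N + 1)).sum() / g.sum())
        v_sim = (speeds[1] - speeds[0]) / 1.0 * p.delta_d
        assert v_sim == pytest.approx(p.v_el, rel=0.05)

    def test_shrinkage_speed_back_substitution(self):
        p = _quiet_params()
        geom = CellGeometry(alpha=0.0)
        N = 100
        state = MTState.initial(N, T_T=0.0, T_D=0.0)
        state.shrink[89] = 1e-6       # seed shrinking polymer of 90 subunits
        sol = solve_ivp(ode_rhs, (0.0, 0.5), state.to_vector(),
                        t_eval=[0.1, 0.5], args=(p, geom, N),
                        method="LSODA", rtol=1e-10, atol=1e-16)
        means = []
        for y in sol.y.T:
            s = y[3 + N:3 + 2 * N]
            means.append((s * np.arange(1, N + 1)).sum() / s.sum())
        v_sim = -(means[1] - means[0]) / 0.4 * p.delta_d
        assert v_sim == pytest.approx(p.v_dp, rel=0.05)

    def test_linearity_and_zero(self):
        assert k_el_from_velocity(0.0, 1625, 0.07) == 0.0
        assert k_el_from_velocity(4.0, 1625, 0.07) == pytest.approx(
            2 * k_el_from_velocity(2.0, 1625, 0.07))
        assert k_dep_from_velocity(0.0, 1625, 0.07) == 0.0
        # frozen shrinking polymers: zero rate constant
        assert k_dep_from_velocity(8.0, 1625, 0.07) == pytest.approx(8.0 / 0.07)

    def test_monomers_per_subunit(self):
        assert MTParams().monomers_per_subunit == pytest.approx(113.75)


class TestCatastropheRate:
    def test_monotone_increase_toward_tip(self):
        p = MTParams()
        rates = k_cat(np.arange(1, 51), 50, p)
        assert np.all(np.diff(rates) > 0)
        assert k_cat(50, 50, p) / k_cat(1, 50, p) == pytest.approx(
            np.exp(p.kcat_b * (1 - 1 / 50)))

    def test_mbc_multiplier(self):
        p1, p5 = MTParams(), MTParams(mbc_factor=5.0)
        assert k_cat(25, 50, p5) == pytest.approx(5 * k_cat(25, 50, p1))

    def test_flat_when_exponent_zero(self):
        p = MTParams(kcat_b=0.0)
        assert k_cat(1, 50, p) == pytest.approx(k_cat(50, 50, p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            k_cat(0, 50, MTParams())
        with pytest.raises(ValueError):
            k_cat(51, 50, MTParams())


class TestODEStructure:
    def test_all_rates_off_gives_zero_derivatives(self):
        p = _quiet_params(v_el=0.0, v_dp=0.0, k_ex=0.0)
        geom = CellGeometry(alpha=0.0)
        state = MTState.initial(50, T_T=5000, T_D=400)
        state.grow[:] = 0.1
        state.shrink[:] = 0.05
        dy = ode_rhs(0.0, state.to_vector(), p, geom, 50)
        assert np.allclose(dy, 0.0)

    def test_tubulin_mass_balance_identity(self):
        """With feeds off, reaction fluxes cancel exactly in the total
        monomer-equivalent mass: d(mass)/dt = -alpha * mass."""
        rng = np.random.default_rng(7)
        p = MTParams(feed_T=0.0, feed_GTP=0.0)
        geom = CellGeometry()
        N = 60
        y = np.abs(rng.normal(size=3 + 2 * N)) * 100.0
        dy = ode_rhs(0.0, y, p, geom, N)
        m = p.monomers_per_subunit
        i = np.arange(1, N + 1)
        mass = y[0] + y[1] + m * (i * (y[3:3 + N] + y[3 + N:])).sum()
        dmass = dy[0] + dy[1] + m * (i * (dy[3:3 + N] + dy[3 + N:])).sum()
        assert dmass == pytest.approx(-geom.alpha * mass, rel=1e-10)

    def test_mass_decays_exponentially_with_feeds_off(self):
        p = MTParams(feed_T=0.0, feed_GTP=0.0)
        geom = CellGeometry()
        traj = simulate_mt(p, geom, t_end=15.0, sample_dt=5.0)
        m = p.monomers_per_subunit
        masses = []
        for st in traj.states:
            i = np.arange(1, st.N + 1)
            masses.append(st.T_D + st.T_T
                          + m * (i * (st.grow + st.shrink)).sum())
        expected = masses[0] * np.exp(-geom.alpha * (traj.t - traj.t[0]))
        assert np.allclose(masses, expected, rtol=1e-6)

    def test_nan_rejected(self):
        y = MTState.initial(10).to_vector()
        y[1] = np.nan
        with pytest.raises(FloatingPointError):
            ode_rhs(0.0, y, MTParams(), CellGeometry(), 10)


class TestGrowthCoupling:
    def test_class_count_anchors(self):
        assert max_classes(7.0, 0.07) == 50
        assert max_classes(14.0, 0.07) == 100

    def test_extend_appends_zero_classes(self):
        p = MTParams()
        state = MTState.initial(50)
        state.grow[:] = 1.0
        out = extend_system(state, 14.0, p)
        assert out.N == 100
        assert np.all(out.grow[50:] == 0.0)
        assert np.all(out.shrink[50:] == 0.0)
        assert np.all(out.grow[:50] == 1.0)

    def test_extend_noop_and_shrink_rejected(self):
        p = MTParams()
        state = MTState.initial(60)
        assert extend_system(state, 8.4, p) is state   # N unchanged at 8.4 um
        with pytest.raises(ValueError):
            extend_system(state, 7.0, p)


class TestFullLengthCount:
    def test_zero_state_counts_zero(self):
        geom = CellGeometry()
        assert count_full_length(MTState.initial(50), geom, 0.0, MTParams()) == 0.0

    def test_copies_conversion_scale(self):
        """1 nM of tip-length polymer in a 74 um^3 cell is ~44.6 copies."""
        geom = CellGeometry(L0=10.5)   # volume 74.2 um^3
        state = MTState.initial(max_classes(10.5, 0.07))
        state.grow[-1] = 1.0
        count = count_full_length(state, geom, 0.0, MTParams())
        assert count == pytest.approx(1e-9 * 6.022e23 * 74.2e-15, rel=0.01)

    def test_nonnegative_concentrations_along_run(self, mt_traj_wt):
        for st in mt_traj_wt.states[::50]:
            assert st.grow.min() >= -1e-9
            assert st.shrink.min() >= -1e-9
            assert min(st.T_D, st.T_T, st.GTP) >= 0.0

    def test_longest_class_dominates_late(self, mt_traj_wt):
        st = mt_traj_wt.states[-1]
        conc = st.grow + st.shrink
        assert conc.argmax() >= st.N - 2

    def test_tip_concentration_dilutes_while_count_steady(self, mt_traj_wt):
        """The tip-class concentration falls roughly with 1/volume while
        the tip-touching copy number stays quasi-constant: the hallmark of
        a size-scaling MT system."""
        t = mt_traj_wt.t
        counts = mt_traj_wt.full_length_counts()
        vol = mt_traj_wt.geom.volume_at(t)
        tip_conc = counts / vol
        late = tip_conc[t >= 80].mean()
        early = tip_conc[(t >= 20) & (t <= 40)].mean()
        assert late < 0.75 * early
        assert counts[t >= 10].std() / counts[t >= 10].mean() < 0.05


class TestSettlingTime:
    def test_flat_series_settles_immediately(self):
        t = np.arange(0, 10, 0.1)
        assert settling_time(t, np.full_like(t, 3.0)) == 0.0

    def test_step_series_settles_after_step(self):
        t = np.arange(0, 100, 0.1)
        c = np.where(t < 20, 1.0, 3.0)
        st = settling_time(t, c)
        assert 19.9 <= st <= 20.2

    def test_oscillating_series_settles_only_at_the_end(self):
        # the final sample always matches its own remaining mean, so an
        # alternating series "settles" only at the very last time point
        t = np.arange(0, 10, 0.1)
        c = np.where(np.arange(t.size) % 2 == 0, 1.0, 3.0)
        assert settling_time(t, c) == pytest.approx(t[-1])
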