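"""Forward kinetic models: ODE simulation, first-integral solution, descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fibrilkin as fk
from fibrilkin.kinetics import _crossing_time

T = np.linspace(0.0, 50.0, 400)


def logistic_trace(midpoint=5.0, rate=3.0, times=None):
    t = np.linspace(0, 2 * midpoint, 501) if times is None else times
    f = 1.0 / (1.0 + np.exp(-rate * (t - midpoint)))
    return fk.NormalizedTrace(times=t, fraction_aggregated=f, m_total=100.0)


class TestSimulate:
    def test_no_dynamics_state_constant(self):
        rates = fk.RateConstants()
        traj = fk.simulate_fibril_mass(rates, 100.0, M0=1.0, P0=0.0, times=T)
        assert np.allclose(traj.M, 1.0)
        assert np.allclose(traj.P, 0.0)

    def test_pure_seeded_elongation(self):
        rates = fk.RateConstants(kplus=20.0)
        traj = fk.simulate_fibril_mass(rates, 100.0, M0=1.0, P0=1e-2, times=T)
        # growth starts immediately (no lag) and saturates monotonically
        assert traj.M[1] > traj.M[0]
        assert np.all(np.diff(traj.M) >= -1e-9)
        assert traj.M[-1] == pytest.approx(100.0, rel=1e-4)

    def test_mass_conservation(self, study_rates):
        traj = fk.simulate_fibril_mass(study_rates, 100.0, 1.0, 1e-3, T)
        assert np.max(np.abs(traj.m + traj.M - 100.0)) < 1e-6 * 100.0

    def test_max_growth_rate_matches_first_integral_solution(self, study_rates):
        """Secondary-dominated sigmoid: the ODE's maximal growth rate agrees
        with the independent first-integral route within 2%."""
        t = np.linspace(0, 60, 2000)
        ode = fk.simulate_fibril_mass(study_rates, 100.0, 0.0, 0.0, t).normalized()
        cf = fk.closed_form_fibril_mass(study_rates, 100.0, 0.0, 0.0, t)
        r_ode = np.max(np.gradient(ode.fraction_aggregated, t))
        r_cf = np.max(np.gradient(cf.fraction_aggregated, t))
        assert r_ode == pytest.approx(r_cf, rel=0.02)

    @pytest.mark.parametrize("bad", [
        dict(m_total=-1.0), dict(M0=-0.1), dict(P0=-0.1), dict(M0=200.0),
    ])
    def test_invalid_inputs_raise(self, study_rates, bad):
        kw = dict(m_total=100.0, M0=0.0, P0=0.0, times=T)
        kw.update(bad)
        with pytest.raises(ValueError):
            fk.simulate_fibril_mass(study_rates, **kw)

    def test_non_monotone_grid_raises(self, study_rates):
        with pytest.raises(ValueError):
            fk.simulate_fibril_mass(study_rates, 100.0, times=np.array([0.0, 2.0, 1.0]))


class TestClosedForm:
    def test_initial_and_final_fractions(self, study_rates):
        t = np.linspace(0, 400, 1000)
        tr = fk.closed_form_fibril_mass(study_rates, 100.0, 0.0, 0.0, t)
        assert tr.fraction_aggregated[0] == pytest.approx(0.0, abs=1e-9)
        assert tr.fraction_aggregated[-1] == pytest.approx(1.0, abs=1e-6)

    def test_seeded_initial_condition(self, study_rates):
        tr = fk.closed_form_fibril_mass(study_rates, 100.0, 2.0, 2e-3, T)
        assert tr.fraction_aggregated[0] == pytest.approx(0.02, abs=1e-9)

    @pytest.mark.parametrize("lam_over_kappa,seed_pct", [
        (0.1, 0.0), (0.01, 0.0), (0.1, 2.0), (0.01, 2.0),
    ])
    def test_agreement_with_ode_in_validity_regime(self, lam_over_kappa, seed_pct):
        """sup-norm agreement <= 5% for lambda/kappa <= 0.1, seeds <= 2%."""
        kplus, m_tot, kappa = 20.0, 100.0, 0.4
        k2 = kappa**2 / (2 * kplus * m_tot)
        lam = lam_over_kappa * kappa
        kn = lam**2 / (2 * kplus * m_tot)
        rates = fk.RateConstants(kn=kn, nc=1.0, kplus=kplus, k2=k2)
        M0 = seed_pct / 100.0 * m_tot
        t = np.linspace(0, 80.0 if seed_pct == 0 else 30.0, 800)
        ode = fk.simulate_fibril_mass(rates, m_tot, M0, M0 / 1000.0, t).normalized()
        cf = fk.closed_form_fibril_mass(rates, m_tot, M0, M0 / 1000.0, t)
        assert np.max(np.abs(cf.fraction_aggregated - ode.fraction_aggregated)) <= 0.05

    def test_half_time_matches_ode(self, study_rates):
        t = np.linspace(0, 80, 2000)
        ode = fk.simulate_fibril_mass(study_rates, 100.0, 0.0, 0.0, t).normalized()
        cf = fk.closed_form_fibril_mass(study_rates, 100.0, 0.0, 0.0, t)
        assert fk.half_time(cf) == pytest.approx(fk.half_time(ode), rel=0.05)

    def test_no_pathway_raises(self):
        with pytest.raises(ValueError):
            fk.closed_form_fibril_mass(fk.RateConstants(), 100.0, 0.0, 0.0, T)


class TestDescriptors:
    def test_half_time_symmetric_logistic(self):
        assert fk.half_time(logistic_trace(5.0)) == pytest.approx(5.0, abs=0.01)

    def test_half_time_translation_equivariance(self):
        tr = logistic_trace(5.0)
        shifted = fk.NormalizedTrace(tr.times + 2.0, tr.fraction_aggregated, 100.0)
        assert fk.half_time(shifted) == pytest.approx(fk.half_time(tr) + 2.0, abs=1e-9)

    def test_lag_below_half_time(self):
        tr = logistic_trace(5.0, rate=5.0)
        assert fk.lag_time(tr) < fk.half_time(tr)
        assert fk.lag_time(tr) == pytest.approx(5.0, abs=0.5)

    def test_lag_zero_when_already_past_threshold(self):
        t = np.linspace(0, 10, 100)
        f = 0.3 + 0.7 * t / 10.0
        tr = fk.NormalizedTrace(t, f, 100.0)
        assert fk.lag_time(tr) == 0.0

    def test_seeded_lag_smaller(self, study_rates):
        t = np.linspace(0, 60, 600)
        un = fk.simulate_fibril_mass(study_rates, 100.0, 0.0, 0.0, t).normalized()
        se = fk.simulate_fibril_mass(study_rates, 100.0, 1.0, 1e-3, t).normalized()
        assert fk.lag_time(se) < fk.lag_time(un)

    def test_never_crossing_raises(self):
        t = np.linspace(0, 10, 100)
        tr = fk.NormalizedTrace(t, np.full(100, 0.1), 100.0)
        with pytest.raises(ValueError):
            fk.half_time(tr)

    def test_first_crossing_breaks_ties(self):
        t = np.linspace(0, 3, 4)
        f = np.array([0.0, 0.6, 0.4, 0.9])  # two upward crossings of 0.5
        tr = fk.NormalizedTrace(t, f, 100.0)
        assert _crossing_time(tr, 0.5) < 1.0


class TestScalingExponent:
    M_TOTALS = np.array([25.0, 50.0, 100.0, 200.0])

    def _half_times(self, rates, t_max=600.0):
        out = []
        for m in self.M_TOTALS:
            t = np.linspace(0, t_max, 4000)
            out.append(fk.half_time(fk.closed_form_fibril_mass(rates, m, 0, 0, t)))
        return np.array(out)

    def test_flat_half_times_give_zero(self):
        assert fk.scaling_exponent([5.0] * 4, self.M_TOTALS) == pytest.approx(0.0)

    def test_secondary_dominated_gives_minus_half(self, study_rates):
        ht = self._half_times(study_rates)
        assert fk.scaling_exponent(ht, self.M_TOTALS) == pytest.approx(-0.5, abs=0.05)

    def test_fragmentation_dominated_gives_minus_half(self, study_rates):
        rates = study_rates.with_(k2=0.0, kminus=study_rates.k2)
        ht = self._half_times(rates)
        assert fk.scaling_exponent(ht, self.M_TOTALS) == pytest.approx(-0.5, abs=0.05)

    def test_primary_only_nc2_gives_minus_one(self):
        kplus = 20.0
        kn = 0.4**2 / (2 * kplus * 100.0**2)
        rates = fk.RateConstants(kn=kn, nc=2.0, kplus=kplus)
        ht = self._half_times(rates, t_max=200.0)
        assert fk.scaling_exponent(ht, self.M_TOTALS) == pytest.approx(-1.0, abs=0.05)

    def test_too_few_concentrations_raise(self):
        with pytest.raises(ValueError):
            fk.scaling_exponent([1.0, 2.0], [50.0, 100.0])
        with pytest.raises(ValueError):
            fk.scaling_exponent([1.0, -2.0, 3.0], [25.0, 50.0, 100.0])


class TestSeedMonotonicity:
    def test_seeds_speed_up_when_secondary_active(self, study_rates):
        t = np.linspace(0, 60, 600)
        hts = []
        for pct in (0.0, 0.25, 1.0):
            M0 = pct
            tr = fk.simulate_fibril_mass(study_rates, 100.0, M0, M0 / 1000.0, t)
            hts.append(fk.half_time(tr.normalized()))
        assert hts[0] > hts[1] > hts[2]

    def test_seeds_barely_matter_without_secondary_processes(self):
        kplus = 20.0
        kn = 0.2**2 / (2 * kplus * 100.0)  # lambda = 0.2/h primary-only
        rates = fk.RateConstants(kn=kn, nc=1.0, kplus=kplus)
        t = np.linspace(0, 60, 1200)
        P0 = 1.0 / fk.bulk.DEFAULT_SEED_MEAN_LENGTH  # 1% unsonicated seeds
        un = fk.half_time(fk.simulate_fibril_mass(rates, 100.0, 0, 0, t).normalized())
        se = fk.half_time(
            fk.simulate_fibril_mass(rates, 100.0, 1.0, P0, t).normalized()
        )
        assert abs(se - un) / un < 0.05


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    log_kn=st.floats(-10, -6),
    log_k2=st.floats(-6, -3),
    kminus=st.floats(0, 1e-4),
    seed_pct=st.floats(0, 5),
)
def test_trajectory_invariants(log_kn, log_k2, kminus, seed_pct):
    """Mass conservation, monotone M and m, non-decreasing P for any rates."""
    rates = fk.RateConstants(kn=10.0**log_kn, nc=1.0, kplus=20.0,
                             k2=10.0**log_k2, kminus=kminus)
    m_tot = 100.0
    M0 = seed_pct / 100.0 * m_tot
    traj = fk.simulate_fibril_mass(rates, m_tot, M0, M0 / 1000.0,
                                   np.linspace(0, 40, 200))
    assert np.max(np.abs(traj.m + traj.M - m_tot)) < 1e-6 * m_tot
    assert np.all(np.diff(traj.M) >= -1e-7 * m_tot)
    assert np.all(np.diff(traj.m) <= 1e-7 * m_tot)
    assert np.all(np.diff(traj.P) >= -1e-12)
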