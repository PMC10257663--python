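"""Mean-field chain model: generator assembly, propagation, dead-cell
accounting, phase durations and the two-state exponential baseline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lctcycle as lc
from lctcycle.mean_field import accumulate_dead_discrete, initial_state


class TestGenerator:
    def test_default_dimensions(self, control_rates):
        A = lc.build_generator(control_rates)
        assert A.shape == (28, 28)
        A_dead = lc.build_generator(control_rates, include_dead_compartments=True)
        assert A_dead.shape == (30, 30)

    def test_mass_conservation_without_division_gain(self, control_rates):
        """With no death and division factor 1 the chain conserves mass."""
        A = lc.build_generator(control_rates, division_factor=1.0)
        assert np.abs(A.sum(axis=0)).max() == pytest.approx(0.0, abs=1e-12)

    def test_division_creates_one_extra_cell(self, control_rates):
        """Division factor 2: net inflow +beta4 at the last S-G2 subphase."""
        A = lc.build_generator(control_rates, division_factor=2.0)
        cols = A.sum(axis=0)
        assert cols[-1] == pytest.approx(control_rates.beta[-1])
        assert np.abs(cols[:-1]).max() == pytest.approx(0.0, abs=1e-12)

    def test_dead_compartments_absorb_death_flux(self, control_rates):
        r = control_rates.replace(gamma1=0.02, gamma2=0.03)
        A = lc.build_generator(r, include_dead_compartments=True)
        # with division factor 2 every column except the division column sums
        # to zero once the absorbing rows are included
        cols = A.sum(axis=0)
        assert np.abs(cols[:27]).max() == pytest.approx(0.0, abs=1e-12)

    def test_negative_rate_rejected_with_name(self):
        with pytest.raises(ValueError, match="gamma1"):
            lc.RateSet(alpha=0.4, beta=1.0, gamma1=[-0.1, 0, 0, 0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            lc.RateSet(alpha=[0.4, 0.4], beta=1.0)

    def test_structure_mismatch_rejected(self, control_rates):
        with pytest.raises(ValueError, match="structure"):
            lc.build_generator(control_rates, structure=lc.PhaseStructure(1, 1, 1, 1))


class TestSimulateMeanField:
    def test_null_dynamics(self):
        r = lc.RateSet(alpha=0.0, beta=0.0)
        traj = lc.simulate_mean_field(r, 0.6)
        assert np.allclose(traj.total, 1.0)
        assert np.allclose(traj.dead_cumulative, 0.0)
        assert np.allclose(traj.g1_total, 0.6)

    def test_pure_death_closed_form(self):
        """No progression, uniform hazard gamma: total(t) = exp(-gamma t)."""
        g = 0.1
        r = lc.RateSet(alpha=0.0, beta=0.0, gamma1=g, gamma2=g)
        traj = lc.simulate_mean_field(r, 0.75)
        assert np.abs(traj.total - np.exp(-g * traj.times)).max() < 1e-10
        assert np.abs(traj.dead_cumulative - (1 - np.exp(-g * traj.times))).max() < 1e-10

    def test_step_composition(self, control_rates):
        """k steps of dt equal one step of k*dt (semigroup property)."""
        r = control_rates.replace(gamma1=0.01, gamma2=0.02)
        fine = lc.simulate_mean_field(r, 0.7, np.linspace(0, 96, 193))
        coarse = lc.simulate_mean_field(r, 0.7, np.linspace(0, 96, 5))
        idx = np.searchsorted(fine.times, coarse.times)
        assert np.allclose(fine.total[idx], coarse.total, rtol=1e-8)
        assert np.allclose(fine.dead_cumulative[idx], coarse.dead_cumulative,
                           rtol=1e-8, atol=1e-12)

    def test_totals_are_sums_of_phase_counts(self, control_rates):
        traj = lc.simulate_mean_field(control_rates, 0.75)
        assert np.allclose(traj.total, traj.g1_total + traj.sg2_total)

    def test_dead_cumulative_monotone(self, control_rates):
        r = control_rates.replace(gamma1=0.03, gamma2=0.01)
        traj = lc.simulate_mean_field(r, 0.75)
        assert np.all(np.diff(traj.dead_cumulative) >= -1e-12)
        assert np.all(traj.dead_cumulative >= -1e-12)

    def test_non_uniform_grid_rejected(self, control_rates):
        with pytest.raises(ValueError, match="uniform"):
            lc.simulate_mean_field(control_rates, 0.7, np.array([0.0, 1.0, 3.0]))

    def test_bad_initial_fraction_rejected(self, control_rates):
        with pytest.raises(ValueError, match="initial_g1_fraction"):
            lc.simulate_mean_field(control_rates, 1.2)

    @pytest.mark.parametrize("spread", ["uniform", "first_subphase", "stationary"])
    def test_init_spread_modes(self, control_rates, spread):
        x = initial_state(control_rates.structure, 0.6, spread, rates=control_rates)
        assert x.sum() == pytest.approx(1.0)
        assert x[:8].sum() == pytest.approx(0.6)
        assert np.all(x >= 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.1, 2.0), st.floats(0.1, 2.0), st.floats(0.0, 1.0))
    def test_conservation_property(self, a, b, f):
        """Division factor 1, no death: live mass stays exactly 1."""
        r = lc.RateSet(alpha=a, beta=b)
        traj = lc.simulate_mean_field(r, f, np.linspace(0, 24, 25),
                                      division_factor=1.0)
        assert np.abs(traj.total - 1.0).max() < 1e-8


class TestDeadAccounting:
    def test_zero_death_gives_zero(self, control_rates):
        traj = lc.simulate_mean_field(control_rates, 0.75)
        assert np.allclose(accumulate_dead_discrete(traj), 0.0)

    def test_pure_death_single_part_within_one_percent(self):
        """Single-compartment pure death: N(96) ~ 1 - exp(-9.6) at dt=0.5."""
        r = lc.RateSet(alpha=0.0, beta=0.0, gamma1=0.1, gamma2=0.1,
                       structure=lc.PhaseStructure(1, 1, 1, 1))
        traj = lc.simulate_mean_field(r, 1.0)
        n96 = accumulate_dead_discrete(traj)[-1]
        target = 1 - np.exp(-9.6)
        assert abs(n96 - target) / target < 0.01

    def test_matches_absorbing_compartments_to_quadrature_error(self, control_rates):
        r = control_rates.replace(gamma1=[0.02, 0.01, 0.03, 0.0],
                                  gamma2=[0.0, 0.02, 0.01, 0.04])
        traj = lc.simulate_mean_field(r, 0.7)
        disc = accumulate_dead_discrete(traj)
        assert np.abs(disc - traj.dead_cumulative).max() < 0.01

    def test_unit_weight_reproduces_bare_sum(self, control_rates):
        r = control_rates.replace(gamma1=0.02)
        traj = lc.simulate_mean_field(r, 0.7)
        bare = accumulate_dead_discrete(traj, weight="unit")
        assert np.allclose(bare, np.cumsum(traj.death_rate_series))


class TestPhaseDurations:
    def test_homogeneous_g1(self):
        r = lc.RateSet(alpha=0.4, beta=1.0)
        g1, sg2 = lc.average_phase_durations(r)
        assert g1 == pytest.approx(4 * 2 / 0.4)   # 20 H
        assert sg2 == pytest.approx(4 * 5 / 1.0)  # 20 H

    def test_death_rates_do_not_enter(self):
        a = lc.average_phase_durations(lc.RateSet(alpha=0.4, beta=1.0))
        b = lc.average_phase_durations(lc.RateSet(alpha=0.4, beta=1.0,
                                                  gamma1=0.5, gamma2=0.5))
        assert a == b

    def test_zero_progression_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            lc.average_phase_durations(lc.RateSet(alpha=0.0, beta=1.0))

    def test_erlang_mean_identity(self):
        """Equal part rates: phase exit time is Erlang(n_subphases, rate)
        whose mean n/rate equals the per-part sum."""
        rate = 0.37
        r = lc.RateSet(alpha=rate, beta=1.0)
        g1, _ = lc.average_phase_durations(r)
        assert g1 == pytest.approx(8 / rate)


class TestExponentialBaseline:
    def test_all_rates_zero_constant(self):
        traj = lc.simulate_exponential_baseline(0, 0, 0, 0, 0.5)
        assert np.allclose(traj.total, 1.0)

    def test_growth_at_dominant_eigenvalue(self):
        a = b = 0.1
        traj = lc.simulate_exponential_baseline(a, b, 0, 0, 0.6)
        lam = np.linalg.eigvals(np.array([[-a, 2 * b], [a, -b]])).real.max()
        # after the transient, log-growth per step approaches lam * dt
        growth = np.diff(np.log(traj.total))[-10:]
        assert np.allclose(growth, lam * 0.5, rtol=1e-6)

    def test_no_sustained_g1_fraction_oscillation(self):
        """Detrended G1-fraction amplitude decays: the memoryless two-state
        model cannot synchronize the population."""
        traj = lc.simulate_exponential_baseline(0.25, 0.3, 0.01, 0.02, 0.9)
        f = traj.frac_g1
        early = np.ptp(f[:48])
        late = np.ptp(f[-48:])
        assert late < 0.05 * max(early, 1e-12) or late < 1e-9

    def test_strict_paper_gamma_variant(self):
        """The printed S-G2 loss term reuses gamma1; variant differs from the
        corrected form exactly when gamma1 != gamma2."""
        kw = dict(alpha=0.2, beta=0.3, initial_g1_fraction=0.7,
                  times=np.linspace(0, 48, 49))
        fixed = lc.simulate_exponential_baseline(gamma1=0.05, gamma2=0.0, **kw)
        strict = lc.simulate_exponential_baseline(gamma1=0.05, gamma2=0.0,
                                                  strict_paper_gamma=True, **kw)
        assert not np.allclose(fixed.total, strict.total)
        same = lc.simulate_exponential_baseline(gamma1=0.05, gamma2=0.05, **kw)
        strict_same = lc.simulate_exponential_baseline(
            gamma1=0.05, gamma2=0.05, strict_paper_gamma=True, **kw)
        assert np.allclose(same.total, strict_same.total)
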