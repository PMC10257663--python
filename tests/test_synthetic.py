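"""Stochastic single-cell simulator: distributional correctness,
reproducibility, fate accounting and dataset generation."""

import numpy as np
import pytest
from scipy import stats

import lctcycle as lc
from lctcycle.synthetic import complete_phase_durations


class TestSimulateCells:
    def test_seed_reproducibility(self, control_rates):
        a = lc.simulate_cells(control_rates, n0=300, seed=42)
        b = lc.simulate_cells(control_rates, n0=300, seed=42)
        assert a.equals(b)
        c = lc.simulate_cells(control_rates, n0=300, seed=43)
        assert not a.equals(c)

    def test_overwhelming_death_kills_everything(self, control_rates):
        r = control_rates.replace(gamma1=control_rates.alpha[0] * 1e3,
                                  gamma2=control_rates.beta[0] * 1e3)
        recs = lc.simulate_cells(r, n0=500, seed=0)
        assert set(recs["fate"]) <= {"died_g1", "died_sg2"}
        assert (recs["fate"] == "divided").sum() == 0

    def test_g1_durations_are_erlang(self):
        """Zero death, equal subphase rates: G1 transit ~ Erlang(8, alpha)."""
        alpha = 0.4
        r = lc.RateSet(alpha=alpha, beta=5.0)
        recs = lc.simulate_cells(r, n0=5000, initial_g1_fraction=1.0,
                                 t_max=150.0, seed=7,
                                 init_spread="first_subphase",
                                 max_cells=200_000)
        dur = complete_phase_durations(recs, "G1")
        founder_dur = dur[:5000]
        assert founder_dur.size >= 4900
        ks = stats.kstest(founder_dur, stats.gamma(a=8, scale=1 / alpha).cdf)
        assert ks.pvalue > 0.01
        assert founder_dur.mean() == pytest.approx(8 / alpha, rel=0.05)

    def test_phase_durations_uncorrelated(self, control_rates):
        """Paired per-cell (G1, S-G2) durations are independent by
        construction: |r| < 0.1 at n = 1000."""
        recs = lc.simulate_cells(control_rates, n0=1500,
                                 initial_g1_fraction=1.0, t_max=150.0,
                                 seed=11, init_spread="first_subphase",
                                 max_cells=300_000)
        div = recs[(recs["fate"] == "divided")
                   & (recs["start_subphase"] == 0)
                   & recs["g1s_time"].notna()]
        g1 = (div["g1s_time"] - div["birth_time"]).to_numpy()[:1000]
        sg2 = (div["end_time"] - div["g1s_time"]).to_numpy()[:1000]
        assert g1.size == 1000
        r, n = lc.phase_correlation(g1, sg2)
        assert abs(r) < 0.1

    def test_heterogeneous_part_rates_duration_mean(self):
        """Mean simulated G1 duration matches the per-part sum for unequal
        part rates (hypoexponential transit)."""
        alpha = np.array([0.2, 0.4, 0.8, 0.4])
        r = lc.RateSet(alpha=alpha, beta=5.0)
        recs = lc.simulate_cells(r, n0=5000, initial_g1_fraction=1.0,
                                 t_max=250.0, seed=3,
                                 init_spread="first_subphase",
                                 max_cells=400_000)
        dur = complete_phase_durations(recs, "G1")[:5000]
        expected = np.sum(2 / alpha)
        assert dur.mean() == pytest.approx(expected, rel=0.03)

    def test_population_cap_flags_and_bounds(self, control_rates):
        recs = lc.simulate_cells(control_rates, n0=400, t_max=96.0, seed=5,
                                 max_cells=600)
        assert recs.attrs["capped"]
        assert len(recs) <= 600

    def test_censoring_at_horizon(self, control_rates):
        recs = lc.simulate_cells(control_rates, n0=200, t_max=10.0, seed=9)
        cens = recs[recs["fate"] == "censored"]
        assert (cens["end_time"] == 10.0).all()
        assert recs["end_time"].max() <= 10.0


class TestEnsembleEquivalence:
    def test_ensemble_mean_matches_mean_field(self, times):
        """Per-founder ensemble means equal the mean-field trajectory
        within 3 Monte-Carlo SE (the simulator is the exact stochastic
        counterpart of the ODE system)."""
        r = lc.RateSet(alpha=[0.55, 0.3, 0.7, 0.45], beta=[1.2, 0.8, 0.6, 1.0],
                       gamma1=0.015, gamma2=0.02)
        n0 = 2000
        recs = lc.simulate_cells(r, n0=n0, initial_g1_fraction=0.7, seed=101)
        em = lc.ensemble_mean(recs, times, n0=n0)
        mf = lc.simulate_mean_field(r, 0.7, times)
        for key, model in (("g1", mf.g1_total), ("sg2", mf.sg2_total),
                           ("dead", mf.dead_cumulative)):
            diff = np.abs(em[f"{key}_mean"].to_numpy() - model)
            bound = 3 * em[f"{key}_se"].to_numpy() + 1e-9
            assert np.all(diff <= bound), key


class TestFateSummary:
    def test_no_death_everything_divides(self, control_rates):
        recs = lc.simulate_cells(control_rates, n0=400, t_max=300.0, seed=2,
                                 max_cells=400_000)
        s = lc.fate_summary(recs)
        assert s["divided_fraction"] > 0.999
        assert s["relative_death_count"] == 0.0

    def test_pure_death_relative_deaths_approach_one(self):
        r = lc.RateSet(alpha=0.0, beta=0.0, gamma1=0.3, gamma2=0.3)
        recs = lc.simulate_cells(r, n0=1000, t_max=96.0, seed=4)
        s = lc.fate_summary(recs)
        assert s["relative_death_count"] > 0.99
        assert s["divided_fraction"] == 0.0

    def test_relative_deaths_match_mean_field(self, control_rates, times):
        r = control_rates.replace(gamma1=0.02, gamma2=0.01)
        n0 = 3000
        recs = lc.simulate_cells(r, n0=n0, initial_g1_fraction=0.75, seed=6)
        s = lc.fate_summary(recs)
        em = lc.ensemble_mean(recs, times, n0=n0)
        mf = lc.simulate_mean_field(r, 0.75, times)
        se = em["dead_se"].to_numpy()[-1]
        assert abs(s["relative_death_count"] - mf.dead_cumulative[-1]) <= 3 * se + 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lc.fate_summary(None)


class TestDatasetGeneration:
    def test_normalization_near_one_at_start(self, g1_blocker):
        ds = lc.generate_dose_response_dataset(g1_blocker, [0.0, 50.0],
                                               replicates=2, n0=400,
                                               noise_cv=0.05, seed=12)
        first = ds.population.groupby(["concentration_nM", "replicate"]).first()
        assert np.allclose(first["count_norm"], 1.0, atol=0.2)

    def test_seeded_determinism(self, g1_blocker):
        kw = dict(replicates=2, n0=300, noise_cv=0.05, seed=21)
        a = lc.generate_dose_response_dataset(g1_blocker, [0.0, 50.0], **kw)
        b = lc.generate_dose_response_dataset(g1_blocker, [0.0, 50.0], **kw)
        assert a.population.equals(b.population)

    def test_noiseless_replicates_match_mean_field(self, control_rates):
        """Replicate-averaged noiseless counts track the expected
        trajectory within 2% everywhere (n0 = 5000 per replicate)."""
        prof = lc.DrugResponseProfile("none", control_rates, ec50=1.0,
                                      steepness=1.0)
        ds = lc.generate_dose_response_dataset(
            prof, [0.0], replicates=3, n0=5000, noise_cv=0.0, seed=31,
            cadence=0.5, t_max=96.0, initial_g1_fraction=0.75)
        avg = ds.population.groupby("time_h")["count_norm"].mean()
        mf = lc.simulate_mean_field(control_rates, 0.75)
        # normalize the model the same way the data are normalized
        model = mf.total / mf.total[:3].mean()
        rel = np.abs(avg.to_numpy() - model) / model
        assert rel.max() < 0.02

    def test_cytostatic_vs_cytotoxic_endpoints(self, g1_blocker, s_phase_drug):
        """Saturating G1 blocker: counts plateau at/above start (cytostatic);
        death-inducing S-phase drug at high dose: counts fall below start."""
        ds_stat = lc.generate_dose_response_dataset(
            g1_blocker, [5000.0], replicates=2, n0=800, noise_cv=0.02, seed=41)
        final_stat = ds_stat.population.groupby("replicate")["count_norm"].last().mean()
        assert final_stat >= 1.0

        ds_tox = lc.generate_dose_response_dataset(
            s_phase_drug, [200.0], replicates=2, n0=800, noise_cv=0.02, seed=42)
        final_tox = ds_tox.population.groupby("replicate")["count_norm"].last().mean()
        assert final_tox < 1.0

    def test_small_n0_warns(self, g1_blocker):
        with pytest.warns(UserWarning, match="small"):
            lc.generate_dose_response_dataset(g1_blocker, [0.0], replicates=1,
                                              n0=50, seed=1)

    def test_metadata_records_ground_truth(self, g1_blocker):
        ds = lc.generate_dose_response_dataset(g1_blocker, [0.0], replicates=1,
                                               n0=200, seed=8)
        assert ds.metadata["seed"] == 8
        assert ds.metadata["true_profile"] is g1_blocker
        assert "noise_cv" in ds.metadata
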