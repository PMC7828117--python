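import dataclasses

import numpy as np
import pytest

from nanomsc_pkpd.dosing import msc_efficacy_regimen, single_bolus
from nanomsc_pkpd.simulate import (
    PKProfiles,
    Scenario,
    dominant_form_crossover,
    run_scenarios,
    simulate_individual_pkpd,
    simulate_pk_profiles,
    simulate_population,
    standard_scenarios,
)


class TestPKProfiles:
    def test_total_is_sum_of_forms(self, params):
        prof = simulate_pk_profiles(params, single_bolus(5000.0, "msc"),
                                    times=np.arange(0.0, 48.1, 0.25))
        for series in (prof.plasma, prof.lung):
            assert np.allclose(series["total"],
                               series["free"] + series["np"] + series["msc"],
                               rtol=1e-12)

    def test_conservation_audit_passes(self, params):
        simulate_pk_profiles(params, single_bolus(5000.0, "msc"),
                             times=np.arange(0.0, 288.1, 0.5),
                             conservation_audit=True)

    def test_wrong_layer_for_arm_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_pk_profiles(params, single_bolus(5000.0, "msc"),
                                 arm="ptx_solution")

    def test_msc_lung_series_monotone_after_peak(self, params):
        # the cell-associated form shows a mono-exponential decline in lung
        prof = simulate_pk_profiles(params, single_bolus(5000.0, "msc"),
                                    times=np.arange(0.0, 288.1, 0.5))
        msc = prof.lung["msc"]
        peak = int(np.argmax(msc))
        assert np.all(np.diff(msc[peak:]) <= 1e-9)

    def test_long_format_export(self, params):
        prof = simulate_pk_profiles(params, single_bolus(5000.0, "msc"),
                                    times=np.arange(0.0, 4.1, 0.5))
        df = prof.to_frame()
        assert set(df.tissue) == {"plasma", "lung"}
        assert set(df.form) == {"free", "np", "msc", "total"}


class TestCrossover:
    def test_free_form_dominates_lung_near_64h(self, params):
        prof = simulate_pk_profiles(params, single_bolus(5000.0, "msc"),
                                    times=np.arange(0.0, 100.1, 0.5))
        t = dominant_form_crossover(prof)
        assert t == pytest.approx(63.3, abs=1.0)

    def test_already_dominant_returns_first_grid_time(self, params):
        times = np.arange(0.0, 5.1, 0.5)
        n = times.size
        prof = PKProfiles(times=times, arm="nano_msc",
                          plasma={}, lung={"free": np.full(n, 2.0),
                                           "np": np.ones(n),
                                           "msc": np.zeros(n)})
        assert dominant_form_crossover(prof) == 0.0

    def test_no_crossover_sentinel(self, params):
        prof = simulate_pk_profiles(params, single_bolus(5000.0, "msc"),
                                    times=np.arange(0.0, 10.1, 0.5))
        assert dominant_form_crossover(prof) is None

    def test_coarse_grid_rejected(self, params):
        prof = simulate_pk_profiles(params, single_bolus(5000.0, "msc"),
                                    times=np.arange(0.0, 100.1, 1.0))
        with pytest.raises(ValueError):
            dominant_form_crossover(prof)


class TestIndividualPKPD:
    def test_untreated_exponential_and_eta_scaling(self, params_dyn):
        ts = np.linspace(0.0, 500.0, 6)
        base = simulate_individual_pkpd(params_dyn, None, "control", eta=0.0,
                                        times=ts)
        expected = params_dyn.pd.TVBL["control"] * np.exp(
            params_dyn.pd.Kg0["control"] * ts)
        assert np.allclose(base.TV, expected, rtol=1e-8)
        doubled = simulate_individual_pkpd(params_dyn, None, "control",
                                           eta=np.log(2.0), times=ts)
        assert np.allclose(doubled.TV, 2.0 * base.TV, rtol=1e-8)

    def test_stronger_kill_never_raises_burden(self, params_dyn):
        ts = np.linspace(0.0, 600.0, 13)
        reg = msc_efficacy_regimen()
        prev = None
        for kmax in (0.001, 0.00343, 0.01):
            p = params_dyn.with_(pd=dataclasses.replace(params_dyn.pd,
                                                        Kmax_PTX=kmax))
            tv = simulate_individual_pkpd(p, reg, "nano_msc", times=ts).TV.values
            if prev is not None:
                assert np.all(tv <= prev + 1e-9)
            prev = tv


class TestPopulation:
    def test_zero_bsv_collapses_bands(self, params_dyn):
        p = params_dyn.with_(pd=dataclasses.replace(params_dyn.pd,
                                                    omega_TVBL=0.0))
        res = simulate_population(p, None, "control", n=20, seed=1,
                                  times=np.linspace(0, 336, 5))
        assert np.allclose(res.p10, res.median)
        assert np.allclose(res.p90, res.median)

    def test_seed_determinism(self, params_dyn):
        a = simulate_population(params_dyn, None, "control", n=15, seed=7,
                                times=np.linspace(0, 336, 5))
        b = simulate_population(params_dyn, None, "control", n=15, seed=7,
                                times=np.linspace(0, 336, 5))
        assert np.array_equal(a.trajectories, b.trajectories)

    def test_bands_monotone_in_probability(self, params_dyn):
        res = simulate_population(params_dyn, msc_efficacy_regimen(),
                                  "nano_msc", n=30, seed=3,
                                  times=np.linspace(0, 1512, 10))
        assert np.all(res.p10 <= res.median + 1e-12)
        assert np.all(res.median <= res.p90 + 1e-12)

    def test_median_matches_typical_untreated_trajectory(self, params_dyn):
        # the median of a log-normal baseline is its typical value; with
        # n = 4000 subjects the sample median of the burden at any time
        # matches the closed form within sampling error (~2%)
        ts = np.array([0.0, 168.0, 336.0])
        res = simulate_population(params_dyn, None, "control", n=4000, seed=11,
                                  times=ts)
        expected = params_dyn.pd.TVBL["control"] * np.exp(
            params_dyn.pd.Kg0["control"] * ts)
        assert np.allclose(res.median, expected, rtol=0.05)

    def test_ruv_observations_returned_on_request(self, params_dyn):
        res = simulate_population(params_dyn, None, "control", n=5, seed=2,
                                  times=np.linspace(0, 336, 4), with_ruv=True)
        assert res.observations is not None
        assert res.observations.shape == res.trajectories.shape
        assert np.all(res.observations > -1e-12)


class TestScenarios:
    def test_duplicate_labels_rejected(self, params_dyn):
        s = standard_scenarios()["krel"][0]
        with pytest.raises(ValueError):
            run_scenarios(params_dyn, [s, s], n=2, seed=0)

    def test_identical_scenarios_identical_summaries(self, params_dyn):
        reg = msc_efficacy_regimen()
        a = Scenario("a", reg)
        b = Scenario("b", reg)
        df = run_scenarios(params_dyn, [a, b], n=8, seed=5,
                           times=np.linspace(0, 1512, 8))
        assert df.median_TV.iloc[0] == pytest.approx(df.median_TV.iloc[1])

    def test_standard_grids_cover_published_scans(self):
        grids = standard_scenarios()
        assert [s.Krel for s in grids["krel"]] == [0.00425, 0.0085, 0.017]
        assert [s.Kexo for s in grids["kexo"]] == [0.06, 0.081, 0.1]
        assert len(grids["dose"]) == 4 and len(grids["interval"]) == 3

    def test_dose_monotonicity_small_population(self, params_dyn):
        df = run_scenarios(params_dyn, standard_scenarios()["dose"], n=12,
                           seed=9, times=np.linspace(0, 1512, 10))
        med = df.set_index("scenario").median_TV
        assert med["maint_0.25e6"] >= med["maint_0.5e6"] >= \
            med["maint_0.75e6"] >= med["maint_2e6"]
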