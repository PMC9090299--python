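"""Rate estimation: round trips, identifiability conventions, derived stats."""

import numpy as np
import pandas as pd
import pytest

from rrnapipe import (
    DataError,
    FitOptions,
    RateParameters,
    derived_rate_stats,
    fit_per_probe,
    fit_timecourse,
    run_recovery_study,
    summarize_ranges,
)
from rrnapipe import synthetic


@pytest.fixture(scope="module")
def noiseless_table():
    return synthetic.gen_timecourse()


@pytest.fixture(scope="module")
def noiseless_fit(noiseless_table):
    return fit_timecourse(noiseless_table, synthetic.default_schedule())


class TestFitRoundTrip:
    def test_noiseless_recovery_within_0p1_percent(self, noiseless_fit):
        true = synthetic.default_true_params()
        for reg in ("baseline22", "heat37"):
            est, tr = noiseless_fit.params_by_regime[reg], true[reg]
            for name in ("sigma", "k45", "k35", "alpha", "kpa3"):
                assert getattr(est, name) == pytest.approx(
                    getattr(tr, name), rel=1e-3
                ), f"{reg}.{name}"

    def test_probe_scales_recovered(self, noiseless_fit):
        for probe, truth in synthetic.DEFAULT_PROBE_SCALES.items():
            assert noiseless_fit.probe_scale[probe] == pytest.approx(truth, rel=1e-3)

    def test_converged_flag_and_sse(self, noiseless_fit, noiseless_table):
        assert noiseless_fit.converged
        assert noiseless_fit.sse >= 0
        assert noiseless_fit.sse < 1e-10
        assert noiseless_fit.n_obs == len(noiseless_table)

    def test_per_probe_fit_recovers_each_probe(self, noiseless_table):
        fits = fit_per_probe(noiseless_table, synthetic.default_schedule())
        assert set(fits) == {"p23", "p43", "p6"}
        ranges = summarize_ranges(fits)
        lo, hi = ranges["pct_reduction_k45"]
        assert lo == pytest.approx(70.0, abs=0.5)
        assert hi == pytest.approx(70.0, abs=0.5)


class TestFitInvariances:
    def test_scale_invariance_per_probe(self, noiseless_table, noiseless_fit):
        scaled = noiseless_table.copy()
        mask = scaled["probe"] == "p43"
        scaled.loc[mask, "value"] *= 3.0
        refit = fit_timecourse(scaled, synthetic.default_schedule())
        for reg in ("baseline22", "heat37"):
            a = noiseless_fit.params_by_regime[reg]
            b = refit.params_by_regime[reg]
            for name in ("sigma", "k45", "k35", "alpha", "kpa3"):
                assert getattr(b, name) == pytest.approx(
                    getattr(a, name), rel=1e-6, abs=1e-9
                )
        assert refit.probe_scale["p43"] == pytest.approx(
            3.0 * noiseless_fit.probe_scale["p43"], rel=1e-6
        )
        assert refit.probe_scale["p23"] == pytest.approx(
            noiseless_fit.probe_scale["p23"], rel=1e-6
        )

    def test_insufficient_data_errors(self):
        sched = synthetic.default_schedule()
        tc = synthetic.gen_timecourse()
        one_species = tc[tc["species"] == "45S"]
        with pytest.raises(DataError, match="insufficient data"):
            fit_timecourse(one_species, sched)
        few_times = tc[tc["time_h"].isin([0.0, 2.0, 3.0])]
        with pytest.raises(DataError, match="insufficient data"):
            fit_timecourse(few_times, sched)

    def test_missing_t0_rejected(self):
        tc = synthetic.gen_timecourse()
        with pytest.raises(DataError, match="insufficient data"):
            fit_timecourse(tc[tc["time_h"] > 0], synthetic.default_schedule())

    def test_negative_values_rejected(self):
        tc = synthetic.gen_timecourse()
        tc.loc[0, "value"] = -1.0
        with pytest.raises(DataError, match="invalid observations"):
            fit_timecourse(tc, synthetic.default_schedule())


class TestDerivedStats:
    def test_examples(self):
        p22 = RateParameters(sigma=1, k45=0.02, k35=0.072, alpha=0.5, kpa3=0.01)
        p37 = RateParameters(sigma=1, k45=0.01, k35=0.072, alpha=0.5, kpa3=0.025)
        d = derived_rate_stats(p22, p37)
        assert d.pct_reduction_k45 == pytest.approx(50.0)
        assert d.alpha_k35_s == pytest.approx(1.0e-5)  # 0.5 * 0.072 / 3600
        assert d.fold_kpa3 == pytest.approx(2.5)
        assert d.k4_comparator == pytest.approx(2.4e-5)

    def test_identity_gives_null_changes(self):
        p = RateParameters(sigma=2, k45=0.3, k35=0.2, alpha=0.6, kpa3=0.1)
        d = derived_rate_stats(p, p)
        assert d.pct_reduction_k45 == pytest.approx(0.0)
        assert d.pct_reduction_35S_to_PA3 == pytest.approx(0.0)
        assert d.fold_kpa3 == pytest.approx(1.0)

    def test_zero_baseline_rate_rejected(self):
        p22 = RateParameters(sigma=1, k45=0.1, k35=0.1, alpha=0.0, kpa3=0.1)
        p37 = RateParameters(sigma=1, k45=0.1, k35=0.1, alpha=0.5, kpa3=0.1)
        with pytest.raises(DataError, match="undefined ratio"):
            derived_rate_stats(p22, p37)


class TestRecoveryStudy:
    def test_noiseless_study_has_zero_error(self):
        rep = run_recovery_study(
            synthetic.default_true_params(),
            synthetic.default_schedule(),
            noise_cv=0.0,
            n_replicates=1,
            seed=7,
        )
        assert np.all(np.abs(rep["bias"]) < 1e-6)
        assert np.all(rep["rmse"] < 1e-6)

    def test_deterministic_given_seed(self):
        kwargs = dict(
            true_params_by_regime=synthetic.default_true_params(),
            schedule=synthetic.default_schedule(),
            noise_cv=0.08,
            n_replicates=2,
            seed=11,
        )
        a = run_recovery_study(**kwargs)
        b = run_recovery_study(**kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_cv_rejected(self):
        with pytest.raises(DataError, match="invalid noise level"):
            run_recovery_study(
                synthetic.default_true_params(),
                synthetic.default_schedule(),
                noise_cv=-0.1,
                n_replicates=1,
                seed=0,
            )

    def test_denser_sampling_reduces_error(self):
        # 12 vs 6 time points at the same noise level: RMSE should shrink
        common = dict(
            true_params_by_regime=synthetic.default_true_params(),
            schedule=synthetic.default_schedule(),
            noise_cv=0.10,
            n_replicates=12,
            seed=3,
        )
        dense = dict(synthetic.default_design())
        dense["times"] = [0, 2, 3, 4, 6, 8, 24, 26, 27, 30, 32, 48]
        sparse = dict(synthetic.default_design())
        # sparsest design the fit accepts: 4 points per regime
        sparse["times"] = [0, 3, 6, 24, 26, 30, 32, 48]
        r12 = run_recovery_study(design=dense, **common)
        r6 = run_recovery_study(design=sparse, **common)
        assert r12["rmse"].median() < r6["rmse"].median()
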