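import math
import warnings

import numpy as np
import pytest

from canidclock.clock import (
    ClockTrainingConfig,
    cross_species_transfer,
    fit_clock,
    loocv_evaluate,
    predict_age,
    preselect_sites,
    weight_correlation,
)
from canidclock.io_formats import ClockEntry, ClockModel, SampleMeta, SiteKey

from conftest import make_freq

CFG_FAST = ClockTrainingConfig(n_penalties=40, seed=0)


def independent_clock_eval(model, freq):
    """Dot-product + exp oracle coded separately from predict_age."""
    out = []
    for j in range(len(freq.samples)):
        acc = model.intercept
        for e in model.entries:
            i = freq.sites.index(e.site)
            acc += e.coef * freq.F[i, j]
        out.append(math.exp(acc))
    return out


class TestPreselect:
    def test_constant_site_never_selected(self):
        ages = np.array([1.0, 2.0, 4.0, 8.0])
        F = np.vstack([np.full(4, 0.5), np.log(ages) / 10])
        sel = preselect_sites(make_freq(F), ages, threshold=0.3)
        assert list(sel) == [1]

    def test_linear_function_of_age_selected(self):
        ages = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        F = (ages / 10.0)[None, :]
        sel = preselect_sites(make_freq(F), ages, threshold=0.3, transform="raw")
        assert list(sel) == [0]

    def test_null_selection_rate_matches_tail_mass(self):
        """With no age signal the selected fraction matches P(|r| > 0.3)
        under the null (t-distributed r, n = 50)."""
        from scipy import stats

        rng = np.random.default_rng(123)
        n = 50
        F = rng.uniform(0, 1, size=(4000, n))
        ages = rng.uniform(1, 10, size=n)
        sel = preselect_sites(make_freq(F), ages, threshold=0.3)
        t_stat = 0.3 * np.sqrt(n - 2) / np.sqrt(1 - 0.09)
        expected = 2 * stats.t.sf(t_stat, df=n - 2)
        frac = sel.size / 4000
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(expected / 4000))


class TestFitAndPredict:
    def test_single_collinear_predictor_recovers_log_age(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(1, 12, 40)
        F = (np.log(ages) / 6 + 0.3)[None, :].repeat(3, axis=0)
        F += rng.normal(0, 1e-6, F.shape)
        model = fit_clock(make_freq(np.clip(F, 0, 1)), ages, CFG_FAST)
        preds = predict_age(model, make_freq(np.clip(F, 0, 1)), ages=ages)
        log_err = np.abs(np.log([p.dnam_age for p in preds]) - np.log(ages))
        assert np.median(log_err) < 0.05

    def test_intercept_only_model_constant_prediction(self):
        model = ClockModel("icpt", "canFam3", 4.382)
        F = np.random.default_rng(1).uniform(0, 1, (3, 5))
        preds = predict_age(model, make_freq(F))
        assert all(p.dnam_age == pytest.approx(math.exp(4.382)) for p in preds)

    def test_zero_model_predicts_one_year(self):
        model = ClockModel("zero", "canFam3", 0.0)
        preds = predict_age(model, make_freq(np.array([[0.5, 0.1]])))
        assert all(p.dnam_age == 1.0 for p in preds)

    def test_predict_matches_independent_oracle(self):
        rng = np.random.default_rng(2)
        sites = [SiteKey("canFam3", "chr1", 100 + i) for i in range(6)]
        model = ClockModel(
            "toy", "canFam3", 0.7,
            [ClockEntry(s, float(rng.normal())) for s in sites[:4]],
        )
        freq = make_freq(rng.uniform(0, 1, (6, 9)))
        preds = predict_age(model, freq)
        oracle = independent_clock_eval(model, freq)
        np.testing.assert_allclose([p.dnam_age for p in preds], oracle, atol=1e-9)

    def test_packaged_model_on_random_vector_matches_oracle(self):
        from canidclock.io_formats import load_packaged_clock

        model = load_packaged_clock("canid")
        rng = np.random.default_rng(3)
        freq = make_freq(rng.uniform(0, 1, (len(model.entries), 4)))
        freq.sites = [e.site for e in model.entries]
        preds = predict_age(model, freq)
        oracle = independent_clock_eval(model, freq)
        np.testing.assert_allclose([p.dnam_age for p in preds], oracle, atol=1e-9)

    def test_site_order_and_extra_sites_irrelevant(self):
        rng = np.random.default_rng(4)
        sites = [SiteKey("canFam3", "chr1", i) for i in (10, 20, 30)]
        model = ClockModel("toy", "canFam3", 0.2,
                           [ClockEntry(sites[0], 1.1), ClockEntry(sites[1], -0.7)])
        F = rng.uniform(0, 1, (3, 5))
        freq = make_freq(F)
        freq.sites = sites
        base = [p.dnam_age for p in predict_age(model, freq)]

        perm = [2, 0, 1]
        freq2 = freq.subset_sites(np.array(perm))
        again = [p.dnam_age for p in predict_age(model, freq2)]
        np.testing.assert_allclose(base, again, atol=1e-12)

    def test_missing_model_site_strict_error_and_fallback(self):
        site_a, site_b = SiteKey("canFam3", "chr1", 1), SiteKey("canFam3", "chr1", 2)
        model = ClockModel("toy", "canFam3", 0.0,
                           [ClockEntry(site_a, 1.0, train_mean_meth=0.5),
                            ClockEntry(site_b, 2.0, train_mean_meth=0.25)])
        freq = make_freq(np.array([[0.4, 0.6]]))
        freq.sites = [site_a]
        with pytest.raises(KeyError, match="absent"):
            predict_age(model, freq)
        preds = predict_age(model, freq, missing_sites="train_mean")
        expect = [math.exp(0.4 + 0.5), math.exp(0.6 + 0.5)]
        np.testing.assert_allclose([p.dnam_age for p in preds], expect, atol=1e-12)

    def test_log_roundtrip_exact(self):
        """ln of the predicted age equals the linear predictor exactly."""
        rng = np.random.default_rng(5)
        ages = rng.uniform(1, 10, 30)
        F = np.clip(
            0.5 + 0.04 * np.log(ages)[None, :] + rng.normal(0, 0.01, (12, 30)), 0, 1
        )
        freq = make_freq(F)
        model = fit_clock(freq, ages, CFG_FAST)
        preds = predict_age(model, freq, ages=ages)
        index = {s: i for i, s in enumerate(freq.sites)}
        for j, p in enumerate(preds):
            lin = model.intercept + sum(
                e.coef * F[index[e.site], j] for e in model.entries
            )
            assert math.log(p.dnam_age) == pytest.approx(lin, abs=1e-12)

    def test_fewer_samples_than_folds_errors(self):
        F = np.random.default_rng(6).uniform(0, 1, (4, 5))
        with pytest.raises(ValueError, match="fold"):
            fit_clock(make_freq(F), np.arange(1.0, 6.0), ClockTrainingConfig(cv_folds=10))

    def test_acceleration_is_exact_difference(self):
        model = ClockModel("icpt", "canFam3", 1.0)
        preds = predict_age(model, make_freq(np.array([[0.5, 0.5]])), ages=[2.0, 3.0])
        for p in preds:
            assert p.age_acceleration == p.dnam_age - p.chrono_age


@pytest.fixture(scope="module")
def noiseless_cohort():
    rng = np.random.default_rng(7)
    n = 12
    ages = np.linspace(1.0, 10.0, n)
    F = np.clip(
        0.5
        + np.outer(rng.uniform(0.05, 0.1, 20), np.log(ages) - np.log(ages).mean())
        + rng.normal(0, 0.002, (20, n)),
        0, 1,
    )
    return make_freq(F), ages


class TestLoocv:
    def test_near_noiseless_recovery(self, noiseless_cohort):
        freq, ages = noiseless_cohort
        cfg = ClockTrainingConfig(cv_folds=5, n_penalties=40, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            preds, summary = loocv_evaluate(freq, ages, cfg)
        assert summary.median_abs_error < 0.2
        assert summary.n_failed == 0

    def test_no_leakage_of_held_out_sample(self, noiseless_cohort):
        """Poisoning the held-out sample's methylation must leave that
        fold's trained model unchanged."""
        freq, ages = noiseless_cohort
        cfg = ClockTrainingConfig(cv_folds=5, n_penalties=40, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, s1 = loocv_evaluate(freq, ages, cfg, keep_fold_models=True)
            poisoned = make_freq(freq.F.copy())
            poisoned.F[:, 0] = 0.99  # corrupt sample 0's profile only
            _, s2 = loocv_evaluate(poisoned, ages, cfg, keep_fold_models=True)
        m1, m2 = s1.fold_models[0], s2.fold_models[0]
        assert m1.intercept == m2.intercept
        assert [(e.site, e.coef) for e in m1.entries] == [
            (e.site, e.coef) for e in m2.entries
        ]

    def test_too_few_samples_errors(self):
        F = np.random.default_rng(8).uniform(0, 1, (5, 6))
        with pytest.raises(ValueError, match="at least 10"):
            loocv_evaluate(make_freq(F), np.arange(1.0, 7.0))


class TestTransferAndWeights:
    def meta_for(self, freq, species, ages, weights=None):
        out = []
        for j, sid in enumerate(freq.samples):
            w = None if weights is None or species[j] != "dog" else weights[j]
            out.append(SampleMeta(sid, species[j], float(ages[j]),
                                  breed_max_weight=w))
        return out

    def test_single_species_errors(self):
        rng = np.random.default_rng(9)
        F = rng.uniform(0, 1, (10, 12))
        freq = make_freq(F)
        ages = rng.uniform(1, 8, 12)
        meta = self.meta_for(freq, ["dog"] * 12, ages)
        with pytest.raises(ValueError, match="per species"):
            cross_species_transfer(freq, meta)

    def test_shared_signal_transfers_positively(self):
        rng = np.random.default_rng(10)
        n = 30
        species = ["dog"] * 15 + ["wolf"] * 15
        ages = np.concatenate([rng.uniform(1, 10, 15), rng.uniform(1, 7, 15)])
        signal = np.log(ages) - np.log(ages).mean()
        F = np.clip(
            0.5 + np.outer(rng.uniform(0.08, 0.15, 30), signal)
            + rng.normal(0, 0.02, (30, n)),
            0, 1,
        )
        freq = make_freq(F)
        meta = self.meta_for(freq, species, ages)
        cfg = ClockTrainingConfig(cv_folds=5, n_penalties=40, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cross_species_transfer(freq, meta, cfg)
        assert res["dog_to_wolf"].transfer_r > 0
        assert res["wolf_to_dog"].transfer_r > 0

    def test_weight_correlation_perfect_and_degenerate(self):
        from canidclock.clock import PredictionRecord

        preds = [PredictionRecord(f"d{i}", 2.0, 2.0 + i, float(i)) for i in range(5)]
        meta = [SampleMeta(f"d{i}", "dog", 2.0, breed_max_weight=10.0 + i)
                for i in range(5)]
        res = weight_correlation(preds, meta)
        assert res.r == pytest.approx(1.0)
        assert res.n == 5

        flat = [PredictionRecord(f"d{i}", 2.0, 3.0, 1.0) for i in range(5)]
        res0 = weight_correlation(flat, meta)
        assert res0.r == 0.0 and res0.zero_variance

    def test_too_few_weighted_dogs_errors(self):
        from canidclock.clock import PredictionRecord

        preds = [PredictionRecord("d0", 2.0, 3.0, 1.0)]
        meta = [SampleMeta("d0", "dog", 2.0, breed_max_weight=12.0)]
        with pytest.raises(ValueError, match="three"):
            weight_correlation(preds, meta)
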