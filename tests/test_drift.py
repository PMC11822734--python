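"""Mixed-model fitting: oracles, equivariances, store round-trips."""

import numpy as np
import pandas as pd
import pytest

from metabodrift.drift import (
    DriftLMM,
    DriftModel,
    ModelSpec,
    ModelStore,
    filter_missingness,
    fit_all,
    fit_drift_model,
    split_donors,
)
from metabodrift.simulate import (
    SyntheticParameter,
    SyntheticTimecourseConfig,
    simulate_timecourse,
)

from conftest import make_line_data


def _ols_line(x, y):
    """Closed-form simple linear regression oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    intercept = y.mean() - slope * x.mean()
    return intercept, slope


class TestFilterMissingness:
    def _data(self, n_missing, n_total=10):
        values = [np.nan] * n_missing + [1.0] * (n_total - n_missing)
        return pd.DataFrame(
            {
                "donor_id": [f"d{i}" for i in range(n_total)],
                "material": "EDTA",
                "phase": "pre",
                "time_h": 0.0,
                "parameter": "p",
                "value": values,
            }
        )

    def test_above_threshold_removed(self):
        filtered, log = filter_missingness(self._data(4), 0.30)
        assert filtered.empty
        assert len(log) == 1 and log["missing_fraction"].iloc[0] == pytest.approx(0.4)

    def test_exactly_at_threshold_kept(self):
        filtered, log = filter_missingness(self._data(3), 0.30)
        assert len(filtered) == 10 and log.empty

    def test_no_missing_nothing_removed(self):
        filtered, log = filter_missingness(self._data(0), 0.30)
        assert len(filtered) == 10 and log.empty

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            filter_missingness(pd.DataFrame(columns=["parameter", "material", "phase", "value"]))


class TestFitDriftModel:
    def test_single_donor_exact_line(self):
        data = make_line_data([2.0], slope=0.5, times=(0.0, 1.0, 2.0))
        model = fit_drift_model(data, ModelSpec(variant="base", min_donors=1))
        assert model.beta0 == pytest.approx(2.0, abs=1e-10)
        assert model.beta1 == pytest.approx(0.5, abs=1e-10)
        assert model.var_donor == 0.0

    def test_two_donors_common_slope(self):
        """Noise-free donors with intercepts 1 and 2, slope 0.5: the
        population intercept is their mean and the slope is shared."""
        data = make_line_data([1.0, 2.0], slope=0.5)
        model = fit_drift_model(data, ModelSpec(variant="base", min_donors=2))
        # noise-free data makes the residual-variance likelihood
        # degenerate (scale -> 0), so the intercept is only accurate to
        # the optimizer's flat-likelihood resolution, not machine eps
        assert model.beta1 == pytest.approx(0.5, abs=1e-6)
        assert model.beta0 == pytest.approx(1.5, abs=1e-4)

    def test_matches_pooled_ols_oracle_with_zero_donor_variance(self):
        """Donors sharing one intercept (zero random-intercept variance):
        the mixed fixed effects coincide with pooled OLS to 1e-6."""
        rng = np.random.default_rng(7)
        data = make_line_data([2.0] * 5, slope=-0.3, times=(0.0, 2.0, 4.0, 6.0, 8.0))
        data["value"] += rng.normal(0, 0.05, size=len(data))
        model = fit_drift_model(data, ModelSpec(variant="base"))
        b0, b1 = _ols_line(data["time_h"], data["value"])
        assert model.beta1 == pytest.approx(b1, rel=1e-6)
        assert model.beta0 == pytest.approx(b0, rel=1e-6)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(11)
        data = make_line_data([1.0, 1.5, 2.0], slope=0.4)
        data["value"] += rng.normal(0, 0.03, size=len(data))
        base = fit_drift_model(data, ModelSpec(variant="base"))
        shifted = data.copy()
        shifted["value"] += 10.0
        model = fit_drift_model(shifted, ModelSpec(variant="base"))
        assert model.beta0 == pytest.approx(base.beta0 + 10.0, abs=1e-8)
        assert model.beta1 == pytest.approx(base.beta1, abs=1e-8)

    def test_scale_equivariance(self):
        cfg = SyntheticTimecourseConfig(
            n_donors=6,
            parameters=(
                SyntheticParameter(
                    name="p", c0=2.0, baseline_cv=0.1, noise_cv=0.05, slopes={("EDTA", "pre"): 0.3}
                ),
            ),
            materials=("EDTA",),
            phases=("pre",),
            seed=3,
        )
        data, _ = simulate_timecourse(cfg)
        base = fit_drift_model(data, ModelSpec(variant="base"))
        scaled = data.copy()
        scaled["value"] *= 3.0
        model = fit_drift_model(scaled, ModelSpec(variant="base"))
        assert model.beta0 == pytest.approx(3.0 * base.beta0, rel=1e-5)
        assert model.beta1 == pytest.approx(3.0 * base.beta1, rel=1e-5)

    def test_r2_ordering(self, small_store):
        for model in small_store:
            assert 0.0 <= model.r2_marginal <= model.r2_conditional <= 1.0

    def test_too_few_donors_rejected(self):
        two = make_line_data([1.0, 2.0], slope=0.5)
        with pytest.raises(ValueError, match="min_donors"):
            DriftLMM(two, ModelSpec(variant="base", min_donors=3)).fit()

    def test_cellcount_variant_requires_cell_counts(self):
        data = make_line_data([1.0, 2.0, 3.0], slope=0.5)
        with pytest.raises(ValueError, match="cell_count"):
            DriftLMM(data, ModelSpec(variant="cellcount"))

    def test_mixed_strata_rejected(self):
        a = make_line_data([1.0], slope=0.5, parameter="a")
        b = make_line_data([1.0], slope=0.5, parameter="b")
        with pytest.raises(ValueError, match="parameter"):
            DriftLMM(pd.concat([a, b]))


class TestSlopeRecovery:
    def test_known_slope_recovered_within_tolerance(self):
        """20 donors, 5% noise CV: slope estimates land within 10% of
        the true -0.3/h in nearly all seeded replicates."""
        true_slope = -0.3
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = SyntheticTimecourseConfig(
                n_donors=20,
                parameters=(
                    SyntheticParameter(
                        name="p",
                        c0=2.0,
                        baseline_cv=0.10,
                        noise_cv=0.05,
                        slopes={("EDTA", "pre"): true_slope},
                    ),
                ),
                materials=("EDTA",),
                phases=("pre",),
                seed=1000 + seed,
            )
            data, _ = simulate_timecourse(cfg)
            model = fit_drift_model(data, ModelSpec(variant="base"))
            if abs(model.beta1 - true_slope) <= 0.1 * abs(true_slope):
                hits += 1
        assert hits >= int(0.95 * n_rep)


class TestModelStore:
    def test_fit_all_counts_strata(self, small_store):
        # 2 parameters x 2 materials x 2 phases
        assert len(small_store) == 8

    def test_round_trip_preserves_coefficients_exactly(self, small_store, tmp_path):
        path = tmp_path / "models.json"
        small_store.save(path)
        loaded = ModelStore.load(path)
        assert len(loaded) == len(small_store)
        for model in small_store:
            other = loaded.get(*model.key)
            assert other.beta0 == model.beta0  # bit-exact
            assert other.beta1 == model.beta1
            assert other.var_donor == model.var_donor
            assert other.r2_conditional == model.r2_conditional

    def test_skipped_stratum_logged(self):
        data = make_line_data([1.0, 2.0], slope=0.5)  # 2 donors < min 3
        store, skipped = fit_all(data, ModelSpec(variant="base", min_donors=3))
        assert len(store) == 0
        assert len(skipped) == 1 and "min_donors" in skipped["reason"].iloc[0]

    def test_empty_data_empty_store_with_warning(self):
        with pytest.warns(UserWarning):
            store, skipped = fit_all(pd.DataFrame(), ModelSpec())
        assert len(store) == 0

    def test_bad_document_rejected(self):
        with pytest.raises(ValueError):
            ModelStore.from_json('{"format": "something-else", "models": []}')


class TestSplitDonors:
    def test_two_thirds_split_is_donor_disjoint(self):
        donors = [f"d{i}" for i in range(30)]
        train, test = split_donors(donors, seed=1)
        assert len(train) == 20 and len(test) == 10
        assert set(train).isdisjoint(test)
        assert set(train) | set(test) == set(donors)

    def test_seed_reproducible(self):
        donors = [f"d{i}" for i in range(12)]
        assert split_donors(donors, seed=5) == split_donors(donors, seed=5)
        assert split_donors(donors, seed=5) != split_donors(donors, seed=6)
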