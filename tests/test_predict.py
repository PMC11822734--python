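"""Percent-change prediction, tolerable-error flags and MPE validation."""

import numpy as np
import pandas as pd
import pytest

from metabodrift.drift import DriftModel, ModelStore
from metabodrift.preanalytics import Material, SampleRecord
from metabodrift.predict import (
    flag_tolerable,
    mpe_validation,
    predict_cohort,
    predict_pct_change,
    validation_frame,
)
from metabodrift.simulate import SyntheticTimecourseConfig, simulate_timecourse


def _model(beta0, beta1, parameter="p", material="EDTA", phase="pre"):
    return DriftModel(
        parameter=parameter,
        material=material,
        phase=phase,
        beta0=beta0,
        beta1=beta1,
        beta1_se=0.01,
        var_donor=0.0,
        var_resid=0.01,
        r2_marginal=0.9,
        r2_conditional=0.9,
        n_obs=50,
        n_donors=10,
        variant="base",
    )


class TestPredictPctChange:
    def test_linear_arithmetic(self):
        pre = _model(1.0, 0.1, phase="pre")
        post = _model(1.0, 0.05, phase="post")
        pct_pre, pct_post, pct_total = predict_pct_change(pre, post, 2.0, 2.0)
        assert pct_pre == pytest.approx(20.0)
        assert pct_post == pytest.approx(10.0)
        assert pct_total == pytest.approx(30.0)

    def test_zero_delays_zero_change(self):
        pre = _model(1.0, 0.1, phase="pre")
        post = _model(1.0, 0.05, phase="post")
        assert predict_pct_change(pre, post, 0.0, 0.0) == (0.0, 0.0, 0.0)

    def test_additivity_over_components(self):
        pre = _model(2.0, -0.3, phase="pre")
        post = _model(2.1, 0.1, phase="post")
        a = predict_pct_change(pre, post, 1.5, 0.0)
        b = predict_pct_change(pre, post, 0.0, 2.5)
        c = predict_pct_change(pre, post, 1.5, 2.5)
        assert c[2] == pytest.approx(a[2] + b[2])

    def test_doubling_delays_doubles_total(self):
        pre = _model(1.5, 0.2, phase="pre")
        post = _model(1.5, -0.1, phase="post")
        one = predict_pct_change(pre, post, 1.0, 2.0)[2]
        two = predict_pct_change(pre, post, 2.0, 4.0)[2]
        assert two == pytest.approx(2 * one)

    def test_baseline_from_pre_model(self):
        """Both components are normalized by the precentrifugation
        intercept (the concentration at blood draw)."""
        pre = _model(2.0, 0.1, phase="pre")
        post = _model(4.0, 0.1, phase="post")  # different intercept
        _, pct_post, _ = predict_pct_change(pre, post, 0.0, 1.0)
        assert pct_post == pytest.approx(100 * 0.1 * 1.0 / 2.0)

    def test_mismatched_models_rejected(self):
        with pytest.raises(ValueError, match="parameter"):
            predict_pct_change(_model(1, 0.1, parameter="a"), _model(1, 0.1, parameter="b"), 1, 1)
        with pytest.raises(ValueError, match="material"):
            predict_pct_change(
                _model(1, 0.1, material="EDTA"), _model(1, 0.1, material="Serum"), 1, 1
            )

    def test_missing_phase_gives_partial(self):
        pre = _model(1.0, 0.1, phase="pre")
        pct_pre, pct_post, pct_total = predict_pct_change(pre, None, 2.0, 5.0)
        assert pct_post is None
        assert pct_total == pytest.approx(pct_pre)

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            predict_pct_change(_model(1, 0.1), None, -1.0, 0.0)


class TestFlagTolerable:
    @pytest.mark.parametrize(
        "pct,tol,expected",
        [
            (30.0, 15.0, True),
            (-10.0, 15.0, False),
            (15.0, 15.0, False),  # strict inequality at the boundary
            (-15.0001, 15.0, True),
        ],
    )
    def test_flag(self, pct, tol, expected):
        assert flag_tolerable(pct, tol) is expected

    def test_symmetry(self):
        for x in (1.0, 14.9, 15.1, 80.0):
            assert flag_tolerable(x, 15.0) == flag_tolerable(-x, 15.0)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            flag_tolerable(10.0, 0.0)


def _record(sample_id, pre_h, post_h, material=Material.EDTA):
    return SampleRecord(
        sample_id=sample_id, material=material, pre_delay_h=pre_h, post_delay_h=post_h
    )


class TestPredictCohort:
    def _store(self):
        models = []
        for name, b0, s_pre, s_post in (
            ("lac", 1.8, 0.88, 0.44),
            ("glc", 5.0, -0.30, -0.10),
            ("ala", 0.35, 0.01, 0.004),
        ):
            models.append(_model(b0, s_pre, parameter=name, phase="pre"))
            models.append(_model(b0, s_post, parameter=name, phase="post"))
        return ModelStore(models)

    def test_entry_count(self):
        records = [_record("s1", 1.0, 0.5), _record("s2", 2.0, 1.0)]
        table = predict_cohort(records, self._store())
        assert len(table) == 6

    def test_zero_delays_no_exceedance(self):
        table = predict_cohort([_record("s1", 0.0, 0.0)], self._store())
        assert (table["pct_total"] == 0).all()
        assert not table["exceeds_tolerable"].any()

    def test_matches_brute_force_formula(self):
        store = self._store()
        records = [_record("s1", 1.3, 0.7), _record("s2", 3.2, 2.1)]
        table = predict_cohort(records, store)
        for _, row in table.iterrows():
            m_pre = store.get(row["parameter"], "EDTA", "pre")
            m_post = store.get(row["parameter"], "EDTA", "post")
            rec = next(r for r in records if r.sample_id == row["sample_id"])
            expected = (
                100.0
                * (m_pre.beta1 * rec.pre_delay_h + m_post.beta1 * rec.post_delay_h)
                / m_pre.beta0
            )
            assert row["pct_total"] == pytest.approx(expected)

    def test_material_without_models_flagged(self):
        records = [_record("s1", 1.0, 1.0, material=Material.Serum)]
        table = predict_cohort(records, self._store())
        assert len(table) == 1
        assert table["partial"].iloc[0]
        assert "Serum" in table["note"].iloc[0]


class TestMpeValidation:
    def _noise_free(self, seed=0, noise_cv=0.0, n_donors=6):
        from metabodrift.simulate import SyntheticParameter

        cfg = SyntheticTimecourseConfig(
            n_donors=n_donors,
            parameters=(
                SyntheticParameter(
                    name="p",
                    c0=2.0,
                    baseline_cv=0.1,
                    noise_cv=noise_cv,
                    slopes={("EDTA", "pre"): 0.4},
                ),
            ),
            materials=("EDTA",),
            phases=("pre",),
            seed=seed,
        )
        return simulate_timecourse(cfg)

    def test_zero_error_on_data_from_the_model_itself(self):
        """Noise-free donor lines with the store's exact slope predict
        perfectly from the time-0 anchor."""
        data, truth = self._noise_free()
        store = ModelStore([_model(2.0, truth["slope"].iloc[0], parameter="p")])
        results = mpe_validation(store, data)
        assert len(results) == 4  # times 2, 4, 6, 8
        for r in results:
            assert abs(r.mpe_pct) < 1e-10
            assert r.n_donors == 6

    def test_signed_vs_absolute_convention(self):
        """Signed MPE averages over donors before the absolute value is
        taken: errors +10% and -10% cancel in mpe_pct."""
        data = pd.DataFrame(
            {
                "donor_id": ["a", "a", "b", "b"],
                "material": "EDTA",
                "phase": "pre",
                "time_h": [0.0, 2.0, 0.0, 2.0],
                "parameter": "p",
                # slope 0 model; obs at t=2 deviate symmetrically
                "value": [1.0, 1.0 / 1.1, 1.0, 1.0 / 0.9],
            }
        )
        store = ModelStore([_model(1.0, 0.0, parameter="p")])
        results = mpe_validation(store, data)
        assert len(results) == 1
        assert results[0].mpe_pct == pytest.approx(0.0, abs=1e-9)
        assert results[0].abs_mpe_pct == pytest.approx(0.0, abs=1e-9)

    def test_donor_without_time0_excluded(self):
        data = pd.DataFrame(
            {
                "donor_id": ["a", "a", "b"],
                "material": "EDTA",
                "phase": "pre",
                "time_h": [0.0, 2.0, 2.0],
                "parameter": "p",
                "value": [1.0, 1.8, 1.9],
            }
        )
        store = ModelStore([_model(1.0, 0.4, parameter="p")])
        with pytest.warns(UserWarning, match="time-0"):
            results = mpe_validation(store, data)
        assert results[0].n_donors == 1

    def test_frame_output_columns(self):
        data, truth = self._noise_free()
        store = ModelStore([_model(2.0, truth["slope"].iloc[0], parameter="p")])
        frame = validation_frame(mpe_validation(store, data))
        assert list(frame.columns) == [
            "parameter",
            "material",
            "phase",
            "time_h",
            "mpe_pct",
            "abs_mpe_pct",
            "n",
        ]
        assert (frame["abs_mpe_pct"] >= 0).all()
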