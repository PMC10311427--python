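"""Person-time construction, Poisson hazard fitting and risk prediction."""

import numpy as np
import pytest

from ropscreen.cohort import InfantRecord
from ropscreen.prescreen import (PrescreenFit, PrescreenHazardModel,
                                 _simpson_H, fit_prescreen, rcs_basis,
                                 split_person_time)


def censored(i, ga=28.0, **kw):
    base = dict(infant_id=f"c{i}", ga_weeks=ga, sex="girl" if i % 2 else "boy",
                bw_g=1100.0, pnd_days=5, last_exam_pna_weeks=20.0)
    base.update(kw)
    return InfantRecord(**base)


def treated(i, t, ga=26.0, **kw):
    base = dict(infant_id=f"t{i}", ga_weeks=ga, sex="girl" if i % 2 else "boy",
                bw_g=900.0, pnd_days=20, treated=True, treatment_pna_weeks=t,
                first_rop_dx_pna_weeks=max(0.9, t - 3), max_rop_stage="3",
                last_exam_pna_weeks=t)
    base.update(kw)
    return InfantRecord(**base)


class TestSplitPersonTime:
    def test_censored_infant_20_rows_no_event(self):
        pt = split_person_time([censored(0)], interval_weeks=1.0)
        assert len(pt) == 20
        assert pt["event"].sum() == 0
        assert pt["exposure"].sum() == pytest.approx(20.0)

    def test_treated_at_12_6_weeks(self):
        pt = split_person_time([treated(0, 12.6)], interval_weeks=1.0)
        assert len(pt) == 13
        assert pt["event"].to_numpy()[-1] == 1
        assert pt["event"].sum() == 1
        assert pt["exposure"].sum() == pytest.approx(12.6)

    def test_row_counting_oracle(self):
        recs = [censored(0), treated(1, 12.6), treated(2, 7.0),
                censored(3, last_exam_pna_weeks=4.5), treated(4, 19.9)]
        for interval in (0.5, 1.0, 2.0):
            pt = split_person_time(recs, interval_weeks=interval)
            expected = sum(
                int(np.ceil(min(r.followup_weeks, 20.0) / interval - 1e-12))
                for r in recs)
            assert len(pt) == expected

    def test_rows_partition_followup(self):
        pt = split_person_time([treated(0, 9.3)], interval_weeks=2.0)
        assert pt["t_start"].iloc[0] == 0.0
        assert np.allclose(pt["t_stop"].to_numpy()[:-1],
                           pt["t_start"].to_numpy()[1:])
        assert pt["t_stop"].iloc[-1] == pytest.approx(9.3)

    def test_treated_without_time_is_fatal(self):
        bad = censored(0)
        bad.treated = True
        with pytest.raises(ValueError, match="treatment time"):
            split_person_time([bad])

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            split_person_time([censored(0)], interval_weeks=0.0)


class TestRcsBasis:
    def test_shape_and_linearity_in_tails(self):
        knots = [2.0, 5.0, 8.0, 11.0]
        B = rcs_basis(np.linspace(0, 20, 50), knots)
        assert B.shape == (50, 3)
        # beyond the last knot every column is linear in t
        t_hi = np.array([15.0, 16.0, 17.0])
        Bh = rcs_basis(t_hi, knots)
        d1 = Bh[1] - Bh[0]
        d2 = Bh[2] - Bh[1]
        assert np.allclose(d1, d2, atol=1e-9)

    def test_needs_three_knots(self):
        with pytest.raises(ValueError):
            rcs_basis([1.0], [1.0, 2.0])


class TestQuadrature:
    def test_constant_hazard_closed_form(self):
        lam = 0.037
        H = _simpson_H(lambda t: np.full(np.shape(t), np.log(lam)), 14.0, 0.1)
        assert H == pytest.approx(lam * 14.0, rel=1e-8)

    def test_loglinear_hazard_closed_form(self):
        a, b = -4.0, 0.21
        H = _simpson_H(lambda t: a + b * np.asarray(t), 20.0, 0.1)
        expected = np.exp(a) / b * (np.exp(b * 20.0) - 1)
        assert H == pytest.approx(expected, rel=1e-6)

    def test_zero_span(self):
        assert _simpson_H(lambda t: np.zeros(np.shape(t)), 0.0, 0.1) == 0.0


class TestConstantHazardFit:
    @pytest.fixture(scope="class")
    def flat_cohort(self):
        rng = np.random.default_rng(10)
        lam = 0.012
        recs = []
        for i in range(1500):
            t = rng.exponential(1 / lam)
            if t <= 20:
                recs.append(treated(i, float(max(t, 1.0))))
            else:
                recs.append(censored(i))
        return recs

    def test_poisson_mle_equals_events_over_exposure(self, flat_cohort):
        m = PrescreenHazardModel(baseline="constant", main_terms=(),
                                 interaction_candidates=(),
                                 select_interactions=False).fit(flat_cohort)
        pt = split_person_time(flat_cohort)
        closed_form = pt["event"].sum() / pt["exposure"].sum()
        assert np.exp(m.coef_[0]) == pytest.approx(closed_form, rel=1e-8)

    def test_risk_from_constant_hazard(self, flat_cohort):
        m = PrescreenHazardModel(baseline="constant", main_terms=(),
                                 interaction_candidates=(),
                                 select_interactions=False).fit(flat_cohort)
        pt = split_person_time(flat_cohort)
        lam_hat = pt["event"].sum() / pt["exposure"].sum()
        p = m.predict_risk(flat_cohort[:1])
        assert p[0] == pytest.approx(1 - np.exp(-lam_hat * 20), rel=1e-6)

    def test_spline_baseline_near_flat_on_constant_data(self, flat_cohort):
        m = PrescreenHazardModel(main_terms=(), interaction_candidates=(),
                                 select_interactions=False).fit(flat_cohort)
        g = m.baseline_log_hazard(np.linspace(1, 19, 10))
        assert g.max() - g.min() < 1.0  # flat within noise


class TestFittedModel:
    def test_cumulative_hazard_monotone_and_zero_at_origin(
            self, fitted_pipeline, small_cohort):
        m = fitted_pipeline.prescreen
        rec = small_cohort[0][:1]
        ts = np.arange(0.0, 20.5, 0.5)
        H = np.array([m.cumulative_hazard(rec, t)[0] for t in ts])
        assert H[0] == 0.0
        assert np.all(np.diff(H) >= -1e-12)

    def test_t_out_of_range_rejected(self, fitted_pipeline, small_cohort):
        with pytest.raises(ValueError):
            fitted_pipeline.prescreen.cumulative_hazard(small_cohort[0][:1],
                                                        25.0)

    def test_risk_log_odds_consistency(self, fitted_pipeline, small_cohort):
        m = fitted_pipeline.prescreen
        recs = small_cohort[0][:50]
        p = m.predict_risk(recs)
        lo = m.predict_log_odds(recs)
        assert np.allclose(lo, np.log(p / (1 - p)))
        assert np.all((p > 0) & (p < 1))

    def test_risk_decreasing_in_gestational_age(self, fitted_pipeline):
        m = fitted_pipeline.prescreen
        recs = [censored(i, ga=g) for i, g in enumerate([24, 26, 28, 30, 32])]
        p = m.predict_risk(recs)
        assert np.all(np.diff(p) < 0)

    def test_risk_invariant_to_split_granularity(self, small_cohort):
        records, _ = small_cohort
        m1 = PrescreenHazardModel(interval_weeks=1.0, knots=(6, 10, 13, 16),
                                  select_interactions=False,
                                  interaction_candidates=()).fit(records)
        m2 = PrescreenHazardModel(interval_weeks=0.5, knots=(6, 10, 13, 16),
                                  select_interactions=False,
                                  interaction_candidates=()).fit(records)
        p1 = m1.predict_risk(records[:200])
        p2 = m2.predict_risk(records[:200])
        assert np.allclose(p1, p2, rtol=0.15, atol=5e-3)

    def test_serialization_round_trip(self, fitted_pipeline, small_cohort):
        m = fitted_pipeline.prescreen
        doc = m.to_fit().to_json()
        m2 = PrescreenHazardModel.from_fit(PrescreenFit.from_json(doc))
        recs = small_cohort[0][:20]
        assert np.allclose(m.predict_risk(recs), m2.predict_risk(recs))

    def test_birth_model_reduction_single_pnd_level(self):
        # forcing one PND level: the model degrades to GA+BW+sex cleanly
        rng = np.random.default_rng(11)
        recs = []
        for i in range(800):
            ga = float(rng.uniform(23, 32))
            t = float(rng.exponential(8 / max(ga - 22, 0.5)))
            if t <= 20 and rng.random() < 0.5:
                recs.append(treated(i, max(t, 1.0), ga=ga, pnd_days=5))
            else:
                recs.append(censored(i, ga=ga, pnd_days=5))
        m = PrescreenHazardModel(main_terms=("ga_c", "bw_100", "male"),
                                 interaction_candidates=(),
                                 select_interactions=False).fit(recs)
        assert set(n for n in m.coef_names_ if not n.startswith("spline")) \
            == {"intercept", "ga_c", "bw_100", "male"}
        assert np.all(np.isfinite(m.coef_))

    def test_aic_reported_consistently(self, fitted_pipeline):
        m = fitted_pipeline.prescreen
        assert m.aic_ == pytest.approx(-2 * m.loglik_ + 2 * m.n_params_)
        cov = np.asarray(m.cov_)
        assert np.allclose(cov, cov.T, atol=1e-8)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-8)

    def test_no_events_is_fatal(self):
        with pytest.raises(ValueError, match="event"):
            fit_prescreen([censored(i) for i in range(30)])


def test_aic_prefers_simpler_model_without_interactions():
    # generated with no sex x PND interaction: selection keeps none
    from ropscreen.simulate import SimulationConfig, generate_cohort
    beta = {"ga_c": -0.35, "bw_100": -0.10, "male": 0.25, "pnd_ge14": 0.9,
            "pnd_unknown": 0.3, "male:pnd_ge14": 0.0, "male:pnd_unknown": 0.0}
    recs, _ = generate_cohort(SimulationConfig(n_infants=6000, seed=21,
                                               true_beta=beta))
    m = PrescreenHazardModel(knots=(6, 10, 13, 16)).fit(recs)
    assert m.selected_interactions_ == []
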