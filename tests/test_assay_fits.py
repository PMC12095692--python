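"""Dose-response, binding, melting, STD and pKa fitters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leadscope import synthetic_data
from leadscope.assay_fits import (FitError, NoTransitionError, TitrationSeries,
                                  bound_fraction, classify_activity,
                                  compute_tm, delta_tm, fit_ic50, fit_mst_kd,
                                  fit_pka, four_pl, henderson_hasselbalch,
                                  normalize_to_vehicle, protonated_fraction,
                                  std_epitope_map)


def series_from(df):
    return TitrationSeries(df.iloc[:, 0].to_numpy(), df.iloc[:, 1:].to_numpy())


class TestNormalization:
    def test_vehicle_maps_to_one(self):
        x = [1.0, 10.0, 100.0]
        raw = np.full((3, 3), 2000.0)
        s = normalize_to_vehicle(x, raw, vehicle=[2000.0, 2000.0])
        assert np.allclose(s.y, 1.0)

    def test_half_and_quarter_signal(self):
        s = normalize_to_vehicle([1.0, 2.0], [[1000.0], [500.0]], [2000.0])
        assert np.allclose(s.y.ravel(), [0.5, 0.25])

    def test_nonpositive_vehicle_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_vehicle([1.0, 2.0], [[1.0], [1.0]], [0.0])


class TestDoseResponse:
    def test_noiseless_recovery_at_reported_potency(self):
        # 62.14 uM planted on the 8-point [1, 450] uM design
        df, _ = synthetic_data.gen_dose_response(ic50=62.14, noise_sd=0.0)
        fit = fit_ic50(series_from(df))
        assert fit.ic50 == pytest.approx(62.14, rel=1e-3)
        assert not fit.extrapolated

    def test_constant_response_rejected(self):
        x = np.logspace(0, 2.65, 8)
        with pytest.raises(FitError, match="dose dependence"):
            fit_ic50(TitrationSeries(x, np.ones((8, 3))))

    def test_monte_carlo_recovery_rate(self):
        hits = 0
        for seed in range(7, 107):
            df, _ = synthetic_data.gen_dose_response(ic50=33.0, noise_sd=0.03,
                                                     seed=seed)
            try:
                fit = fit_ic50(series_from(df))
            except FitError:
                continue
            if abs(fit.ic50 - 33.0) / 33.0 <= 0.15:
                hits += 1
        assert hits >= 95

    def test_rss_at_optimum_beats_truth(self):
        df, _ = synthetic_data.gen_dose_response(ic50=33.0, noise_sd=0.0)
        fit = fit_ic50(series_from(df))
        x, y = series_from(df).flat()
        rss_truth = float(np.sum((four_pl(x, np.log10(33.0), 1.2, 1.0, 0.05) - y) ** 2))
        assert fit.rss <= rss_truth + 1e-9

    def test_inactive_classification(self):
        df, _ = synthetic_data.gen_dose_response(ic50=33.0, noise_sd=0.0)
        fit = fit_ic50(series_from(df))
        assert classify_activity(fit) == "active"
        # shift the curve out of the tested range: the fit extrapolates
        df2, _ = synthetic_data.gen_dose_response(ic50=5000.0, hill=1.0,
                                                  noise_sd=0.0)
        try:
            fit2 = fit_ic50(series_from(df2))
            assert classify_activity(fit2) == "inactive"
        except FitError:
            pass  # an unconstrained fit may legitimately fail out of range


class TestBinding:
    def test_hyperbolic_limit(self):
        # a vanishing target concentration reduces the quadratic isotherm to
        # the hyperbola L/(L+K); the leading deviation is of order T/K
        L = np.logspace(-2, 3, 30)
        K = 10.0
        assert np.allclose(bound_fraction(L, K, K * 1e-6), L / (L + K), atol=1e-6)
        assert np.allclose(bound_fraction(L, K, K / 1000), L / (L + K), atol=2e-4)

    def test_saturation_and_midpoint(self):
        assert bound_fraction(np.array([1e9]), 39.0, 0.1)[0] == pytest.approx(1.0, abs=1e-4)
        # L = K >> T gives half occupancy
        assert bound_fraction(np.array([39.0]), 39.0, 0.001)[0] == pytest.approx(0.5, abs=1e-3)

    def test_noiseless_recovery_at_reported_affinity(self):
        df, _ = synthetic_data.gen_mst_titration(kd=39.0, noise_sd=0.0)
        fit = fit_mst_kd(series_from(df), target_conc_nM=100.0)
        assert fit.kd_app == pytest.approx(39.0, rel=1e-3)
        assert not fit.flagged

    def test_monte_carlo_recovery_rate(self):
        hits = 0
        for seed in range(7, 107):
            df, _ = synthetic_data.gen_mst_titration(kd=39.0, noise_sd=0.5,
                                                     seed=seed)  # 5% of amplitude
            try:
                fit = fit_mst_kd(series_from(df), target_conc_nM=100.0)
            except FitError:
                continue
            if abs(fit.kd_app - 39.0) / 39.0 <= 0.25:
                hits += 1
        assert hits >= 95


class TestMelting:
    def test_noiseless_midpoints_recovered(self):
        for tm in (74.5, 84.1):
            df, _ = synthetic_data.gen_melting_curve(tm=tm, noise_sd=0.0)
            fit = compute_tm(df["temperature_C"], df["F330"], df["F350"])
            assert fit.tm == pytest.approx(tm, abs=0.1)

    def test_flat_curve_reports_no_transition(self):
        df, _ = synthetic_data.gen_melting_curve(amplitude=0.0,
                                                 baseline_slope=0.0)
        with pytest.raises(NoTransitionError):
            compute_tm(df["temperature_C"], df["F330"], df["F350"])

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_invariant_to_common_channel_rescaling(self, scale):
        df, _ = synthetic_data.gen_melting_curve(tm=74.5, noise_sd=0.005, seed=1)
        base = compute_tm(df["temperature_C"], df["F330"], df["F350"])
        scaled = compute_tm(df["temperature_C"], df["F330"] * scale,
                            df["F350"] * scale)
        assert scaled.tm == pytest.approx(base.tm, abs=1e-6)

    def test_monte_carlo_recovery_rate(self):
        hits = 0
        for seed in range(11, 111):
            df, _ = synthetic_data.gen_melting_curve(tm=74.5, noise_sd=0.005,
                                                     seed=seed)
            fit = compute_tm(df["temperature_C"], df["F330"], df["F350"])
            if abs(fit.tm - 74.5) <= 0.2:
                hits += 1
        assert hits >= 95

    @pytest.mark.parametrize("tm_complex,expected",
                             [(72.9, -1.6), (74.5, 0.0), (74.4, -0.1)])
    def test_thermal_shift(self, tm_complex, expected):
        apo_df, _ = synthetic_data.gen_melting_curve(tm=74.5, noise_sd=0.0)
        cx_df, _ = synthetic_data.gen_melting_curve(tm=tm_complex, noise_sd=0.0)
        apo = compute_tm(apo_df["temperature_C"], apo_df["F330"], apo_df["F350"])
        cx = compute_tm(cx_df["temperature_C"], cx_df["F330"], cx_df["F350"])
        assert delta_tm(apo, cx) == pytest.approx(expected, abs=0.05)


class TestSTD:
    def test_max_reference_normalization(self):
        records = [("H1", 410.0, 1000.0), ("H2", 660.0, 1000.0),
                   ("H3", 910.0, 1000.0)]
        out = std_epitope_map(records, reference="max")
        rel = [r.relative_pct for r in out]
        assert rel == pytest.approx([45.1, 72.5, 100.0], abs=0.1)
        assert max(rel) == 100.0

    def test_single_proton_is_its_own_reference(self):
        out = std_epitope_map([("H1", 500.0, 1000.0)])
        assert out[0].relative_pct == 100.0

    def test_named_reference_allows_over_100_percent(self):
        # mirrors relative values like 137% and 199% against an 8 ppm peak
        records = [("8ppm", 1.00, 1.0), ("cp1", 1.37, 1.0), ("cp2", 1.99, 1.0)]
        out = std_epitope_map(records, reference="8ppm")
        assert [round(r.relative_pct) for r in out] == [100, 137, 199]

    def test_nonpositive_reference_intensity_rejected(self):
        with pytest.raises(ValueError, match="H2"):
            std_epitope_map([("H1", 1.0, 2.0), ("H2", 1.0, 0.0)])

    def test_difference_convention(self):
        out = std_epitope_map([("H1", 200.0, 1000.0), ("H2", 600.0, 1000.0)],
                              convention="difference")
        assert out[0].effect == pytest.approx(0.8)
        assert out[0].relative_pct == pytest.approx(100.0)


class TestPka:
    def test_noiseless_recovery_of_reported_pka(self):
        df, _ = synthetic_data.gen_ph_titration(pka=6.69, noise_sd=0.0)
        fit = fit_pka(TitrationSeries(df["pH"].to_numpy(),
                                      df["shift_ppm"].to_numpy()))
        assert fit.pka == pytest.approx(6.69, abs=0.01)

    def test_flat_shift_rejected(self):
        ph = np.arange(2.0, 13.1, 0.5)
        with pytest.raises(FitError, match="transition"):
            fit_pka(TitrationSeries(ph, np.full_like(ph, 1.1)))

    def test_noisy_recovery_weak_base(self):
        df, _ = synthetic_data.gen_ph_titration(pka=7.8, noise_sd=0.005, seed=3)
        fit = fit_pka(TitrationSeries(df["pH"].to_numpy(),
                                      df["shift_ppm"].to_numpy()))
        assert fit.pka == pytest.approx(7.8, abs=0.05)

    def test_direction_invariance(self):
        # rising and falling titration curves recover the same pKa
        for d_acid, d_base in ((1.20, 0.95), (0.95, 1.20)):
            df, _ = synthetic_data.gen_ph_titration(pka=6.69, delta_acid=d_acid,
                                                    delta_base=d_base,
                                                    noise_sd=0.0)
            fit = fit_pka(TitrationSeries(df["pH"].to_numpy(),
                                          df["shift_ppm"].to_numpy()))
            assert fit.pka == pytest.approx(6.69, abs=0.01)
            assert fit.delta_acid == pytest.approx(d_acid, abs=1e-3)

    def test_monte_carlo_recovery_rate(self):
        hits = 0
        for seed in range(42, 142):
            df, _ = synthetic_data.gen_ph_titration(pka=6.69, noise_sd=0.005,
                                                    seed=seed)
            try:
                fit = fit_pka(TitrationSeries(df["pH"].to_numpy(),
                                              df["shift_ppm"].to_numpy()))
            except FitError:
                continue
            if abs(fit.pka - 6.69) <= 0.05:
                hits += 1
        assert hits >= 95


class TestProtonation:
    def test_half_protonated_at_pka(self):
        assert protonated_fraction(7.0, 7.0) == 0.5

    def test_weak_base_at_physiological_ph(self):
        # closed-form evaluation: pKa 6.65 at pH 7.5
        assert protonated_fraction(6.65, 7.5) == pytest.approx(0.124, abs=1e-3)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(pka=st.floats(min_value=2, max_value=12),
           ph=st.floats(min_value=0, max_value=14))
    def test_fraction_bounded_and_monotone(self, pka, ph):
        f = protonated_fraction(pka, ph)
        assert 0.0 <= f <= 1.0
        assert protonated_fraction(pka, ph - 5) >= f  # more acidic, more protonated

    def test_fully_protonated_limit(self):
        assert protonated_fraction(7.0, -20.0) == pytest.approx(1.0)


def test_henderson_hasselbalch_midpoint():
    # at pH = pKa the shift is the mean of the two limits
    assert henderson_hasselbalch(np.array([6.69]), 6.69, 1.2, 0.95)[0] == \
        pytest.approx((1.2 + 0.95) / 2)
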