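"""Axial regression fitting, Cohen's f², power and sample-size logic."""

import math

import numpy as np
import pytest

from chromaxial import (
    AberrationSample,
    CalibrationModel,
    DataError,
    build_model,
    cohens_f2,
    fit_axial,
    regression_power,
    required_n,
)


def _samples(depths, dz_values, target="559", ref="473"):
    return [
        AberrationSample(
            label=f"s{i}",
            depth=float(d),
            shifts={ref: (0.0, 0.0, 0.0), target: (0.05, -0.02, float(v))},
        )
        for i, (d, v) in enumerate(zip(depths, dz_values))
    ]


class TestCohensF2:
    @pytest.mark.parametrize(
        "r2, expected",
        [(0.5, 1.0), (0.0, 0.0), (0.757, 0.757 / 0.243)],
    )
    def test_values(self, r2, expected):
        assert cohens_f2(r2) == pytest.approx(expected, rel=1e-12)

    def test_r2_one_is_flagged_infinite(self):
        assert math.isinf(cohens_f2(1.0))

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(DataError):
            cohens_f2(bad)


class TestFitAxial:
    def test_closed_form_three_points(self):
        # OLS through (0,1), (100,2), (200,3) is exactly dz = 0.01 d + 1
        s = _samples([0, 100, 200], [1, 2, 3])
        reg = fit_axial(s, "473", "559")
        assert reg.slope == pytest.approx(0.01, abs=1e-12)
        assert reg.intercept == pytest.approx(1.0, abs=1e-10)
        assert reg.r2 == pytest.approx(1.0)
        assert "degenerate_fit" in reg.flags

    def test_noiseless_line_reports_degenerate_power(self):
        d = np.linspace(50, 1950, 30)
        s = _samples(d, 0.004 * d - 18.0)
        reg = fit_axial(s, "473", "559")
        assert reg.slope == pytest.approx(0.004, abs=1e-12)
        assert reg.intercept == pytest.approx(-18.0, abs=1e-9)
        assert math.isinf(reg.f2) and reg.power == 1.0

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(42)
        d = rng.uniform(0, 2000, size=100)
        dz = 0.004 * d - 18.0 + rng.normal(0, 0.5, size=100)
        reg = fit_axial(_samples(d, dz), "473", "559")
        assert abs(reg.slope - 0.004) < 3 * reg.stderr_slope
        assert abs(reg.intercept + 18.0) < 3 * reg.stderr_intercept
        assert 0.9 < reg.r2 < 1.0

    def test_bias_vanishes_with_sample_size(self):
        rng = np.random.default_rng(3)
        errs = []
        for n in (10, 100, 1000):
            d = rng.uniform(0, 2000, size=n)
            dz = 0.004 * d - 18.0 + rng.normal(0, 0.5, size=n)
            reg = fit_axial(_samples(d, dz), "473", "559")
            errs.append(abs(reg.slope - 0.004))
        assert errs[2] < errs[0]
        assert errs[2] < 3 * 0.5 / (np.sqrt(1000) * np.std(np.linspace(0, 2000, 1000)))

    def test_reference_vs_reference_is_exactly_zero(self):
        s = _samples([10, 500, 900, 1500], [0.0, 0.0, 0.0, 0.0])
        reg = fit_axial(s, "473", "559")
        assert reg.slope == 0.0 and reg.intercept == 0.0
        assert reg.r2 == 0.0

    def test_degenerate_designs_rejected(self):
        with pytest.raises(DataError, match="3 samples"):
            fit_axial(_samples([0, 1], [0, 1]), "473", "559")
        with pytest.raises(DataError, match="depth"):
            fit_axial(_samples([5, 5, 5], [1, 2, 3]), "473", "559")

    def test_prediction_se_grows_away_from_mean_depth(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0, 1000, 50)
        reg = fit_axial(_samples(d, 0.01 * d + rng.normal(0, 1, 50)), "473", "559")
        assert reg.prediction_se(reg.depth_mean) < reg.prediction_se(reg.depth_mean + 800)

    def test_outlier_flagging_pass(self):
        rng = np.random.default_rng(12)
        d = np.linspace(0, 1000, 20)
        dz = 0.01 * d + 1.0 + rng.normal(0, 0.5, 20)
        dz[7] += 50.0  # gross outlier
        reg = fit_axial(_samples(d, dz), "473", "559", flag_outliers_mad=3.0)
        assert any(f.startswith("outliers_excluded") for f in reg.flags)
        assert reg.slope == pytest.approx(0.01, abs=3 * reg.stderr_slope)
        baseline = fit_axial(_samples(d, dz), "473", "559")
        assert abs(reg.slope - 0.01) < abs(baseline.slope - 0.01)


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        for alpha in (0.01, 0.05, 0.2):
            assert regression_power(0.0, 25, alpha) == alpha

    def test_monotone_in_n_and_f2(self):
        # modest effect sizes keep the power away from float saturation at 1
        grid_n = [5, 10, 20, 40]
        for f2 in (0.05, 0.15, 0.3):
            p = [regression_power(f2, n) for n in grid_n]
            assert all(b > a for a, b in zip(p, p[1:]))
        for n in (7, 25):
            p = [regression_power(f2, n) for f2 in (0.02, 0.1, 0.4, 1.0)]
            assert all(b > a for a, b in zip(p, p[1:]))

    def test_agrees_with_statsmodels_convention(self):
        from statsmodels.stats.power import FTestPowerF2

        sm_power = FTestPowerF2()
        for f2, n in [(3.1152263374485596, 7), (3.1152263374485596, 10), (0.25, 20), (0.8, 12)]:
            expected = sm_power.power(effect_size=f2, df_num=1, df_denom=n - 2, alpha=0.05)
            assert regression_power(f2, n) == pytest.approx(expected, abs=1e-10)

    def test_infinite_effect_size_gives_certainty(self):
        assert regression_power(math.inf, 5) == 1.0

    @pytest.mark.parametrize("bad", [dict(n=2), dict(alpha=0.0), dict(f2=-1.0)])
    def test_domain_errors(self, bad):
        kw = dict(f2=1.0, n=10, alpha=0.05)
        kw.update(bad)
        with pytest.raises(DataError):
            regression_power(**kw)


class TestRequiredN:
    def test_printed_guide_star_pair(self):
        f2 = cohens_f2(0.757)
        assert required_n(f2, 0.95) == 7

    def test_matches_exhaustive_scan(self):
        for f2, target in [(0.5, 0.8), (1.0, 0.9), (3.1152, 0.95), (0.15, 0.7)]:
            brute = next(
                n for n in range(3, 200) if regression_power(f2, n) >= target
            )
            assert required_n(f2, target) == brute

    def test_alpha_level_target_gives_minimum_n(self):
        assert required_n(5.0, 0.06) == 3

    def test_monotone_in_target_and_effect(self):
        assert required_n(0.5, 0.95) >= required_n(0.5, 0.8)
        assert required_n(0.2, 0.9) >= required_n(1.0, 0.9)


class TestBuildModel:
    def _four_channel_samples(self, noise=0.0, seed=0, n=30):
        rng = np.random.default_rng(seed)
        d = np.linspace(20, 1800, n)
        truth = {"488": (0.001, -2.0), "552": (0.003, -9.0), "638": (0.005, -16.0)}
        out = []
        for i, depth in enumerate(d):
            shifts = {"405": (0.0, 0.0, 0.0)}
            for ch, (a, b) in truth.items():
                shifts[ch] = (0.1, -0.1, a * depth + b + rng.normal(0, noise))
            out.append(AberrationSample(label=f"b{i}", depth=float(depth), shifts=shifts))
        return out

    def test_all_pairs_fitted(self):
        model = build_model(self._four_channel_samples(noise=0.3), "405")
        assert sorted(model.regressions) == ["488", "552", "638"]
        assert model.reference_channel == "405"
        for ch in model.regressions:
            assert model.lateral_summary[ch]["mean_abs_dx_um"] == pytest.approx(0.1)

    def test_weak_regression_flagged_insufficient(self):
        d = [100, 400, 800, 1200, 1600]
        dz = [0.0, 4.0, -4.0, 4.0, -4.0]  # zigzag: r2 ~ 0.11, f2 ~ 0.12
        model = build_model(_samples(d, dz), "473", power_threshold=0.7)
        reg = model.regressions["559"]
        assert reg.power < 0.7
        assert "insufficient_power" in reg.flags
        assert model.insufficient_channels() == ["559"]

    def test_slope_transitivity_on_noiseless_chain(self):
        # with A as reference: B and C lie on exact lines; refitting with B as
        # reference must give slope(A->C) ~ slope(A->B) + slope(B->C)
        a_b, b_b = 3e-4, 1.0
        a_c, b_c = 5e-4, -2.0
        d = np.linspace(0, 2000, 25)
        samples_ab = []
        samples_bc = []
        for i, depth in enumerate(d):
            z_b = depth + a_b * depth + b_b
            z_c = depth + a_c * depth + b_c
            samples_ab.append(AberrationSample(
                label=f"p{i}", depth=float(depth),
                shifts={"A": (0, 0, 0), "B": (0, 0, z_b - depth), "C": (0, 0, z_c - depth)},
            ))
            samples_bc.append(AberrationSample(
                label=f"q{i}", depth=float(z_b),
                shifts={"B": (0, 0, 0), "C": (0, 0, z_c - z_b)},
            ))
        slope_ab = fit_axial(samples_ab, "A", "B").slope
        slope_ac = fit_axial(samples_ab, "A", "C").slope
        slope_bc = fit_axial(samples_bc, "B", "C").slope
        assert slope_ab + slope_bc == pytest.approx(slope_ac, abs=1e-6)

    def test_json_round_trip_including_infinite_f2(self, tmp_path):
        model = build_model(self._four_channel_samples(noise=0.0), "405")
        path = tmp_path / "model.json"
        model.save(path)
        back = CalibrationModel.load(path)
        assert back.reference_channel == "405"
        for ch, reg in model.regressions.items():
            assert back.regressions[ch].slope == reg.slope
            assert back.regressions[ch].power == reg.power
            assert math.isinf(back.regressions[ch].f2) == math.isinf(reg.f2)
        assert back.power_threshold == model.power_threshold

    def test_no_samples_is_error(self):
        with pytest.raises(DataError):
            build_model([], "405")
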