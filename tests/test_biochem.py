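"""Band fractions, isotherm fitting, dose-response tables and SEC inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtbundle import (
    BindingSeries,
    BiochemError,
    band_fraction,
    binding_series_from_rows,
    dose_response_summary,
    fit_isotherm,
    gen_cosed,
    hyperbolic,
    sec_oligomer,
)


class TestBandFraction:
    @pytest.mark.parametrize("p,s,expect", [(60, 40, 0.60), (0, 100, 0.0), (100, 0, 1.0)])
    def test_basic(self, p, s, expect):
        assert band_fraction(p, s) == pytest.approx(expect)

    def test_both_zero_error(self):
        with pytest.raises(BiochemError):
            band_fraction(0.0, 0.0)

    def test_background_subtraction(self):
        assert band_fraction(70, 40, pellet_background=10) == pytest.approx(0.6)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=1e-6, max_value=1e6),
           st.floats(min_value=1e-6, max_value=1e6),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance_and_range(self, p, s, c):
        f = band_fraction(p, s)
        assert 0.0 <= f <= 1.0
        assert band_fraction(c * p, c * s) == pytest.approx(f, rel=1e-9)


class TestFitIsotherm:
    def test_noiseless_fit_is_exact(self):
        conc = np.geomspace(0.1, 20.0, 8)
        frac = hyperbolic(conc, 0.69, 1.0)
        fit = fit_isotherm(BindingSeries(conc, frac))
        assert fit.kd_uM == pytest.approx(0.69, abs=1e-6)
        assert fit.bmax == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("kd,bmax", [(0.2, 0.8), (2.0, 1.0), (15.0, 0.6)])
    def test_oracle_equivalence_across_parameter_range(self, kd, bmax):
        conc = np.geomspace(0.05, 50.0, 10)
        fit = fit_isotherm(BindingSeries(conc, hyperbolic(conc, kd, bmax)))
        assert fit.kd_uM == pytest.approx(kd, rel=1e-6)
        assert fit.bmax == pytest.approx(bmax, rel=1e-6)

    def test_constant_response_warns_unconstrained(self):
        conc = np.geomspace(0.1, 20.0, 8)
        with pytest.warns(UserWarning):
            fit = fit_isotherm(BindingSeries(conc, np.full(8, 0.9)))
        assert any("curvature" in w or "constrained" in w for w in fit.warnings)

    def test_two_concentrations_error(self):
        with pytest.raises(BiochemError):
            fit_isotherm(BindingSeries([1.0, 2.0], [[0.3, 0.5]]))

    def test_narrow_span_warns(self):
        conc = np.array([1.0, 2.0, 4.0])
        with pytest.warns(UserWarning, match="order of magnitude"):
            fit_isotherm(BindingSeries(conc, hyperbolic(conc, 1.0, 1.0)))

    def test_noisy_recovery_median_within_10pct(self):
        kds = []
        for seed in range(60):
            rows, _ = gen_cosed(kd_uM=0.69, cv_noise=0.05, seed=seed)
            fit = fit_isotherm(binding_series_from_rows(rows))
            kds.append(fit.kd_uM)
        assert np.median(kds) == pytest.approx(0.69, rel=0.10)

    def test_replicate_mean_and_sd_reported(self):
        rows, _ = gen_cosed(kd_uM=1.0, cv_noise=0.05, n_replicates=3, seed=4)
        fit = fit_isotherm(binding_series_from_rows(rows))
        assert fit.kd_per_replicate.shape == (3,)
        assert fit.kd_uM == pytest.approx(fit.kd_per_replicate.mean())
        assert fit.kd_sd_uM == pytest.approx(fit.kd_per_replicate.std(ddof=1))

    def test_quadratic_model_matches_hyperbolic_at_low_probe(self):
        conc = np.geomspace(0.1, 20.0, 8)
        frac = hyperbolic(conc, 0.69, 1.0)
        fit = fit_isotherm(BindingSeries(conc, frac), model="quadratic",
                           probe_uM=1e-4)
        assert fit.kd_uM == pytest.approx(0.69, rel=1e-3)


class TestDoseResponse:
    def test_mean_and_sd(self):
        rows = pd.DataFrame({
            "condition": ["FL"] * 3, "concentration_uM": [16.0] * 3,
            "replicate": [1, 2, 3],
            "pellet": [58.0, 60.0, 62.0], "supernatant": [42.0, 40.0, 38.0]})
        out = dose_response_summary(rows)
        assert out["mean_fraction"].iloc[0] == pytest.approx(0.60)
        assert out["sd_fraction"].iloc[0] == pytest.approx(0.02)

    def test_single_replicate_flags_undefined_sd(self):
        rows = pd.DataFrame({"condition": ["x"], "concentration_uM": [4.0],
                             "replicate": [1], "pellet": [30.0], "supernatant": [70.0]})
        out = dose_response_summary(rows)
        assert not out["sd_defined"].iloc[0]
        assert np.isnan(out["sd_fraction"].iloc[0])

    def test_construct_ordering_preserved(self):
        # full-length bundles more than the C-terminal truncation
        rows = []
        for rep, (fl, dc) in enumerate([(0.58, 0.21), (0.60, 0.23), (0.62, 0.25)], 1):
            rows.append(("FL", 16.0, rep, fl * 100, (1 - fl) * 100))
            rows.append(("dC", 16.0, rep, dc * 100, (1 - dc) * 100))
        df = pd.DataFrame(rows, columns=["condition", "concentration_uM",
                                         "replicate", "pellet", "supernatant"])
        out = dose_response_summary(df).set_index("condition")
        assert out.loc["FL", "mean_fraction"] == pytest.approx(0.60)
        assert out.loc["dC", "mean_fraction"] == pytest.approx(0.23)
        assert out.loc["FL", "mean_fraction"] > out.loc["dC", "mean_fraction"]


class TestSecOligomer:
    STANDARDS = [(66.0, 10.0), (29.0, 12.0), (12.4, 13.9)]

    def test_dimer_from_standard_calibration(self):
        res = sec_oligomer(self.STANDARDS, sample_elution=10.0,
                           theoretical_mw_kDa=34.0)
        assert res.apparent_mw_kDa == pytest.approx(66.0, rel=0.05)
        assert res.oligomer_state == 2

    def test_exact_on_log_linear_calibration(self):
        slope, intercept = -0.25, 4.0
        standards = [(10 ** (slope * v + intercept), v) for v in (9.0, 11.0, 13.0)]
        res = sec_oligomer(standards, sample_elution=10.0, theoretical_mw_kDa=50.0)
        assert res.apparent_mw_kDa == pytest.approx(10 ** (slope * 10.0 + intercept),
                                                    rel=1e-9)

    def test_monomer_when_ratio_near_one(self):
        res = sec_oligomer(self.STANDARDS, sample_elution=12.0,
                           theoretical_mw_kDa=30.0)
        assert res.oligomer_state == 1

    def test_two_standards_error(self):
        with pytest.raises(BiochemError):
            sec_oligomer(self.STANDARDS[:2], 10.0, 34.0)

    def test_non_monotonic_standards_error(self):
        bad = [(66.0, 10.0), (29.0, 9.0), (12.4, 13.9)]
        with pytest.raises(BiochemError, match="monotonic"):
            sec_oligomer(bad, 10.0, 34.0)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="extrapolat"):
            sec_oligomer(self.STANDARDS, sample_elution=8.0, theoretical_mw_kDa=100.0)
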