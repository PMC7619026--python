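"""Binding-kinetics fitting: step shifts, exponential models, affinity, dose-response."""

import numpy as np
import pytest

from cgmr.kinetics import (
    AffinityResult,
    DoseResponseModel,
    KineticsError,
    SingleExponentialModel,
    TwoPhaseModel,
    extract_step,
    fit_single_exp,
    fit_two_phase,
    kd_distribution,
)

T300 = np.arange(0.0, 300.0, 1.0)


def single_exp_curve(t, dr, k, c=0.0):
    return dr * (1.0 - np.exp(-k * t)) + c


def biphasic_pair(kd=336e-9, conc=1e-6, k_on_f=3e4, k_on_s=4e3, frac=0.5, amp=2e-3,
                  t_assoc=1000.0, t_dissoc=1200.0):
    """Association + dissociation where *each* phase has k_off/k_on = kd."""
    k_off_f, k_off_s = kd * k_on_f, kd * k_on_s
    k_obs_f, k_obs_s = k_on_f * conc + k_off_f, k_on_s * conc + k_off_s
    ta = np.arange(0.0, t_assoc, 1.0)
    td = np.arange(0.0, t_dissoc, 1.0)
    ya = amp * (frac * (1 - np.exp(-k_obs_f * ta)) + (1 - frac) * (1 - np.exp(-k_obs_s * ta)))
    bf = amp * frac * (1 - np.exp(-k_obs_f * ta[-1]))
    bs = amp * (1 - frac) * (1 - np.exp(-k_obs_s * ta[-1]))
    yd = bf * np.exp(-k_off_f * td) + bs * np.exp(-k_off_s * td)
    return (ta, ya), (td, yd)


class TestExtractStep:
    def test_flat_trace_zero(self):
        t = np.arange(100.0)
        assert extract_step((t, np.full(100, 0.3)), t_pre=40, t_post=60) == 0.0

    def test_step_amplitude_recovered(self):
        t = np.arange(0.0, 400.0)
        y = single_exp_curve(np.clip(t - 100, 0, None), 9.76e-4, 0.0649)
        assert extract_step((t, y), t_pre=100, t_post=350) == pytest.approx(9.76e-4, rel=1e-4)

    def test_window_too_large_errors(self):
        t = np.arange(30.0)
        with pytest.raises(KineticsError):
            extract_step((t, t * 0.0), t_pre=10, t_post=20, window=20)


class TestSingleExponential:
    @pytest.mark.parametrize(
        "dr,k",
        [(4.16e-3, 0.0374), (5.62e-4, 0.2732), (9.76e-4, 0.0649)],
    )
    def test_noiseless_recovery_to_1e6(self, dr, k):
        """The three functionalisation/binding steps (immobilisation,
        blocking, antigen binding) are recovered to 1e-6 relative."""
        res = fit_single_exp((T300, single_exp_curve(T300, dr, k)))
        assert res["delta_riu"] == pytest.approx(dr, rel=1e-6)
        assert res["k_app"] == pytest.approx(k, rel=1e-6)
        assert abs(res["offset"]) < dr * 1e-6

    def test_t0_offset_handled(self):
        t = np.arange(0.0, 400.0)
        y = 2e-4 + single_exp_curve(np.clip(t - 120, 0, None), 9.76e-4, 0.0649)
        res = fit_single_exp((t, y), t0=120.0)
        assert res["k_app"] == pytest.approx(0.0649, rel=1e-6)
        assert res["offset"] == pytest.approx(2e-4, rel=1e-4)

    def test_median_unbiased_at_five_percent_noise(self):
        """100 noisy repeats: median recovered k_app within 5% of truth."""
        rng = np.random.default_rng(10)
        ks = []
        y0 = single_exp_curve(T300, 9.76e-4, 0.0649)
        for _ in range(100):
            y = y0 + rng.normal(0, 0.05 * 9.76e-4, T300.size)
            ks.append(fit_single_exp((T300, y))["k_app"])
        assert np.median(ks) == pytest.approx(0.0649, rel=0.05)

    def test_fast_step_within_bootstrap_ci(self):
        rng = np.random.default_rng(11)
        y = single_exp_curve(T300, 5.62e-4, 0.2732) + rng.normal(0, 0.02 * 5.62e-4, T300.size)
        res = fit_single_exp((T300, y), bootstrap=199, seed=0)
        lo, hi = res.ci["k_app"]
        assert lo <= 0.2732 <= hi

    def test_bootstrap_ci_coverage(self):
        """90% residual-bootstrap CIs cover the true rate 85-95% of the time."""
        rng = np.random.default_rng(12)
        y0 = single_exp_curve(T300, 9.76e-4, 0.0649)
        hits = 0
        n = 150
        for i in range(n):
            y = y0 + rng.normal(0, 0.05 * 9.76e-4, T300.size)
            res = fit_single_exp((T300, y), bootstrap=99, seed=i)
            lo, hi = res.ci["k_app"]
            hits += lo <= 0.0649 <= hi
        assert 0.85 <= hits / n <= 0.95

    def test_flat_segment_rejected(self):
        with pytest.raises(KineticsError):
            SingleExponentialModel((T300, np.zeros_like(T300)))

    def test_too_few_frames_rejected(self):
        with pytest.raises(KineticsError):
            SingleExponentialModel((np.arange(5.0), np.arange(5.0)))


class TestTwoPhase:
    def test_kd_arithmetic(self):
        a = AffinityResult(k_on=1e4, k_off=3.36e-3, K_D=3.36e-3 / 1e4)
        assert a.K_D == pytest.approx(336e-9)

    def test_noiseless_kd_recovery(self):
        (ta, ya), (td, yd) = biphasic_pair(kd=336e-9)
        res = fit_two_phase((ta, ya), (td, yd), 1e-6)
        assert res.affinity.valid
        assert res.affinity.K_D == pytest.approx(336e-9, rel=0.02)

    def test_noisy_kd_recovery_within_ten_percent(self):
        (ta, ya), (td, yd) = biphasic_pair(kd=336e-9, amp=2e-3)
        rng = np.random.default_rng(13)
        res = fit_two_phase(
            (ta, ya + rng.normal(0, 0.02 * 2e-3, ta.size)),
            (td, yd + rng.normal(0, 0.02 * 2e-3, td.size)),
            1e-6,
        )
        assert res.affinity.K_D == pytest.approx(336e-9, rel=0.10)

    def test_phase_rates_recovered_noiseless(self):
        (ta, ya), (td, yd) = biphasic_pair()
        res = fit_two_phase((ta, ya), (td, yd), 1e-6)
        assert res.assoc["k_obs_fast"] == pytest.approx(0.04008, rel=1e-3)
        assert res.assoc["k_obs_slow"] == pytest.approx(0.005344, rel=1e-3)
        assert res.dissoc["k_off_fast"] == pytest.approx(0.01008, rel=1e-3)
        assert res.dissoc["k_off_slow"] == pytest.approx(0.001344, rel=1e-3)

    def test_single_phase_input_collapses_gracefully(self):
        """A pure single-exponential input triggers the identifiability
        warning and yields the same K_D as the single-phase analysis."""
        conc, k_on, k_off = 1e-6, 1e4, 3.36e-3
        k_obs = k_on * conc + k_off
        ta = np.arange(0.0, 900.0, 1.0)
        td = np.arange(0.0, 1200.0, 1.0)
        ya = 2e-3 * (1 - np.exp(-k_obs * ta))
        yd = ya[-1] * np.exp(-k_off * td)
        with pytest.warns(UserWarning, match="indistinguishable"):
            res = fit_two_phase((ta, ya), (td, yd), conc)
        assert res.collapsed
        assert res.affinity.K_D == pytest.approx(k_off / k_on, rel=0.02)

    def test_zero_slow_amplitude_matches_single_exp(self):
        """With no slow phase the two-phase machinery reproduces the
        single-exponential parameters."""
        (ta, ya), (td, yd) = biphasic_pair(frac=1.0)
        with pytest.warns(UserWarning):
            res = fit_two_phase((ta, ya), (td, yd), 1e-6)
        single = fit_single_exp((ta, ya))
        k_obs_eff = res.assoc["k_obs_fast"]
        assert k_obs_eff == pytest.approx(single["k_app"], rel=1e-3)

    def test_nonphysical_rates_withhold_kd(self):
        # dissociation faster than the observed association rate
        ta = np.arange(0.0, 200.0, 1.0)
        td = np.arange(0.0, 200.0, 1.0)
        ya = 1e-3 * (0.5 * (1 - np.exp(-0.005 * ta)) + 0.5 * (1 - np.exp(-0.001 * ta)))
        yd = 5e-4 * np.exp(-0.05 * td) + 5e-4 * np.exp(-0.01 * td)
        res = TwoPhaseModel((ta, ya), (td, yd), 1e-6).fit()
        assert not res.affinity.valid
        assert res.affinity.K_D is None
        assert res.affinity.flags

    def test_segment_length_guard(self):
        t = np.arange(10.0)
        with pytest.raises(KineticsError):
            TwoPhaseModel((t, t), (t, t), 1e-6)


class TestKdDistribution:
    @staticmethod
    def _aff(kd_nm):
        return AffinityResult(k_on=1e4, k_off=kd_nm * 1e-9 * 1e4, K_D=kd_nm * 1e-9)

    def test_nine_pair_summary(self):
        kds = [28, 95, 170, 250, 336, 400, 460, 510, 564]
        summary = kd_distribution({f"{i:03d}A": self._aff(k) for i, k in enumerate(kds)})
        assert summary["n"] == 9
        assert summary["min_KD"] == pytest.approx(28e-9)
        assert summary["max_KD"] == pytest.approx(564e-9)
        assert summary["median_KD"] == pytest.approx(336e-9)
        assert len(summary["table"]) == 9

    def test_single_pair(self):
        s = kd_distribution([self._aff(336)])
        assert s["median_KD"] == pytest.approx(336e-9)

    def test_empty_input_no_crash(self):
        s = kd_distribution([])
        assert s["n"] == 0
        assert np.isnan(s["median_KD"])

    def test_invalid_results_excluded_from_stats(self):
        bad = AffinityResult(k_on=None, k_off=1e-3, K_D=None, flags=("x",))
        s = kd_distribution([self._aff(100), bad])
        assert s["n"] == 1
        assert len(s["table"]) == 2


class TestDoseResponse:
    CONC = np.array([10e-9, 30e-9, 100e-9, 300e-9, 1e-6, 3e-6])

    def test_kd_recovered_within_ten_percent(self):
        rng = np.random.default_rng(14)
        r = 1e-3 * self.CONC / (253e-9 + self.CONC)
        r = r + rng.normal(0, 5e-6, r.size)
        res = DoseResponseModel(self.CONC, r).fit()
        assert res.K_D == pytest.approx(253e-9, rel=0.10)

    def test_langmuir_midpoint(self):
        r = 2e-3 * self.CONC / (150e-9 + self.CONC)
        res = DoseResponseModel(self.CONC, r).fit()
        assert res.predict(res.K_D) == pytest.approx(res.R_max / 2, rel=1e-9)

    def test_zero_blank_sigma_gives_zero_lod(self):
        r = 1e-3 * self.CONC / (253e-9 + self.CONC)
        res = DoseResponseModel(self.CONC, r).fit(sigma_blank=0.0)
        assert res.conc_lod == 0.0

    def test_lod_crosses_three_sigma(self):
        r = 1e-3 * self.CONC / (253e-9 + self.CONC)
        sigma = 1e-5
        res = DoseResponseModel(self.CONC, r).fit(sigma_blank=sigma)
        assert res.predict(res.conc_lod) == pytest.approx(3 * sigma, rel=1e-6)

    def test_curve_never_clearing_threshold_not_detectable(self):
        r = 1e-6 * self.CONC / (253e-9 + self.CONC)
        res = DoseResponseModel(self.CONC, r).fit(sigma_blank=1e-3)
        assert np.isinf(res.conc_lod)

    def test_input_guards(self):
        with pytest.raises(KineticsError):
            DoseResponseModel(self.CONC[:3], np.ones(3))
        with pytest.raises(KineticsError):
            DoseResponseModel(np.array([1e-9, 2e-9, 3e-9, 4e-9]), np.ones(4))

    def test_rate_and_dose_response_kd_agree(self):
        """K_D from (k_on, k_off) matches K_D fitted from equilibrium
        responses generated by the same constants."""
        kd = 336e-9
        (ta, ya), (td, yd) = biphasic_pair(kd=kd)
        rate_kd = fit_two_phase((ta, ya), (td, yd), 1e-6).affinity.K_D
        conc = np.array([30e-9, 100e-9, 336e-9, 1e-6, 3e-6, 10e-6])
        resp = 1e-3 * conc / (kd + conc)
        dose_kd = DoseResponseModel(conc, resp).fit().K_D
        assert rate_kd == pytest.approx(dose_kd, rel=0.05)
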