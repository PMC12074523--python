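"""Spectral estimation and the VM/HS/IR/HR parameter derivations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmsflow import (
    BandTone,
    OscillationSpec,
    ProtocolSpec,
    ResponseSpec,
    analyze_trace,
    band_power,
    compute_band_shares,
    compute_hs,
    compute_ir_hr,
    compute_psd,
    compute_vm,
    generate_trace,
    log_param,
)
from fmsflow.bands import DEFAULT_BAND_SCHEME, Band

from conftest import VM_11P6_AMPLITUDE, brute_force_dft_band_power

MYO = DEFAULT_BAND_SCHEME["myogenic"]


class TestComputePsd:
    def test_zero_input_zero_spectrum(self):
        spec = compute_psd(np.zeros(256), 10.0)
        assert spec.total_power == 0.0

    def test_unit_sinusoid_total_power_half(self):
        t = np.arange(1800) / 10.0
        spec = compute_psd(np.sin(2 * np.pi * 0.1 * t), 10.0)  # exact-bin frequency
        assert spec.total_power == pytest.approx(0.5, rel=1e-10)

    def test_white_noise_integrated_power_matches_variance(self):
        sigma = 0.7
        rng = np.random.default_rng(12)
        totals = [
            compute_psd(rng.normal(0.0, sigma, 2048), 10.0).total_power for _ in range(20)
        ]
        # Monte-Carlo oracle: mean integrated power ~ sigma^2 within 3 SE
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - sigma**2) < 3 * se

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="64"):
            compute_psd(np.zeros(32), 10.0)

    @given(seed=st.integers(0, 100), n=st.sampled_from([128, 500, 1024, 1800]))
    @settings(deadline=None, max_examples=20)
    def test_parseval_identity_always(self, seed, n):
        """Integrated one-sided density equals the segment mean square."""
        x = np.random.default_rng(seed).standard_normal(n)
        x -= x.mean()
        spec = compute_psd(x, 10.0)
        assert spec.total_power == pytest.approx(float(np.mean(x**2)), rel=1e-10)


class TestBandPower:
    def test_sinusoid_band_power_and_leakage(self):
        t = np.arange(1800) / 10.0
        amp = 0.01
        spec = compute_psd(amp * np.sin(2 * np.pi * 0.1 * t + 1.1), 10.0)
        assert band_power(spec, MYO) == pytest.approx(amp**2 / 2, rel=0.05)
        assert band_power(spec, DEFAULT_BAND_SCHEME["endothelial"]) < 0.02 * amp**2 / 2

    def test_disjoint_band_powers_additive(self):
        t = np.arange(1800) / 10.0
        a = 0.01 * np.sin(2 * np.pi * 0.1 * t)
        b = 0.02 * np.sin(2 * np.pi * 0.25 * t)
        resp_band = DEFAULT_BAND_SCHEME["respiratory"]
        both = compute_psd(a + b, 10.0)
        assert band_power(both, MYO) == pytest.approx(
            band_power(compute_psd(a, 10.0), MYO), rel=1e-6
        )
        assert band_power(both, resp_band) == pytest.approx(
            band_power(compute_psd(b, 10.0), resp_band), rel=1e-6
        )

    def test_empty_band_names_required_duration(self):
        spec = compute_psd(np.random.default_rng(0).standard_normal(640), 10.0)
        with pytest.raises(ValueError, match="s needed"):
            band_power(spec, Band(0.0001, 0.001))

    @pytest.mark.parametrize("n", [128, 512, 1800, 2048])
    def test_matches_brute_force_dft_oracle(self, n):
        """Dual route: periodogram band integration vs direct DFT sums."""
        x = np.random.default_rng(n).standard_normal(n)
        x -= x.mean()
        spec = compute_psd(x, 10.0)
        for band in DEFAULT_BAND_SCHEME.values():
            if not ((spec.frequencies > band.lower) & (spec.frequencies <= band.upper)).any():
                continue  # short segments cannot resolve the lowest bands
            oracle = brute_force_dft_band_power(x, 10.0, band.lower, band.upper)
            assert band_power(spec, band) == pytest.approx(oracle, rel=1e-10)


class TestVmHs:
    def test_vm_worked_example(self, clean_myogenic_trace):
        """Single 0.1 Hz tone at fractional amplitude 4.8166e-3 gives the
        reference VM of 11.6 within the 5% leakage tolerance."""
        assert compute_vm(clean_myogenic_trace) == pytest.approx(11.6, rel=0.05)

    def test_vm_quadratic_in_amplitude(self, protocol, flat_response):
        def vm_for(amplitude):
            osc = OscillationSpec(tones=(BandTone("myogenic", 0.1, amplitude),))
            return compute_vm(generate_trace(protocol, osc, flat_response, 0.0, seed=2))

        assert vm_for(2 * VM_11P6_AMPLITUDE) == pytest.approx(4 * vm_for(VM_11P6_AMPLITUDE), rel=1e-6)

    def test_vm_monotone_in_amplitude(self, protocol, flat_response):
        vms = []
        for amplitude in (1e-3, 3e-3, 5e-3, 9e-3):
            osc = OscillationSpec(tones=(BandTone("myogenic", 0.1, amplitude),))
            vms.append(compute_vm(generate_trace(protocol, osc, flat_response, 0.0, seed=2)))
        assert np.all(np.diff(vms) > 0)

    def test_hs_worked_example(self, protocol, flat_response):
        """Reperfusion amplitude sqrt(2*150.6e-6) gives HS near 150.6."""
        amp = np.sqrt(2.0 * 150.6e-6)
        osc = OscillationSpec(
            tones=(BandTone("myogenic", 0.1, amp),), reperfusion_myogenic_gain=1.0
        )
        trace = generate_trace(protocol, osc, flat_response, noise_sd=0.0, seed=8)
        assert compute_hs(trace) == pytest.approx(150.6, rel=0.05)

    def test_hs_vm_ratio_is_gain_squared(self, protocol, flat_response):
        osc = OscillationSpec(
            tones=(BandTone("myogenic", 0.1, VM_11P6_AMPLITUDE),), reperfusion_myogenic_gain=3.6
        )
        trace = generate_trace(protocol, osc, flat_response, noise_sd=0.0, seed=8)
        assert compute_hs(trace) / compute_vm(trace) == pytest.approx(3.6**2, rel=0.05)

    def test_gain_one_gives_hs_equal_vm(self, protocol, flat_response):
        osc = OscillationSpec(
            tones=(BandTone("myogenic", 0.1, 5e-3),), reperfusion_myogenic_gain=1.0
        )
        trace = generate_trace(protocol, osc, flat_response, noise_sd=0.0, seed=8)
        assert compute_hs(trace) == pytest.approx(compute_vm(trace), rel=0.05)

    def test_gain_ratio_robust_to_porh_envelope(self, protocol):
        """The hyperemic envelope is removed by detrending: the HS/VM ratio
        stays within 5% of gain^2 with the full response present."""
        osc = OscillationSpec(
            tones=(BandTone("myogenic", 0.1, VM_11P6_AMPLITUDE),), reperfusion_myogenic_gain=3.6
        )
        trace = generate_trace(protocol, osc, ResponseSpec(), noise_sd=0.0, seed=8)
        assert compute_hs(trace) / compute_vm(trace) == pytest.approx(3.6**2, rel=0.05)

    def test_scale_invariance_of_all_parameters(self, protocol):
        import dataclasses

        osc = OscillationSpec()
        trace = generate_trace(protocol, osc, ResponseSpec(), noise_sd=1e-3, seed=4)
        scaled = dataclasses.replace(trace, fluorescence=123.4 * trace.fluorescence)
        res_a, res_b = analyze_trace(trace), analyze_trace(scaled)
        for key, value in res_a.to_dict().items():
            assert res_b.to_dict()[key] == pytest.approx(value, rel=1e-9), key


class TestLogParam:
    @pytest.mark.parametrize(
        "value,expected", [(11.6, 1.06), (150.6, 2.18), (38.3, 1.58), (246.0, 2.39), (1.0, 0.0)]
    )
    def test_reference_pairs_base10(self, value, expected):
        assert round(log_param(value), 2) == expected

    @pytest.mark.parametrize("bad", [0.0, -3.0, float("nan")])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            log_param(bad)


class TestBandShares:
    def test_single_tone_share_one(self):
        t = np.arange(1800) / 10.0
        spec = compute_psd(0.01 * np.sin(2 * np.pi * 0.1 * t), 10.0)
        shares = compute_band_shares(spec)
        assert shares["myogenic"] == pytest.approx(1.0, abs=0.02)

    def test_power_ratio_1_2_4(self):
        """Tones with powers 1:2:4 in endothelial:neurogenic:myogenic give
        shares 1/7, 2/7, 4/7 within leakage tolerance."""
        t = np.arange(7200) / 10.0  # long segment resolves the low bands
        base = 1e-3
        x = (
            base * np.sin(2 * np.pi * 0.015 * t)
            + base * np.sqrt(2) * np.sin(2 * np.pi * 0.035 * t + 1.0)
            + base * 2 * np.sin(2 * np.pi * 0.1 * t + 2.0)
        )
        shares = compute_band_shares(
            compute_psd(x, 10.0), bands_to_include=("endothelial", "neurogenic", "myogenic")
        )
        assert shares["endothelial"] == pytest.approx(1 / 7, abs=0.01)
        assert shares["neurogenic"] == pytest.approx(2 / 7, abs=0.01)
        assert shares["myogenic"] == pytest.approx(4 / 7, abs=0.01)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)

    def test_zero_power_rejected(self):
        spec = compute_psd(np.zeros(2000), 10.0)
        with pytest.raises(ValueError, match="zero"):
            compute_band_shares(spec)


class TestIrHr:
    def test_generator_round_trip(self, protocol):
        osc = OscillationSpec(tones=(BandTone("myogenic", 0.1, 0.0),))
        resp = ResponseSpec(ir_max=20.0, hr_max=25.0)
        trace = generate_trace(protocol, osc, resp, noise_sd=0.0, seed=1)
        ir, hr = compute_ir_hr(trace)
        assert ir == pytest.approx(20.0, rel=0.01)
        assert hr == pytest.approx(25.0, rel=0.01)

    def test_flat_trace_zero_response(self, protocol, flat_response):
        osc = OscillationSpec(tones=(BandTone("myogenic", 0.1, 0.0),))
        trace = generate_trace(protocol, osc, flat_response, noise_sd=0.0, seed=1)
        assert compute_ir_hr(trace) == (0.0, 0.0)

    def test_control_scale_round_trip(self, protocol):
        """IR_max set to the control-group mean 16.3% is recovered."""
        osc = OscillationSpec(tones=(BandTone("myogenic", 0.1, 0.0),))
        resp = ResponseSpec(ir_max=16.3, hr_max=19.8)
        ir, hr = compute_ir_hr(generate_trace(protocol, osc, resp, noise_sd=0.0, seed=1))
        assert ir == pytest.approx(16.3, rel=0.01)
        assert hr == pytest.approx(19.8, rel=0.01)
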