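"""LFP smoothing, CSD estimation, AVREC, layer traces, best frequency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal.windows import hamming

from lamcsd import (
    CsdProfile,
    LayerMap,
    LfpRecording,
    SimConfig,
    compute_avrec,
    compute_csd,
    compute_layer_traces,
    compute_traces,
    find_best_frequency,
    lfp_from_csd_array,
    smooth_lfp,
)


def rec_from(arr, fs=1000.0, dz=50.0):
    return LfpRecording(np.asarray(arr, dtype=float), fs, dz)


class TestSmoothLfp:
    def test_constant_profile_unchanged(self):
        rec = rec_from(np.full((2, 32, 10), 4.2))
        out = smooth_lfp(rec, 7)
        assert np.allclose(out.potentials, 4.2, rtol=1e-14)

    def test_window_one_is_identity(self, rng):
        rec = rec_from(rng.standard_normal((2, 16, 8)))
        out = smooth_lfp(rec, 1)
        assert np.array_equal(out.potentials, rec.potentials)

    def test_impulse_response_matches_explicit_weighted_sum(self, rng):
        """A depth impulse spreads into the normalized 7-point Hamming
        weights; checked against a brute-force loop over the window at every
        channel, including truncated edges."""
        x = np.zeros((1, 32, 1))
        x[0, 16, 0] = 1.0
        out = smooth_lfp(rec_from(x), 7).potentials[0, :, 0]

        w = hamming(7, sym=True)
        expected = np.zeros(32)
        for c in range(32):
            num = den = 0.0
            for j in range(-3, 4):
                if 0 <= c + j < 32:
                    num += w[j + 3] * x[0, c + j, 0]
                    den += w[j + 3]
            expected[c] = num / den
        assert np.allclose(out, expected, atol=1e-14)
        assert np.allclose(out[13:20], w / w.sum(), atol=1e-14)

    def test_random_profile_matches_loop_oracle(self, rng):
        pot = rng.standard_normal((3, 12, 5))
        out = smooth_lfp(rec_from(pot), 5).potentials
        w = hamming(5, sym=True)
        for t in range(3):
            for c in range(12):
                num = den = 0.0
                for j in range(-2, 3):
                    if 0 <= c + j < 12:
                        num += w[j + 2] * pot[t, c + j]
                        den += w[j + 2]
                assert np.allclose(out[t, c], num / den, atol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_lfp(rec_from(np.zeros((1, 8, 4))), 4)

    @given(c=st.floats(-100, 100), w=st.sampled_from([3, 5, 7]))
    @settings(max_examples=25, deadline=None)
    def test_property_constants_preserved(self, c, w):
        rec = rec_from(np.full((1, 16, 3), c))
        assert np.allclose(smooth_lfp(rec, w).potentials, c, atol=1e-9 * max(1, abs(c)))


class TestComputeCsd:
    def test_affine_in_depth_annihilated(self):
        z = np.arange(32, dtype=float)
        pot = (2.5 * z - 7.0)[None, :, None] * np.ones((3, 1, 6))
        prof = compute_csd(rec_from(pot), n=1, pad="none")
        assert np.allclose(prof.csd, 0.0, atol=1e-9)

    def test_smoothed_affine_still_annihilated(self):
        """Hamming smoothing preserves interior affine structure, so the CSD
        of a smoothed affine-in-depth LFP is zero on channels where neither
        stage touched the probe edge."""
        z = np.arange(32, dtype=float)
        pot = (1.5 * z + 2.0)[None, :, None] * np.ones((1, 1, 4))
        sm = smooth_lfp(rec_from(pot), 7)
        prof = compute_csd(sm, n=1, pad="none")
        inner = prof.csd[:, 3:-3, :]  # clear of edge truncation effects
        assert np.allclose(inner, 0.0, atol=1e-9)

    def test_quadratic_unit_grid_gives_two(self):
        z = np.arange(10, dtype=float)
        pot = (z ** 2)[None, :, None]
        prof = compute_csd(rec_from(pot, dz=1000.0), n=1, pad="none")  # dz = 1 mm
        assert np.allclose(prof.csd, 2.0, rtol=1e-12)

    def test_forward_model_roundtrip(self, rng):
        csd = rng.standard_normal((2, 32, 40))
        rec = rec_from(lfp_from_csd_array(csd, 0.05))
        back = compute_csd(rec, n=1, pad="none")
        x = csd[:, 1:-1, :]
        assert np.max(np.abs(back.csd - x)) / np.max(np.abs(x)) < 1e-9
        assert np.array_equal(back.valid_channels, np.arange(1, 31))

    def test_pad_none_shrinks_by_2n(self, rng):
        pot = rng.standard_normal((1, 32, 5))
        for n in (1, 2, 3):
            prof = compute_csd(rec_from(pot), n=n, pad="none")
            assert prof.csd.shape[1] == 32 - 2 * n

    def test_pad_replicate_keeps_all_channels_flags_boundary(self, rng):
        pot = rng.standard_normal((1, 32, 5))
        prof = compute_csd(rec_from(pot), n=1, pad="replicate")
        assert prof.csd.shape[1] == 32
        assert prof.provenance["boundary_channels"] == [0, 31]
        inner = compute_csd(rec_from(pot), n=1, pad="none")
        assert np.allclose(prof.csd[:, 1:-1, :], inner.csd, rtol=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="channels"):
            compute_csd(rec_from(np.zeros((1, 4, 3))), n=2)
        with pytest.raises(ValueError, match="pad"):
            compute_csd(rec_from(np.zeros((1, 8, 3))), pad="mirror")


class TestAvrec:
    def test_zero_csd_zero_avrec(self):
        prof = CsdProfile(np.zeros((2, 5, 4)), np.arange(5), 1000.0)
        assert np.all(compute_avrec(prof) == 0.0)

    def test_symmetric_plus_minus_c(self):
        csd = np.concatenate([np.full((1, 4, 3), 2.0), np.full((1, 4, 3), -2.0)], axis=1)
        prof = CsdProfile(csd, np.arange(8), 1000.0)
        assert np.allclose(compute_avrec(prof), 2.0, rtol=1e-14)

    def test_matches_two_loop_oracle(self, rng):
        csd = rng.standard_normal((3, 7, 11))
        prof = CsdProfile(csd, np.arange(7), 1000.0)
        av = compute_avrec(prof)
        for tr in range(3):
            for t in range(11):
                expect = sum(abs(csd[tr, c, t]) for c in range(7)) / 7
                assert abs(av[tr, t] - expect) < 1e-12

    @given(alpha=st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_property_absolute_homogeneity(self, alpha):
        rng = np.random.default_rng(7)
        csd = rng.standard_normal((1, 6, 5))
        base = compute_avrec(CsdProfile(csd, np.arange(6), 1000.0))
        scaled = compute_avrec(CsdProfile(alpha * csd, np.arange(6), 1000.0))
        assert np.allclose(scaled, abs(alpha) * base, rtol=1e-12, atol=1e-15)


class TestLayerTraces:
    def test_all_positive_layer_gives_zero(self):
        csd = np.full((1, 32, 4), 1.5)
        prof = CsdProfile(csd, np.arange(32), 1000.0)
        traces = compute_layer_traces(prof, LayerMap.default_32())
        for arr in traces.values():
            assert np.all(arr == 0.0)

    def test_uniform_sink_passes_through(self):
        csd = np.full((1, 32, 4), -3.0)
        prof = CsdProfile(csd, np.arange(32), 1000.0)
        traces = compute_layer_traces(prof, LayerMap({"L": (10, 12)}))
        assert np.allclose(traces["L"], -3.0, rtol=1e-14)

    def test_mixed_sign_divisor_includes_zeroed_channels(self):
        csd = np.zeros((1, 32, 1))
        csd[0, 10, 0], csd[0, 11, 0], csd[0, 12, 0] = -6.0, 2.0, 0.0
        prof = CsdProfile(csd, np.arange(32), 1000.0)
        traces = compute_layer_traces(prof, LayerMap({"L": (10, 13)}))
        assert traces["L"][0, 0] == pytest.approx(-2.0, abs=1e-15)

    def test_matches_brute_force_oracle(self, rng):
        csd = rng.standard_normal((2, 32, 6))
        prof = CsdProfile(csd, np.arange(32), 1000.0)
        lm = LayerMap.default_32()
        traces = compute_layer_traces(prof, lm)
        for name in lm:
            chans = lm.channels(name)
            for tr in range(2):
                for t in range(6):
                    vals = [min(csd[tr, c, t], 0.0) for c in chans]
                    assert abs(traces[name][tr, t] - sum(vals) / len(vals)) < 1e-12

    def test_traces_nonpositive_avrec_nonnegative(self, small_dataset, layer_map):
        rec = small_dataset.recordings[0]
        prof = compute_csd(smooth_lfp(rec, 7), pad="replicate")
        ts = compute_traces(prof, layer_map)
        assert np.all(ts.avrec >= 0)
        for arr in ts.layer_traces.values():
            assert np.all(arr <= 0)

    def test_layer_outside_valid_channels_names_layer(self):
        csd = np.zeros((1, 30, 4))
        prof = CsdProfile(csd, np.arange(1, 31), 1000.0)  # pad=none indexing
        with pytest.raises(ValueError, match="'II'"):
            compute_layer_traces(prof, LayerMap.default_32())


class TestBestFrequency:
    @staticmethod
    def profile_with_sink(amplitude, rng=None, noise=0.0, n_trials=5):
        csd = np.zeros((n_trials, 32, 250))
        csd[:, 6:12, 20:80] = amplitude
        if noise:
            csd += noise * rng.standard_normal(csd.shape)
        return CsdProfile(csd, np.arange(32), 1000.0)

    def test_single_frequency_returned(self):
        profiles = {"1kHz": self.profile_with_sink(-1.0)}
        assert find_best_frequency(profiles, LayerMap.default_32()) == "1kHz"

    def test_strongest_sink_wins(self):
        profiles = {"1000": self.profile_with_sink(-1.0),
                    "2000": self.profile_with_sink(-5.0)}
        assert find_best_frequency(profiles, LayerMap.default_32()) == "2000"

    def test_missing_granular_layer_errors(self):
        profiles = {"1000": self.profile_with_sink(-1.0)}
        with pytest.raises(ValueError, match="IV"):
            find_best_frequency(profiles, LayerMap({"II": (0, 6)}))

    def test_recovery_under_noise_snr10(self):
        """Gaussian tuning curve over 7 frequencies, peak at index 3, trial
        noise at SNR 10: the peak frequency is recovered in >= 95% of 200
        seeded replicates."""
        freqs = [125 * 2 ** i for i in range(7)]
        tuning = -np.exp(-0.5 * ((np.arange(7) - 3) / 1.2) ** 2)  # peak idx 3
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(200):
            profiles = {
                str(f): self.profile_with_sink(tuning[i], rng, noise=abs(tuning[i]) / 10
                                               if tuning[i] else 0.1)
                for i, f in enumerate(freqs)
            }
            if find_best_frequency(profiles, LayerMap.default_32()) == str(freqs[3]):
                hits += 1
        assert hits >= 190


class TestLayerMap:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            LayerMap({"A": (0, 6), "B": (5, 10)})

    def test_from_dict_one_based_inclusive(self):
        lm = LayerMap.from_dict({"II": (1, 6), "IV": (7, 12)}, 32)
        assert lm.ranges["II"] == (0, 6)
        assert lm.ranges["IV"] == (6, 12)

    def test_empty_or_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            LayerMap({"A": (3, 3)})
        with pytest.raises(ValueError, match="exceeds"):
            LayerMap({"A": (30, 40)}, 32)
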