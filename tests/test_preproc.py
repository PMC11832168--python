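"""Filtering, segmentation, rejection/interpolation, normalisation, inclusion."""

import numpy as np
import pandas as pd
import pytest

from slentrain import montage, preproc, simeeg, streamgen


def sine_recording(freq_hz, n_channels=4, duration_s=60.0, srate=250.0):
    t = np.arange(int(duration_s * srate)) / srate
    data = np.tile(np.sin(2 * np.pi * freq_hz * t), (n_channels, 1))
    events = pd.DataFrame({"onset": [0.0], "duration": [duration_s]})
    return simeeg.EEGRecording(data, srate, montage.make_montage(n_channels), events)


class TestFilter:
    def test_passband_preserves_4hz(self):
        rec = sine_recording(4.0)
        out = preproc.bandpass_filter(rec, 0.2, 20.0)
        mid = slice(2500, -2500)  # avoid edge transients
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_highpass_attenuates_slow_drift(self):
        rec = sine_recording(0.05, duration_s=200.0)
        out = preproc.bandpass_filter(rec, 0.2, None)
        mid = slice(10000, -10000)
        atten_db = 20 * np.log10(rec.data[0, mid].std() / out.data[0, mid].std())
        assert atten_db >= 20

    def test_bandpass_reduces_white_noise_variance(self, rng):
        rec = sine_recording(4.0)
        rec.data = rng.standard_normal(rec.data.shape)
        out = preproc.bandpass_filter(rec, 0.2, 20.0)
        assert out.data.var() < 0.5 * rec.data.var()

    def test_invalid_band_rejected(self):
        rec = sine_recording(4.0)
        with pytest.raises(ValueError):
            preproc.bandpass_filter(rec, 30.0, 20.0)
        with pytest.raises(ValueError):
            preproc.bandpass_filter(rec, 0.2, 200.0)


class TestSegmentation:
    def test_random_stream_gives_240_epochs(self):
        stream = streamgen.generate_random_stream(480, seed=0)
        cfg = simeeg.SimulationConfig(n_channels=4, seed=0)
        rec = simeeg.simulate_stream_eeg(stream, cfg)
        segs = preproc.segment_duplets(rec)
        assert segs.n_epochs == 240
        assert segs.epochs.shape[2] == 125

    def test_ten_short_streams_give_600_epochs(self):
        lex = streamgen.build_lexicon("phoneme", "A")
        cfg = simeeg.SimulationConfig(n_channels=4, seed=0)
        pieces = []
        for b in range(10):
            s = streamgen.generate_structured_stream(
                lex, 60, seed=b, condition=streamgen.Condition.structured_short
            )
            pieces.append(simeeg.simulate_stream_eeg(s, cfg))
            pieces[-1].events["stream_id"] = f"short_{b}"
        rec = simeeg.concatenate_recordings(pieces)
        segs = preproc.segment_duplets(rec)
        assert segs.n_epochs == 600
        assert len(np.unique(segs.segment_ids)) == 10

    def test_empty_events_error(self):
        rec = sine_recording(4.0)
        with pytest.raises(ValueError):
            preproc.segment_duplets(rec, rec.events.iloc[:0])


def make_epochset(n_epochs=4, n_channels=128, n_samples=125, seed=0):
    r = np.random.default_rng(seed)
    return preproc.EpochSet(
        r.standard_normal((n_epochs, n_channels, n_samples)),
        0.5 * np.arange(n_epochs),
        np.ones(n_epochs, bool),
        np.array(["structured_long"] * n_epochs, dtype=object),
        250.0,
    )


class TestRejection:
    def test_forty_of_128_rejected(self, positions_128):
        eps = make_epochset()
        eps.artifact_mask[0, :40, 10] = True  # 31% of channels at one sample
        out = preproc.reject_and_interpolate(eps, positions_128)
        assert not out.valid[0]
        assert out.valid[1:].all()

    def test_threshold_is_strictly_greater(self, positions_128):
        eps = make_epochset()
        eps.artifact_mask[0, :38, 10] = True  # 29.7% — below the 30% rule
        out = preproc.reject_and_interpolate(eps, positions_128)
        assert out.valid[0]

    def test_clean_epoch_bit_identical(self, positions_128):
        eps = make_epochset()
        out = preproc.reject_and_interpolate(eps, positions_128)
        assert np.array_equal(out.epochs, eps.epochs)

    def test_interpolation_is_weighted_neighbour_mean(self, positions_128):
        eps = make_epochset(n_epochs=2)
        eps.artifact_mask[0, 5, 30] = True
        out = preproc.reject_and_interpolate(eps, positions_128)
        d = np.linalg.norm(positions_128 - positions_128[5], axis=1)
        d[5] = np.inf
        neigh = np.argsort(d)[:8]
        w = 1 / d[neigh]
        expected = np.dot(w, eps.epochs[0, neigh, 30]) / w.sum()
        assert out.epochs[0, 5, 30] == pytest.approx(expected)
        # untouched elsewhere
        assert np.array_equal(out.epochs[1], eps.epochs[1])

    def test_matches_brute_force_oracle(self, positions_128, rng):
        eps = make_epochset(n_epochs=30, seed=3)
        mask = rng.random((30, 128, 125)) < 0.004
        heavy = rng.choice(30, 6, replace=False)
        for e in heavy:
            eps.artifact_mask[e, : rng.integers(30, 80), rng.integers(125)] = True
        eps.artifact_mask |= mask
        out = preproc.reject_and_interpolate(eps, positions_128)
        oracle = preproc.brute_force_rejection_oracle(eps.artifact_mask, 128)
        assert np.array_equal(~out.valid, oracle)


class TestReshape:
    def test_240_clean_epochs_make_16_long(self):
        eps = make_epochset(n_epochs=240, n_channels=4)
        long = preproc.reshape_long_epochs(eps)
        assert long.n_epochs == 16
        assert long.epochs.shape[2] == 1875

    def test_29_clean_epochs_make_1_long(self):
        eps = make_epochset(n_epochs=29, n_channels=4)
        long = preproc.reshape_long_epochs(eps)
        assert long.n_epochs == 1

    def test_first_long_epoch_is_first_15_duplets(self):
        eps = make_epochset(n_epochs=31, n_channels=2)
        long = preproc.reshape_long_epochs(eps)
        expected = np.concatenate(eps.epochs[:15], axis=1)
        assert np.array_equal(long.epochs[0], expected)
        assert long.epoch_onsets_s[0] == eps.epoch_onsets_s[0]

    def test_invalid_epochs_skipped(self):
        eps = make_epochset(n_epochs=31, n_channels=2)
        eps.valid[0] = False
        long = preproc.reshape_long_epochs(eps)
        assert long.n_epochs == 2
        assert np.array_equal(long.epochs[0], np.concatenate(eps.epochs[1:16], axis=1))

    def test_never_mixes_stream_segments(self):
        eps = make_epochset(n_epochs=40, n_channels=2)
        eps.segment_ids = np.repeat([0, 1], 20)
        long = preproc.reshape_long_epochs(eps)
        assert long.n_epochs == 2  # 20 -> 1 per segment, leftovers dropped


class TestNormalisation:
    def test_reference_and_scale(self):
        eps = make_epochset(n_epochs=3, n_channels=8)
        out = preproc.reference_and_normalize(eps)
        assert np.allclose(out.epochs.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(out.epochs.std(axis=(1, 2)), 1.0, atol=1e-10)

    def test_idempotent(self):
        eps = make_epochset(n_epochs=2, n_channels=8)
        once = preproc.reference_and_normalize(eps)
        twice = preproc.reference_and_normalize(once)
        assert np.allclose(once.epochs, twice.epochs, atol=1e-12)

    def test_constant_epoch_errors(self):
        eps = make_epochset(n_epochs=2, n_channels=4)
        eps.epochs[0] = 3.14
        with pytest.raises(ValueError):
            preproc.reference_and_normalize(eps)


class TestInclusion:
    @pytest.mark.parametrize(
        "n_rand, n_struct, included",
        [(7, 40, False), (8, 28, True), (16, 27, False), (16, 56, True)],
    )
    def test_entrainment_thresholds(self, n_rand, n_struct, included):
        rec = preproc.apply_inclusion_rules("s", "phoneme", n_rand, n_struct, 90, 90)
        assert rec.included_entrainment is included

    @pytest.mark.parametrize(
        "n_word, n_pw, included", [(44, 90, False), (45, 45, True), (90, 44, False)]
    )
    def test_erp_thresholds(self, n_word, n_pw, included):
        rec = preproc.apply_inclusion_rules("s", "voice", 16, 56, n_word, n_pw)
        assert rec.included_erp is included

    def test_exclusion_reason_recorded(self):
        rec = preproc.apply_inclusion_rules("s", "phoneme", 7, 56, 90, 90)
        assert "random" in rec.reason
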