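"""Context stacking, the MLP forward map, training behavior, dataset splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vocalmix import scenes
from vocalmix.dsp import AudioSignal, MagnitudeSpectrogram, STFTConfig
from vocalmix.metrics import bss_decompose, evaluate_pair
from vocalmix.separator import (
    SeparatorModel,
    SourcePair,
    TrainConfig,
    chunk_and_split,
    forward,
    load_checkpoint,
    save_checkpoint,
    separate,
    stack_context,
    train,
)

RATE = 44_100


def mag_spec(frames, cfg=None):
    cfg = cfg or STFTConfig()
    return MagnitudeSpectrogram(frames, cfg, origin_length=frames.shape[0] * cfg.hop)


class TestStackContext:
    def test_row_dimension_is_three_times_bins(self):
        feats = stack_context(mag_spec(np.abs(np.random.default_rng(0).standard_normal((6, 513)))))
        assert feats.rows.shape == (6, 1539)

    def test_single_frame_padded_with_zeros(self):
        frame = np.arange(513, dtype=float)[None, :]
        feats = stack_context(mag_spec(frame))
        np.testing.assert_array_equal(feats.rows[0, :1026], 0.0)
        np.testing.assert_array_equal(feats.rows[0, 1026:], frame[0])

    def test_causal_blocks_enumerated_by_hand(self):
        frames = np.stack([np.full(513, i + 1.0) for i in range(5)])
        rows = stack_context(mag_spec(frames)).rows
        # row 3 holds frames 1, 2, 3 (constants 2, 3, 4)
        np.testing.assert_array_equal(rows[3, :513], 2.0)
        np.testing.assert_array_equal(rows[3, 513:1026], 3.0)
        np.testing.assert_array_equal(rows[3, 1026:], 4.0)
        # stride of one frame: successive rows share two frames of context
        np.testing.assert_array_equal(rows[4, :1026], rows[3, 513:])

    def test_empty_spectrogram_rejected(self):
        with pytest.raises(ValueError):
            stack_context(mag_spec(np.empty((0, 513))))


def tiny_model(w1, b1, w2, b2, cfg=None):
    return SeparatorModel(
        w1=w1, b1=b1, w2=w2, b2=b2, input_scale=1.0, stft_config=cfg or STFTConfig()
    )


class TestForward:
    def test_zero_weights_give_zero_outputs(self, small_model, default_cfg):
        model = tiny_model(
            np.zeros_like(small_model.w1), np.zeros_like(small_model.b1),
            np.zeros_like(small_model.w2), np.zeros_like(small_model.b2),
        )
        feats = stack_context(mag_spec(np.abs(np.random.default_rng(1).standard_normal((4, 513)))))
        v, i = forward(model, feats)
        assert np.all(v.frames == 0) and np.all(i.frames == 0)

    def test_output_width_is_two_spectra(self, small_model):
        feats = stack_context(mag_spec(np.abs(np.random.default_rng(2).standard_normal((3, 513)))))
        v, i = forward(small_model, feats)
        assert v.frames.shape[1] == 513 and i.frames.shape[1] == 513
        assert small_model.output_dim == 1026

    def test_hand_computed_two_layer_map(self):
        """1-bin toy: rectified affine layers checked against pencil arithmetic."""
        # input dim 3 (three 1-bin frames), hidden 2, output 2 (vocal+instr bins)
        w1 = np.array([[1.0, -1.0], [0.0, 1.0], [2.0, 0.0]])
        b1 = np.array([0.5, -0.25])
        w2 = np.array([[1.0, -2.0], [3.0, 1.0]])
        b2 = np.array([-1.0, 0.5])
        model = tiny_model(w1, b1, w2, b2, cfg=STFTConfig(window_len=2, hop=1))
        x = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        # row 0: h = relu([1*1+0*2+2*3+0.5, -1+2-0.25]) = [7.5, 0.75]
        #        out = relu([7.5+2.25-1, -15+0.75+0.5]) = [8.75, 0]
        # row 1: h = relu([0.5, -0.25]) = [0.5, 0]; out = relu([-0.5, -0.5]) = [0, 0]
        v, i = model.predict(x)
        np.testing.assert_allclose(np.column_stack([v, i]), [[8.75, 0.0], [0.0, 0.0]])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_outputs_always_non_negative(self, seed):
        rng = np.random.default_rng(seed)
        model = tiny_model(
            rng.standard_normal((6, 4)), rng.standard_normal(4),
            rng.standard_normal((4, 2)), rng.standard_normal(2),
            cfg=STFTConfig(window_len=2, hop=1),
        )
        v, i = model.predict(rng.standard_normal((5, 6)))
        assert np.all(v >= 0) and np.all(i >= 0)

    def test_dimension_mismatch_rejected(self, small_model):
        with pytest.raises(ValueError):
            small_model.predict(np.zeros((2, 100)))


class TestTraining:
    def test_learning_rate_schedule(self):
        cfg = TrainConfig(initial_lr=0.005, lr_decay_per_epoch=0.9)
        assert cfg.learning_rate(0) == 0.005
        assert cfg.learning_rate(1) == pytest.approx(0.0045)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainConfig(epochs=1))

    def test_identical_seed_gives_bit_identical_history(self):
        pair = scenes.disjoint_band_pair(1.0, seed=0)
        cfg = TrainConfig(epochs=2, seed=5, hidden_units=16)
        _, h1 = train([pair], cfg)
        m2, h2 = train([pair], cfg)
        assert h1 == h2
        m1, _ = train([pair], cfg)
        np.testing.assert_array_equal(m1.w1, m2.w1)

    def test_loss_history_length_matches_epochs(self):
        pair = scenes.disjoint_band_pair(1.0, seed=1)
        _, hist = train([pair], TrainConfig(epochs=3, seed=0, hidden_units=16))
        assert len(hist) == 3

    def test_loss_converges_on_separable_data(self, trained_disjoint):
        _, hist = trained_disjoint
        assert hist[-1] < 0.25 * hist[0]
        assert np.median(hist[-5:]) < np.median(hist[:5])

    def test_heldout_sdr_exceeds_10db(self, trained_disjoint, disjoint_holdout):
        model, _ = trained_disjoint
        est = separate(model, disjoint_holdout.mixture)
        ev = evaluate_pair(est, disjoint_holdout)
        assert ev.vocal.sdr_db > 10.0

    def test_beats_mixture_baseline_by_5db(self, trained_disjoint, disjoint_holdout):
        """Capacity sanity: trained model vs 'predict the mixture for both'."""
        model, _ = trained_disjoint
        truths = [disjoint_holdout.vocal, disjoint_holdout.instruments]
        baseline = bss_decompose(disjoint_holdout.mixture, truths, 0)
        est = separate(model, disjoint_holdout.mixture)
        trained = bss_decompose(est.vocal, truths, 0)
        assert trained.sdr_db >= baseline.sdr_db + 5.0


class TestSeparate:
    def test_silent_mixture_gives_silent_estimates(self, small_model):
        est = separate(small_model, AudioSignal(np.zeros(10_000)))
        assert np.all(est.vocal.samples == 0)
        assert np.all(est.instruments.samples == 0)

    def test_estimates_match_input_length(self, small_model):
        mixture = AudioSignal(np.random.default_rng(3).standard_normal(12_345) * 0.1)
        est = separate(small_model, mixture)
        assert len(est.vocal) == len(est.instruments) == 12_345

    def test_oracle_magnitudes_through_pipeline_exceed_10db(self, disjoint_pair):
        """Ideal magnitudes fed through `separate` bound the pipeline quality."""
        from vocalmix.dsp import stft
        from vocalmix.separator import OracleModel

        model = OracleModel(
            stft(disjoint_pair.vocal).magnitude(),
            stft(disjoint_pair.instruments).magnitude(),
        )
        est = separate(model, disjoint_pair.mixture)
        ev = evaluate_pair(est, disjoint_pair)
        assert ev.vocal.sdr_db > 10.0 and ev.instruments.sdr_db > 10.0

    def test_magnitudes_summing_to_mixture_reconstruct_it(self, disjoint_pair):
        """Phase-reapplied synthesis is linear: |X| split two ways sums back to x."""
        from vocalmix.dsp import resynthesize_with_mixture_phase, stft

        spec = stft(disjoint_pair.mixture)
        mag = np.abs(spec.frames)
        rng = np.random.default_rng(0)
        alpha = rng.uniform(0, 1, mag.shape)
        part = lambda a: MagnitudeSpectrogram(a, spec.config, spec.origin_length)
        v = resynthesize_with_mixture_phase(part(alpha * mag), spec)
        i = resynthesize_with_mixture_phase(part((1 - alpha) * mag), spec)
        np.testing.assert_allclose(
            v.samples + i.samples, disjoint_pair.mixture.samples, atol=1e-9
        )


class TestSourcePair:
    def test_mixture_sum_invariant_enforced(self):
        v = AudioSignal(np.ones(100) * 0.1)
        i = AudioSignal(np.ones(100) * 0.2)
        with pytest.raises(ValueError):
            SourcePair(v, i, AudioSignal(np.ones(100)))
        pair = SourcePair.from_sources(v, i)
        np.testing.assert_allclose(pair.mixture.samples, 0.3, rtol=1e-12)


class TestChunkAndSplit:
    def _track(self, seconds, ident, seed=0):
        n = int(seconds * RATE)
        rng = np.random.default_rng(seed)
        v = AudioSignal(rng.standard_normal(n) * 0.01)
        i = AudioSignal(rng.standard_normal(n) * 0.01)
        return SourcePair.from_sources(v, i, identifier=ident)

    def test_95s_track_yields_three_chunks(self):
        corpus = chunk_and_split([self._track(95 / 30, "t", 0)], chunk_seconds=1.0)
        assert len(corpus.chunks) == 3
        assert all(len(p) == RATE for p in corpus.chunks.values())

    def test_ten_tracks_split_6_2_2(self):
        tracks = [self._track(0.1, f"t{i}", i) for i in range(10)]
        corpus = chunk_and_split(tracks, chunk_seconds=0.1, seed=1)
        sizes = (len(corpus.split.train), len(corpus.split.validation), len(corpus.split.test))
        assert sizes == (6, 2, 2)

    def test_split_is_deterministic_and_disjoint(self):
        tracks = [self._track(0.1, f"t{i}", i) for i in range(7)]
        c1 = chunk_and_split(tracks, chunk_seconds=0.1, seed=42)
        c2 = chunk_and_split(tracks, chunk_seconds=0.1, seed=42)
        assert c1.split == c2.split
        ids = c1.split.train + c1.split.validation + c1.split.test
        assert sorted(ids) == sorted(c1.chunks)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            chunk_and_split([self._track(0.1, "t")], fractions=(0.5, 0.2, 0.2))


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, small_model, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(small_model, path)
        loaded = load_checkpoint(path)
        rows = np.random.default_rng(4).standard_normal((3, small_model.input_dim))
        for a, b in zip(small_model.predict(rows), loaded.predict(rows)):
            np.testing.assert_array_equal(a, b)
        assert loaded.stft_config == small_model.stft_config
        assert loaded.input_scale == small_model.input_scale
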