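"""Synthetic-EMG generator: spectra, confound structure, protocols, streams."""

import numpy as np
import pytest
from scipy import signal as sps

from emgrasp.classes import GRASPS, HAND_OPEN, NO_MOVEMENT
from emgrasp.features import FeatureConfig, sliding_window_features
from emgrasp.lda import predict_batch, train_lda, two_fold_cv
from emgrasp.synth import (DYNAMIC_DOFS, STATIC_POSITIONS, ProtocolSpec, SubjectSkill,
                           SubjectStream, SynthConfig, generate_protocol, parse_wrist_tag,
                           stream_subject, synth_trial)


def rms(x, axis=0):
    return np.sqrt(np.mean(np.asarray(x, dtype=float) ** 2, axis=axis))


@pytest.fixture(scope="module")
def config():
    return SynthConfig()


class TestSynthTrial:
    def test_same_seed_is_bitwise_identical(self, config):
        a = synth_trial("chuck", "static:neutral", 1000, config, 42)
        b = synth_trial("chuck", "static:neutral", 1000, config, 42)
        assert np.array_equal(a.samples, b.samples)

    def test_power_concentrated_in_acquisition_band(self, config):
        rec = synth_trial("power", "static:neutral", 10_000, config, 3)
        f, p = sps.welch(rec.samples.astype(float), fs=1000, nperseg=1024, axis=0)
        frac = p[(f >= 30) & (f <= 350)].sum() / p.sum()
        assert frac >= 0.95

    def test_wrist_confound_hits_extrinsic_channels_harder(self, config):
        neutral = synth_trial("chuck", "static:neutral", 4000, config, 11)
        flexed = synth_trial("chuck", "static:flexion", 4000, config, 11)
        ratio = rms(flexed.samples) / rms(neutral.samples)
        assert ratio[:8].mean() > ratio[8:].mean()

    def test_no_movement_sits_at_noise_floor(self, config):
        rec = synth_trial(NO_MOVEMENT, "static:neutral", 2000, config, 5)
        assert rms(rec.samples).mean() == pytest.approx(config.noise_floor, rel=0.3)

    def test_onset_transient_ramps_amplitude(self, config):
        rec = synth_trial("key", "static:neutral", 2000, config, 9)
        early = rms(rec.samples[:100]).mean()
        late = rms(rec.samples[1000:]).mean()
        assert early < 0.5 * late

    def test_unknown_class_or_wrist_raises(self, config):
        with pytest.raises(ValueError, match="unknown class"):
            synth_trial("wave", "static:neutral", 1000, config, 0)
        with pytest.raises(ValueError, match="valid tags"):
            synth_trial("chuck", "static:akimbo", 1000, config, 0)

    def test_wrist_tag_parsing(self):
        assert parse_wrist_tag("dynamic:flexion-extension:reverse") == (
            "dynamic", "extension", "flexion")
        assert parse_wrist_tag("static:pronation") == ("static", "pronation", "pronation")


class TestProtocols:
    def test_variable_wrist_protocol_counts(self, config):
        recs = generate_protocol(ProtocolSpec.variable_wrist(), config, 0)
        assert len(recs) == 224  # 8 postures x 7 positions x 4 reps
        assert all(r.duration_ms == 4000 for r in recs)
        tags = {r.wrist_condition for r in recs}
        assert tags == {f"static:{p}" for p in STATIC_POSITIONS}

    def test_dynamic_wrist_protocol_counts(self, config):
        recs = generate_protocol(ProtocolSpec.dynamic_wrist(), config, 0)
        assert len(recs) == 192  # 8 postures x 3 DOFs x 2 directions x 4 reps
        assert all(r.duration_ms == 4000 for r in recs)

    def test_hybrid_recordings_are_8s_with_hold_move_structure(self, config):
        recs = generate_protocol(
            ProtocolSpec.hybrid(postures=("chuck",)), config, 1)
        assert len(recs) == len(DYNAMIC_DOFS) * 2
        rec = recs[0]
        assert rec.duration_ms == 8000
        # during holds the wrist gain is constant: compare segment RMS of an
        # extrinsic channel across the two holds (start vs opposite position)
        hold1 = rms(rec.samples[1000:2000, 0])
        hold2 = rms(rec.samples[4500:5500, 0])
        assert hold1 != pytest.approx(hold2, rel=0.02)

    def test_realtime_training_protocol_counts(self, config):
        recs = generate_protocol(ProtocolSpec.realtime_training(), config, 0)
        neutral = [r for r in recs if r.wrist_condition == "static:neutral"]
        hybrid = [r for r in recs if r.wrist_condition.startswith("hybrid:")]
        assert len(neutral) == 6 * 2
        assert len(hybrid) == 6 * 6
        assert all(r.duration_ms == 8000 for r in hybrid)

    def test_rep_metadata_supports_two_folds(self, config):
        recs = generate_protocol(ProtocolSpec.neutral(postures=("chuck",)), config, 0)
        assert sorted(r.meta["rep"] for r in recs) == [1, 2, 3, 4]


class TestSeparabilityControl:
    @staticmethod
    def _cv_error(contrast, seed):
        cfg = SynthConfig(class_contrast=contrast)
        recs = generate_protocol(
            ProtocolSpec.neutral(postures=(NO_MOVEMENT, "chuck", "fine_pinch", "key")),
            cfg, seed)
        fc = FeatureConfig(window_ms=200)
        Xs, ys, folds = [], [], []
        for rec in recs:
            X, _, labs = sliding_window_features(rec, fc, end_min_ms=500)
            Xs.append(X)
            ys.append(labs)
            folds.append(np.full(len(labs), (rec.meta["rep"] - 1) % 2))
        return two_fold_cv(np.concatenate(Xs), np.concatenate(ys),
                           np.concatenate(folds), shrinkage=1e-2)

    def test_error_decreases_with_class_contrast(self):
        lo = np.mean([self._cv_error(0.1, s) for s in range(3)])
        hi = np.mean([self._cv_error(1.2, s) for s in range(3)])
        assert hi < lo


class TestSubjectStream:
    def test_same_seed_gives_identical_stream(self, config):
        sched = [(500, "chuck", "neutral"), (500, HAND_OPEN, "flexion")]
        a = stream_subject(sched, config, seed=4)
        b = stream_subject(sched, config, seed=4)
        assert np.array_equal(a, b)
        assert a.shape == (1000, 12)

    def test_pure_no_movement_stream_sits_at_noise_floor(self, config):
        x = stream_subject([(2000, NO_MOVEMENT, "neutral")], config, seed=1)
        assert rms(x).mean() == pytest.approx(config.noise_floor, rel=0.3)

    def test_zero_confusion_subject_decodes_cleanly(self):
        """A classifier trained on protocol data decodes the intended class
        of a confusion-free stream in >= 99 % of steady-state frames."""
        cfg = SynthConfig.well_separated()
        postures = (NO_MOVEMENT, HAND_OPEN, "chuck", "key")
        recs = generate_protocol(ProtocolSpec.neutral(postures=postures, reps=2), cfg, 0)
        fc = FeatureConfig(window_ms=250)
        Xs, ys = [], []
        for rec in recs:
            X, _, labs = sliding_window_features(rec, fc)
            Xs.append(X)
            ys.append(labs)
        model = train_lda(np.concatenate(Xs), np.concatenate(ys), shrinkage=1e-2)

        stream = SubjectStream(cfg, skill=SubjectSkill(burst_rate_hz=0.0), seed=7)
        hits = total = 0
        for cls in ("chuck", "key", NO_MOVEMENT):
            stream.set_intent(cls)
            buf = np.concatenate([stream.emit(25) for _ in range(160)])  # 4 s
            rec_like = type("R", (), {"n_samples": buf.shape[0], "n_channels": 12,
                                      "samples": buf,
                                      "labels": np.full(buf.shape[0], cls, dtype=object)})
            X, ends, _ = sliding_window_features(rec_like, fc, end_min_ms=1000)
            pred = predict_batch(model, X)
            hits += np.sum(pred == cls)
            total += len(pred)
        assert hits / total >= 0.99

    def test_burst_rate_produces_confusable_segments(self, config):
        skill = SubjectSkill(burst_rate_hz=5.0, burst_ms=100)
        stream = SubjectStream(config, skill=skill, seed=3)
        stream.set_intent("chuck")
        x = np.concatenate([stream.emit(25) for _ in range(200)])
        # with heavy bursting the channel profile must deviate from the pure
        # class pattern more than a burst-free stream does
        quiet = SubjectStream(config, skill=SubjectSkill(burst_rate_hz=0.0), seed=3)
        quiet.set_intent("chuck")
        xq = np.concatenate([quiet.emit(25) for _ in range(200)])
        gain = config.class_gain("chuck")
        dev = np.linalg.norm(rms(x[2000:]) - gain)
        dev_q = np.linalg.norm(rms(xq[2000:]) - gain)
        assert dev > dev_q
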