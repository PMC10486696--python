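"""Component fingerprinting, labelling rules, artifact back-projection."""

import numpy as np
import pytest

from holssa.artifacts import (
    ComponentScore,
    LabelThresholds,
    label_component,
    remove_and_backproject,
    score_component,
)
from holssa.synthetic import ArtifactSpec, SourceSpec, generate_artifact, generate_oscillation

FS = 250.0


def _score(**kw):
    base = dict(
        index=0, kurtosis=3.0, lowfreq_ratio=0.0, midband_ratio=0.0,
        highfreq_ratio=0.0, line_ratio=0.0, periodicity=0.0, period_s=0.0,
    )
    base.update(kw)
    return ComponentScore(**base)


class TestScoreComponent:
    def test_mains_tone_line_ratio(self):
        x = generate_artifact(ArtifactSpec("line_noise", amplitude=1, seed=0), FS, 10)
        assert score_component(x, FS).line_ratio >= 0.9

    def test_alpha_tone_midband_ratio(self):
        x = generate_oscillation(SourceSpec(center_freq=10, seed=0), FS, 10)
        assert score_component(x, FS).midband_ratio >= 0.9

    def test_blink_train_fingerprint(self):
        x = generate_artifact(ArtifactSpec("eog_blink", rate=0.3, amplitude=5, seed=4), FS, 20)
        s = score_component(x, FS)
        assert s.kurtosis > 3
        assert s.lowfreq_ratio > 0.6

    def test_ecg_periodicity_detected(self):
        x = generate_artifact(ArtifactSpec("ecg_spike", rate=1.2, seed=3), FS, 30)
        s = score_component(x, FS)
        assert s.periodicity > 0.3
        assert 0.6 <= s.period_s <= 1.5

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            score_component(np.zeros(100), FS)


class TestLabelComponent:
    def test_clear_brain(self):
        assert label_component(_score(midband_ratio=0.95)) == "brain"

    def test_line_precedence_over_everything(self):
        s = _score(line_ratio=0.95, highfreq_ratio=0.99, midband_ratio=0.9, kurtosis=30)
        assert label_component(s) == "line_noise"

    def test_eye_needs_both_lowfreq_and_kurtosis(self):
        assert label_component(_score(lowfreq_ratio=0.8, kurtosis=9)) == "eye"
        assert label_component(_score(lowfreq_ratio=0.8, kurtosis=3)) == "other"

    def test_heart_rule(self):
        s = _score(periodicity=0.6, period_s=0.85, kurtosis=12)
        assert label_component(s) == "heart"

    def test_impossible_thresholds_give_other(self):
        th = LabelThresholds(line=2, emg=2, eog=2, kurtosis=1e9, heart=2, brain=2)
        s = _score(line_ratio=0.99, midband_ratio=0.99, kurtosis=100)
        assert label_component(s, th) == "other"

    def test_generated_artifacts_get_expected_labels(self):
        cases = [
            (generate_artifact(ArtifactSpec("line_noise", amplitude=1, seed=1), FS, 20), "line_noise"),
            (generate_artifact(ArtifactSpec("emg_burst", rate=1.0, seed=1), FS, 20), "muscle"),
            (generate_artifact(ArtifactSpec("eog_blink", rate=0.3, amplitude=5, seed=1), FS, 20), "eye"),
            (generate_oscillation(SourceSpec(center_freq=10, seed=1), FS, 20), "brain"),
        ]
        for x, expected in cases:
            s = score_component(x, FS)
            assert label_component(s) == expected, (expected, s)


class TestRemoveAndBackproject:
    def test_keep_all_is_identity(self, rng):
        comp = rng.normal(size=(3, 500))
        mixing = rng.normal(size=(4, 3))
        labels = ["brain", "eye", "muscle"]
        out = remove_and_backproject(comp, labels, mixing, keep=set(labels))
        np.testing.assert_allclose(out, mixing @ comp, atol=1e-10)

    def test_single_kept_component_is_rank_one(self, rng):
        comp = rng.normal(size=(3, 500))
        mixing = rng.normal(size=(4, 3))
        out = remove_and_backproject(comp, ["brain", "eye", "eye"], mixing)
        assert np.linalg.matrix_rank(out) == 1

    def test_removing_eye_improves_correlation_with_clean_source(self, rng):
        """Mixture of alpha + blinks: dropping the eye component helps."""
        alpha = generate_oscillation(SourceSpec(center_freq=10, seed=2), FS, 20)
        eog = generate_artifact(ArtifactSpec("eog_blink", rate=0.4, amplitude=6, seed=2), FS, 20)
        mixing = np.array([[1.0, 0.8], [0.7, 1.2]])
        comp = np.vstack([alpha, eog])
        contaminated = mixing @ comp
        cleaned = remove_and_backproject(comp, ["brain", "eye"], mixing)
        for ch in range(2):
            clean_target = mixing[ch, 0] * alpha
            c_dirty = np.corrcoef(contaminated[ch], clean_target)[0, 1]
            c_clean = np.corrcoef(cleaned[ch], clean_target)[0, 1]
            assert c_clean > c_dirty

    def test_all_removed_is_error(self, rng):
        comp = rng.normal(size=(2, 100))
        with pytest.raises(ValueError, match="all-zero"):
            remove_and_backproject(comp, ["eye", "muscle"], np.eye(2))

    def test_shape_checks(self, rng):
        comp = rng.normal(size=(2, 100))
        with pytest.raises(ValueError):
            remove_and_backproject(comp, ["brain"], np.eye(2))
        with pytest.raises(ValueError):
            remove_and_backproject(comp, ["brain", "brain"], np.eye(3))
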