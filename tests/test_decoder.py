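"""Decoder operations and the leave-one-subject-out protocol."""

import numpy as np
import pytest

from invdecode.datatypes import ValidationError
from invdecode.decoder import (ConfigurationError, DecoderConfig,
                               TrainingHyper, build_decoder,
                               compare_stimulus_accuracies,
                               count_trainable_parameters, evaluate_decoder,
                               run_loso_protocol, train_decoder)


def test_reference_configuration_counts_1502():
    model = build_decoder(DecoderConfig(), seed=0)
    assert count_trainable_parameters(model) == 1502
    assert DecoderConfig().expected_parameter_count() == 1502


def test_count_matches_closed_form_for_variants():
    for cfg in (DecoderConfig(temporal_kernel_len=1, pool_factor=100,
                              spatial_depth_multiplier=1),
                DecoderConfig(spatial_depth_multiplier=4),
                DecoderConfig(temporal_kernel_len=17, pool_factor=4)):
        model = build_decoder(cfg, seed=0)
        assert count_trainable_parameters(model) == cfg.expected_parameter_count()


def test_invalid_pool_configuration():
    with pytest.raises(ConfigurationError):
        DecoderConfig(pool_factor=3)


def test_probabilities_sum_to_one(rng):
    model = build_decoder(seed=2)
    pred = model.predict(rng.standard_normal((5, 68, 100)))
    assert np.allclose(pred.probabilities.sum(axis=1), 1.0, atol=1e-6)
    with pytest.raises(ValidationError):
        model.predict(rng.standard_normal((5, 68, 50)))


def _separable_data(rng, n, scale=4.0):
    X = rng.standard_normal((n, 68, 100)).astype(np.float32)
    y = np.tile([0, 1], n // 2)
    X[y == 1, 20:24, 30:50] += scale
    return X, y


def test_training_fits_separable_data(rng):
    X, y = _separable_data(rng, 96)
    Xv, yv = _separable_data(rng, 16)
    model = train_decoder((X, y), (Xv, yv), seed=0,
                          hyper=TrainingHyper(lr=3e-3, max_epochs=60, patience=60))
    cm, acc = evaluate_decoder(model, (X, y))
    assert acc > 0.95


def test_training_determinism(rng):
    X, y = _separable_data(rng, 32)
    models = [train_decoder((X, y), (X[:8], y[:8]), seed=7,
                            hyper=TrainingHyper(max_epochs=4, patience=4))
              for _ in range(2)]
    for a, b in zip(models[0].net.parameters(), models[1].net.parameters()):
        assert np.array_equal(a, b)


def test_empty_validation_rejected(rng):
    X, y = _separable_data(rng, 8)
    with pytest.raises(ConfigurationError):
        train_decoder((X, y), (X[:0], y[:0]), seed=0)


class TestEvaluate:
    def test_perfect_and_degenerate_predictions(self):
        model = build_decoder(seed=0)

        class Stub:
            config = model.config

            def __init__(self, labels):
                self.labels = np.asarray(labels)

            def predict_labels(self, X):
                return self.labels

        import invdecode.decoder as dec

        y = np.array([0] * 10 + [1] * 10)
        cm, acc = dec.evaluate_decoder(Stub(y), (np.zeros((20, 68, 100)), y))
        assert acc == 1.0 and cm[0, 1] == 0 and cm[1, 0] == 0
        cm, acc = dec.evaluate_decoder(Stub(np.zeros(20, dtype=int)),
                                       (np.zeros((20, 68, 100)), y))
        assert acc == 0.5 and cm[1, 0] == 10

    def test_untrained_model_near_chance(self, rng):
        model = build_decoder(seed=3)
        X = rng.standard_normal((1000, 68, 100))
        y = np.tile([0, 1], 500)
        _, acc = evaluate_decoder(model, (X, y))
        assert 0.40 < acc < 0.60


class TestLOSO:
    def test_full_protocol_enumeration(self):
        from invdecode.datatypes import StimulusDataset, TrialMatrix

        # dry-run only needs dataset identity, not real data
        dss = [
            StimulusDataset(
                trials=[TrialMatrix(X=np.zeros((68, 100)), y=0, subject=s)],
                subject=s,
            )
            for s in range(23)
        ]
        runs = run_loso_protocol(dss, n_seeds=10, dry_run=True)
        assert len(runs) == 230  # x3 stimuli = 690 decoders overall
        assert len({(r["held_out_subject"], r["seed"]) for r in runs}) == 230

    def test_single_subject_rejected(self, tiny_cohort):
        with pytest.raises(ConfigurationError):
            run_loso_protocol(tiny_cohort["face"][:1], n_seeds=1)

    def test_two_subject_protocol(self, tiny_cohort, fast_hyper):
        res = run_loso_protocol(tiny_cohort["face"][:2], seeds=[0],
                                hyper=fast_hyper, keep_models=False)
        assert len(res.folds) == 2
        assert all(0.0 <= f.accuracy <= 1.0 for f in res.folds)
        assert res.folds[0].subject != res.folds[1].subject
        df = res.metrics_frame()
        assert set(df.columns) == {"stimulus", "subject", "seed", "accuracy"}


class TestCompareAccuracies:
    def test_identical_vectors_not_significant(self):
        v = np.linspace(0.5, 0.8, 23)
        df = compare_stimulus_accuracies(v, v, v)
        pw = df[df.kind == "pairwise"]
        assert len(pw) == 3
        assert (pw.p_corrected == 1.0).all()

    def test_large_uniform_shift_detected(self):
        rng = np.random.default_rng(0)
        house = 0.5 + 0.02 * rng.standard_normal(23)
        face = house + 0.2
        df = compare_stimulus_accuracies(face, face, house)
        row = df[df.test == "face vs house"].iloc[0]
        assert row.p_corrected < 0.05
        assert row.direction > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compare_stimulus_accuracies(np.ones(5), np.ones(5), np.ones(6))
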