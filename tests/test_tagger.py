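"""Tagger architecture, training schedule, and hyperparameter search."""

import numpy as np
import pytest

from medextract.labels import N_TAGS, TAG_TO_INDEX
from medextract.nn import Adam
from medextract.tagger import (
    ConfigError,
    EarlyStopping,
    ReduceLROnPlateau,
    TaggerConfig,
    build_model,
    decode_tags,
    encode_tags,
    load_model,
    predict,
    random_search,
    save_model,
    train,
)


def make_separable_dataset(n_sentences=20, seed=0):
    """Sentences where the input vector determines the tag exactly."""
    rng = np.random.default_rng(seed)
    prototypes = rng.normal(size=(N_TAGS, 12)) * 3.0
    data = []
    for _ in range(n_sentences):
        T = rng.integers(3, 9)
        y = rng.integers(0, N_TAGS, T)
        X = prototypes[y] + 0.01 * rng.normal(size=(T, 12))
        data.append((X, y))
    return data


class TestBuildModel:
    def test_parameter_shapes(self):
        cfg = TaggerConfig(hidden_size=128)
        model = build_model(cfg, 115)
        assert model.fwd.W.shape == (115, 4 * 128)
        assert model.bwd.U.shape == (128, 4 * 128)
        assert model.out.W.shape == (256, N_TAGS)

    def test_same_seed_same_initialization(self):
        cfg = TaggerConfig(seed=5)
        a, b = build_model(cfg, 20), build_model(cfg, 20)
        for k, v in a.params().items():
            np.testing.assert_array_equal(v, b.params()[k])

    def test_crf_flag_toggles_transition_table(self):
        assert build_model(TaggerConfig(use_crf=False), 10).transitions is None
        A = build_model(TaggerConfig(use_crf=True), 10).transitions
        assert A is not None and A.shape == (N_TAGS, N_TAGS)

    @pytest.mark.parametrize(
        "kwargs",
        [{"hidden_size": 100}, {"batch_size": 32}, {"dropout_before": 0.4},
         {"learning_rate": -1.0}],
    )
    def test_off_grid_values_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            TaggerConfig(**kwargs)


class TestSchedule:
    def test_improving_loss_never_stops(self):
        stopper = EarlyStopping(patience=8)
        assert not any(stopper.update(1.0 / (e + 1)) for e in range(50))

    def test_frozen_loss_stops_at_best_plus_patience(self):
        """Dev loss improving until epoch 3 then frozen stops at epoch 11."""
        stopper = EarlyStopping(patience=8)
        stopped_at = None
        losses = [3.0, 2.0, 1.0] + [1.0] * 47
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(loss):
                stopped_at = epoch
                break
        assert stopper.best_epoch == 3
        assert stopped_at == 11

    def test_plateau_reduces_lr_by_factor(self):
        opt = Adam({"w": np.zeros(1)}, lr=1e-3)
        sched = ReduceLROnPlateau(opt, factor=0.1, patience=3, min_delta=1e-4)
        for loss in (1.0, 0.5, 0.5, 0.5, 0.5):
            sched.update(loss)
        assert opt.lr == pytest.approx(1e-4)

    def test_improvement_below_min_delta_counts_as_plateau(self):
        opt = Adam({"w": np.zeros(1)}, lr=1e-3)
        sched = ReduceLROnPlateau(opt, factor=0.1, patience=2, min_delta=1e-4)
        sched.update(1.0)
        sched.update(1.0 - 5e-5)
        sched.update(1.0 - 6e-5)
        assert opt.lr == pytest.approx(1e-4)


class TestTraining:
    def test_empty_training_set_raises(self):
        cfg = TaggerConfig()
        with pytest.raises(ValueError):
            train(build_model(cfg, 12), [], [], cfg)

    def test_overfits_separable_corpus(self):
        data = make_separable_dataset()
        cfg = TaggerConfig(hidden_size=128, batch_size=64, max_epochs=120,
                           learning_rate=0.01, seed=0)
        model = build_model(cfg, 12)
        model, history = train(model, data, data, cfg)
        correct = total = 0
        preds = predict(model, [x for x, _ in data])
        for (x, y), tags in zip(data, preds):
            correct += sum(int(TAG_TO_INDEX[t] == yi) for t, yi in zip(tags, y))
            total += len(y)
        assert correct / total >= 0.99
        assert history.learning_rates[0] == 0.01

    def test_history_invariants(self):
        data = make_separable_dataset(8)
        cfg = TaggerConfig(max_epochs=5, seed=1)
        model, history = train(build_model(cfg, 12), data, data, cfg)
        assert history.stopped_epoch <= cfg.max_epochs
        assert history.learning_rates == sorted(history.learning_rates, reverse=True)
        assert len(history.dev_loss) == history.stopped_epoch


class TestPredict:
    def test_single_token_sentence(self):
        cfg = TaggerConfig()
        model = build_model(cfg, 6)
        (tags,) = predict(model, [np.zeros((1, 6))])
        assert len(tags) == 1

    def test_inference_is_deterministic(self):
        cfg = TaggerConfig(dropout_before=0.5, dropout_after=0.5)
        model = build_model(cfg, 6)
        x = np.random.default_rng(0).normal(size=(7, 6))
        assert predict(model, [x]) == predict(model, [x])

    def test_dimension_mismatch_raises(self):
        model = build_model(TaggerConfig(), 6)
        with pytest.raises(ValueError):
            predict(model, [np.zeros((3, 9))])

    def test_tag_round_trip(self):
        tags = ["O", "B-dosage", "I-dosage", "B-route"]
        assert decode_tags(encode_tags(tags)) == tags


class TestCRFPath:
    def test_transitions_change_decoding(self):
        """A transition table that forbids entering I from O must flip a
        dense-argmax decision on an ambiguous emission."""
        cfg = TaggerConfig(use_crf=True, seed=0)
        model = build_model(cfg, 4)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 4))
        X = x[None, :, :]
        lengths = np.array([5])
        logits, _ = model._encode(X, lengths)
        dense_choice = logits[0].argmax(axis=1)
        # forbid every transition into tag 2 (I-medication_name) from O
        model.transitions[...] = 0.0
        model.transitions[TAG_TO_INDEX["O"], TAG_TO_INDEX["I-medication_name"]] = -50.0
        model.transitions[:, dense_choice[2]] -= 30.0
        (marginal_choice,) = model.decode(X, lengths)
        assert not np.array_equal(marginal_choice, dense_choice)

    def test_crf_training_runs_and_improves(self):
        data = make_separable_dataset(10, seed=2)
        cfg = TaggerConfig(use_crf=True, max_epochs=8, learning_rate=0.01, seed=2)
        model, history = train(build_model(cfg, 12), data, data, cfg)
        assert history.dev_loss[-1] < history.dev_loss[0]

    def test_viterbi_flag_changes_decoder_not_shapes(self):
        cfg = TaggerConfig(use_crf=True, viterbi=True)
        model = build_model(cfg, 6)
        (tags,) = predict(model, [np.zeros((4, 6))])
        assert len(tags) == 4


class TestRandomSearch:
    SPACE = {"hidden_size": [128, 256], "dropout_before": [0.0, 0.2]}

    def _data(self):
        return make_separable_dataset(6, seed=3)

    def test_seed_reproducible_trial_sequence(self):
        data = self._data()
        base = TaggerConfig(max_epochs=2)
        _, _, t1 = random_search(self.SPACE, data, data, n_iter=4, seed=9, base=base)
        _, _, t2 = random_search(self.SPACE, data, data, n_iter=4, seed=9, base=base)
        assert [c for c, _ in t1] == [c for c, _ in t2]
        assert len(t1) == 4

    def test_degenerate_single_point_space(self):
        data = self._data()
        base = TaggerConfig(max_epochs=1)
        cfg, _, trials = random_search(
            {"hidden_size": [256]}, data, data, n_iter=2, seed=0, base=base
        )
        assert cfg.hidden_size == 256
        assert all(c.hidden_size == 256 for c, _ in trials)

    def test_returns_argmax_trial(self):
        data = self._data()
        base = TaggerConfig(max_epochs=2)
        cfg, _, trials = random_search(self.SPACE, data, data, n_iter=3, seed=1, base=base)
        best_score = max(score for _, score in trials)
        assert any(c == cfg and s == best_score for c, s in trials)

    def test_rejects_nonpositive_iterations(self):
        with pytest.raises(ValueError):
            random_search(self.SPACE, self._data(), self._data(), n_iter=0, seed=0)


class TestSerialization:
    def test_archive_round_trip(self, tmp_path):
        data = make_separable_dataset(5, seed=4)
        cfg = TaggerConfig(max_epochs=2, use_crf=True, seed=4)
        model, _ = train(build_model(cfg, 12), data, data, cfg)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        assert back.config == model.config
        inputs = [x for x, _ in data]
        assert predict(back, inputs) == predict(model, inputs)
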