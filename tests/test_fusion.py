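import numpy as np
import pandas as pd
import pytest

from spdfatigue import fusion, spd

from ._oracles import confusion_metrics_naive


class TestFuseAndPredict:
    layout = fusion.FeatureLayout((("XL", 64), ("XS", 136), ("XD", 2)))

    def test_concatenation_length(self, rng):
        fused = fusion.fuse(rng.standard_normal(64), rng.standard_normal(136),
                            rng.standard_normal(2), self.layout)
        assert fused.shape == (202,)

    def test_zero_in_zero_out(self):
        fused = fusion.fuse(np.zeros(64), np.zeros(136), np.zeros(2), self.layout)
        assert not fused.any()

    def test_layout_roundtrip(self, rng):
        xl, xs, xd = rng.standard_normal(64), rng.standard_normal(136), rng.standard_normal(2)
        parts = self.layout.split(fusion.fuse(xl, xs, xd, self.layout))
        assert np.array_equal(parts["XL"], xl)
        assert np.array_equal(parts["XS"], xs)
        assert np.array_equal(parts["XD"], xd)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="XS"):
            fusion.fuse(np.zeros(64), np.zeros(10), np.zeros(2), self.layout)

    def test_zero_weights_give_even_odds(self):
        probs = fusion.predict(np.ones((3, 5)), np.zeros((5, 2)), np.zeros(2))
        assert np.allclose(probs, 0.5)

    def test_probabilities_normalized(self, rng):
        probs = fusion.predict(rng.standard_normal((10, 4)),
                               rng.standard_normal((4, 2)), rng.standard_normal(2))
        assert np.max(np.abs(probs.sum(axis=1) - 1.0)) <= 1e-12

    def test_softmax_saturation(self):
        probs = fusion.predict(np.ones((1, 1)), np.array([[0.0, 10.0]]), np.zeros(2))
        assert probs[0, 1] > 0.9999


class TestMetrics:
    def test_hand_confusion_case(self):
        m = fusion.metrics_from_confusion(tp=3, fn=1, tn=4, fp=2)
        acc, sens, spec, f1 = confusion_metrics_naive(3, 1, 4, 2)
        assert m["accuracy"] == pytest.approx(acc) == pytest.approx(70.0)
        assert m["sensitivity"] == pytest.approx(sens) == pytest.approx(75.0)
        assert m["specificity"] == pytest.approx(spec) == pytest.approx(100 * 2 / 3)
        assert m["f1"] == pytest.approx(f1) == pytest.approx(100 * 2 / 3)

    def test_perfect_predictor(self):
        m = fusion.metrics_from_confusion(tp=5, fn=0, tn=5, fp=0)
        for k in ("accuracy", "sensitivity", "specificity", "f1"):
            assert m[k] == 100.0

    def test_summary_mentions_positive_class(self):
        metrics = fusion.Metrics(pd.DataFrame([
            fusion.metrics_from_confusion(3, 1, 4, 2) | {"subject": 0, "n_test": 10},
        ]))
        assert "drowsy" in metrics.summary()


class TestTrainAlternating:
    def test_training_separates_classes(self, small_features, small_train_config):
        covs, seqs, y, _ = small_features
        hist = {}
        model = fusion.train_alternating(covs, seqs, y, small_train_config, history=hist)
        probs = fusion.model_probabilities(model, covs, seqs)
        assert np.mean(probs.argmax(axis=1) == y) >= 0.95
        # alternating bookkeeping: odd iterations step the LSTM, even ones the SPDNet
        n = len(hist["loss"])
        assert hist["t_l"] == (n + 1) // 2
        assert hist["t_s"] == n // 2

    def test_loss_decreases_in_moving_average(self, small_features, small_train_config):
        from dataclasses import replace

        covs, seqs, y, _ = small_features
        hist = {}
        cfg = replace(small_train_config, maxite=30, early_stopping=False)
        fusion.train_alternating(covs, seqs, y, cfg, history=hist)
        loss = np.asarray(hist["loss"])
        smooth = np.convolve(loss, np.ones(10) / 10, mode="valid")
        assert np.all(np.diff(smooth) <= 1e-6)

    def test_odd_iteration_leaves_spdnet_unchanged(self, small_features,
                                                   small_train_config):
        from dataclasses import replace

        covs, seqs, y, _ = small_features
        init = fusion.train_alternating(covs, seqs, y,
                                        replace(small_train_config, maxite=0))
        one = fusion.train_alternating(covs, seqs, y,
                                       replace(small_train_config, maxite=1))
        assert np.array_equal(init.spdnet.w1, one.spdnet.w1)
        assert np.array_equal(init.spdnet.w2, one.spdnet.w2)
        assert not np.array_equal(init.lstm.layers[0].wx, one.lstm.layers[0].wx)
        assert not np.array_equal(init.fc_w, one.fc_w)

    def test_maxite_zero_returns_initialization_with_centers(self, small_features,
                                                             small_train_config):
        from dataclasses import replace

        covs, seqs, y, _ = small_features
        hist = {}
        model = fusion.train_alternating(covs, seqs, y,
                                         replace(small_train_config, maxite=0),
                                         history=hist)
        assert hist["loss"] == []
        assert model.centers is not None
        expected = spd.class_centers(covs, y)
        assert np.allclose(model.centers.vigilant.matrix, expected.vigilant.matrix)
        assert np.allclose(model.centers.drowsy.matrix, expected.drowsy.matrix)

    def test_single_class_rejected(self, small_features, small_train_config):
        covs, seqs, y, _ = small_features
        with pytest.raises(ValueError, match="both classes"):
            fusion.train_alternating(covs, seqs, np.zeros_like(y), small_train_config)


class TestVariants:
    def test_layout_lengths(self, small_train_config):
        from dataclasses import replace

        cfg = small_train_config
        xs_len = cfg.d2 * (cfg.d2 + 1) // 2
        expected = {
            "full": cfg.hidden_size + xs_len + 2,
            "TRDC": cfg.hidden_size,
            "SDTR": cfg.hidden_size + 2,
            "SNTR": cfg.hidden_size + xs_len,
        }
        for name, total in expected.items():
            layout = fusion.layout_for(replace(cfg, variant=name))
            assert layout.total == total

    def test_unknown_variant_lists_valid_names(self, small_train_config):
        with pytest.raises(ValueError, match="TRDC"):
            fusion.ablation_variants(small_train_config, ["bogus"])

    def test_variant_configs_differ_only_in_layout(self, small_train_config):
        configs = fusion.ablation_variants(small_train_config)
        assert set(configs) == {"full", "TRDC", "SDTR", "SNTR"}
        for name, cfg in configs.items():
            assert cfg.variant == name
            assert cfg.hidden_size == small_train_config.hidden_size


class TestLOSO:
    def test_fold_count_and_accuracy(self, small_dataset, small_features,
                                     small_train_config):
        covs, seqs, y, subj = small_features
        metrics = fusion.evaluate_loso(None, y, subj, small_train_config,
                                       features=(covs, seqs))
        assert len(metrics.per_fold) == len(np.unique(subj))
        assert metrics.mean["accuracy"] >= 90.0

    def test_seeded_determinism(self, small_features, small_train_config):
        covs, seqs, y, subj = small_features
        m1 = fusion.evaluate_loso(None, y, subj, small_train_config,
                                  features=(covs, seqs))
        m2 = fusion.evaluate_loso(None, y, subj, small_train_config,
                                  features=(covs, seqs))
        assert m1.per_fold.equals(m2.per_fold)

    def test_no_leakage_centers_from_training_fold(self, small_features,
                                                   small_train_config):
        """A fold's class centers must equal centers of its training trials only."""
        covs, seqs, y, subj = small_features
        subj0 = np.unique(subj)[0]
        train = subj != subj0
        from dataclasses import replace

        cfg = replace(small_train_config, seed=fusion._fold_seed(small_train_config.seed, 0))
        model = fusion.train_alternating(covs[train], seqs[train], y[train], cfg)
        expected = spd.class_centers(covs[train], y[train])
        assert np.allclose(model.centers.vigilant.matrix, expected.vigilant.matrix)

    def test_requires_two_subjects(self, small_features, small_train_config):
        covs, seqs, y, subj = small_features
        with pytest.raises(ValueError, match="2 subjects"):
            fusion.evaluate_loso(None, y, np.zeros_like(subj), small_train_config,
                                 features=(covs, seqs))
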