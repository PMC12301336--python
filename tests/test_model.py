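"""Classifier primitives, end-to-end training, and prediction contracts."""

import numpy as np
import pytest

from synfuse import autodiff as ad
from synfuse.data import LabeledTriplet
from synfuse.metrics import run_cross_validation
from synfuse.data import make_random_kfold
from synfuse.model import (TrainConfig, _batch_logits, _batch_loss, _Prepared,
                           cross_entropy, enumerate_screen, forward,
                           hidden_activations, init_params, predict,
                           predict_batch, predict_proba, train_model)


class TestPredictProba:
    def test_uniform_logits(self):
        assert np.allclose(predict_proba([0.0, 0.0]), [0.5, 0.5])

    def test_closed_form(self):
        assert np.allclose(predict_proba([np.log(3), 0.0]), [0.75, 0.25])

    def test_extreme_logits_stable(self):
        p = predict_proba([1000.0, 0.0])
        # high-precision reference: 1/(1+e^-1000), e^-1000 underflows to 0
        assert np.isfinite(p).all()
        assert p[0] == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        P = predict_proba(rng.normal(scale=10, size=(100, 2)))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            predict_proba([np.nan, 0.0])


class TestCrossEntropy:
    def test_perfect_prediction(self):
        assert cross_entropy([[0.0, 1.0]], [1]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction(self):
        assert cross_entropy([[0.5, 0.5]], [0]) == pytest.approx(np.log(2), abs=1e-9)

    def test_batch_mean_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet([1, 1], size=10)
        labels = rng.integers(0, 2, size=10)
        expected = np.mean([-np.log(probs[i, labels[i]]) for i in range(10)])
        assert cross_entropy(probs, labels) == pytest.approx(expected)


class TestForward:
    def setup_params(self, variant="full", seed=0):
        cfg = TrainConfig(seed=seed, dtype="float64")
        return init_params(variant, 30, cfg, np.random.default_rng(seed),
                           dtype=np.float64), cfg

    def test_zero_params_zero_logits(self):
        params, _ = self.setup_params()
        for t in params.clf_W + params.clf_b:
            t.data[:] = 0
        out = forward(np.ones(1792), np.ones(256), params)
        assert np.allclose(out, [0.0, 0.0])

    def test_eval_determinism(self):
        params, _ = self.setup_params(seed=1)
        x1 = np.random.default_rng(2).normal(size=1792)
        x2 = np.random.default_rng(3).normal(size=256)
        assert np.array_equal(forward(x1, x2, params), forward(x1, x2, params))

    def test_hidden_activations_at_interpretable_widths(self):
        params, _ = self.setup_params(seed=4)
        capture = {}
        forward(np.ones(1792), np.ones(256), params, capture=capture)
        assert 512 in capture and 32 in capture
        assert capture[512].shape == (1, 512)
        assert capture[32].shape == (1, 32)

    def test_width_mismatch(self):
        params, _ = self.setup_params()
        with pytest.raises(ValueError):
            forward(np.ones(100), np.ones(256), params)


class TestGradients:
    def test_analytic_matches_numerical(self, small_study, small_table):
        """Central differences vs backprop on a float64 toy configuration."""
        cfg = TrainConfig(seed=0, dtype="float64", dropout=0.0)
        prep = _Prepared(small_study.triplets[:24], small_study.expression.matrix,
                         small_table, np.float64)
        prep.set_normalization(np.arange(len(prep.cell_names)))
        params = init_params("full", 30, cfg, np.random.default_rng(0),
                             dtype=np.float64)
        idx = np.arange(24)

        def loss_value():
            logits = _batch_logits(prep, params, idx, "full", False, None)
            return float(_batch_loss(logits, prep.labels[idx]).data)

        for t in params.tensors():
            t.grad = None
        logits = _batch_logits(prep, params, idx, "full", False, None)
        loss = _batch_loss(logits, prep.labels[idx])
        ad.backward(loss)

        rng = np.random.default_rng(5)
        checked = 0
        for tensor in (params.gcn.W0, params.pool.layers[0].attn.Wq[0],
                       params.pool.W_out, params.cell.weights[0],
                       params.clf_W[0], params.clf_b[-1]):
            flat_idx = rng.integers(tensor.data.size, size=2)
            for fi in flat_idx:
                pos = np.unravel_index(fi, tensor.data.shape)
                orig = tensor.data[pos]
                eps = 1e-5 * max(1.0, abs(orig))
                tensor.data[pos] = orig + eps
                up = loss_value()
                tensor.data[pos] = orig - eps
                down = loss_value()
                tensor.data[pos] = orig
                numeric = (up - down) / (2 * eps)
                analytic = tensor.grad[pos]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-8)
                checked += 1
        assert checked == 12


class TestTrainModel:
    def test_history_bookkeeping(self, small_study, small_table):
        cfg = TrainConfig(epochs=3, seed=0, batch_size=64)
        m = train_model(small_study.triplets[:50], small_study.expression.matrix,
                        small_table, cfg, "full")
        assert len(m.history["train_loss"]) == 3
        assert np.isfinite(m.history["train_loss"]).all()

    def test_seeded_determinism(self, small_study, small_table):
        cfg = TrainConfig(epochs=2, seed=11, batch_size=64)
        losses = []
        for _ in range(2):
            m = train_model(small_study.triplets[:60], small_study.expression.matrix,
                            small_table, cfg, "full")
            losses.append(m.history["train_loss"][-1])
        assert losses[0] == losses[1]

    def test_learns_separable_planted_rule(self, small_study, small_table):
        """Noise-free planted data drives training loss below ln 2."""
        cfg = TrainConfig(epochs=12, patience=12, seed=0, batch_size=64)
        m = train_model(small_study.triplets, small_study.expression.matrix,
                        small_table, cfg, "full")
        assert m.history["train_loss"][-1] < np.log(2) * 0.9

    def test_unknown_cell_line_listed(self, small_study, small_table):
        bad = LabeledTriplet(drug_a="D001", drug_b="D002", smiles_a="CC",
                             smiles_b="CCO", cell_line="NOPE", label=1)
        with pytest.raises(ValueError, match="NOPE"):
            train_model(small_study.triplets[:20] + [bad],
                        small_study.expression.matrix, small_table,
                        TrainConfig(epochs=1), "full")

    def test_bad_smiles_listed(self, small_study, small_table):
        bad = LabeledTriplet(drug_a="DX", drug_b="D002", smiles_a="xx(",
                             smiles_b="CCO", cell_line="CL01", label=1)
        with pytest.raises(ValueError, match="DX"):
            train_model(small_study.triplets[:20] + [bad],
                        small_study.expression.matrix, small_table,
                        TrainConfig(epochs=1), "full")

    def test_unknown_variant(self, small_study, small_table):
        with pytest.raises(ValueError, match="variant"):
            train_model(small_study.triplets[:20], small_study.expression.matrix,
                        small_table, TrainConfig(epochs=1), "3d_only")


class TestPredict:
    def test_order_symmetry_exact(self, trained_small, small_study):
        t = small_study.triplets[0]
        swapped = LabeledTriplet(drug_a=t.drug_b, drug_b=t.drug_a,
                                 smiles_a=t.smiles_b, smiles_b=t.smiles_a,
                                 cell_line=t.cell_line, label=t.label)
        assert predict(trained_small, t).probability == \
            predict(trained_small, swapped).probability

    def test_probability_range_and_order(self, trained_small, small_study):
        preds = predict_batch(trained_small, small_study.triplets[:20])
        assert len(preds) == 20
        for p, t in zip(preds, small_study.triplets[:20]):
            assert 0.0 <= p.probability <= 1.0
            assert (p.drug_a, p.drug_b, p.cell_line) == \
                (t.drug_a, t.drug_b, t.cell_line)

    def test_hidden_activation_export(self, trained_small, small_study):
        acts = hidden_activations(trained_small, small_study.triplets[:15])
        assert acts[512].shape == (15, 512)
        assert acts[32].shape == (15, 32)


class TestEnumerateScreen:
    def test_row_count(self, trained_small, small_study):
        library = small_study.library[:4]
        cells = list(small_study.expression.matrix.index[:3])
        frame = enumerate_screen(trained_small, "Q", small_study.library[0][1],
                                 library, cells)
        assert len(frame) == 4 * 3

    def test_single_pairing(self, trained_small, small_study):
        frame = enumerate_screen(trained_small, "Q", small_study.library[0][1],
                                 small_study.library[:1],
                                 [small_study.expression.matrix.index[0]])
        assert len(frame) == 1

    def test_empty_cell_lines(self, trained_small, small_study):
        frame = enumerate_screen(trained_small, "Q", small_study.library[0][1],
                                 small_study.library[:2], [])
        assert len(frame) == 0


class TestCrossValidationDriver:
    def test_fold_bookkeeping_and_exclusion(self, small_study, small_table):
        plan = make_random_kfold(small_study.triplets, k=2, seed=0)
        cfg = TrainConfig(epochs=1, seed=0, batch_size=64)
        summary = run_cross_validation(small_study.triplets,
                                       small_study.expression.matrix,
                                       small_table, plan, cfg, "1d_only")
        assert len(summary.reports) == 2
        accs = [r.acc for r in summary.reports]
        assert summary.mean["acc"] == pytest.approx(np.mean(accs), abs=1e-12)

    def test_model_round_trip(self, trained_small, small_study, tmp_path):
        prefix = tmp_path / "model"
        trained_small.save(prefix)
        from synfuse.model import TrainedModel
        loaded = TrainedModel.load(prefix)
        p1 = predict_batch(trained_small, small_study.triplets[:5])
        p2 = predict_batch(loaded, small_study.triplets[:5])
        for a, b in zip(p1, p2):
            assert a.probability == pytest.approx(b.probability, abs=1e-7)
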