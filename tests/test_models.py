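"""Model forward passes, gradients, training contracts, and baselines."""

import datetime as dt

import numpy as np
import pytest

from edrevisit.ehr_data import PatientHistory, VisitRecord
from edrevisit.graph_builder import PatientGraph, batch_graphs, build_patient_graph
from edrevisit.models import (TrainConfig, Predictor, _gnn_backward_core,
                              _gnn_forward_core, _rnn_backward_core,
                              _rnn_forward_core, flatten_for_baseline,
                              gnn_forward, init_gnn_params, init_rnn_params,
                              predict, rnn_forward, train)
from edrevisit.preprocessing import (LabeledInstance, PreprocessConfig,
                                     encode_instance, fit_schema)


def _toy_instances(make_visit, n=20, seed=0):
    """Separable toy set: triage 1 visits are positive, triage 5 negative."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        label = i % 2
        triage = 1 if label else 5
        date = dt.date(2020, 1, 1) + dt.timedelta(days=i)
        v = make_visit(patient_id=f"P{i}", date=date.isoformat(), triage=triage,
                       age=float(rng.integers(5, 18)))
        out.append(LabeledInstance(f"P{i}", (v,), label))
    return out


@pytest.fixture
def toy(make_visit, pp_cfg):
    instances = _toy_instances(make_visit)
    schema = fit_schema(instances, pp_cfg)
    return instances, schema


class TestGNNForward:
    def test_zero_weights_give_half(self, toy, pp_cfg):
        instances, schema = toy
        graphs = [build_patient_graph(i, schema) for i in instances]
        batch = batch_graphs(graphs)
        width = batch.features.shape[1]
        params = {"W1": np.zeros((width, 8)), "b1": np.zeros(8),
                  "w2": np.zeros(8), "b2": 0.0}
        pred = Predictor("gnn", params, schema, TrainConfig(), 10)
        assert np.allclose(gnn_forward(batch, pred), 0.5)

    def test_single_isolated_node_readout_is_its_features(self):
        rng = np.random.default_rng(3)
        feats = rng.normal(size=(1, 5))
        g = PatientGraph("P1", ("visit:0",), ("visit",), feats, frozenset(), 0)
        batch = batch_graphs([g])
        params = init_gnn_params(5, 4, rng)
        pred = Predictor("gnn", params, None, TrainConfig(), 10)
        probs = gnn_forward(batch, pred)
        h = np.maximum(feats @ params["W1"] + params["b1"], 0.0)
        expected = 1.0 / (1.0 + np.exp(-(h @ params["w2"] + params["b2"])))
        assert probs[0] == pytest.approx(float(expected[0]))

    def test_invariant_to_node_permutation(self, toy, pp_cfg, make_visit):
        _, schema = toy
        inst = LabeledInstance("P1", (
            make_visit(triage=1, services=("SVCA", "SVCB")),
            make_visit(date="2020-02-01", triage=5, services=("SVCA",)),
        ), 1)
        schema2 = fit_schema([inst], pp_cfg)
        g = build_patient_graph(inst, schema2)
        rng = np.random.default_rng(5)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        g_perm = PatientGraph(
            g.patient_id,
            tuple(g.node_ids[i] for i in perm),
            tuple(g.node_types[i] for i in perm),
            g.features[perm],
            frozenset((min(inv[i], inv[j]), max(inv[i], inv[j]), t)
                      for i, j, t in g.edges),
            g.label,
        )
        params = init_gnn_params(g.features.shape[1], 8, rng)
        pred = Predictor("gnn", params, schema2, TrainConfig(), 10)
        p1 = gnn_forward(batch_graphs([g]), pred)
        p2 = gnn_forward(batch_graphs([g_perm]), pred)
        assert p1[0] == pytest.approx(p2[0], abs=1e-12)

    def test_dimension_mismatch_raises(self, toy):
        instances, schema = toy
        batch = batch_graphs([build_patient_graph(instances[0], schema)])
        params = {"W1": np.zeros((3, 4)), "b1": np.zeros(4), "w2": np.zeros(4), "b2": 0.0}
        pred = Predictor("gnn", params, schema, TrainConfig(), 10)
        with pytest.raises(ValueError, match="width"):
            gnn_forward(batch, pred)


class TestRNNForward:
    def test_zero_weights_give_half(self, toy):
        instances, schema = toy
        params = {k: np.zeros_like(np.asarray(v, dtype=float))
                  for k, v in init_rnn_params(schema.width, 6, "gru",
                                              np.random.default_rng(0)).items()}
        pred = Predictor("rnn", params, schema, TrainConfig(), 10)
        seq = encode_instance(instances[0], schema)
        assert rnn_forward(seq, pred) == pytest.approx(0.5)

    def test_length_one_equals_single_step(self, toy):
        _, schema = toy
        rng = np.random.default_rng(7)
        params = init_rnn_params(4, 3, "tanh", rng)
        pred = Predictor("rnn", params, None, TrainConfig(rnn_cell="tanh"), 10)
        x = rng.normal(size=(1, 4))
        h = np.tanh(x @ params["W"] + params["b"])  # h0 = 0
        expected = 1.0 / (1.0 + np.exp(-(h @ params["w_out"] + params["b_out"])))
        assert rnn_forward(x, pred) == pytest.approx(float(expected[0]))

    def test_order_sensitivity(self):
        rng = np.random.default_rng(11)
        params = init_rnn_params(5, 6, "gru", rng)
        pred = Predictor("rnn", params, None, TrainConfig(), 10)
        seq = rng.normal(size=(4, 5))
        assert rnn_forward(seq, pred) != pytest.approx(rnn_forward(seq[::-1], pred))

    def test_empty_sequence_rejected(self):
        pred = Predictor("rnn", {}, None, TrainConfig(), 10)
        with pytest.raises(ValueError):
            rnn_forward([], pred)


class TestGradients:
    """Analytic backward passes against central finite differences."""

    @staticmethod
    def _loss_from(probs, y):
        p = np.clip(probs, 1e-12, 1 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def _check(self, params, grads, loss_fn):
        eps = 1e-6
        for key, g in grads.items():
            g_flat = np.asarray(g, dtype=float).reshape(-1)
            base = np.asarray(params[key], dtype=float).copy()
            flat = base.reshape(-1)
            for k in range(min(flat.size, 6)):
                orig = flat[k]
                flat[k] = orig + eps
                params[key] = flat.reshape(base.shape)
                lp = loss_fn(params)
                flat[k] = orig - eps
                params[key] = flat.reshape(base.shape)
                lm = loss_fn(params)
                flat[k] = orig
                params[key] = flat.reshape(base.shape)
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g_flat[k], abs=1e-6, rel=1e-3), key

    def test_gnn_gradients_match_numerical(self):
        rng = np.random.default_rng(17)
        m = rng.normal(size=(7, 5))
        pool_w = np.array([0.5, 0.5, 1 / 3, 1 / 3, 1 / 3, 0.5, 0.5])
        seg = np.array([0, 0, 1, 1, 1, 2, 2])
        y = np.array([1.0, 0.0, 1.0])
        params = init_gnn_params(5, 4, rng)
        probs, cache = _gnn_forward_core(m, pool_w, seg, 3, params)
        grads = _gnn_backward_core(probs, y, params, cache)

        def loss_fn(p):
            pr, _ = _gnn_forward_core(m, pool_w, seg, 3, p)
            return self._loss_from(pr, y)

        self._check(params, grads, loss_fn)

    @pytest.mark.parametrize("cell", ["gru", "tanh"])
    def test_rnn_gradients_match_numerical(self, cell):
        rng = np.random.default_rng(19)
        x = rng.normal(size=(3, 4, 5))
        mask = np.array([[1, 1, 1, 1], [0, 0, 1, 1], [0, 1, 1, 1]], dtype=float)
        y = np.array([1.0, 0.0, 1.0])
        params = init_rnn_params(5, 4, cell, rng)
        probs, caches = _rnn_forward_core(x, mask, params, cell)
        grads = _rnn_backward_core(probs, y, params, caches, cell)

        def loss_fn(p):
            pr, _ = _rnn_forward_core(x, mask, p, cell)
            return self._loss_from(pr, y)

        self._check(params, grads, loss_fn)


class TestFlatten:
    def test_right_alignment(self, toy, make_visit):
        _, schema = toy
        visits = tuple(
            make_visit(date=f"2020-01-{d:02d}", age=float(5 + d)) for d in (1, 2, 3)
        )
        inst = LabeledInstance("P1", visits, 0)
        row = flatten_for_baseline(inst, schema, visit_cap=10)
        assert row.shape == (10 * schema.width,)
        slots = row.reshape(10, schema.width)
        nonzero = [i for i in range(10) if np.any(slots[i])]
        assert nonzero == [7, 8, 9]
        # temporal order preserved: ages increase across the filled slots
        ages = [slots[i][0] for i in nonzero]
        assert ages == sorted(ages)

    def test_single_visit_fills_last_slot_only(self, toy):
        instances, schema = toy
        row = flatten_for_baseline(instances[0], schema, visit_cap=10)
        slots = row.reshape(10, schema.width)
        assert [i for i in range(10) if np.any(slots[i])] == [9]

    def test_full_cap_no_padding(self, toy, make_visit):
        _, schema = toy
        visits = tuple(make_visit(date=f"2020-01-{d:02d}") for d in range(1, 11))
        row = flatten_for_baseline(LabeledInstance("P1", visits, 0), schema, 10)
        slots = row.reshape(10, schema.width)
        assert all(np.any(slots[i]) for i in range(10))


class TestTraining:
    def test_loss_decreases_on_separable_toy(self, toy, pp_cfg):
        instances, _ = toy
        for kind in ("gnn", "rnn"):
            p = train(kind, instances, TrainConfig(epochs=10, batch_size=20,
                                                   learning_rate=0.05, hidden_width=8,
                                                   seed=1), preprocess_cfg=pp_cfg)
            assert p.loss_history[-1] < p.loss_history[0]
            diffs = np.diff(p.loss_history)
            assert np.all(diffs < 0.02)  # monotone within tolerance

    def test_logistic_on_perfect_predictor_column(self, toy, pp_cfg):
        instances, _ = toy
        p = train("logistic", instances, TrainConfig(seed=0), preprocess_cfg=pp_cfg)
        _, labels = predict(p, instances)
        assert np.mean(labels == [i.label for i in instances]) >= 0.95

    def test_same_seed_reproduces_gnn_predictions(self, toy, pp_cfg):
        instances, _ = toy
        cfg = TrainConfig(epochs=5, batch_size=8, hidden_width=8, seed=42)
        p1 = train("gnn", instances[:16], cfg, preprocess_cfg=pp_cfg)
        p2 = train("gnn", instances[:16], cfg, preprocess_cfg=pp_cfg)
        probs1, _ = predict(p1, instances[16:])
        probs2, _ = predict(p2, instances[16:])
        assert np.array_equal(probs1, probs2)

    def test_single_class_training_set_names_missing_class(self, toy, pp_cfg):
        instances, _ = toy
        only_pos = [i for i in instances if i.label == 1]
        with pytest.raises(ValueError, match="class 0"):
            train("logistic", only_pos, TrainConfig(), preprocess_cfg=pp_cfg)

    def test_unknown_kind_rejected(self, toy):
        with pytest.raises(ValueError, match="model kind"):
            train("svm", toy[0], TrainConfig())


class TestPredict:
    def test_probability_at_threshold_labels_positive(self, toy, pp_cfg):
        instances, schema = toy
        params = {"W1": np.zeros((3 + max(schema.visit_node_width,
                                          len(schema.service_index),
                                          len(schema.diagnosis_index)), 4)),
                  "b1": np.zeros(4), "w2": np.zeros(4), "b2": 0.0}
        pred = Predictor("gnn", params, schema, TrainConfig(threshold=0.5), 10)
        probs, labels = predict(pred, instances[:4])
        assert np.allclose(probs, 0.5)
        assert np.all(labels == 1)  # p == threshold -> positive by convention

    def test_raising_threshold_never_increases_positives(self, toy, pp_cfg):
        instances, _ = toy
        p = train("gradient_boosting", instances, TrainConfig(seed=0),
                  preprocess_cfg=pp_cfg)
        counts = []
        for thr in (0.2, 0.5, 0.8):
            p.config = TrainConfig(threshold=thr)
            _, labels = predict(p, instances)
            counts.append(labels.sum())
        assert counts[0] >= counts[1] >= counts[2]

    def test_unfitted_predictor_rejected(self, toy):
        _, schema = toy
        pred = Predictor("gnn", {}, schema, TrainConfig(), 10, fitted=False)
        with pytest.raises(ValueError, match="not fitted"):
            predict(pred, [])
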