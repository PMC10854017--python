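"""Classifiers: one-layer GNN, one-layer recurrent net, and flat baselines.

All models are binary classifiers of 30-day revisit trained with binary
cross-entropy, kept deliberately shallow (one layer each) so the comparison
isolates *representation* — graph vs sequence vs concatenated row — rather
than capacity.

* ``gnn``: one message-passing layer (degree-normalized neighbor averaging
  with self-inclusion, affine map, ReLU), mean-pool readout over the graph's
  nodes, then an affine map and sigmoid.  Output is invariant to node
  relabeling within a graph.
* ``rnn``: one recurrent layer (GRU-style gated cell by default, plain tanh
  cell as an option) over the encoded visit sequence in temporal order; the
  final hidden state feeds an affine map and sigmoid.  Output is order
  sensitive.
* ``logistic``, ``decision_tree``, ``gradient_boosting``: standard fits on
  visits concatenated into a single fixed-width row that retains temporal
  ordering (right-aligned, zero-padded on the left).

The neural models are implemented directly on numpy with analytically
derived gradients and an Adam optimizer; CPU-sized problems need nothing
more.  Gradients are exercised against numerical differentiation in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .graph_builder import GraphBatch, PatientGraph, batch_graphs, build_patient_graph
from .preprocessing import FeatureSchema, LabeledInstance, PreprocessConfig, encode_instance, fit_schema

__all__ = [
    "MODEL_KINDS",
    "TrainConfig",
    "Predictor",
    "gnn_forward",
    "rnn_forward",
    "flatten_for_baseline",
    "train",
    "predict",
    "init_gnn_params",
    "init_rnn_params",
]

MODEL_KINDS = ("gnn", "rnn", "logistic", "decision_tree", "gradient_boosting")

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 300
    batch_size: int = 500
    learning_rate: float = 1e-3
    hidden_width: int = 64
    seed: int = 0
    threshold: float = 0.5
    gnn_aggregate: str = "mean"  # or "sum"
    gnn_readout: str = "all"  # or "visits"
    rnn_cell: str = "gru"  # or "tanh"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.gnn_aggregate not in ("mean", "sum"):
            raise ValueError("gnn_aggregate must be 'mean' or 'sum'")
        if self.gnn_readout not in ("all", "visits"):
            raise ValueError("gnn_readout must be 'all' or 'visits'")
        if self.rnn_cell not in ("gru", "tanh"):
            raise ValueError("rnn_cell must be 'gru' or 'tanh'")


@dataclass
class Predictor:
    """A fitted model plus the schema and config it was fitted with."""

    model_kind: str
    params: object
    schema: FeatureSchema
    config: TrainConfig
    visit_cap: int
    loss_history: list[float] = field(default_factory=list)
    fitted: bool = True


# ---------------------------------------------------------------------------
# GNN
# ---------------------------------------------------------------------------

def init_gnn_params(feature_width: int, hidden: int, rng: np.random.Generator) -> dict:
    s1 = math.sqrt(2.0 / feature_width)
    s2 = math.sqrt(1.0 / hidden)
    return {
        "W1": rng.normal(0.0, s1, (feature_width, hidden)),
        "b1": np.zeros(hidden),
        "w2": rng.normal(0.0, s2, hidden),
        "b2": 0.0,
    }


def _propagated_features(graph: PatientGraph, aggregate: str) -> np.ndarray:
    """Precompute the aggregation  X̂ = D⁻¹(A+I) X  (or (A+I) X for sum).

    The propagation is fixed by the graph, so it is computed once per graph
    and reused across every epoch.
    """
    from .graph_builder import to_matrices

    adj, feats = to_matrices(graph)
    a_hat = adj + np.eye(graph.n_nodes)
    if aggregate == "mean":
        a_hat = a_hat / a_hat.sum(axis=1, keepdims=True)
    return a_hat @ feats


def _readout_weights(graph: PatientGraph, readout: str) -> np.ndarray:
    """Per-node mean-pool weights; optionally restricted to visit nodes."""
    if readout == "visits":
        mask = np.array([t == "visit" for t in graph.node_types], dtype=float)
    else:
        mask = np.ones(graph.n_nodes)
    return mask / mask.sum()


def _gnn_forward_core(m: np.ndarray, pool_w: np.ndarray, seg: np.ndarray,
                      n_graphs: int, params: dict) -> tuple[np.ndarray, dict]:
    pre = m @ params["W1"] + params["b1"]
    h = np.maximum(pre, 0.0)
    pooled = np.zeros((n_graphs, h.shape[1]))
    np.add.at(pooled, seg, h * pool_w[:, None])
    logits = pooled @ params["w2"] + params["b2"]
    probs = expit(logits)
    cache = {"m": m, "pre": pre, "h": h, "pooled": pooled, "pool_w": pool_w, "seg": seg}
    return probs, cache


def _gnn_backward_core(probs: np.ndarray, y: np.ndarray, params: dict, cache: dict) -> dict:
    n = len(y)
    dlogit = (probs - y) / n
    dw2 = cache["pooled"].T @ dlogit
    db2 = float(dlogit.sum())
    dpooled = np.outer(dlogit, params["w2"])
    dh = dpooled[cache["seg"]] * cache["pool_w"][:, None]
    dpre = dh * (cache["pre"] > 0.0)
    dW1 = cache["m"].T @ dpre
    db1 = dpre.sum(axis=0)
    return {"W1": dW1, "b1": db1, "w2": dw2, "b2": db2}


def gnn_forward(batch: GraphBatch, predictor: Predictor) -> np.ndarray:
    """Probability per graph in *batch* under the GNN predictor.

    One degree-normalized message-passing step with self-inclusion, ReLU,
    mean-pool readout, affine map, sigmoid.
    """
    params = predictor.params
    cfg = predictor.config
    if batch.features.shape[1] != params["W1"].shape[0]:
        raise ValueError(
            f"feature width {batch.features.shape[1]} does not match "
            f"GNN input width {params['W1'].shape[0]}"
        )
    m = np.vstack([_propagated_features(g, cfg.gnn_aggregate) for g in batch.graphs])
    pool_w = np.concatenate([_readout_weights(g, cfg.gnn_readout) for g in batch.graphs])
    seg = batch.graph_index()
    probs, _ = _gnn_forward_core(m, pool_w, seg, batch.n_graphs, params)
    return probs


# ---------------------------------------------------------------------------
# Recurrent net
# ---------------------------------------------------------------------------

def init_rnn_params(input_width: int, hidden: int, cell: str, rng: np.random.Generator) -> dict:
    sx = math.sqrt(1.0 / input_width)
    sh = math.sqrt(1.0 / hidden)
    if cell == "gru":
        params = {}
        for gate in ("z", "r", "n"):
            params[f"W{gate}"] = rng.normal(0.0, sx, (input_width, hidden))
            params[f"U{gate}"] = rng.normal(0.0, sh, (hidden, hidden))
            params[f"b{gate}"] = np.zeros(hidden)
    else:
        params = {
            "W": rng.normal(0.0, sx, (input_width, hidden)),
            "U": rng.normal(0.0, sh, (hidden, hidden)),
            "b": np.zeros(hidden),
        }
    params["w_out"] = rng.normal(0.0, sh, hidden)
    params["b_out"] = 0.0
    return params


def _rnn_forward_core(x: np.ndarray, mask: np.ndarray, params: dict, cell: str
                      ) -> tuple[np.ndarray, list[dict]]:
    """Run the recurrent layer over (B, T, D) input with a (B, T) step mask.

    Sequences are left-padded; masked steps leave the hidden state untouched,
    so the state after the last step is the true final state for every
    sequence length.
    """
    b, t_max, _ = x.shape
    hidden = params["w_out"].shape[0]
    h = np.zeros((b, hidden))
    caches = []
    for t in range(t_max):
        xt, mt = x[:, t, :], mask[:, t][:, None]
        if cell == "gru":
            z = expit(xt @ params["Wz"] + h @ params["Uz"] + params["bz"])
            r = expit(xt @ params["Wr"] + h @ params["Ur"] + params["br"])
            n = np.tanh(xt @ params["Wn"] + (r * h) @ params["Un"] + params["bn"])
            h_new = (1.0 - z) * n + z * h
            caches.append({"x": xt, "h_prev": h, "z": z, "r": r, "n": n, "m": mt})
        else:
            h_new = np.tanh(xt @ params["W"] + h @ params["U"] + params["b"])
            caches.append({"x": xt, "h_prev": h, "h_new": h_new, "m": mt})
        h = mt * h_new + (1.0 - mt) * h
    logits = h @ params["w_out"] + params["b_out"]
    caches.append({"h_final": h})
    return expit(logits), caches


def _rnn_backward_core(probs: np.ndarray, y: np.ndarray, params: dict,
                       caches: list[dict], cell: str) -> dict:
    n_obs = len(y)
    dlogit = (probs - y) / n_obs
    h_final = caches[-1]["h_final"]
    grads = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in params.items()}
    grads["w_out"] = h_final.T @ dlogit
    grads["b_out"] = float(dlogit.sum())
    dh = np.outer(dlogit, params["w_out"])
    for c in reversed(caches[:-1]):
        m = c["m"]
        dh_cell = dh * m
        dh_skip = dh * (1.0 - m)
        if cell == "gru":
            z, r, n, h_prev, xt = c["z"], c["r"], c["n"], c["h_prev"], c["x"]
            dn = dh_cell * (1.0 - z)
            dz = dh_cell * (h_prev - n)
            dh_prev = dh_cell * z
            dn_pre = dn * (1.0 - n * n)
            grads["Wn"] += xt.T @ dn_pre
            grads["Un"] += (r * h_prev).T @ dn_pre
            grads["bn"] += dn_pre.sum(axis=0)
            drh = dn_pre @ params["Un"].T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            grads["Wz"] += xt.T @ dz_pre
            grads["Uz"] += h_prev.T @ dz_pre
            grads["bz"] += dz_pre.sum(axis=0)
            grads["Wr"] += xt.T @ dr_pre
            grads["Ur"] += h_prev.T @ dr_pre
            grads["br"] += dr_pre.sum(axis=0)
            dh_prev = dh_prev + dz_pre @ params["Uz"].T + dr_pre @ params["Ur"].T
        else:
            h_new, h_prev, xt = c["h_new"], c["h_prev"], c["x"]
            dpre = dh_cell * (1.0 - h_new * h_new)
            grads["W"] += xt.T @ dpre
            grads["U"] += h_prev.T @ dpre
            grads["b"] += dpre.sum(axis=0)
            dh_prev = dpre @ params["U"].T
        dh = dh_prev + dh_skip
    return grads


def rnn_forward(sequence: Sequence[np.ndarray], predictor: Predictor) -> float:
    """Probability for one encoded visit sequence (temporal order)."""
    if len(sequence) == 0:
        raise ValueError("rnn_forward requires a non-empty sequence")
    x = np.asarray(sequence, dtype=float)[None, :, :]
    mask = np.ones((1, x.shape[1]))
    probs, _ = _rnn_forward_core(x, mask, predictor.params, predictor.config.rnn_cell)
    return float(probs[0])


def _pad_sequences(mats: Sequence[np.ndarray], t_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Left-pad encoded visit matrices to (B, t_max, D) plus a step mask."""
    b, d = len(mats), mats[0].shape[1]
    x = np.zeros((b, t_max, d))
    mask = np.zeros((b, t_max))
    for i, m in enumerate(mats):
        t = m.shape[0]
        x[i, t_max - t:, :] = m
        mask[i, t_max - t:] = 1.0
    return x, mask


# ---------------------------------------------------------------------------
# Flat baselines
# ---------------------------------------------------------------------------

def flatten_for_baseline(instance: LabeledInstance, schema: FeatureSchema,
                         visit_cap: int) -> np.ndarray:
    """Concatenate the instance's visits into one fixed-width row.

    ``visit_cap`` slots of ``schema.width`` each, filled right-aligned in
    temporal order (most recent visit in the last slot) and zero-padded on
    the left, so temporal position is preserved across instances.
    """
    row = np.zeros(visit_cap * schema.width)
    visits = instance.input_visits[-visit_cap:]
    start = visit_cap - len(visits)
    for k, v in enumerate(visits):
        from .preprocessing import encode_visit

        sl = (start + k) * schema.width
        row[sl:sl + schema.width] = encode_visit(v, schema)
    return row


def _baseline_matrix(instances: Sequence[LabeledInstance], schema: FeatureSchema,
                     visit_cap: int) -> np.ndarray:
    return np.stack([flatten_for_baseline(i, schema, visit_cap) for i in instances])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in params.items()}
        self.v = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * np.square(g)
            update = self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)
            params[k] = params[k] - update


def _bce(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _check_both_classes(labels: np.ndarray) -> None:
    present = set(np.unique(labels).astype(int))
    missing = {0, 1} - present
    if missing:
        raise ValueError(f"training set lacks class {sorted(missing)[0]}; both labels required")


def _train_gnn(instances, schema, cfg: TrainConfig) -> tuple[dict, list[float]]:
    rng = np.random.default_rng(cfg.seed)
    graphs = [build_patient_graph(inst, schema) for inst in instances]
    prop = [_propagated_features(g, cfg.gnn_aggregate) for g in graphs]
    pool = [_readout_weights(g, cfg.gnn_readout) for g in graphs]
    sizes = np.array([g.n_nodes for g in graphs])
    y_all = np.array([g.label for g in graphs], dtype=float)
    width = graphs[0].features.shape[1]
    params = init_gnn_params(width, cfg.hidden_width, rng)
    opt = _Adam(params, cfg.learning_rate)
    history = []
    n = len(graphs)
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            m = np.vstack([prop[i] for i in idx])
            pw = np.concatenate([pool[i] for i in idx])
            seg = np.repeat(np.arange(len(idx)), sizes[idx])
            y = y_all[idx]
            probs, cache = _gnn_forward_core(m, pw, seg, len(idx), params)
            grads = _gnn_backward_core(probs, y, params, cache)
            opt.step(params, grads)
            epoch_loss += _bce(probs, y) * len(idx)
            seen += len(idx)
        history.append(epoch_loss / seen)
    return params, history


def _train_rnn(instances, schema, cfg: TrainConfig, visit_cap: int) -> tuple[dict, list[float]]:
    rng = np.random.default_rng(cfg.seed)
    mats = [encode_instance(inst, schema) for inst in instances]
    t_max = max(visit_cap, max(m.shape[0] for m in mats))
    x, mask = _pad_sequences(mats, t_max)
    y_all = np.array([inst.label for inst in instances], dtype=float)
    params = init_rnn_params(schema.width, cfg.hidden_width, cfg.rnn_cell, rng)
    opt = _Adam(params, cfg.learning_rate)
    history = []
    n = len(instances)
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            probs, caches = _rnn_forward_core(x[idx], mask[idx], params, cfg.rnn_cell)
            grads = _rnn_backward_core(probs, y_all[idx], params, caches, cfg.rnn_cell)
            opt.step(params, grads)
            epoch_loss += _bce(probs, y_all[idx]) * len(idx)
            seen += len(idx)
        history.append(epoch_loss / seen)
    return params, history


def _make_baseline(model_kind: str, cfg: TrainConfig):
    if model_kind == "logistic":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=2000)
    if model_kind == "decision_tree":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(random_state=cfg.seed)
    if model_kind == "gradient_boosting":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=cfg.seed, n_jobs=1, verbosity=0)
    raise ValueError(f"unknown model kind {model_kind!r}")


def train(model_kind: str, train_instances: Sequence[LabeledInstance],
          cfg: TrainConfig, *, schema: FeatureSchema | None = None,
          preprocess_cfg: PreprocessConfig | None = None) -> Predictor:
    """Fit one model kind on training instances.

    The feature schema is fitted from the training instances unless one is
    supplied (so held-out data never leaks into vocabularies or age
    normalization).  A fixed ``cfg.seed`` reproduces the fit exactly.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}; choose from {MODEL_KINDS}")
    if not train_instances:
        raise ValueError("training set is empty")
    labels = np.array([i.label for i in train_instances])
    _check_both_classes(labels)
    pp = preprocess_cfg or PreprocessConfig()
    if schema is None:
        schema = fit_schema(train_instances, pp)
    visit_cap = pp.visit_cap

    history: list[float] = []
    if model_kind == "gnn":
        params, history = _train_gnn(train_instances, schema, cfg)
    elif model_kind == "rnn":
        params, history = _train_rnn(train_instances, schema, cfg, visit_cap)
    else:
        est = _make_baseline(model_kind, cfg)
        est.fit(_baseline_matrix(train_instances, schema, visit_cap), labels)
        params = est
    return Predictor(model_kind, params, schema, cfg, visit_cap, history)


def predict(predictor: Predictor, instances: Sequence[LabeledInstance]
            ) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and thresholded labels (label 1 iff p >= threshold)."""
    if not getattr(predictor, "fitted", False):
        raise ValueError("predictor is not fitted")
    kind = predictor.model_kind
    if kind == "gnn":
        graphs = [build_patient_graph(i, predictor.schema) for i in instances]
        probs = gnn_forward(batch_graphs(graphs), predictor)
    elif kind == "rnn":
        mats = [encode_instance(i, predictor.schema) for i in instances]
        t_max = max(predictor.visit_cap, max(m.shape[0] for m in mats))
        x, mask = _pad_sequences(mats, t_max)
        probs, _ = _rnn_forward_core(x, mask, predictor.params, predictor.config.rnn_cell)
    else:
        xmat = _baseline_matrix(instances, predictor.schema, predictor.visit_cap)
        probs = predictor.params.predict_proba(xmat)[:, 1]
    probs = np.asarray(probs, dtype=float)
    labels = (probs >= predictor.config.threshold).astype(int)
    return probs, labels
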