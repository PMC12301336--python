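"""End-to-end model: fuse 1D and 2D features and train the softmax classifier.

The classifier input a⁰ concatenates the 1792-d 1D feature (two 768-d
chemical-language drug vectors + the 256-d compressed cell-line vector)
with the 256-d pooled 2D feature, then passes through ReLU hidden layers

    aˡ = ReLU(Wˡ aˡ⁻¹ + bˡ),   widths 2048 → 512 → 128 → 32 → 2,

a softmax over the two classes (synergistic / antagonistic), and the
cross-entropy loss, minimized with Adam.  Everything trains jointly —
the molecular GCN, the cell-line MLP, the transformer pooling block, and
the classifier — except the chemical-language drug vectors and the PPI
node embeddings, which are precomputed and frozen.

Ablation variants reproduce the component study: ``1d_only`` feeds the
classifier only the 1792-d feature, ``2d_only`` only the 256-d pooled
feature, and ``2d_no_graphtrans`` replaces the transformer stack with
direct mean pooling of the raw tokens.

Drug pairs are unordered: the token set of the 2D branch is symmetric by
construction, and prediction averages the two 1D concatenation orders, so
``predict(A, B, cell) == predict(B, A, cell)`` exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from .data import LabeledTriplet
from .molgraph import GCNParams, MolecularGraph, SmilesParseError, pad_graphs, smiles_to_graph
from .onedim import (CELL_DIM, CHEM_DIM, CellLineEncoderParams, ChemEmbedderBackend,
                     embed_smiles, encode_cell_line_batch)
from .pool import (MODEL_DIM, PoolParams, TokenMatrix, assemble_tokens,
                   graph_trans_pool_batched)
from .ppi import NodeEmbeddingTable

logger = logging.getLogger(__name__)

VARIANTS = ("full", "1d_only", "2d_only", "2d_no_graphtrans")
CLASSIFIER_HIDDEN = (512, 128, 32)
ONE_D_DIM = 2 * CHEM_DIM + CELL_DIM          # 1792
TWO_D_DIM = 256


@dataclass
class TrainConfig:
    """Training hyperparameters (Adam, early stopping on validation loss)."""

    learning_rate: float = 5e-4
    dropout: float = 0.3
    batch_size: int = 128
    epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0
    optimizer: str = "adam"
    device: str = "cpu"
    order_augmentation: bool = True
    n_heads: int = 2
    n_encoder_layers: int = 2
    dtype: str = "float32"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class Prediction:
    """Synergy probability (class 1) and thresholded call for one triplet."""

    drug_a: str
    drug_b: str
    cell_line: str
    probability: float
    label: int


@dataclass
class ModelParams:
    """All trainable parameter groups of one model variant."""

    gcn: GCNParams | None
    cell: CellLineEncoderParams | None
    pool: PoolParams | None
    clf_W: list[ad.Tensor]
    clf_b: list[ad.Tensor]
    dropout: float

    def tensors(self) -> list[ad.Tensor]:
        out: list[ad.Tensor] = []
        if self.gcn is not None:
            out += self.gcn.tensors()
        if self.cell is not None:
            out += self.cell.tensors()
        if self.pool is not None:
            out += self.pool.tensors()
        out += self.clf_W + self.clf_b
        return out

    def copy_data(self) -> list[np.ndarray]:
        return [t.data.copy() for t in self.tensors()]

    def load_data(self, arrays: list[np.ndarray]) -> None:
        for t, a in zip(self.tensors(), arrays):
            t.data = a.copy()


def classifier_input_dim(variant: str) -> int:
    if variant == "full":
        return ONE_D_DIM + TWO_D_DIM
    if variant == "1d_only":
        return ONE_D_DIM
    if variant in ("2d_only", "2d_no_graphtrans"):
        return TWO_D_DIM
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def init_params(variant: str, n_genes: int, config: TrainConfig,
                rng: np.random.Generator, dtype=None) -> ModelParams:
    """Seeded initialization of every parameter group a variant needs."""
    dtype = dtype or np.dtype(config.dtype)
    uses_2d = variant in ("full", "2d_only", "2d_no_graphtrans")
    uses_1d = variant in ("full", "1d_only")
    gcn = GCNParams.init(rng, dtype=dtype) if uses_2d else None
    cell = (CellLineEncoderParams.init(rng, n_genes, dropout=config.dropout,
                                       dtype=dtype) if uses_1d else None)
    pool = (PoolParams.init(rng, n_layers=config.n_encoder_layers,
                            dropout=config.dropout, n_heads=config.n_heads,
                            dtype=dtype) if uses_2d else None)
    widths = (classifier_input_dim(variant), *CLASSIFIER_HIDDEN, 2)
    clf_W, clf_b = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        clf_W.append(ad.Tensor(rng.uniform(-limit, limit, (fan_in, fan_out)).astype(dtype),
                               requires_grad=True))
        clf_b.append(ad.Tensor(np.zeros(fan_out, dtype=dtype), requires_grad=True))
    return ModelParams(gcn=gcn, cell=cell, pool=pool, clf_W=clf_W, clf_b=clf_b,
                       dropout=config.dropout)


# ---------------------------------------------------------------------------
# Spec-level primitives
# ---------------------------------------------------------------------------


def classifier_forward(feature: ad.Tensor, params: ModelParams,
                       train_mode: bool = False,
                       rng: np.random.Generator | None = None,
                       capture: dict | None = None) -> ad.Tensor:
    """(B, in) → logits (B, 2); hidden activations optionally captured."""
    h = feature
    n_hidden = len(params.clf_W) - 1
    for i in range(n_hidden):
        h = ad.relu(ad.add(ad.matmul(h, params.clf_W[i]), params.clf_b[i]))
        if capture is not None:
            capture[params.clf_W[i].shape[1]] = h.data.copy()
        h = ad.dropout(h, params.dropout, rng, train_mode)
    return ad.add(ad.matmul(h, params.clf_W[-1]), params.clf_b[-1])


def forward(feature_1d: np.ndarray, feature_2d: np.ndarray | None,
            params: ModelParams, train_mode: bool = False,
            capture: dict | None = None) -> np.ndarray:
    """Single-example fused forward pass to the 2-logit output."""
    parts = []
    if feature_1d is not None:
        parts.append(np.asarray(feature_1d, dtype=float))
    if feature_2d is not None:
        parts.append(np.asarray(feature_2d, dtype=float))
    x = np.concatenate(parts)
    expected = params.clf_W[0].shape[0]
    if x.shape[0] != expected:
        raise ValueError(f"classifier expects input width {expected}, got {x.shape[0]}")
    out = classifier_forward(ad.Tensor(x[None]), params, train_mode=train_mode,
                             capture=capture)
    return out.data[0]


def predict_proba(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    logits = np.asarray(logits, dtype=float)
    if not np.isfinite(logits).all():
        raise ValueError("logits must be finite")
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true class, floored at 1e-12."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    p_true = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.mean(np.log(p_true)))


# ---------------------------------------------------------------------------
# Dataset preparation
# ---------------------------------------------------------------------------


class _Prepared:
    """Dataset tensors shared by training and prediction."""

    def __init__(self, triplets, expression: pd.DataFrame,
                 ppi_table: NodeEmbeddingTable, dtype):
        self.triplets = list(triplets)
        self.genes = list(expression.columns)
        errors = []
        drugs: dict[str, str] = {}
        for t in self.triplets:
            for d, s in ((t.drug_a, t.smiles_a), (t.drug_b, t.smiles_b)):
                if d not in drugs:
                    drugs[d] = s
            if t.cell_line not in expression.index:
                errors.append(f"unknown cell line {t.cell_line!r}")
        self.drug_names = sorted(drugs)
        self.graphs: dict[str, MolecularGraph] = {}
        chem_cache: dict[str, np.ndarray] = {}
        backend = ChemEmbedderBackend()
        chem_rows = []
        for d in self.drug_names:
            try:
                self.graphs[d] = smiles_to_graph(drugs[d])
                chem_rows.append(embed_smiles(drugs[d], backend, _cache=chem_cache))
            except SmilesParseError:
                errors.append(f"unparseable SMILES for drug {d!r}: {drugs[d]!r}")
                chem_rows.append(np.zeros(CHEM_DIM))
        if errors:
            raise ValueError("invalid triplets:\n  " + "\n  ".join(sorted(set(errors))))
        self.dtype = dtype
        self.drug_index = {d: i for i, d in enumerate(self.drug_names)}
        self.chem = np.stack(chem_rows).astype(dtype)                  # (D, 768)
        gx, ga, counts = pad_graphs([self.graphs[d] for d in self.drug_names])
        self.graph_X = gx.astype(dtype)
        self.graph_A = ga.astype(dtype)
        self.atom_counts = counts
        self.vmax = gx.shape[1]

        self.cell_names = list(expression.index)
        self.cell_index = {c: i for i, c in enumerate(self.cell_names)}
        self.expr_raw = expression.to_numpy(dtype=float)

        self.gene_matrix = ppi_table.matrix_for(self.genes).astype(dtype)  # (G, 128)

        self.a_idx = np.array([self.drug_index[t.drug_a] for t in self.triplets])
        self.b_idx = np.array([self.drug_index[t.drug_b] for t in self.triplets])
        self.c_idx = np.array([self.cell_index[t.cell_line] for t in self.triplets])
        self.labels = np.array([t.label for t in self.triplets], dtype=int)

        # unordered pair ids (the 2D token set is order-symmetric)
        pair_keys = [tuple(sorted(p)) for p in zip(self.a_idx, self.b_idx)]
        uniq = sorted(set(pair_keys))
        self.pair_lookup = {k: i for i, k in enumerate(uniq)}
        self.pair_of_triplet = np.array([self.pair_lookup[k] for k in pair_keys])
        self.pairs = np.array(uniq)                                    # (P, 2)

        self.expr_mean = np.zeros(len(self.genes))
        self.expr_std = np.ones(len(self.genes))

    def set_normalization(self, train_cell_rows: np.ndarray) -> None:
        """Z-score statistics per gene over the training cell lines."""
        rows = self.expr_raw[train_cell_rows]
        self.expr_mean = rows.mean(axis=0)
        self.expr_std = np.maximum(rows.std(axis=0), 1e-8)

    @property
    def expr_z(self) -> np.ndarray:
        return ((self.expr_raw - self.expr_mean) / self.expr_std).astype(self.dtype)


def _pair_features(prep: _Prepared, params: ModelParams, pair_ids: np.ndarray,
                   variant: str, train_mode: bool, rng) -> tuple[ad.Tensor, np.ndarray]:
    """2D features for the requested unique pairs: (len(pair_ids), 256)."""
    from .molgraph import gcn_forward_batched

    pairs = prep.pairs[pair_ids]
    drug_ids = np.unique(pairs)
    local = {d: i for i, d in enumerate(drug_ids)}
    emb = gcn_forward_batched(ad.Tensor(prep.graph_X[drug_ids]),
                              prep.graph_A[drug_ids], params.gcn)  # (D, Vmax, 128)
    ia = np.array([local[p[0]] for p in pairs])
    ib = np.array([local[p[1]] for p in pairs])
    tok_a = ad.gather(emb, ia)
    tok_b = ad.gather(emb, ib)
    P = len(pairs)
    genes = ad.Tensor(np.broadcast_to(prep.gene_matrix,
                                      (P, *prep.gene_matrix.shape)).copy())
    tokens = ad.concat([tok_a, tok_b, genes], axis=1)
    T = tokens.data.shape[1]
    mask = np.zeros((P, T), dtype=bool)
    ar = np.arange(prep.vmax)
    mask[:, :prep.vmax] = ar[None, :] < prep.atom_counts[pairs[:, 0]][:, None]
    mask[:, prep.vmax:2 * prep.vmax] = ar[None, :] < prep.atom_counts[pairs[:, 1]][:, None]
    mask[:, 2 * prep.vmax:] = True
    feat = graph_trans_pool_batched(tokens, params.pool, mask=mask,
                                    train_mode=train_mode, rng=rng,
                                    skip_encoders=(variant == "2d_no_graphtrans"))
    return feat, pair_ids


def _batch_logits(prep: _Prepared, params: ModelParams, idx: np.ndarray,
                  variant: str, train_mode: bool, rng,
                  swap: np.ndarray | None = None,
                  capture: dict | None = None) -> ad.Tensor:
    """Differentiable logits for the triplets at ``idx``."""
    parts: list[ad.Tensor] = []
    a = prep.a_idx[idx]
    b = prep.b_idx[idx]
    if swap is not None:
        a, b = np.where(swap, b, a), np.where(swap, a, b)
    if variant in ("full", "1d_only"):
        cells = np.unique(prep.c_idx[idx])
        cell_local = {c: i for i, c in enumerate(cells)}
        cell_vec = encode_cell_line_batch(ad.Tensor(prep.expr_z[cells]), params.cell,
                                          train_mode=train_mode, rng=rng)
        ci = np.array([cell_local[c] for c in prep.c_idx[idx]])
        parts.append(ad.Tensor(prep.chem[a]))
        parts.append(ad.Tensor(prep.chem[b]))
        parts.append(ad.gather(cell_vec, ci))
    if variant in ("full", "2d_only", "2d_no_graphtrans"):
        batch_pairs = np.unique(prep.pair_of_triplet[idx])
        pair_local = {p: i for i, p in enumerate(batch_pairs)}
        feat2d, _ = _pair_features(prep, params, batch_pairs, variant, train_mode, rng)
        pi = np.array([pair_local[p] for p in prep.pair_of_triplet[idx]])
        parts.append(ad.gather(feat2d, pi))
    feature = ad.concat(parts, axis=1) if len(parts) > 1 else parts[0]
    return classifier_forward(feature, params, train_mode=train_mode, rng=rng,
                              capture=capture)


def _batch_loss(logits: ad.Tensor, labels: np.ndarray) -> ad.Tensor:
    onehot = np.zeros(logits.data.shape, dtype=logits.data.dtype)
    onehot[np.arange(len(labels)), labels] = 1.0
    logp = ad.log_softmax_last(logits)
    nll = ad.mul(ad.sum_along(ad.sum_along(ad.mul(logp, onehot), 1), 0),
                 np.asarray(-1.0 / len(labels), dtype=logits.data.dtype))
    return nll


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """Trained parameters plus everything needed to featurize new triplets."""

    params: ModelParams
    config: TrainConfig
    variant: str
    genes: list[str]
    expression: pd.DataFrame
    ppi_table: NodeEmbeddingTable
    expr_mean: np.ndarray
    expr_std: np.ndarray
    history: dict

    def _prep(self, triplets) -> _Prepared:
        prep = _Prepared(triplets, self.expression, self.ppi_table,
                         np.dtype(self.config.dtype))
        prep.expr_mean = self.expr_mean
        prep.expr_std = self.expr_std
        return prep

    def save(self, prefix) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": t.data for i, t in enumerate(self.params.tensors())}
        arrays["expr_mean"] = self.expr_mean
        arrays["expr_std"] = self.expr_std
        arrays["ppi_vectors"] = self.ppi_table.vectors
        np.savez(prefix.with_suffix(".npz"), **arrays)
        sidecar = {
            "variant": self.variant,
            "config": asdict(self.config),
            "genes": self.genes,
            "ppi_genes": self.ppi_table.genes,
            "history": self.history,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar))
        self.expression.to_csv(prefix.with_suffix(".expression.tsv"), sep="\t",
                               index_label="cell_line")

    @classmethod
    def load(cls, prefix) -> "TrainedModel":
        prefix = Path(prefix)
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        config = TrainConfig(**sidecar["config"])
        arrays = np.load(prefix.with_suffix(".npz"))
        rng = np.random.default_rng(0)
        params = init_params(sidecar["variant"], len(sidecar["genes"]), config, rng)
        params.load_data([arrays[f"p{i}"] for i in range(len(params.tensors()))])
        expression = pd.read_csv(prefix.with_suffix(".expression.tsv"), sep="\t",
                                 index_col=0)
        table = NodeEmbeddingTable(genes=sidecar["ppi_genes"],
                                   vectors=arrays["ppi_vectors"])
        return cls(params=params, config=config, variant=sidecar["variant"],
                   genes=sidecar["genes"], expression=expression, ppi_table=table,
                   expr_mean=arrays["expr_mean"], expr_std=arrays["expr_std"],
                   history=sidecar["history"])


def train_model(triplets, expression: pd.DataFrame, ppi_table: NodeEmbeddingTable,
                config: TrainConfig | None = None, variant: str = "full") -> TrainedModel:
    """Train one model variant end to end; returns params + loss history.

    A seeded fraction of the training triplets is held aside for early
    stopping on validation loss (patience in epochs); the best-validation
    parameters are restored.  All randomness (init, shuffling, dropout,
    drug-order augmentation) derives from ``config.seed``.
    """
    config = config or TrainConfig()
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    dtype = np.dtype(config.dtype)
    prep = _Prepared(triplets, expression, ppi_table, dtype)
    root = np.random.default_rng(config.seed)
    init_rng, shuffle_rng, _drop, aug_rng, split_rng = root.spawn(5)
    # dropout burns through bulk random draws; SFC64 keeps that cheap
    drop_rng = np.random.Generator(np.random.SFC64(config.seed + 0x5F0))

    n = len(prep.triplets)
    order = split_rng.permutation(n)
    n_val = int(round(config.val_fraction * n))
    n_val = min(n_val, n - 1)
    val_idx, train_idx = order[:n_val], order[n_val:]
    prep.set_normalization(np.unique(prep.c_idx[train_idx]))

    params = init_params(variant, len(prep.genes), config, init_rng, dtype=dtype)
    opt = ad.Adam(params.tensors(), lr=config.learning_rate)

    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_arrays = params.copy_data()
    best_epoch = 0
    for epoch in range(config.epochs):
        perm = shuffle_rng.permutation(train_idx)
        losses = []
        for s in range(0, len(perm), config.batch_size):
            idx = perm[s : s + config.batch_size]
            swap = (aug_rng.random(len(idx)) < 0.5) if config.order_augmentation else None
            opt.zero_grad()
            logits = _batch_logits(prep, params, idx, variant, True, drop_rng, swap=swap)
            loss = _batch_loss(logits, prep.labels[idx])
            ad.backward(loss)
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        if n_val > 0:
            vlogits = _batch_logits(prep, params, val_idx, variant, False, None)
            vloss = float(_batch_loss(vlogits, prep.labels[val_idx]).data)
        else:
            vloss = history["train_loss"][-1]
        history["val_loss"].append(vloss)
        if vloss < best_val - 1e-6:
            best_val = vloss
            best_arrays = params.copy_data()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
            break
    params.load_data(best_arrays)
    return TrainedModel(params=params, config=config, variant=variant,
                        genes=prep.genes, expression=expression,
                        ppi_table=ppi_table, expr_mean=prep.expr_mean,
                        expr_std=prep.expr_std, history=history)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_batch(model: TrainedModel, triplets, capture: dict | None = None,
                  threshold: float = 0.5) -> list[Prediction]:
    """Synergy probabilities for a triplet list, preserving input order.

    With order augmentation the forward pass runs in both drug orders and
    the two class probabilities are averaged, making the output exactly
    symmetric in drug order.
    """
    prep = model._prep(triplets)
    idx = np.arange(len(prep.triplets))
    probs = []
    orders = [np.zeros(len(idx), bool)]
    if model.config.order_augmentation:
        orders.append(np.ones(len(idx), bool))
    for swap in orders:
        logits = _batch_logits(prep, model.params, idx, model.variant, False, None,
                               swap=swap, capture=capture)
        probs.append(predict_proba(logits.data)[:, 1])
    p = np.mean(probs, axis=0)
    return [
        Prediction(drug_a=t.drug_a, drug_b=t.drug_b, cell_line=t.cell_line,
                   probability=float(pi), label=int(pi >= threshold))
        for t, pi in zip(triplets, p)
    ]


def predict(model: TrainedModel, triplet: LabeledTriplet) -> Prediction:
    """Order-symmetric prediction for a single triplet."""
    return predict_batch(model, [triplet])[0]


def hidden_activations(model: TrainedModel, triplets) -> dict[int, np.ndarray]:
    """Classifier hidden activations (widths 512, 128, 32), first drug order."""
    prep = model._prep(triplets)
    capture: dict[int, np.ndarray] = {}
    _batch_logits(prep, model.params, np.arange(len(prep.triplets)), model.variant,
                  False, None, capture=capture)
    return capture


def attention_for(model: TrainedModel, triplet: LabeledTriplet):
    """Token matrix and attention records of the trained pooling block."""
    if model.params.pool is None or model.params.gcn is None:
        raise ValueError(f"variant {model.variant!r} has no attention block")
    from .molgraph import gcn_forward
    from .pool import graph_trans_pool

    graph_a = smiles_to_graph(triplet.smiles_a)
    graph_b = smiles_to_graph(triplet.smiles_b)
    emb_a = gcn_forward(graph_a, model.params.gcn)
    emb_b = gcn_forward(graph_b, model.params.gcn)
    table = NodeEmbeddingTable(genes=model.genes,
                               vectors=model.ppi_table.matrix_for(model.genes))
    tokens = assemble_tokens(emb_a, emb_b, table)
    tokens.atom_elements = {"atomA": graph_a.elements, "atomB": graph_b.elements}
    feature, records = graph_trans_pool(tokens, model.params.pool)
    return tokens, feature, records


def enumerate_screen(model: TrainedModel, query_drug: str, query_smiles: str,
                     library: list[tuple[str, str]],
                     cell_lines: list[str]) -> pd.DataFrame:
    """Screen a query drug against a library across cell lines.

    Returns one row per (library drug, cell line) pairing — |library| ×
    |cell lines| rows.
    """
    triplets = [
        LabeledTriplet(drug_a=query_drug, drug_b=d, smiles_a=query_smiles,
                       smiles_b=s, cell_line=c, label=0)
        for d, s in library
        for c in cell_lines
    ]
    if not triplets:
        return pd.DataFrame(columns=["drug_a", "drug_b", "cell_line",
                                     "probability", "synergistic"])
    preds = predict_batch(model, triplets)
    return pd.DataFrame(
        [(p.drug_a, p.drug_b, p.cell_line, p.probability, p.label) for p in preds],
        columns=["drug_a", "drug_b", "cell_line", "probability", "synergistic"],
    )
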