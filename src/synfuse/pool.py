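"""Graph-trans pooling: transformer encoders over atom + protein tokens.

The "2D" view of a triplet stacks three token groups into one set: the
GCN atom embeddings of drug A, those of drug B, and the frozen node2vec
embeddings of every PPI protein — all 128-d, so a pair with V_A and V_B
atoms over G genes yields T = V_A + V_B + G tokens.  Two transformer
encoder layers with multi-head scaled dot-product attention

    Attention(Q_i, K_i, V_i) = softmax(Q_i K_iᵀ / √d_k) V_i

let every atom attend to every other atom and every protein (and vice
versa); heads are concatenated and projected, each sublayer is wrapped in
a residual connection + layer normalization, and the feed-forward sublayer
is a two-layer ReLU network.  Tokens carry no positional encoding — the
input is a set — so the pooled output is invariant under token
permutation.  Mean pooling over tokens followed by a ReLU-activated fully
connected layer yields the 256-d 2D feature; the per-head softmax score
matrices are exposed for interpretability.

Defaults: 2 heads × d_k 32 (total projection width 64), FFN inner width
64, 2 encoder layers, dropout 0.3 after each sublayer during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .ppi import NodeEmbeddingTable

MODEL_DIM = 128
N_HEADS = 2
ATTN_WIDTH = 64          # total Q/K/V projection width = heads × d_k
FFN_WIDTH = 64
N_LAYERS = 2
POOL_DIM = 256


@dataclass
class TokenMatrix:
    """Stacked (atomsA, atomsB, genes) token rows with a role index."""

    X: np.ndarray                    # (T, 128)
    roles: list[tuple[str, object]]  # ("atomA", i) | ("atomB", i) | ("gene", symbol)

    def __post_init__(self):
        if len(self.roles) != self.X.shape[0]:
            raise ValueError("role index must cover every token row exactly once")

    @property
    def n_tokens(self) -> int:
        return self.X.shape[0]

    def role_positions(self, role: str) -> np.ndarray:
        return np.array([i for i, (r, _) in enumerate(self.roles) if r == role],
                        dtype=int)


@dataclass
class AttentionRecord:
    """Softmax score matrix of one head in one encoder layer."""

    layer: int
    head: int
    scores: np.ndarray               # (T, T), rows sum to 1
    roles: list[tuple[str, object]]


def _glorot(rng, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


@dataclass
class AttentionParams:
    """Per-head Q/K/V projections plus the output projection."""

    Wq: list[ad.Tensor]              # per head: (128, d_k)
    Wk: list[ad.Tensor]
    Wv: list[ad.Tensor]
    Wo: ad.Tensor                    # (heads·d_k, 128)

    @classmethod
    def init(cls, rng, n_heads: int = N_HEADS, model_dim: int = MODEL_DIM,
             attn_width: int = ATTN_WIDTH, dtype=np.float64):
        if attn_width % n_heads:
            raise ValueError("attention width must divide evenly across heads")
        dk = attn_width // n_heads
        mk = lambda: ad.Tensor(_glorot(rng, model_dim, dk, dtype), requires_grad=True)
        return cls(
            Wq=[mk() for _ in range(n_heads)],
            Wk=[mk() for _ in range(n_heads)],
            Wv=[mk() for _ in range(n_heads)],
            Wo=ad.Tensor(_glorot(rng, attn_width, model_dim, dtype), requires_grad=True),
        )

    @property
    def n_heads(self) -> int:
        return len(self.Wq)

    @property
    def d_k(self) -> int:
        return self.Wq[0].shape[1]

    def tensors(self):
        return [*self.Wq, *self.Wk, *self.Wv, self.Wo]


@dataclass
class EncoderParams:
    """One transformer encoder layer: attention + FFN + two layer norms."""

    attn: AttentionParams
    W1: ad.Tensor
    b1: ad.Tensor
    W2: ad.Tensor
    b2: ad.Tensor
    ln1_g: ad.Tensor
    ln1_b: ad.Tensor
    ln2_g: ad.Tensor
    ln2_b: ad.Tensor
    dropout: float = 0.3

    @classmethod
    def init(cls, rng, n_heads: int = N_HEADS, model_dim: int = MODEL_DIM,
             attn_width: int = ATTN_WIDTH, ffn_width: int = FFN_WIDTH,
             dropout: float = 0.3, dtype=np.float64):
        t = lambda arr, g=True: ad.Tensor(arr.astype(dtype), requires_grad=g)
        return cls(
            attn=AttentionParams.init(rng, n_heads, model_dim, attn_width, dtype),
            W1=t(_glorot(rng, model_dim, ffn_width, dtype)),
            b1=t(np.zeros(ffn_width)),
            W2=t(_glorot(rng, ffn_width, model_dim, dtype)),
            b2=t(np.zeros(model_dim)),
            ln1_g=t(np.ones(model_dim)),
            ln1_b=t(np.zeros(model_dim)),
            ln2_g=t(np.ones(model_dim)),
            ln2_b=t(np.zeros(model_dim)),
            dropout=dropout,
        )

    def tensors(self):
        return [*self.attn.tensors(), self.W1, self.b1, self.W2, self.b2,
                self.ln1_g, self.ln1_b, self.ln2_g, self.ln2_b]


@dataclass
class PoolParams:
    """Full graph-trans pooling block: encoder stack + output projection."""

    layers: list[EncoderParams]
    W_out: ad.Tensor                 # (128, 256)
    b_out: ad.Tensor

    @classmethod
    def init(cls, rng, n_layers: int = N_LAYERS, model_dim: int = MODEL_DIM,
             pool_dim: int = POOL_DIM, dropout: float = 0.3,
             n_heads: int = N_HEADS, dtype=np.float64):
        return cls(
            layers=[EncoderParams.init(rng, n_heads=n_heads, model_dim=model_dim,
                                       dropout=dropout, dtype=dtype)
                    for _ in range(n_layers)],
            W_out=ad.Tensor(_glorot(rng, model_dim, pool_dim, dtype), requires_grad=True),
            b_out=ad.Tensor(np.zeros(pool_dim, dtype=dtype), requires_grad=True),
        )

    def tensors(self):
        out = [self.W_out, self.b_out]
        for layer in self.layers:
            out.extend(layer.tensors())
        return out


def assemble_tokens(atom_emb_a: np.ndarray, atom_emb_b: np.ndarray,
                    ppi_table: NodeEmbeddingTable) -> TokenMatrix:
    """Stack drug-A atoms, drug-B atoms, and every PPI gene into one token set."""
    atom_emb_a = np.asarray(atom_emb_a)
    atom_emb_b = np.asarray(atom_emb_b)
    gene_rows = ppi_table.vectors
    widths = {atom_emb_a.shape[1], atom_emb_b.shape[1], gene_rows.shape[1]}
    if len(widths) != 1:
        raise ValueError(f"token widths differ: {sorted(widths)}")
    X = np.concatenate([atom_emb_a, atom_emb_b, gene_rows], axis=0)
    roles = (
        [("atomA", i) for i in range(atom_emb_a.shape[0])]
        + [("atomB", i) for i in range(atom_emb_b.shape[0])]
        + [("gene", g) for g in ppi_table.genes]
    )
    return TokenMatrix(X=X, roles=roles)


# ---------------------------------------------------------------------------
# Differentiable batched forward
# ---------------------------------------------------------------------------


def _mask_bias(mask: np.ndarray | None, dtype) -> np.ndarray | None:
    """(B, T) validity mask → additive (B, 1, T) key-side logit bias."""
    if mask is None:
        return None
    bias = np.where(mask, 0.0, -1e9).astype(dtype)
    return bias[:, None, :]


def multi_head_attention_batched(X: ad.Tensor, params: AttentionParams,
                                 mask: np.ndarray | None = None,
                                 collect: list | None = None) -> ad.Tensor:
    """Masked multi-head attention on (B, T, 128) stacks.

    Raises on non-finite inputs (exploding upstream activations).  When
    ``collect`` is a list, per-head softmax score arrays (B, T, T) are
    appended to it.
    """
    if not np.isfinite(X.data).all():
        raise FloatingPointError("non-finite attention input")
    dk = params.d_k
    bias = _mask_bias(mask, X.data.dtype)
    heads = []
    scale = np.asarray(1.0 / np.sqrt(dk), dtype=X.data.dtype)
    for h in range(params.n_heads):
        # scaling Q (T × d_k) is equivalent to scaling the T × T logits
        Q = ad.mul(ad.matmul(X, params.Wq[h]), scale)
        K = ad.matmul(X, params.Wk[h])
        V = ad.matmul(X, params.Wv[h])
        logits = ad.matmul(Q, ad.transpose_last(K))
        scores = ad.softmax_last(logits, additive_mask=bias)
        if collect is not None:
            collect.append(scores.data)
        heads.append(ad.matmul(scores, V))
    out = ad.matmul(ad.concat(heads, axis=-1), params.Wo)
    return out


def transformer_encoder_layer_batched(X: ad.Tensor, params: EncoderParams,
                                      mask: np.ndarray | None = None,
                                      train_mode: bool = False,
                                      rng: np.random.Generator | None = None,
                                      collect: list | None = None) -> ad.Tensor:
    """Post-norm encoder layer: LN(X + MHA(X)) then LN(y + FFN(y))."""
    attn_out = multi_head_attention_batched(X, params.attn, mask=mask, collect=collect)
    attn_out = ad.dropout(attn_out, params.dropout, rng, train_mode)
    y = ad.layer_norm_last(ad.add(X, attn_out), params.ln1_g, params.ln1_b)
    ffn = ad.add(ad.matmul(ad.relu(ad.add(ad.matmul(y, params.W1), params.b1)),
                           params.W2), params.b2)
    ffn = ad.dropout(ffn, params.dropout, rng, train_mode)
    return ad.layer_norm_last(ad.add(y, ffn), params.ln2_g, params.ln2_b)


def masked_mean_pool(X: ad.Tensor, mask: np.ndarray | None) -> ad.Tensor:
    """Mean over valid token rows: (B, T, D) → (B, D)."""
    if mask is None:
        B, T, _ = X.data.shape
        return ad.mul(ad.sum_along(X, axis=1), np.asarray(1.0 / T, dtype=X.data.dtype))
    m = mask.astype(X.data.dtype)
    counts = m.sum(axis=1, keepdims=True)
    weighted = ad.mul(X, m[:, :, None])
    return ad.mul(ad.sum_along(weighted, axis=1),
                  np.asarray(1.0, dtype=X.data.dtype) / counts)


def graph_trans_pool_batched(X: ad.Tensor, params: PoolParams,
                             mask: np.ndarray | None = None,
                             train_mode: bool = False,
                             rng: np.random.Generator | None = None,
                             collect: list | None = None,
                             skip_encoders: bool = False) -> ad.Tensor:
    """Encoder stack → masked mean pooling → ReLU projection to 256-d.

    ``skip_encoders`` bypasses the transformer stack (direct mean pooling
    of raw tokens), the configuration used by the no-graph-trans ablation.
    """
    h = X
    if not skip_encoders:
        for layer in params.layers:
            h = transformer_encoder_layer_batched(
                h, layer, mask=mask, train_mode=train_mode, rng=rng, collect=collect
            )
    pooled = masked_mean_pool(h, mask)
    return ad.relu(ad.add(ad.matmul(pooled, params.W_out), params.b_out))


# ---------------------------------------------------------------------------
# Single-instance API with attention records
# ---------------------------------------------------------------------------


def multi_head_attention(tokens: TokenMatrix, params: AttentionParams):
    """(T, 128) attention forward returning output and per-head records."""
    collect: list = []
    out = multi_head_attention_batched(ad.Tensor(tokens.X[None]), params,
                                       collect=collect)
    records = [AttentionRecord(layer=0, head=h, scores=s[0], roles=list(tokens.roles))
               for h, s in enumerate(collect)]
    return out.data[0], records


def transformer_encoder_layer(tokens: TokenMatrix, params: EncoderParams) -> np.ndarray:
    """Eval-mode single-instance encoder layer."""
    out = transformer_encoder_layer_batched(ad.Tensor(tokens.X[None]), params)
    return out.data[0]


def graph_trans_pool(tokens: TokenMatrix, params: PoolParams):
    """Eval-mode pooling of one token set → (256-d feature, attention records)."""
    collect: list = []
    out = graph_trans_pool_batched(ad.Tensor(tokens.X[None]), params, collect=collect)
    n_heads = params.layers[0].attn.n_heads if params.layers else 0
    records = [
        AttentionRecord(layer=i // n_heads, head=i % n_heads, scores=s[0],
                        roles=list(tokens.roles))
        for i, s in enumerate(collect)
    ]
    return out.data[0], records
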