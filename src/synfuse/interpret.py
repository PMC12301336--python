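"""Attention-based interpretability and hidden-embedding projection.

Two views explain a prediction: (1) slices of the transformer attention
matrices — which genes a drug's atoms attend to, and which atoms of one
drug attend to which atoms of the other — min–max normalized per column so
each column's strongest entry is 1; (2) 2D UMAP projections of classifier
hidden activations (widths 512 and 32), which separate synergistic from
antagonistic triplets when the model has learned the decision structure.

Normalization is applied AFTER slicing, so the scale is relative to the
displayed sub-matrix (the heatmap scope), not the full token set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pool import AttentionRecord

logger = logging.getLogger(__name__)


@dataclass
class AttentionView:
    """A labeled slice of an attention matrix (queries × keys)."""

    matrix: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    query_role: str
    key_role: str
    normalization: str = "none"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.row_labels,
                            columns=self.col_labels)

    def to_tsv(self, path) -> None:
        """Long-format export: (row label, column label, score)."""
        frame = self.to_frame().stack().rename("score").reset_index()
        frame.columns = ["query", "key", "score"]
        frame.to_csv(path, sep="\t", index=False)


def normalize_attention_columns(matrix: np.ndarray) -> np.ndarray:
    """Min–max normalize each column to [0, 1]; constant columns become 0."""
    matrix = np.asarray(matrix, dtype=float)
    if not np.isfinite(matrix).all():
        raise ValueError("attention matrix must be finite")
    lo = matrix.min(axis=0, keepdims=True)
    hi = matrix.max(axis=0, keepdims=True)
    span = hi - lo
    constant = span[0] == 0
    if constant.any():
        logger.info("%d constant attention columns mapped to zero",
                    int(constant.sum()))
    out = np.zeros_like(matrix)
    ok = ~constant
    out[:, ok] = (matrix[:, ok] - lo[:, ok]) / span[:, ok]
    return out


def _role_label(role: tuple[str, object]) -> str:
    kind, ident = role
    if kind == "gene":
        return str(ident)
    return f"{kind}:{ident}"


def slice_attention(records: list[AttentionRecord], query_role: str,
                    key_role: str, head_aggregation: str = "mean",
                    layer: int = -1, normalize: bool = True):
    """Extract a (query role × key role) attention view from the records.

    ``layer`` selects an encoder layer (default: final).  Heads are either
    averaged (``mean``) or returned per head (``per_head``, a list).
    Min–max column normalization is applied to the slice afterwards.
    """
    layers = sorted({r.layer for r in records})
    if not layers:
        raise ValueError("no attention records supplied")
    chosen = layers[layer] if layer < 0 else layer
    selected = [r for r in records if r.layer == chosen]
    if not selected:
        raise ValueError(f"no records for encoder layer {chosen}")
    roles = selected[0].roles
    q_idx = np.array([i for i, (k, _) in enumerate(roles) if k == query_role])
    k_idx = np.array([i for i, (k, _) in enumerate(roles) if k == key_role])
    if q_idx.size == 0 or k_idx.size == 0:
        raise ValueError(
            f"empty role selection: {query_role!r} × {key_role!r}"
        )
    row_labels = [_role_label(roles[i]) for i in q_idx]
    col_labels = [_role_label(roles[i]) for i in k_idx]

    def build(matrix: np.ndarray) -> AttentionView:
        sliced = matrix[np.ix_(q_idx, k_idx)]
        norm_tag = "none"
        if normalize:
            sliced = normalize_attention_columns(sliced)
            norm_tag = "column_minmax"
        return AttentionView(matrix=sliced, row_labels=row_labels,
                             col_labels=col_labels, query_role=query_role,
                             key_role=key_role, normalization=norm_tag)

    if head_aggregation == "mean":
        return build(np.mean([r.scores for r in selected], axis=0))
    if head_aggregation == "per_head":
        return [build(r.scores) for r in sorted(selected, key=lambda r: r.head)]
    raise ValueError(f"unknown head aggregation {head_aggregation!r}")


def top_attended_genes(view: AttentionView, k: int) -> list[tuple[str, float]]:
    """Rank genes by the maximum attention any atom of the drug pays them.

    Max-aggregation over atoms preserves sharp single-atom signals; ties
    break lexicographically on the gene symbol.  The ranking is computed
    on the view as given and the per-gene scores are min–max normalized
    for reporting.  Rank on an *unnormalized* slice
    (``slice_attention(..., normalize=False)``): per-column min–max
    normalization pins every non-constant column's maximum at 1, which
    would erase the between-gene differences the ranking relies on.
    """
    if view.key_role != "gene":
        raise ValueError("view keys must be genes")
    scores = view.matrix.max(axis=0)
    span = scores.max() - scores.min()
    norm = (scores - scores.min()) / span if span > 0 else np.zeros_like(scores)
    ranked = sorted(zip(view.col_labels, norm), key=lambda gs: (-gs[1], gs[0]))
    return [(g, float(s)) for g, s in ranked[:max(k, 0)]]


def project_hidden_embeddings(activations: np.ndarray, labels,
                              seed: int = 0, n_neighbors: int = 15,
                              min_dist: float = 0.1) -> pd.DataFrame:
    """Seeded 2D UMAP projection of hidden activations, one row per triplet."""
    import umap

    activations = np.asarray(activations, dtype=float)
    labels = np.asarray(labels)
    if activations.shape[0] != labels.shape[0]:
        raise ValueError("activations and labels must be row-aligned")
    if activations.shape[0] < 10:
        raise ValueError("need at least 10 rows for a stable projection")
    reducer = umap.UMAP(n_components=2, random_state=seed,
                        n_neighbors=min(n_neighbors, activations.shape[0] - 1),
                        min_dist=min_dist)
    coords = reducer.fit_transform(activations)
    return pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "label": labels})
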