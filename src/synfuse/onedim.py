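"""One-dimensional feature embedding: drug language vectors + cell-line MLP.

The "1D" view of a drug pair–cell line triplet concatenates three parts:
a 768-d vector per drug from a chemical-language embedder, and a 256-d
cell-line vector produced by a three-layer MLP that compresses the
landmark-gene expression profile (978 genes at full scale).

The chemical-language embedder is an interface.  The ``pretrained``
backend slot is where a fine-tuned transformer language model plugs in;
the ``hashed_fallback`` backend ships with the package and is fully
offline: it hashes the molecule's circular (Morgan, radius 2) substructure
identifiers into 768 buckets by identifier modulus, accumulates counts,
and L2-normalizes — deterministic, structure-sensitive, and dependency-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from . import autodiff as ad
from .molgraph import SmilesParseError

CHEM_DIM = 768
CELL_DIM = 256
#: widths of the three-layer expression compressor (input width follows the
#: configured gene count; 978 at full scale)
CELL_HIDDEN = (768, 512)

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2)


@dataclass(frozen=True)
class ChemEmbedderBackend:
    """Tagged chemical-language embedder; output is always 768-d."""

    backend: str = "hashed_fallback"
    dim: int = CHEM_DIM


def embed_smiles(smiles: str, backend: ChemEmbedderBackend | None = None,
                 _cache: dict | None = None) -> np.ndarray:
    """Deterministic 768-d chemical-language vector for one molecule."""
    if backend is None:
        backend = ChemEmbedderBackend()
    if _cache is not None and smiles in _cache:
        return _cache[smiles]
    if backend.backend == "hashed_fallback":
        vec = _hashed_embedding(smiles, backend.dim)
    elif backend.backend == "pretrained":
        raise NotImplementedError(
            "no pretrained chemical-language weights are bundled; use "
            "ChemEmbedderBackend(backend='hashed_fallback')"
        )
    else:
        raise ValueError(f"unknown embedder backend {backend.backend!r}")
    if _cache is not None:
        _cache[smiles] = vec
    return vec


def _hashed_embedding(smiles: str, dim: int) -> np.ndarray:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    counts = _MORGAN.GetSparseCountFingerprint(mol).GetNonzeroElements()
    vec = np.zeros(dim)
    for identifier, count in counts.items():
        vec[identifier % dim] += count
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec


@dataclass
class CellLineEncoderParams:
    """Weights of the 3-layer expression compressor (genes → 768 → 512 → 256)."""

    weights: list[ad.Tensor]
    biases: list[ad.Tensor]
    dropout: float = 0.3

    @classmethod
    def init(cls, rng: np.random.Generator, n_genes: int,
             hidden=CELL_HIDDEN, out_dim: int = CELL_DIM,
             dropout: float = 0.3, dtype=np.float64):
        widths = (n_genes, *hidden, out_dim)
        weights, biases = [], []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            weights.append(ad.Tensor(
                rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype),
                requires_grad=True))
            biases.append(ad.Tensor(np.zeros(fan_out, dtype=dtype), requires_grad=True))
        return cls(weights=weights, biases=biases, dropout=dropout)

    @property
    def n_genes(self) -> int:
        return self.weights[0].shape[0]

    def tensors(self) -> list[ad.Tensor]:
        return [*self.weights, *self.biases]


def encode_cell_line_batch(expr: ad.Tensor, params: CellLineEncoderParams,
                           train_mode: bool = False,
                           rng: np.random.Generator | None = None) -> ad.Tensor:
    """Differentiable (B, genes) → (B, 256) forward pass.

    ReLU after each hidden layer; dropout only in train mode.
    """
    h = expr
    last = len(params.weights) - 1
    for i, (W, b) in enumerate(zip(params.weights, params.biases)):
        h = ad.add(ad.matmul(h, W), b)
        if i < last:
            h = ad.relu(h)
            h = ad.dropout(h, params.dropout, rng, train_mode)
    return h


def encode_cell_line(expression: np.ndarray, params: CellLineEncoderParams,
                     train_mode: bool = False,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Compress one expression profile into the 256-d cell-line vector."""
    expression = np.asarray(expression, dtype=float)
    if expression.shape != (params.n_genes,):
        raise ValueError(
            f"expected expression vector of length {params.n_genes}, "
            f"got shape {expression.shape}"
        )
    out = encode_cell_line_batch(ad.Tensor(expression[None, :]), params,
                                 train_mode=train_mode, rng=rng)
    return out.data[0]


def fuse_1d(vec_a: np.ndarray, vec_b: np.ndarray, cell_vec: np.ndarray) -> np.ndarray:
    """Concatenate (drug A, drug B, cell line) into the 1792-d 1D feature."""
    vec_a, vec_b, cell_vec = map(np.asarray, (vec_a, vec_b, cell_vec))
    if vec_a.shape != (CHEM_DIM,) or vec_b.shape != (CHEM_DIM,):
        raise ValueError(f"drug vectors must have length {CHEM_DIM}")
    if cell_vec.shape != (CELL_DIM,):
        raise ValueError(f"cell-line vector must have length {CELL_DIM}")
    return np.concatenate([vec_a, vec_b, cell_vec])
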