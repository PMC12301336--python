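"""SMILES → molecular graph featurization and the two-layer GCN encoder.

Each drug becomes an undirected heavy-atom graph: one node per atom, one
edge per bond, and a 78-dimensional binary feature row per atom built from
standard RDKit descriptors — element one-hot (44 symbols with an "other"
bucket), degree one-hot (0–10), attached-hydrogen one-hot (0–10), implicit
valence one-hot (0–10), and an aromaticity flag.  The graph encoder is a
two-layer graph convolution

    h^(l+1) = ReLU( D^{-1/2} (A + I) D^{-1/2} h^(l) W^(l) )

with widths 78 → 512 → 128, so every atom ends up as a 128-d embedding
aligned with the protein node embeddings downstream.  Self-loops keep each
atom's own features in the update; a flag reproduces the bare-adjacency
variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from . import autodiff as ad

RDLogger.DisableLog("rdApp.*")

# Element vocabulary used by the GCN featurization lineage this follows;
# the final slot is the catch-all "other" bucket.
ELEMENTS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "other",
]
N_ATOM_FEATURES = len(ELEMENTS) + 11 + 11 + 11 + 1  # 78

GCN_WIDTHS = (N_ATOM_FEATURES, 512, 128)


class SmilesParseError(ValueError):
    """Raised when a SMILES string does not describe a valid molecule."""

    def __init__(self, smiles: str):
        super().__init__(f"could not parse SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass
class MolecularGraph:
    """Atom-feature matrix + binary adjacency for one molecule."""

    X: np.ndarray            # (V, 78) binary atom features
    A: np.ndarray            # (V, V) symmetric binary adjacency, zero diagonal
    smiles: str
    elements: list[str]      # per-atom element symbol

    @property
    def n_atoms(self) -> int:
        return self.X.shape[0]


@dataclass
class GCNParams:
    """Trainable weights of the two-layer graph convolution."""

    W0: ad.Tensor
    W1: ad.Tensor

    @classmethod
    def init(cls, rng: np.random.Generator, widths=GCN_WIDTHS, dtype=np.float64):
        c, h, d = widths
        return cls(
            W0=ad.Tensor(_glorot(rng, c, h).astype(dtype), requires_grad=True),
            W1=ad.Tensor(_glorot(rng, h, d).astype(dtype), requires_grad=True),
        )

    def tensors(self) -> list[ad.Tensor]:
        return [self.W0, self.W1]


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _one_hot(value: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[min(value, size - 1)] = 1.0
    return v


def atom_features(atom: Chem.Atom) -> np.ndarray:
    """78-d binary feature row for one RDKit atom.

    Out-of-range counts saturate into the last bucket, so the row always has
    the four one-hot blocks set plus an aromatic flag in {0, 1}.
    """
    symbol = atom.GetSymbol()
    elem = np.zeros(len(ELEMENTS))
    elem[ELEMENTS.index(symbol) if symbol in ELEMENTS else len(ELEMENTS) - 1] = 1.0
    return np.concatenate(
        [
            elem,
            _one_hot(atom.GetDegree(), 11),
            _one_hot(atom.GetTotalNumHs(), 11),
            _one_hot(atom.GetImplicitValence(), 11),
            [1.0 if atom.GetIsAromatic() else 0.0],
        ]
    )


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom molecular graph."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    n = mol.GetNumAtoms()
    X = np.stack([atom_features(a) for a in mol.GetAtoms()])
    A = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        A[i, j] = A[j, i] = 1.0
    return MolecularGraph(
        X=X, A=A, smiles=smiles, elements=[a.GetSymbol() for a in mol.GetAtoms()]
    )


def has_aromatic_ring(smiles: str) -> bool:
    """True when the molecule contains at least one aromatic atom."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return any(a.GetIsAromatic() for a in mol.GetAtoms())


def normalize_adjacency(A: np.ndarray, add_self_loops: bool = True) -> np.ndarray:
    """Symmetric degree normalization D^{-1/2} A D^{-1/2}.

    With ``add_self_loops`` the identity is added first (the standard
    renormalization trick).  Zero-degree rows stay zero rather than
    dividing by zero.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if add_self_loops:
        A = A + np.eye(A.shape[0])
    deg = A.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    return A * inv_sqrt[:, None] * inv_sqrt[None, :]


def gcn_forward(graph: MolecularGraph, params: GCNParams,
                add_self_loops: bool = True) -> np.ndarray:
    """Encode one molecule's atoms: (V, 78) → (V, 128), eval mode."""
    A_hat = normalize_adjacency(graph.A, add_self_loops=add_self_loops)
    out = gcn_forward_batched(
        ad.Tensor(graph.X[None, :, :]), A_hat[None, :, :], params
    )
    return out.data[0]


def gcn_forward_batched(X: ad.Tensor, A_hat: np.ndarray, params: GCNParams) -> ad.Tensor:
    """Differentiable batched GCN over padded graphs.

    ``X`` is (B, Vmax, 78) and ``A_hat`` (B, Vmax, Vmax) with zero rows at
    padding positions, so padded atoms stay exactly zero through both
    layers.
    """
    h1 = ad.relu(ad.matmul(ad.Tensor(A_hat), ad.matmul(X, params.W0)))
    h2 = ad.relu(ad.matmul(ad.Tensor(A_hat), ad.matmul(h1, params.W1)))
    return h2


def pad_graphs(graphs: list[MolecularGraph], add_self_loops: bool = True):
    """Stack variable-size graphs into padded (X, Â, atom-count) arrays."""
    vmax = max(g.n_atoms for g in graphs)
    B = len(graphs)
    X = np.zeros((B, vmax, N_ATOM_FEATURES))
    A_hat = np.zeros((B, vmax, vmax))
    counts = np.zeros(B, dtype=int)
    for i, g in enumerate(graphs):
        v = g.n_atoms
        X[i, :v] = g.X
        A_hat[i, :v, :v] = normalize_adjacency(g.A, add_self_loops=add_self_loops)
        counts[i] = v
    return X, A_hat, counts
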