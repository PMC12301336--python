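"""Offline synthetic data with the statistical structure the model assumes.

Real inputs are a drug-combination score table, SMILES per drug, a
landmark-gene expression matrix, and a PPI edge list.  This module
generates stand-ins for all four so every pipeline stage — and the
end-to-end learnability check — runs with no downloads:

* a curated in-package library of valid drug-like SMILES spanning aromatic
  and aliphatic scaffolds;
* a connected preferential-attachment (scale-free) PPI graph;
* Gaussian expression profiles where half the cell lines carry a +2 shift
  on a 10-gene signature;
* triplet labels planted by a stated rule — synergistic iff
  [both drugs contain an aromatic ring] XOR [the cell line carries the
  signature shift] — then flipped independently with probability ε.

The XOR construction means neither the drug-structure modality nor the
expression modality alone determines the label, so single-modality
ablations are information-limited by design while the fused model can in
principle reach the Bayes ceiling AUROC of 1 − ε.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .data import LabeledTriplet
from .molgraph import has_aromatic_ring, smiles_to_graph
from .ppi import PPINetwork

# Drug-like SMILES, all RDKit-valid, mixing aromatic scaffolds with
# purely aliphatic ones (the planted rule needs both kinds).
SMILES_LIBRARY: list[str] = [
    # aromatic
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "CC(=O)Nc1ccc(O)cc1",               # paracetamol
    "CCOC(=O)c1ccc(N)cc1",              # benzocaine
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",       # caffeine
    "CN1CCC[C@H]1c1cccnc1",             # nicotine
    "Oc1ccccc1C(=O)O",                  # salicylic acid
    "NC(=O)c1ccccc1",                   # benzamide
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",       # ibuprofen
    "COc1ccc2cc(C(C)C(=O)O)ccc2c1",     # naproxen core
    "Nc1ccc(S(N)(=O)=O)cc1",            # sulfanilamide
    "Brc1ccccc1",                       # bromobenzene
    "Cc1ccccc1N",                       # o-toluidine
    "Oc1ccc(Cl)cc1",                    # chlorophenol
    "COc1ccccc1OC",                     # veratrole
    "O=Cc1ccc(O)c(OC)c1",               # vanillin
    "c1ccc2[nH]ccc2c1",                 # indole
    "c1ccc2ncccc2c1",                   # quinoline
    "Cc1ccc(S(=O)(=O)N)cc1",            # tosylamide
    "Nc1ncnc2[nH]cnc12",                # adenine
    "O=c1cc[nH]c(=O)[nH]1",             # uracil
    "Fc1ccc(F)cc1",                     # difluorobenzene
    "Clc1ccc(Cl)cc1",                   # dichlorobenzene
    "Oc1ccc(/C=C/C(=O)O)cc1",           # coumaric acid
    "CCOc1ccc(NC(C)=O)cc1",             # phenacetin
    "Cc1cccc(C)c1O",                    # xylenol
    "Nc1ccccc1C(=O)O",                  # anthranilic acid
    "O=C(Nc1ccccc1)c1ccccc1",           # benzanilide
    "Cc1ncc([N+](=O)[O-])n1C",          # metronidazole-like
    "CC(N)Cc1ccccc1",                   # amphetamine
    "OCC(O)c1ccccc1",                   # phenylglycol
    "CN(C)c1ccc(C=O)cc1",               # DMAB aldehyde
    "COc1ccc(CCN)cc1",                  # methoxyphenethylamine
    "O=C(O)Cc1ccccc1",                  # phenylacetic acid
    "N#Cc1ccccc1",                      # benzonitrile
    "CC(=O)c1ccccc1",                   # acetophenone
    "c1ccsc1",                          # thiophene
    "c1ccoc1",                          # furan
    "c1cc[nH]c1",                       # pyrrole
    # aliphatic
    "CCO",                              # ethanol
    "CC(C)O",                           # isopropanol
    "C1CCCCC1",                         # cyclohexane
    "OCC(O)CO",                         # glycerol
    "CC(=O)O",                          # acetic acid
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",       # citric acid
    "CCCC(CCC)C(=O)O",                  # valproic acid
    "CN(C)C(=N)NC(=N)N",                # metformin
    "NCC1(CC(=O)O)CCCCC1",              # gabapentin
    "NC12CC3CC(CC(C3)C1)C2",            # amantadine
    "CC(C)C1CCC(C)CC1O",                # menthol
    "CC1(C)C2CCC1(C)C(=O)C2",           # camphor
    "NCCCC(N)C(=O)O",                   # ornithine
    "CC(N)C(=O)O",                      # alanine
    "OC(C(=O)O)C(O)C(=O)O",             # tartaric acid
    "CCCCCCCC(=O)O",                    # octanoic acid
    "OCCO",                             # ethylene glycol
    "C1CCOC1",                          # THF
    "C1CCNCC1",                         # piperidine
    "C1CCNC1",                          # pyrrolidine
    "CC(C)(C)O",                        # tert-butanol
    "O=C1CCCCC1",                       # cyclohexanone
    "NC(=O)C1CCCNC1",                   # nipecotamide
]


@dataclass
class FixtureConfig:
    """Scale and noise of the synthetic study conditions."""

    n_drugs: int = 20
    n_cell_lines: int = 12
    n_genes: int = 60
    n_triplets: int = 2000
    noise: float = 0.1          # label-flip probability ε
    seed: int = 0
    n_signature_genes: int = 10
    signature_shift: float = 2.0

    def __post_init__(self):
        if not (0.0 <= self.noise < 0.5):
            raise ValueError("noise must lie in [0, 0.5)")
        for name in ("n_drugs", "n_cell_lines", "n_genes", "n_triplets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ExpressionFixture:
    """Synthetic expression matrix plus the planted signature bookkeeping."""

    matrix: pd.DataFrame                # cell_line × gene
    signature_genes: list[str]
    signature_cells: list[str]


@dataclass
class PlantedRule:
    """Ground truth behind a synthetic triplet set."""

    noiseless_labels: list[int]
    aromatic_pair: list[bool]
    signature_cell: list[bool]
    noise: float

    def bayes_auroc(self) -> float:
        """Ranking ceiling of any predictor: 1 − ε under symmetric flips."""
        return 1.0 - self.noise


def make_smiles_library(n_drugs: int, seed: int = 0) -> list[tuple[str, str]]:
    """Draw ``n_drugs`` (drug id, SMILES) entries from the curated library."""
    if n_drugs > len(SMILES_LIBRARY):
        raise ValueError(
            f"library holds {len(SMILES_LIBRARY)} molecules, requested {n_drugs}"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(SMILES_LIBRARY), size=n_drugs, replace=False)
    return [(f"D{i + 1:03d}", SMILES_LIBRARY[p]) for i, p in enumerate(sorted(picks))]


def make_synthetic_ppi(n_genes: int, attachment: int = 2, seed: int = 0) -> PPINetwork:
    """Connected preferential-attachment graph over G0001…G{n} gene symbols."""
    if n_genes < 3:
        raise ValueError("need at least 3 genes")
    g = nx.barabasi_albert_graph(n_genes, attachment, seed=seed)
    g = nx.relabel_nodes(g, {i: f"G{i + 1:04d}" for i in g.nodes})
    return PPINetwork(g)


def gene_symbols(n_genes: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n_genes)]


def make_synthetic_expression(cell_lines: list[str], n_genes: int,
                              seed: int = 0, n_signature_genes: int = 10,
                              shift: float = 2.0) -> ExpressionFixture:
    """Standard-normal profiles; half the cell lines get a shifted signature.

    The first half of ``cell_lines`` (rounded down) carries a ``+shift``
    mean on a random signature gene set — the cell-line signal the planted
    label rule reads.
    """
    rng = np.random.default_rng(seed)
    genes = gene_symbols(n_genes)
    X = rng.standard_normal((len(cell_lines), n_genes))
    sig_gene_idx = sorted(rng.choice(n_genes, size=min(n_signature_genes, n_genes),
                                     replace=False))
    sig_cells = cell_lines[: len(cell_lines) // 2]
    for i, cl in enumerate(cell_lines):
        if cl in sig_cells:
            X[i, sig_gene_idx] += shift
    return ExpressionFixture(
        matrix=pd.DataFrame(X, index=list(cell_lines), columns=genes),
        signature_genes=[genes[i] for i in sig_gene_idx],
        signature_cells=list(sig_cells),
    )


def make_labeled_triplets(library: list[tuple[str, str]],
                          expression: ExpressionFixture,
                          config: FixtureConfig):
    """Sample unique (pair, cell line) triplets labeled by the planted rule.

    label = [both drugs aromatic] XOR [signature cell line], then flipped
    independently with probability ``config.noise``.  Keys are sampled
    without replacement, so duplicate averaging never mixes labels.  With
    half the cell lines carrying the signature the noiseless labels are
    balanced by construction.
    """
    rng = np.random.default_rng(config.seed + 7)
    aromatic = {drug: has_aromatic_ring(smi) for drug, smi in library}
    smiles = dict(library)
    cells = list(expression.matrix.index)
    sig = set(expression.signature_cells)
    keys = [
        (a, b, c)
        for i, (a, _) in enumerate(library)
        for b, _ in library[i + 1:]
        for c in cells
    ]
    if config.n_triplets > len(keys):
        raise ValueError(
            f"requested {config.n_triplets} triplets but only {len(keys)} "
            "unique (pair, cell line) keys exist"
        )
    picked = rng.permutation(len(keys))[: config.n_triplets]
    triplets, clean, arom_flags, sig_flags = [], [], [], []
    flips = rng.random(config.n_triplets) < config.noise
    for j, k in enumerate(picked):
        a, b, c = keys[k]
        both_aromatic = aromatic[a] and aromatic[b]
        in_sig = c in sig
        rule = int(both_aromatic != in_sig)
        label = int(rule != flips[j])
        triplets.append(
            LabeledTriplet(drug_a=a, drug_b=b, smiles_a=smiles[a],
                           smiles_b=smiles[b], cell_line=c, label=label)
        )
        clean.append(rule)
        arom_flags.append(both_aromatic)
        sig_flags.append(in_sig)
    rule_record = PlantedRule(noiseless_labels=clean, aromatic_pair=arom_flags,
                              signature_cell=sig_flags, noise=config.noise)
    return triplets, rule_record


@dataclass
class SyntheticStudy:
    """A complete synthetic study: drugs, network, expression, triplets."""

    library: list[tuple[str, str]]
    network: PPINetwork
    expression: ExpressionFixture
    triplets: list[LabeledTriplet]
    rule: PlantedRule
    config: FixtureConfig


def make_study(config: FixtureConfig | None = None) -> SyntheticStudy:
    """Generate the full synthetic study at the configured conditions."""
    config = config or FixtureConfig()
    library = make_smiles_library(config.n_drugs, seed=config.seed)
    network = make_synthetic_ppi(config.n_genes, seed=config.seed)
    cells = [f"CL{i + 1:02d}" for i in range(config.n_cell_lines)]
    expression = make_synthetic_expression(
        cells, config.n_genes, seed=config.seed,
        n_signature_genes=config.n_signature_genes, shift=config.signature_shift,
    )
    triplets, rule = make_labeled_triplets(library, expression, config)
    return SyntheticStudy(library=library, network=network, expression=expression,
                          triplets=triplets, rule=rule, config=config)


def write_fixture_files(study: SyntheticStudy, out_dir) -> dict[str, Path]:
    """Emit the study in exactly the text formats the real pipeline reads.

    Synthetic Loewe scores are drawn consistent with each label (above 10
    for synergistic, below 0 for antagonistic) so the combination table
    exercises the full threshold-labeling path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(study.config.seed + 13)
    rows = []
    for t in study.triplets:
        score = (12.0 + 8.0 * rng.random()) if t.label == 1 else (-2.0 - 8.0 * rng.random())
        rows.append((t.drug_a, t.drug_b, t.smiles_a, t.smiles_b, t.cell_line, score))
    comb = out_dir / "combinations.csv"
    pd.DataFrame(rows, columns=["drug_a", "drug_b", "smiles_a", "smiles_b",
                                "cell_line", "score"]).to_csv(comb, index=False)
    expr = out_dir / "expression.tsv"
    study.expression.matrix.to_csv(expr, sep="\t", index_label="cell_line")
    ppi = out_dir / "ppi_edges.tsv"
    with open(ppi, "w") as fh:
        for u, v in study.network.graph.edges:
            fh.write(f"{u}\t{v}\n")
    tissues = ["lung", "skin", "intestine", "ovary", "breast", "prostate"]
    tissue = out_dir / "tissues.tsv"
    with open(tissue, "w") as fh:
        for i, cl in enumerate(study.expression.matrix.index):
            fh.write(f"{cl}\t{tissues[i % len(tissues)]}\n")
    return {"combinations": comb, "expression": expr, "ppi": ppi, "tissues": tissue}
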