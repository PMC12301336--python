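"""Synergy-record parsing, deduplication, labeling, and cross-validation splits.

A screening record is a drug pair tested on a cancer cell line with a Loewe
synergy score: positive scores mean the combination beat the additive
expectation of the two single agents.  This module turns raw score tables
into binary-labeled triplets (synergistic vs antagonistic) and builds the
split plans used for evaluation — shuffled k-fold plus the four
leave-group-out schemes (drug combination, drug, cell line, tissue) that
probe generalization to unseen biology.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("drug_a", "drug_b", "smiles_a", "smiles_b", "cell_line", "score")

#: Loewe-score cutoffs: strictly above POS_THRESHOLD is synergistic, strictly
#: below NEG_THRESHOLD is antagonistic, anything between is dropped as
#: ambiguous.
POS_THRESHOLD = 10.0
NEG_THRESHOLD = 0.0


@dataclass(frozen=True)
class SynergyRecord:
    """One drug pair–cell line measurement with its Loewe synergy score."""

    drug_a: str
    drug_b: str
    smiles_a: str
    smiles_b: str
    cell_line: str
    score: float

    def pair_key(self) -> tuple[str, str]:
        """Unordered drug-pair identity."""
        return tuple(sorted((self.drug_a, self.drug_b)))

    def key(self) -> tuple[tuple[str, str], str]:
        return (self.pair_key(), self.cell_line)


@dataclass(frozen=True)
class LabeledTriplet:
    """A (drug pair, cell line) example with a binary synergy label."""

    drug_a: str
    drug_b: str
    smiles_a: str
    smiles_b: str
    cell_line: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    def pair_key(self) -> tuple[str, str]:
        return tuple(sorted((self.drug_a, self.drug_b)))


@dataclass
class SplitPlan:
    """A named list of (train, test) index-set folds over a triplet list."""

    scheme: str
    folds: list[tuple[np.ndarray, np.ndarray]]

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)

    def to_json(self, path) -> None:
        payload = {
            "scheme": self.scheme,
            "folds": [
                {"train": np.asarray(tr).tolist(), "test": np.asarray(te).tolist()}
                for tr, te in self.folds
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path) as fh:
            payload = json.load(fh)
        folds = [
            (np.asarray(f["train"], dtype=int), np.asarray(f["test"], dtype=int))
            for f in payload["folds"]
        ]
        return cls(scheme=payload["scheme"], folds=folds)


def load_combination_table(path) -> list[SynergyRecord]:
    """Read a combination table (CSV or TSV, header-keyed) into records.

    Rows whose score does not parse as a finite number are skipped and the
    skip count logged.  Column order is irrelevant; the header names are
    authoritative.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"combination table {path} missing columns: {missing}")
    if df.empty:
        logger.warning("combination table %s is empty", path)
        return []
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = ~np.isfinite(scores)
    if bad.any():
        logger.warning("skipped %d rows with unparseable scores", int(bad.sum()))
    df = df.loc[~bad]
    scores = scores.loc[~bad]
    return [
        SynergyRecord(
            drug_a=str(r.drug_a),
            drug_b=str(r.drug_b),
            smiles_a=str(r.smiles_a),
            smiles_b=str(r.smiles_b),
            cell_line=str(r.cell_line),
            score=float(s),
        )
        for r, s in zip(df.itertuples(index=False), scores)
    ]


def average_duplicates(records: list[SynergyRecord]) -> list[SynergyRecord]:
    """Collapse repeated (unordered drug pair, cell line) measurements.

    The replicates' scores are averaged into a single record; the first
    occurrence fixes the drug order and SMILES of the survivor.  Output
    preserves first-occurrence order.
    """
    groups: dict = {}
    order: list = []
    for rec in records:
        k = rec.key()
        if k not in groups:
            groups[k] = [rec, [rec.score]]
            order.append(k)
        else:
            groups[k][1].append(rec.score)
    out = []
    for k in order:
        first, scores = groups[k]
        out.append(
            SynergyRecord(
                drug_a=first.drug_a,
                drug_b=first.drug_b,
                smiles_a=first.smiles_a,
                smiles_b=first.smiles_b,
                cell_line=first.cell_line,
                score=float(np.mean(scores)),
            )
        )
    return out


def label_by_threshold(
    records: list[SynergyRecord],
    pos_thr: float = POS_THRESHOLD,
    neg_thr: float = NEG_THRESHOLD,
) -> list[LabeledTriplet]:
    """Binarize scores: > ``pos_thr`` → 1, < ``neg_thr`` → 0, rest dropped.

    Both inequalities are strict, so boundary scores (exactly 10 or 0 at the
    defaults) fall in the dropped middle band.  The drop count is logged.
    """
    if neg_thr > pos_thr:
        raise ValueError("neg_thr must be <= pos_thr")
    out = []
    dropped = 0
    for rec in records:
        if rec.score > pos_thr:
            label = 1
        elif rec.score < neg_thr:
            label = 0
        else:
            dropped += 1
            continue
        out.append(
            LabeledTriplet(
                drug_a=rec.drug_a,
                drug_b=rec.drug_b,
                smiles_a=rec.smiles_a,
                smiles_b=rec.smiles_b,
                cell_line=rec.cell_line,
                label=label,
            )
        )
    if dropped:
        logger.info(
            "dropped %d records in the ambiguous band [%g, %g]", dropped, neg_thr, pos_thr
        )
    return out


def preprocess(records: list[SynergyRecord]) -> list[LabeledTriplet]:
    """Full pipeline: average duplicates first, then threshold-label."""
    return label_by_threshold(average_duplicates(records))


# ---------------------------------------------------------------------------
# Split plans
# ---------------------------------------------------------------------------


def make_random_kfold(triplets, k: int = 5, seed: int = 0) -> SplitPlan:
    """Shuffled k-fold partition of the triplet indices."""
    n = len(triplets)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of triplets ({n})")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [(tr.copy(), te.copy()) for tr, te in kf.split(np.arange(n))]
    return SplitPlan(scheme="random_kfold", folds=folds)


def _group_key(triplet: LabeledTriplet, group_by: str, tissue_map: dict | None):
    if group_by == "combination":
        return triplet.pair_key()
    if group_by == "drug":
        # a triplet belongs to the groups of BOTH its drugs; handled by caller
        raise RuntimeError("drug grouping handled by membership test")
    if group_by == "cell_line":
        return triplet.cell_line
    if group_by == "tissue":
        try:
            return tissue_map[triplet.cell_line]
        except (TypeError, KeyError):
            raise ValueError(
                f"tissue_map does not cover cell line {triplet.cell_line!r}"
            ) from None
    raise ValueError(f"unknown group_by {group_by!r}")


def _matches(triplet: LabeledTriplet, group, group_by: str, tissue_map) -> bool:
    if group_by == "drug":
        return group in (triplet.drug_a, triplet.drug_b)
    return _group_key(triplet, group_by, tissue_map) == group


def make_leave_group_out(
    triplets,
    group_by: str,
    groups,
    tissue_map: dict | None = None,
) -> SplitPlan:
    """Build a leave-group-out plan: one fold per entry of ``groups``.

    Each entry of ``groups`` may be a single group key or a list of keys
    held out together (the leave-combination scheme holds out subsets of
    three pairs per fold).  Test folds contain exactly the triplets matching
    a held-out group; those triplets never appear in that fold's training
    set.  For the drug scheme a triplet matches if either of its drugs is
    the held-out drug.
    """
    if not groups:
        raise ValueError("groups must be non-empty")
    folds = []
    for entry in groups:
        # a list entry holds out several groups together in one fold; a str
        # or tuple entry (combination keys are 2-tuples) is a single group
        fold_groups = list(entry) if isinstance(entry, list) else [entry]
        test_idx, train_idx = [], []
        per_group_counts: Counter = Counter()
        for i, t in enumerate(triplets):
            hit = False
            for g in fold_groups:
                if _matches(t, tuple(sorted(g)) if group_by == "combination" else g,
                            group_by, tissue_map):
                    per_group_counts[g] += 1
                    hit = True
            (test_idx if hit else train_idx).append(i)
        for g in fold_groups:
            if per_group_counts[g] == 0:
                raise ValueError(f"group {g!r} matches no triplets")
        folds.append((np.asarray(train_idx, dtype=int), np.asarray(test_idx, dtype=int)))
    return SplitPlan(scheme=f"leave_{group_by}", folds=folds)


def rank_groups_by_frequency(triplets, group_by: str, tissue_map: dict | None = None):
    """Groups sorted by descending triplet count, ties broken lexicographically."""
    counts: Counter = Counter()
    for t in triplets:
        if group_by == "drug":
            counts[t.drug_a] += 1
            counts[t.drug_b] += 1
        else:
            counts[_group_key(t, group_by, tissue_map)] += 1
    return sorted(counts, key=lambda g: (-counts[g], str(g)))


def top_group_folds(triplets, group_by: str, n_groups: int = 5,
                    groups_per_fold: int = 1, tissue_map: dict | None = None):
    """Convenience: rank groups, keep the top ``n_groups``, chunk into folds.

    The leave-combination protocol takes the 15 most frequent pairs in five
    subsets of three; the drug / cell-line / tissue protocols take the top
    five, one per fold.
    """
    ranked = rank_groups_by_frequency(triplets, group_by, tissue_map)[:n_groups]
    if groups_per_fold == 1:
        return list(ranked)
    return [
        list(ranked[i : i + groups_per_fold])
        for i in range(0, len(ranked), groups_per_fold)
    ]


def load_expression_matrix(path, expected_genes: int | None = None) -> pd.DataFrame:
    """Read a cell-line × gene expression TSV (first column ``cell_line``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise ValueError("expression matrix has duplicate gene columns")
    if expected_genes is not None and df.shape[1] != expected_genes:
        raise ValueError(
            f"expected {expected_genes} gene columns, found {df.shape[1]}"
        )
    return df


def load_tissue_map(path) -> dict[str, str]:
    """Read a two-column (cell_line, tissue) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_line", "tissue"])
    return dict(zip(df.cell_line.astype(str), df.tissue.astype(str)))
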