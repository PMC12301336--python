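"""Parsing, deduplication, threshold labeling, and split plans."""

import numpy as np
import pytest

from synfuse.data import (LabeledTriplet, SplitPlan, SynergyRecord,
                          average_duplicates, label_by_threshold,
                          load_combination_table, make_leave_group_out,
                          make_random_kfold, rank_groups_by_frequency,
                          top_group_folds)


def rec(a="A", b="B", cl="CL1", score=5.0):
    return SynergyRecord(drug_a=a, drug_b=b, smiles_a="CC", smiles_b="CCO",
                         cell_line=cl, score=score)


def trip(a="A", b="B", cl="CL1", label=1):
    return LabeledTriplet(drug_a=a, drug_b=b, smiles_a="CC", smiles_b="CCO",
                          cell_line=cl, label=label)


class TestLoadCombinationTable:
    HEADER = "drug_a,drug_b,smiles_a,smiles_b,cell_line,score\n"

    def test_well_formed_rows(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(self.HEADER + "A,B,CC,CCO,CL1,5\nA,C,CC,CCC,CL2,-3\nB,C,CCO,CCC,CL1,12\n")
        records = load_combination_table(p)
        assert len(records) == 3
        assert records[0].score == 5.0

    def test_unparseable_score_skipped(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(self.HEADER + "A,B,CC,CCO,CL1,NA\nA,C,CC,CCC,CL2,2\n")
        records = load_combination_table(p)
        assert len(records) == 1

    def test_header_keyed_not_positional(self, tmp_path):
        p1 = tmp_path / "a.csv"
        p1.write_text(self.HEADER + "A,B,CC,CCO,CL1,5\n")
        p2 = tmp_path / "b.csv"
        p2.write_text("score,cell_line,drug_b,drug_a,smiles_b,smiles_a\n"
                      "5,CL1,B,A,CCO,CC\n")
        assert load_combination_table(p1) == load_combination_table(p2)

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("drug_a,drug_b,score\nA,B,5\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_combination_table(p)

    def test_tab_separated_accepted(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(self.HEADER.replace(",", "\t") + "A\tB\tCC\tCCO\tCL1\t5\n")
        assert len(load_combination_table(p)) == 1


class TestAverageDuplicates:
    def test_unordered_pair_key_mean(self):
        out = average_duplicates([rec("A", "B", score=8), rec("B", "A", score=12)])
        assert len(out) == 1
        assert out[0].score == 10.0

    def test_identity_without_duplicates(self):
        records = [rec("A", "B"), rec("A", "C"), rec("A", "B", cl="CL2")]
        assert average_duplicates(records) == records

    def test_mean_of_three(self):
        out = average_duplicates([rec(score=0), rec(score=3), rec(score=6)])
        assert out[0].score == pytest.approx(3.0)

    def test_no_repeated_keys_in_output(self):
        rng = np.random.default_rng(0)
        records = [rec(a=f"D{rng.integers(3)}", b=f"D{rng.integers(3)}",
                       cl=f"C{rng.integers(2)}", score=float(i))
                   for i in range(50)]
        out = average_duplicates(records)
        keys = [r.key() for r in out]
        assert len(keys) == len(set(keys))


class TestLabelByThreshold:
    def test_strict_inequalities(self):
        records = [rec(a="A", b=f"B{i}", score=s)
                   for i, s in enumerate([12.3, -5.0, 4.2, 10.0, 0.0])]
        out = label_by_threshold(records)
        assert [t.label for t in out] == [1, 0]
        assert len(out) == 2  # the three boundary/ambiguous scores drop

    def test_all_positive(self):
        out = label_by_threshold([rec(score=s) for s in (11, 20, 300)])
        assert [t.label for t in out] == [1, 1, 1]

    def test_duplicates_averaging_to_boundary_dropped(self):
        averaged = average_duplicates([rec(score=8), rec(score=12)])
        assert label_by_threshold(averaged) == []

    def test_partitions_input(self):
        rng = np.random.default_rng(1)
        records = [rec(a="A", b=f"B{i}", score=float(s))
                   for i, s in enumerate(rng.uniform(-20, 30, size=200))]
        out = label_by_threshold(records)
        n_pos = sum(1 for r in records if r.score > 10)
        n_neg = sum(1 for r in records if r.score < 0)
        n_mid = sum(1 for r in records if 0 <= r.score <= 10)
        assert len(out) == n_pos + n_neg
        assert n_pos + n_neg + n_mid == len(records)
        # idempotence: relabeling already-labeled scores changes nothing
        assert label_by_threshold(records) == out

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            label_by_threshold([rec()], pos_thr=0, neg_thr=10)


class TestRandomKFold:
    def test_balanced_partition(self):
        triplets = [trip(b=f"B{i}") for i in range(10)]
        plan = make_random_kfold(triplets, k=5, seed=0)
        assert len(plan) == 5
        assert all(len(te) == 2 for _, te in plan)
        covered = np.sort(np.concatenate([te for _, te in plan]))
        assert np.array_equal(covered, np.arange(10))

    def test_deterministic_per_seed(self):
        triplets = [trip(b=f"B{i}") for i in range(23)]
        p1 = make_random_kfold(triplets, k=5, seed=3)
        p2 = make_random_kfold(triplets, k=5, seed=3)
        for (tr1, te1), (tr2, te2) in zip(p1, p2):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)

    def test_disjoint_train_test(self):
        triplets = [trip(b=f"B{i}") for i in range(17)]
        for tr, te in make_random_kfold(triplets, k=4, seed=1):
            assert np.intersect1d(tr, te).size == 0

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            make_random_kfold([trip()], k=5, seed=0)


class TestLeaveGroupOut:
    def build(self):
        triplets = []
        for a, b in [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D")]:
            for cl in ("CL1", "CL2", "CL3"):
                triplets.append(trip(a=a, b=b, cl=cl))
        return triplets

    def test_leave_drug_exclusion(self):
        triplets = self.build()
        plan = make_leave_group_out(triplets, "drug", ["A"])
        tr, te = plan.folds[0]
        assert all("A" in (triplets[i].drug_a, triplets[i].drug_b) for i in te)
        assert all("A" not in (triplets[i].drug_a, triplets[i].drug_b) for i in tr)

    def test_combination_subsets_give_one_fold_each(self):
        rng = np.random.default_rng(0)
        triplets = [trip(a=f"D{i}", b=f"D{i + 1}", cl=f"CL{j}")
                    for i in range(15) for j in range(3)]
        pairs = sorted({t.pair_key() for t in triplets})
        subsets = [pairs[i:i + 3] for i in range(0, 15, 3)]
        plan = make_leave_group_out(triplets, "combination", subsets)
        assert len(plan) == 5
        for tr, te in plan:
            held = {triplets[i].pair_key() for i in te}
            assert not held & {triplets[i].pair_key() for i in tr}

    def test_leave_tissue_exclusion(self):
        triplets = self.build()
        tissue_map = {"CL1": "lung", "CL2": "skin", "CL3": "lung"}
        plan = make_leave_group_out(triplets, "tissue", ["lung"], tissue_map)
        tr, te = plan.folds[0]
        assert {triplets[i].cell_line for i in te} == {"CL1", "CL3"}
        assert {triplets[i].cell_line for i in tr} == {"CL2"}

    def test_empty_group_named_in_error(self):
        with pytest.raises(ValueError, match="ZZZ"):
            make_leave_group_out(self.build(), "drug", ["ZZZ"])

    def test_empty_group_list_rejected(self):
        with pytest.raises(ValueError):
            make_leave_group_out(self.build(), "drug", [])


class TestRankGroups:
    def test_count_then_lexicographic(self):
        triplets = ([trip(cl="A")] * 5 + [trip(cl="B")] * 3 + [trip(cl="C")] * 5)
        assert rank_groups_by_frequency(triplets, "cell_line") == ["A", "C", "B"]

    def test_single_group(self):
        assert rank_groups_by_frequency([trip(cl="X")], "cell_line") == ["X"]

    def test_empty_input(self):
        assert rank_groups_by_frequency([], "cell_line") == []

    def test_top_group_folds_chunking(self):
        triplets = [trip(a=f"D{i}", b=f"D{i + 1}") for i in range(20) for _ in range(2)]
        folds = top_group_folds(triplets, "combination", n_groups=15, groups_per_fold=3)
        assert len(folds) == 5
        assert all(len(f) == 3 for f in folds)


def test_split_plan_json_round_trip(tmp_path):
    triplets = [trip(b=f"B{i}") for i in range(12)]
    plan = make_random_kfold(triplets, k=3, seed=2)
    path = tmp_path / "plan.json"
    plan.to_json(path)
    loaded = SplitPlan.from_json(path)
    assert loaded.scheme == plan.scheme
    for (tr1, te1), (tr2, te2) in zip(plan, loaded):
        assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)
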