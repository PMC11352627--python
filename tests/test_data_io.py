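"""File dialects, validation, and split utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synergynet.data_io import (DataError, SynergyExample, kfold, read_omics,
                                read_synergy_table, split_leave_drug_out,
                                split_train_test, write_synergy_table)


def _examples(n):
    return [SynergyExample(f"d{i}", f"d{i+1}", f"c{i % 4}", float(i))
            for i in range(n)]


class TestSynergyTable:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "syn.csv"
        examples = _examples(5)
        write_synergy_table(examples, path)
        assert read_synergy_table(path) == examples

    def test_three_row_toy(self, tmp_path):
        path = tmp_path / "toy.csv"
        path.write_text("drug_a,drug_b,cell_line,synergy\n"
                        "a,b,c1,1.5\na,b,c2,-3.0\nb,c,c1,0.0\n")
        out = read_synergy_table(path)
        assert len(out) == 3 and out[0].score == 1.5

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("drug_a,drug_b,score\na,b,1\n")
        with pytest.raises(DataError, match="missing column"):
            read_synergy_table(path)

    def test_non_numeric_score_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("drug_a,drug_b,cell_line,synergy\na,b,c,oops\n")
        with pytest.raises(DataError, match="line 2"):
            read_synergy_table(path)

    def test_duplicate_combination_rejected_either_order(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("drug_a,drug_b,cell_line,synergy\n"
                        "a,b,c,1.0\nb,a,c,2.0\n")
        with pytest.raises(DataError, match="duplicate"):
            read_synergy_table(path)


class TestOmics:
    def _write(self, tmp_path, mut_value=1):
        expr = pd.DataFrame(np.arange(6.0).reshape(2, 3),
                            index=["c1", "c2"], columns=list("abc"))
        mut = pd.DataFrame([[0, mut_value], [1, 0]],
                           index=["c1", "c2"], columns=["g1", "g2"])
        expr.index.name = mut.index.name = "cell_id"
        expr.to_csv(tmp_path / "expr.tsv", sep="\t")
        mut.to_csv(tmp_path / "mut.tsv", sep="\t")
        return tmp_path / "expr.tsv", tmp_path / "mut.tsv"

    def test_two_cell_toy_zscored(self, tmp_path):
        ep, mp = self._write(tmp_path)
        cells = read_omics(ep, mp)
        assert set(cells) == {"c1", "c2"}
        stacked = np.vstack([cells["c1"].expr, cells["c2"].expr])
        np.testing.assert_allclose(stacked.mean(axis=0), 0.0, atol=1e-12)

    def test_non_binary_mutation_rejected(self, tmp_path):
        ep, mp = self._write(tmp_path, mut_value=2)
        with pytest.raises(DataError, match="non-binary"):
            read_omics(ep, mp)

    def test_mismatched_cells_warn_and_exclude(self, tmp_path):
        ep, mp = self._write(tmp_path)
        mut = pd.read_csv(mp, sep="\t", index_col=0)
        mut.loc["c3"] = [0, 1]
        mut.to_csv(mp, sep="\t")
        with pytest.warns(UserWarning, match="c3"):
            cells = read_omics(ep, mp)
        assert "c3" not in cells


class TestSplits:
    def test_nine_to_one(self):
        train, test = split_train_test(_examples(1000), 0.9, seed=0)
        assert len(train) == 900 and len(test) == 100

    def test_seed_reproducibility_and_partition(self):
        examples = _examples(57)
        a = split_train_test(examples, 0.8, seed=4)
        b = split_train_test(examples, 0.8, seed=4)
        assert a == b
        train, test = a
        assert sorted(train + test, key=str) == sorted(examples, key=str)
        assert not set(map(str, train)) & set(map(str, test))

    def test_independent_of_input_order(self):
        examples = _examples(40)
        a = split_train_test(examples, 0.75, seed=9)
        b = split_train_test(list(reversed(examples)), 0.75, seed=9)
        assert a == b

    def test_group_split_keeps_pairs_together(self):
        examples = [SynergyExample("a", "b", f"c{i}", float(i))
                    for i in range(6)]
        examples += [SynergyExample("c", "d", f"c{i}", float(i))
                     for i in range(6)]
        train, test = split_train_test(examples, 0.5, seed=1,
                                       split_by="drug-pair")
        train_pairs = {(e.drug_a, e.drug_b) for e in train}
        test_pairs = {(e.drug_a, e.drug_b) for e in test}
        assert not train_pairs & test_pairs

    def test_leave_drug_out_isolates_training_drugs(self):
        examples = [SynergyExample(f"d{i}", f"d{j}", f"c{k}", 0.0)
                    for i in range(8) for j in range(i + 1, 8)
                    for k in range(3)]
        train, test = split_leave_drug_out(examples, 0.7, seed=2)
        train_drugs = {d for e in train for d in (e.drug_a, e.drug_b)}
        for e in test:
            assert e.drug_a not in train_drugs or e.drug_b not in train_drugs
        assert sorted(map(str, train + test)) == sorted(map(str, examples))
        # reproducible per seed
        assert (train, test) == split_leave_drug_out(examples, 0.7, seed=2)

    @given(n=st.integers(10, 80), k=st.integers(2, 7), seed=st.integers(0, 99))
    @settings(max_examples=25, deadline=None)
    def test_kfold_coverage_and_exclusivity(self, n, k, seed):
        examples = _examples(n)
        folds = kfold(examples, k, seed=seed)
        assert len(folds) == k
        all_val = [str(e) for _, val in folds for e in val]
        assert sorted(all_val) == sorted(str(e) for e in examples)
        sizes = [len(val) for _, val in folds]
        assert max(sizes) - min(sizes) <= 1
        for train, val in folds:
            assert len(train) + len(val) == n
            assert not set(map(str, train)) & set(map(str, val))

    def test_kfold_seed_reproducibility(self):
        a = kfold(_examples(10), 5, seed=3)
        b = kfold(_examples(10), 5, seed=3)
        assert a == b
        assert all(len(val) == 2 for _, val in a)

    def test_errors(self):
        with pytest.raises(ValueError):
            split_train_test([], 0.9, seed=0)
        with pytest.raises(ValueError):
            kfold(_examples(3), 5, seed=0)
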