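"""Dataset I/O, filtering, statistics, fold splitting and the fixture
generator."""

import numpy as np
import pytest

from mlpathway.dataset_io import (DatasetFormatError, DatasetValidationError,
                                  FRAGMENT_CLASSES, LabeledCompoundTable,
                                  default_cooccurrence_spec,
                                  filter_valid_structures, generate_fixture,
                                  label_statistics, make_cv_split,
                                  read_dataset, write_dataset,
                                  write_demo_wordvec_file)
from mlpathway.pathway_graph import load_word_vectors


def make_table(smiles, Y, names=("p0", "p1")):
    return LabeledCompoundTable(
        ids=[f"c{i}" for i in range(len(smiles))], smiles=list(smiles),
        Y=np.asarray(Y), pathway_names=list(names))


class TestReadWrite:
    def test_round_trip(self, tmp_path):
        table = make_table(["C", "CCO", "c1ccccc1"],
                           [[1, 0], [0, 1], [1, 1]])
        path = tmp_path / "data.csv"
        write_dataset(table, path)
        back = read_dataset(path)
        assert back.ids == table.ids
        assert back.smiles == table.smiles
        np.testing.assert_array_equal(back.Y, table.Y)
        assert back.pathway_names == table.pathway_names
        # second round trip is identical
        path2 = tmp_path / "again.csv"
        write_dataset(back, path2)
        assert path.read_text() == path2.read_text()

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,p0,p1\nc0,1,0\n")
        with pytest.raises(DatasetFormatError, match="smiles"):
            read_dataset(path)

    def test_non_binary_label_cites_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,smiles,p0,p1\nc0,C,1,0\nc1,CC,2,1\n")
        with pytest.raises(DatasetValidationError, match="row 1"):
            read_dataset(path)

    def test_explicit_label_columns(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("id,smiles,extra,p0,p1\nc0,C,x,1,0\nc1,CC,y,0,1\n")
        table = read_dataset(path, label_columns=["p0", "p1"])
        assert table.pathway_names == ["p0", "p1"]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(DatasetValidationError, match="unique"):
            LabeledCompoundTable(ids=["a", "a"], smiles=["C", "CC"],
                                 Y=np.array([[1, 0], [0, 1]]),
                                 pathway_names=["p0", "p1"])

    def test_record_without_labels_rejected(self):
        with pytest.raises(DatasetValidationError, match="positive"):
            make_table(["C", "CC"], [[1, 0], [0, 0]])


class TestFilter:
    def test_removes_only_malformed(self):
        table = make_table(["C", "not_a_smiles", "CCO"],
                           [[1, 0], [0, 1], [1, 1]])
        kept, removed = filter_valid_structures(table)
        assert len(kept) == 2
        assert removed == ["c1"]
        assert kept.smiles == ["C", "CCO"]

    def test_identity_on_valid_table_and_idempotent(self):
        table = make_table(["C", "CCO"], [[1, 0], [0, 1]])
        kept, removed = filter_valid_structures(table)
        assert removed == [] and kept.smiles == table.smiles
        again, removed2 = filter_valid_structures(kept)
        assert removed2 == [] and again.smiles == kept.smiles


class TestLabelStatistics:
    def test_hand_counts(self):
        stats = label_statistics(make_table(["C", "CC"], [[1, 0], [1, 1]]))
        np.testing.assert_array_equal(stats.per_label, [2, 1])
        assert stats.n_single == 1
        assert stats.n_multi == 1
        assert stats.total_entries == 3

    def test_single_record(self):
        stats = label_statistics(make_table(["C"], [[1, 0]]))
        assert (stats.n_single, stats.n_multi, stats.total_entries) == (1, 0, 1)

    def test_all_label_count_and_conservation_under_permutation(self):
        rng = np.random.default_rng(3)
        Y = (rng.random((30, 3)) > 0.4).astype(int)
        Y[Y.sum(axis=1) == 0, 0] = 1
        table = make_table(["C"] * 30, Y, names=("a", "b", "c"))
        table.ids = [f"c{i}" for i in range(30)]
        stats = label_statistics(table)
        assert stats.total_entries == int(stats.per_label.sum())
        assert stats.n_all == int((Y.sum(axis=1) == 3).sum())
        perm = table.subset(rng.permutation(30))
        pstats = label_statistics(perm)
        np.testing.assert_array_equal(stats.per_label, pstats.per_label)
        assert stats.n_single == pstats.n_single


class TestCvSplit:
    def test_even_fold_sizes(self):
        table = make_table(["C"] * 10, np.tile([1, 0], (10, 1)))
        split = make_cv_split(table, k=5, seed=0)
        sizes = np.bincount(split.fold_assignments, minlength=5)
        assert sorted(sizes) == [2, 2, 2, 2, 2]

    def test_uneven_sizes_pigeonhole(self):
        table = make_table(["C"] * 11, np.tile([1, 0], (11, 1)))
        sizes = np.bincount(make_cv_split(table, 5, 1).fold_assignments)
        assert sorted(sizes) == [2, 2, 2, 2, 3]

    def test_deterministic_given_seed(self):
        table = make_table(["C"] * 23, np.tile([1, 0], (23, 1)))
        a = make_cv_split(table, 4, seed=9).fold_assignments
        b = make_cv_split(table, 4, seed=9).fold_assignments
        np.testing.assert_array_equal(a, b)

    def test_k_exceeding_records_errors(self):
        table = make_table(["C"] * 3, np.tile([1, 0], (3, 1)))
        with pytest.raises(ValueError):
            make_cv_split(table, 5, 0)

    def test_folds_partition_records(self):
        table = make_table(["C"] * 17, np.tile([1, 0], (17, 1)))
        split = make_cv_split(table, 4, 2)
        seen = np.concatenate([test for _, test in split.iter_folds()])
        assert sorted(seen) == list(range(17))


class TestFixtureGenerator:
    def test_vocabulary_all_valid(self):
        from mlpathway.mol_graph import smiles_to_graph
        for cls, frags in FRAGMENT_CLASSES.items():
            for smi in frags:
                smiles_to_graph(smi)  # must not raise

    def test_generated_structures_all_parse(self):
        table = generate_fixture(60, seed=3)
        kept, removed = filter_valid_structures(table)
        assert removed == []

    def test_deterministic_given_seed(self):
        a = generate_fixture(40, seed=5)
        b = generate_fixture(40, seed=5)
        assert a.smiles == b.smiles
        np.testing.assert_array_equal(a.Y, b.Y)

    def test_every_record_has_a_label(self):
        table = generate_fixture(150, seed=2)
        assert (table.Y.sum(axis=1) >= 1).all()

    def test_forced_dependence_is_exact(self):
        spec = np.array([[0.5, 0.5], [0.5, 0.6]])
        spec[0, 1] = spec[1, 0] = 0.5  # joint == p0 -> l0 implies l1
        table = generate_fixture(100, n_pathways=2, cooccurrence_spec=spec,
                                 seed=4)
        Y = table.Y
        assert np.all(Y[Y[:, 0] == 1, 1] == 1)

    def test_empirical_conditional_converges(self):
        spec = np.array([[0.5, 0.25], [0.25, 0.5]])
        table = generate_fixture(2000, n_pathways=2, cooccurrence_spec=spec,
                                 seed=8, distractor_rate=0.0)
        Y = table.Y
        cond = Y[Y[:, 0] == 1, 1].mean()
        assert abs(cond - 0.5) < 0.05

    def test_infeasible_spec_errors(self):
        spec = np.array([[0.2, 0.3], [0.3, 0.2]])  # joint > marginals
        with pytest.raises(ValueError, match="infeasible"):
            generate_fixture(10, n_pathways=2, cooccurrence_spec=spec)

    def test_default_spec_plants_strong_dependence(self):
        table = generate_fixture(800, seed=12)
        Y = table.Y
        cond = Y[Y[:, 0] == 1, 1].mean()
        assert cond > 0.85  # planted p(l1|l0) = 0.95 up to sampling noise


class TestDemoWordVectors:
    def test_file_loads_and_covers_default_names(self, tmp_path):
        path = write_demo_wordvec_file(tmp_path / "wv.txt", r=10)
        vecs = load_word_vectors(path)
        assert all(v.shape == (10,) for v in vecs.values())
        for tok in ("carbohydrate", "metabolism", "lipid"):
            assert tok in vecs

    def test_content_is_stable(self, tmp_path):
        a = write_demo_wordvec_file(tmp_path / "a.txt", r=8).read_text()
        b = write_demo_wordvec_file(tmp_path / "b.txt", r=8).read_text()
        assert a == b

    def test_related_tokens_are_closer_than_unrelated(self, tmp_path):
        vecs = load_word_vectors(write_demo_wordvec_file(tmp_path / "wv.txt"))
        d_related = np.linalg.norm(vecs["carbohydrate"] - vecs["glycan"])
        d_unrelated = np.linalg.norm(vecs["carbohydrate"] - vecs["lipid"])
        assert d_related < d_unrelated
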