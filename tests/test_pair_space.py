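"""Closed-world enumeration, pair assembly, normalization and ARFF I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from negspace.pair_space import (
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    PairTable,
    apply_minmax,
    assemble_pair_vector,
    enumerate_negative_pool,
    fit_minmax,
    read_arff,
    write_arff,
)
from negspace.seq_features import FeatureBlock, Scheme


class TestNegativePool:
    def test_study_scale_counts(self):
        cyts = [f"C{i}" for i in range(123)]
        recs = [f"R{i}" for i in range(102)]
        positives = [(cyts[i % 123], recs[(i * 7) % 102]) for i in range(400)]
        positives = list(dict.fromkeys(positives))[:203]
        pool = enumerate_negative_pool(cyts, recs, positives)
        assert len(cyts) * len(recs) == 12546
        assert len(pool) == 12343

    def test_small_counts(self):
        pool = enumerate_negative_pool(
            ["a", "b", "c"], ["x", "y"], [("a", "x"), ("c", "y")]
        )
        assert len(pool) == 4
        assert enumerate_negative_pool(["a"], ["x"], [("a", "x")]) == []

    def test_unknown_id_errors(self):
        with pytest.raises(ValueError, match="unknown ID"):
            enumerate_negative_pool(["a"], ["x"], [("b", "x")])

    def test_duplicate_positive_errors(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_negative_pool(["a"], ["x", "y"],
                                    [("a", "x"), ("a", "x")])

    @settings(max_examples=40, derandomize=True)
    @given(
        nc=st.integers(1, 8), nr=st.integers(1, 8),
        data=st.data(),
    )
    def test_pool_disjoint_and_complementary(self, nc, nr, data):
        cyts = [f"c{i}" for i in range(nc)]
        recs = [f"r{i}" for i in range(nr)]
        all_pairs = [(c, r) for c in cyts for r in recs]
        k = data.draw(st.integers(0, len(all_pairs)))
        positives = data.draw(
            st.permutations(all_pairs).map(lambda p: list(p)[:k])
        )
        pool = enumerate_negative_pool(cyts, recs, positives)
        assert len(pool) + len(positives) == nc * nr
        assert not set(pool) & set(positives)
        assert pool == sorted(pool)


class TestPairVectors:
    def test_widths(self):
        b56 = FeatureBlock(Scheme.COMBINED56,
                           tuple(f"f{i}" for i in range(56)), np.arange(56))
        assert len(assemble_pair_vector(b56, b56)) == 112
        b20 = FeatureBlock(Scheme.AAC,
                           tuple(f"a{i}" for i in range(20)), np.arange(20))
        assert len(assemble_pair_vector(b20, b20)) == 40

    def test_cytokine_block_comes_first(self):
        names = tuple(f"a{i}" for i in range(20))
        cyt = FeatureBlock(Scheme.AAC, names, np.arange(20))
        rec = FeatureBlock(Scheme.AAC, names, np.arange(20) + 100)
        vec = assemble_pair_vector(cyt, rec)
        np.testing.assert_array_equal(vec[:20], cyt.values)
        np.testing.assert_array_equal(vec[20:], rec.values)

    def test_scheme_mismatch_errors(self):
        a = FeatureBlock(Scheme.AAC, ("x",), [1.0])
        b = FeatureBlock(Scheme.ATC, ("x",), [1.0])
        with pytest.raises(ValueError, match="scheme mismatch"):
            assemble_pair_vector(a, b)


def make_table(vectors, labels=None):
    vectors = np.asarray(vectors, dtype=float)
    n = len(vectors)
    labels = labels or [NEGATIVE_LABEL] * n
    return PairTable(
        tuple((f"c{i}", f"r{i}") for i in range(n)),
        tuple(labels),
        vectors,
        tuple(f"f{j}" for j in range(vectors.shape[1])),
    )


class TestMinMax:
    def test_column_mapping(self):
        table = make_table([[2.0], [4.0], [6.0]])
        out = apply_minmax(table, fit_minmax(table))
        np.testing.assert_allclose(out.vectors.ravel(), [0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        table = make_table([[5.0, 1.0], [5.0, 2.0]])
        out = apply_minmax(table, fit_minmax(table))
        np.testing.assert_array_equal(out.vectors[:, 0], 0.0)

    @settings(max_examples=30, derandomize=True)
    @given(
        data=st.lists(
            st.lists(st.floats(-100, 100), min_size=3, max_size=3),
            min_size=2, max_size=10,
        )
    )
    def test_fit_on_self_yields_unit_range(self, data):
        table = make_table(data)
        out = apply_minmax(table, fit_minmax(table))
        assert np.all(out.vectors >= 0) and np.all(out.vectors <= 1)


class TestArff:
    def test_round_trip_identity(self, tmp_path, rng):
        vectors = rng.normal(size=(5, 4))
        labels = [POSITIVE_LABEL] * 2 + [NEGATIVE_LABEL] * 3
        table = make_table(vectors, labels)
        path = tmp_path / "t.arff"
        write_arff(table, path)
        back = read_arff(path)
        assert back.pairs == table.pairs
        assert back.labels == table.labels
        assert back.feature_names == table.feature_names
        np.testing.assert_allclose(back.vectors, table.vectors, rtol=1e-11)

    def test_missing_class_attribute_errors(self, tmp_path):
        path = tmp_path / "noclass.arff"
        path.write_text(
            "@relation x\n@attribute f0 numeric\n@data\n1.0\n"
        )
        with pytest.raises(ValueError, match="class"):
            read_arff(path)

    def test_class_value_outside_declared_set_errors(self, tmp_path):
        path = tmp_path / "bad.arff"
        path.write_text(
            "@relation x\n@attribute f0 numeric\n"
            "@attribute class {interacting,non_interacting}\n"
            "@data\n1.0,maybe\n"
        )
        with pytest.raises(ValueError, match="outside"):
            read_arff(path)

    def test_balanced_counts_preserved(self, tmp_path, rng):
        n = 203
        table = make_table(
            rng.normal(size=(2 * n, 3)),
            [POSITIVE_LABEL] * n + [NEGATIVE_LABEL] * n,
        )
        path = tmp_path / "bal.arff"
        write_arff(table, path)
        back = read_arff(path)
        assert back.labels.count(POSITIVE_LABEL) == n
        assert back.labels.count(NEGATIVE_LABEL) == n
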