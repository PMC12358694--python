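"""Count-table data model and Hill-number diversity."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import entropy
from skbio.diversity import alpha as skbio_alpha

from divarea import (
    CommunityTable,
    accumulation_curve,
    hill_number,
    pooled_diversity,
    read_biom_json,
    read_counts_tsv,
    read_metadata_tsv,
    relative_abundances,
)
from conftest import make_disjoint_table, make_identical_table


class TestRelativeAbundances:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((2, 2), (0.5, 0.5)),
            ((8, 2, 0), (0.8, 0.2, 0.0)),
            ((1, 3), (0.25, 0.75)),
        ],
    )
    def test_normalization(self, counts, expected):
        np.testing.assert_allclose(relative_abundances(counts), expected)

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError, match="empty community"):
            relative_abundances((0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            relative_abundances((3, -1))


class TestHillNumber:
    @pytest.mark.parametrize("q", [0, 0.5, 1, 2, 3])
    def test_uniform_community_gives_richness(self, q):
        assert hill_number([0.25] * 4, q) == pytest.approx(4.0)

    def test_shannon_limit_at_q1(self):
        assert hill_number([0.5, 0.5], 1) == pytest.approx(2.0)

    def test_hand_computed_inverse_simpson(self):
        # (0.8^2 + 0.2^2)^(1/(1-2)) = 1/0.68
        assert hill_number([0.8, 0.2], 2) == pytest.approx(1 / 0.68, abs=1e-12)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            hill_number([0.5, 0.5], -1)

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError):
            hill_number([0.5, 0.6], 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_closed_forms_match_independent_oracles(self, seed):
        """D_0 = support, D_1 = exp(H), D_2 = inverse Simpson, checked
        against scipy entropy and scikit-bio's implementations."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=30)
        counts[0] = 1  # non-empty
        p = relative_abundances(counts)
        assert hill_number(p, 0) == np.count_nonzero(counts)
        assert hill_number(p, 1) == pytest.approx(np.exp(entropy(p)))
        assert hill_number(p, 2) == pytest.approx(1.0 / np.sum(p**2))
        nz = counts[counts > 0]
        assert hill_number(p, 1) == pytest.approx(
            np.exp(skbio_alpha.shannon(nz)))
        assert hill_number(p, 2) == pytest.approx(skbio_alpha.inv_simpson(nz))
        for q in (0.5, 1.7, 3.0):
            assert hill_number(p, q) == pytest.approx(
                skbio_alpha.hill(nz, order=q))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_non_increasing_in_q(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(rng.integers(2, 40)))
        p = p / p.sum()
        values = [hill_number(p, q) for q in np.linspace(0, 3, 13)]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_taxon_permutation_and_zero_padding(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(10))
        p = p / p.sum()
        for q in (0, 1, 2, 2.5):
            base = hill_number(p, q)
            assert hill_number(rng.permutation(p), q) == pytest.approx(base)
            assert hill_number(np.concatenate([p, [0, 0]]), q) == pytest.approx(base)


class TestCommunityTable:
    def test_zero_sum_rows_dropped_with_warning(self):
        counts = np.array([[1, 2], [0, 0], [3, 0]])
        with pytest.warns(UserWarning, match="zero-count"):
            t = CommunityTable(counts, ["a", "b", "c"], ["x", "y"])
        assert t.sample_ids == ["a", "c"]
        assert t.n_samples == 2

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CommunityTable(np.ones((2, 2), dtype=int), ["a", "a"], ["x", "y"])
        with pytest.raises(ValueError, match="duplicate"):
            CommunityTable(np.ones((2, 2), dtype=int), ["a", "b"], ["x", "x"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CommunityTable(np.array([[1, -1]]), ["a"], ["x", "y"])

    def test_group_selection(self):
        t = make_disjoint_table(6).with_groups(
            {f"S{i}": ("A" if i < 3 else "B") for i in range(6)})
        assert t.group_labels() == ["A", "B"]
        assert t.by_group("A").sample_ids == ["S0", "S1", "S2"]
        with pytest.raises(ValueError):
            t.by_group("C")

    def test_concat_unions_taxa(self):
        a = CommunityTable(np.array([[1, 2]]), ["s1"], ["x", "y"])
        b = CommunityTable(np.array([[3]]), ["s2"], ["z"])
        merged = CommunityTable.concat([a, b])
        assert merged.n_samples == 2
        assert set(merged.taxon_ids) == {"x", "y", "z"}
        assert merged.to_dataframe().loc["s2", "x"] == 0


class TestPooling:
    def test_disjoint_union_richness(self):
        a = CommunityTable(np.array([[1, 0], [0, 1]]), ["s1", "s2"], ["a", "b"])
        assert pooled_diversity(a, [0, 1], 0) == 2

    def test_pooling_idempotent_on_support(self):
        t = CommunityTable(np.array([[3, 1], [3, 1]]), ["s1", "s2"], ["a", "b"])
        assert pooled_diversity(t, [0, 1], 0) == 2

    def test_pooled_counts_make_uniform_pair(self):
        t = CommunityTable(np.array([[3, 1], [1, 3]]), ["s1", "s2"], ["a", "b"])
        assert pooled_diversity(t, [0, 1], 2) == pytest.approx(2.0)

    def test_empty_subset_rejected(self):
        t = make_identical_table(3)
        with pytest.raises(ValueError):
            pooled_diversity(t, [], 0)


class TestAccumulationCurve:
    def test_single_sample(self):
        t = CommunityTable(np.array([[1, 1, 1]]), ["s"], ["a", "b", "c"])
        curve = accumulation_curve(t, [0], 0)
        assert list(curve.areas) == [1]
        assert curve.diversities[0] == 3

    def test_disjoint_additivity(self):
        t = CommunityTable(
            np.array([[1, 1, 1, 0, 0], [0, 0, 0, 1, 1]]),
            ["s1", "s2"], list("abcde"))
        curve = accumulation_curve(t, [0, 1], 0)
        np.testing.assert_array_equal(curve.diversities, [3, 5])

    def test_identical_samples_constant_curve(self, identical_table):
        for q in (0, 1, 2):
            curve = accumulation_curve(identical_table, range(10), q)
            np.testing.assert_allclose(curve.diversities,
                                       curve.diversities[0])

    def test_richness_curve_non_decreasing_and_order_free_endpoint(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 20, size=(8, 15))
        counts[:, 0] += 1
        t = CommunityTable(counts, [f"S{i}" for i in range(8)],
                           [f"T{j}" for j in range(15)])
        endpoints = []
        for seed in range(4):
            ordering = np.random.default_rng(seed).permutation(8)
            for q in (0, 1, 2):
                curve = accumulation_curve(t, ordering, q)
                if q == 0:
                    assert np.all(np.diff(curve.diversities) >= -1e-9)
                if q == 2:
                    endpoints.append(curve.diversities[-1])
        np.testing.assert_allclose(endpoints, endpoints[0])

    def test_non_permutation_rejected(self, identical_table):
        with pytest.raises(ValueError, match="permutation"):
            accumulation_curve(identical_table, [0, 0, 1], 0)


class TestIO:
    def test_tsv_round_trip(self, tmp_path, disjoint_table):
        path = tmp_path / "table.tsv"
        disjoint_table.to_tsv(path)
        back = read_counts_tsv(path)
        np.testing.assert_array_equal(back.counts, disjoint_table.counts)
        assert back.sample_ids == disjoint_table.sample_ids
        # taxa-as-rows orientation via explicit flag
        disjoint_table.to_dataframe().T.to_csv(
            tmp_path / "t.tsv", sep="\t", index_label="taxon_id")
        back_t = read_counts_tsv(tmp_path / "t.tsv", transpose=True)
        np.testing.assert_array_equal(back_t.counts, disjoint_table.counts)

    @pytest.mark.parametrize("matrix_type", ["sparse", "dense"])
    def test_biom_json(self, tmp_path, matrix_type):
        counts = np.array([[5, 0], [1, 2], [0, 7]])  # taxa x samples
        doc = {
            "id": "t", "format": "Biological Observation Matrix 1.0.0",
            "type": "OTU table", "matrix_type": matrix_type,
            "shape": [3, 2],
            "rows": [{"id": f"T{i}", "metadata": None} for i in range(3)],
            "columns": [{"id": f"S{j}", "metadata": None} for j in range(2)],
            "data": (
                counts.tolist() if matrix_type == "dense"
                else [[i, j, int(counts[i, j])]
                      for i in range(3) for j in range(2) if counts[i, j]]
            ),
        }
        path = tmp_path / "table.biom"
        path.write_text(json.dumps(doc))
        t = read_biom_json(path)
        assert t.sample_ids == ["S0", "S1"]
        np.testing.assert_array_equal(t.counts, counts.T)

    def test_metadata_reader(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("sample_id\tgroup\nS1\tNT\nS2\tPT\n")
        assert read_metadata_tsv(path) == {"S1": "NT", "S2": "PT"}
        bad = tmp_path / "bad.tsv"
        bad.write_text("sample\tlabel\nS1\tNT\n")
        with pytest.raises(ValueError, match="sample_id"):
            read_metadata_tsv(bad)
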