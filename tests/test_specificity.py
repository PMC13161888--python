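"""Specificity scores and the bootstrap enrichment test: closed forms,
independent oracles, exact enumeration on a tiny universe."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from dystogex.errors import InputError
from dystogex.specificity import (bootstrap_enrichment, normalize_counts,
                                  specificity_scores, SpecificityMatrix)

from conftest import make_cell_dataset


class TestNormalize:
    def test_equal_counts_closed_form(self):
        ds = make_cell_dataset([[1, 1]])
        norm = normalize_counts(ds, scale=1e4)
        assert np.allclose(norm.toarray(), np.log1p(5000.0))

    def test_depth_invariance(self):
        ds = make_cell_dataset([[2, 6, 2], [4, 12, 4]])
        norm = normalize_counts(ds).toarray()
        assert np.allclose(norm[0], norm[1], atol=1e-12)

    def test_three_by_three_hand_computation(self):
        counts = np.array([[1, 2, 7], [5, 0, 5], [0, 0, 4]])
        norm = normalize_counts(make_cell_dataset(counts), scale=100).toarray()
        expected = np.log1p(100 * counts / counts.sum(axis=1, keepdims=True))
        assert np.allclose(norm, expected, atol=1e-12)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(InputError):
            normalize_counts(make_cell_dataset([[0, 0], [1, 1]]))


class TestSpecificityScores:
    def _spec(self, means_by_type, gene_symbols):
        """Build a SpecificityMatrix via the public path from per-type
        single-cell data whose means are exactly the given values."""
        blocks, types = [], []
        for t, col in means_by_type.items():
            blocks.append(np.array(col, dtype=float)[None, :])
            types.append(t)
        mat = sp.csr_matrix(np.vstack(blocks))
        return specificity_scores(mat, types, gene_symbols)

    def test_exclusive_gene_scores_one(self):
        spec = self._spec({"A": [2, 1], "B": [0, 1], "C": [0, 2]}, ["G1", "G2"])
        assert np.allclose(spec.scores.loc["G1"], [1.0, 0.0, 0.0])

    def test_uniform_gene_scores_quarter(self):
        spec = self._spec({t: [3.0] for t in "ABCD"}, ["G1"])
        assert np.allclose(spec.scores.loc["G1"], 0.25)

    def test_five_gene_three_type_independent_oracle(self, rng):
        means = rng.uniform(0, 5, size=(5, 3))
        spec = self._spec({"A": means[:, 0], "B": means[:, 1], "C": means[:, 2]},
                          [f"G{i}" for i in range(5)])
        oracle = means / means.sum(axis=1, keepdims=True)
        assert np.allclose(spec.scores.to_numpy(), oracle, atol=1e-12)

    def test_rows_sum_to_one_and_zero_genes_excluded(self, rng):
        counts = rng.integers(0, 6, size=(40, 25)) + np.eye(40, 25, dtype=np.int64)
        counts[:, 0] = 0  # one gene with no expression anywhere
        ds = make_cell_dataset(counts, cell_types=list("AB") * 20)
        norm = normalize_counts(ds)
        spec = specificity_scores(norm, ds.cells["cell_type"],
                                  ds.genes["gene_symbol"])
        expressed = spec.expressed_genes
        sums = spec.scores.loc[expressed].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert "G000" not in expressed
        assert (spec.scores.loc["G000"] == 0).all()

    def test_single_cell_type_rejected(self):
        with pytest.raises(InputError):
            specificity_scores(sp.csr_matrix(np.ones((3, 2))), ["A"] * 3,
                               ["G1", "G2"])

    def test_column_permutation_equivariance(self, rng):
        counts = rng.integers(0, 5, size=(30, 10)) + 1
        types = list(rng.choice(["A", "B", "C"], 30))
        ds = make_cell_dataset(counts, cell_types=types)
        norm = normalize_counts(ds)
        spec1 = specificity_scores(norm, types, ds.genes["gene_symbol"])
        relabel = {"A": "Z", "B": "Y", "C": "X"}
        spec2 = specificity_scores(norm, [relabel[t] for t in types],
                                   ds.genes["gene_symbol"])
        for old, new in relabel.items():
            assert np.array_equal(spec1.scores[old].to_numpy(),
                                  spec2.scores[new].to_numpy())


def _toy_spec(values, genes, types):
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=types)
    return SpecificityMatrix(scores=df.div(df.sum(axis=1), axis=0),
                             mean_expression=df)


class TestBootstrap:
    def test_minimum_possible_p(self, rng):
        # a query that dominates every null draw hits the +1 floor; with a
        # 200-gene universe the chance of redrawing the query itself (the
        # only possible tie) is 1/C(200,5)
        vals = np.full((200, 2), 0.1)
        vals[:5, 0] = 50.0
        spec = _toy_spec(vals, [f"G{i}" for i in range(200)], ["A", "B"])
        out = bootstrap_enrichment(spec, [f"G{i}" for i in range(5)],
                                   n_iter=1000, seed=0)
        pA = out.set_index("cell_type").loc["A", "empirical_p"]
        assert pA == pytest.approx(1 / 1001)

    def test_seed_determinism(self, rng):
        vals = rng.uniform(0.1, 2, size=(30, 3))
        spec = _toy_spec(vals, [f"G{i}" for i in range(30)], list("ABC"))
        a = bootstrap_enrichment(spec, ["G1", "G2", "G3"], n_iter=500, seed=42)
        b = bootstrap_enrichment(spec, ["G1", "G2", "G3"], n_iter=500, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_disjoint_query_rejected(self, rng):
        spec = _toy_spec(rng.uniform(0.1, 1, (10, 2)),
                         [f"G{i}" for i in range(10)], ["A", "B"])
        with pytest.raises(InputError, match="NOPE"):
            bootstrap_enrichment(spec, ["NOPE", "NADA"], n_iter=200, seed=0)

    def test_small_universe_matches_exhaustive_enumeration(self, rng):
        genes = [f"G{i}" for i in range(6)]
        vals = rng.uniform(0.1, 2, size=(6, 2))
        spec = _toy_spec(vals, genes, ["A", "B"])
        query = ["G0", "G3"]
        n_iter = 4000
        out = bootstrap_enrichment(spec, query, n_iter=n_iter, seed=7)
        s = spec.scores["A"].to_numpy()
        observed = s[[0, 3]].mean()
        tail = np.mean([np.mean([s[i], s[j]]) >= observed
                        for i, j in combinations(range(6), 2)])
        expected_p = (1 + n_iter * tail) / (n_iter + 1)
        sd = np.sqrt(tail * (1 - tail) / n_iter)
        pA = out.set_index("cell_type").loc["A", "empirical_p"]
        assert abs(pA - expected_p) <= 2 * sd + 1e-9

    def test_fdr_dominates_raw_p(self, rng):
        vals = rng.uniform(0.1, 2, size=(40, 4))
        spec = _toy_spec(vals, [f"G{i}" for i in range(40)], list("ABCD"))
        out = bootstrap_enrichment(spec, ["G0", "G1", "G2"], n_iter=300, seed=3)
        assert (out["p_fdr"] >= out["empirical_p"] - 1e-15).all()
        assert (out["empirical_p"] >= 1 / 301).all()
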