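"""Unit and oracle tests for the pathway-bridge featurization chain."""

import numpy as np
import pandas as pd
import pytest

from pathsyn.io_formats import DrugRecord, GeneSetCollection
from pathsyn.pathway_bridge import (
    all_pairs,
    build_combination_pathway_features,
    build_drug_pathway_matrix,
    build_pathway_similarity,
    canonical_pair,
    filter_drugs_and_pathways,
    refine_drug_pathway,
)


def _drug(i, targets):
    return DrugRecord(f"d{i}", target_genes=frozenset(targets))


def random_fixture(rng, m=None, n=None):
    """Random drugs and gene sets over a small shared universe."""
    m = m or int(rng.integers(2, 11))
    n = n or int(rng.integers(2, 9))
    genes = [f"g{k}" for k in range(30)]
    drugs = [
        _drug(i, rng.choice(genes, size=int(rng.integers(1, 12)), replace=False))
        for i in range(m)
    ]
    sets = {
        f"P{j}": frozenset(rng.choice(genes, size=int(rng.integers(2, 15)), replace=False))
        for j in range(n)
    }
    return drugs, GeneSetCollection(sets)


def brute_force_bridge(drugs, genesets):
    """Triple-loop evaluation of the whole featurization chain."""
    names = genesets.names
    m, n = len(drugs), len(names)
    D = np.zeros((m, n))
    for i, drug in enumerate(drugs):
        for j, name in enumerate(names):
            D[i, j] = 1.0 if len(drug.target_genes & genesets[name]) > 0 else 0.0
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            si, sj = genesets[names[i]], genesets[names[j]]
            P[i, j] = len(si & sj) / len(si | sj)
    Dt = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            Dt[i, j] = sum(D[i, k] * P[k, j] for k in range(n))
    A = {}
    for i in range(m):
        for j in range(i + 1, m):
            A[(i, j)] = np.array(
                [0.5 * (D[i, k] * Dt[j, k] + D[j, k] * Dt[i, k]) for k in range(n)]
            )
    return D, P, Dt, A


class TestFilters:
    def test_target_count_boundary(self):
        drugs = [_drug(0, [f"g{k}" for k in range(9)]),
                 _drug(1, [f"g{k}" for k in range(10)])]
        sets = GeneSetCollection({"P0": frozenset(f"g{k}" for k in range(10))})
        kept, _ = filter_drugs_and_pathways(drugs, sets, min_drug_fraction=0.0)
        assert [d.drug_id for d in kept] == ["d1"]

    def test_pathway_size_boundary(self):
        drugs = [_drug(i, [f"g{k}" for k in range(10)]) for i in range(2)]
        sets = GeneSetCollection(
            {
                "small": frozenset(f"g{k}" for k in range(9)),
                "at": frozenset(f"g{k}" for k in range(10)),
            }
        )
        _, kept = filter_drugs_and_pathways(drugs, sets)
        assert kept.names == ["at"]

    def test_half_of_drugs_boundary_is_fractional(self):
        """With 87 retained drugs, 43 acting drugs drop a pathway, 44 keep it."""
        n_drugs = 87
        drugs = []
        for i in range(n_drugs):
            base = {f"t{i}_{k}" for k in range(10)}  # private targets
            drugs.append(_drug(i, base | ({"shared43"} if i < 43 else set())
                               | ({"shared44"} if i < 44 else set())))
        sets = GeneSetCollection(
            {
                "hit43": frozenset({"shared43", *{f"f{k}" for k in range(9)}}),
                "hit44": frozenset({"shared44", *{f"f{k}" for k in range(9)}}),
            }
        )
        kept_drugs, kept_sets = filter_drugs_and_pathways(drugs, sets)
        assert len(kept_drugs) == 87
        assert kept_sets.names == ["hit44"]

    def test_retention_invariant_to_input_order(self, rng):
        drugs, sets = random_fixture(rng, m=8, n=6)
        drugs = [
            DrugRecord(d.drug_id, target_genes=frozenset(list(d.target_genes) + [f"x{i}_{k}" for k in range(10)]))
            for i, d in enumerate(drugs)
        ]
        kept1, sets1 = filter_drugs_and_pathways(drugs, sets, min_genes=2)
        shuffled = list(drugs)[::-1]
        rev_names = sets.names[::-1]
        sets_rev = GeneSetCollection({n: sets[n] for n in rev_names})
        kept2, sets2 = filter_drugs_and_pathways(shuffled, sets_rev, min_genes=2)
        assert {d.drug_id for d in kept1} == {d.drug_id for d in kept2}
        assert set(sets1.names) == set(sets2.names)

    def test_all_filtered_out_is_an_error(self):
        drugs = [_drug(0, ["g1"])]
        sets = GeneSetCollection({"P": frozenset({"g1", "g2"})})
        with pytest.raises(ValueError):
            filter_drugs_and_pathways(drugs, sets)


class TestMatrices:
    def test_indicator_entries(self):
        drugs = [_drug(0, {"g1"}), _drug(1, {"g9"})]
        sets = GeneSetCollection({"P": frozenset({"g1", "g2"})})
        D = build_drug_pathway_matrix(drugs, sets)
        assert D.loc["d0", "P"] == 1
        assert D.loc["d1", "P"] == 0

    def test_jaccard_values(self):
        sets = GeneSetCollection(
            {
                "A": frozenset({"g1", "g2", "g3"}),
                "B": frozenset({"g2", "g3", "g4"}),
                "C": frozenset({"g9"}),
            }
        )
        P = build_pathway_similarity(sets)
        assert P.loc["A", "B"] == pytest.approx(0.5)
        assert P.loc["A", "A"] == 1.0
        assert P.loc["A", "C"] == 0.0
        assert np.allclose(P.values, P.values.T)

    def test_refine_hand_example(self):
        D = pd.DataFrame([[1, 0], [0, 1]], index=["d0", "d1"], columns=["P0", "P1"])
        P = pd.DataFrame(
            [[1.0, 0.5], [0.5, 1.0]], index=["P0", "P1"], columns=["P0", "P1"]
        )
        Dt = refine_drug_pathway(D, P)
        assert np.allclose(Dt.values, [[1.0, 0.5], [0.5, 1.0]])
        # identity similarity leaves D unchanged
        ident = pd.DataFrame(np.eye(2), index=["P0", "P1"], columns=["P0", "P1"])
        assert np.allclose(refine_drug_pathway(D, ident).values, D.values)

    def test_combination_hand_example(self):
        D = pd.DataFrame([[1, 0], [0, 1]], index=["d0", "d1"], columns=["P0", "P1"])
        P = pd.DataFrame(
            [[1.0, 0.5], [0.5, 1.0]], index=["P0", "P1"], columns=["P0", "P1"]
        )
        A = build_combination_pathway_features(D, refine_drug_pathway(D, P), [("d0", "d1")])
        # pathway P0: (d_{0,0}*dt_{1,0} + d_{1,0}*dt_{0,0})/2 = (1*0.5 + 0*1)/2
        assert A.loc[("d0", "d1"), "P0"] == pytest.approx(0.25)
        assert A.loc[("d0", "d1"), "P1"] == pytest.approx(0.25)

    def test_pair_with_unknown_drug(self):
        D = pd.DataFrame([[1]], index=["d0"], columns=["P0"])
        with pytest.raises(KeyError):
            build_combination_pathway_features(D, D.astype(float), [("d0", "dX")])


class TestOracleEquivalence:
    def test_random_fixtures_match_triple_loops(self, rng):
        for _ in range(20):
            drugs, sets = random_fixture(rng)
            D_ref, P_ref, Dt_ref, A_ref = brute_force_bridge(drugs, sets)
            D = build_drug_pathway_matrix(drugs, sets)
            P = build_pathway_similarity(sets)
            Dt = refine_drug_pathway(D, P)
            pairs = all_pairs([d.drug_id for d in drugs])
            A = build_combination_pathway_features(D, Dt, pairs)
            assert np.allclose(D.values, D_ref, atol=1e-12)
            assert np.allclose(P.values, P_ref, atol=1e-12)
            assert np.allclose(Dt.values, Dt_ref, atol=1e-12)
            for (i, j), vec in A_ref.items():
                key = canonical_pair(f"d{i}", f"d{j}")
                assert np.allclose(A.loc[key].to_numpy(), vec, atol=1e-12)

    def test_tensor_symmetry_and_sparsity(self, rng):
        drugs, sets = random_fixture(rng, m=6, n=5)
        D = build_drug_pathway_matrix(drugs, sets)
        Dt = refine_drug_pathway(D, build_pathway_similarity(sets))
        ids = [d.drug_id for d in drugs]
        A_fwd = build_combination_pathway_features(D, Dt, [(ids[0], ids[3])])
        A_rev = build_combination_pathway_features(D, Dt, [(ids[3], ids[0])])
        pd.testing.assert_frame_equal(A_fwd, A_rev)
        # zero wherever neither drug acts directly
        both_zero = (D.loc[ids[0]] == 0) & (D.loc[ids[3]] == 0)
        key = canonical_pair(ids[0], ids[3])
        assert (A_fwd.loc[key][both_zero] == 0).all()

    def test_refined_dominates_indicator(self, rng):
        drugs, sets = random_fixture(rng, m=5, n=6)
        D = build_drug_pathway_matrix(drugs, sets)
        Dt = refine_drug_pathway(D, build_pathway_similarity(sets))
        assert (Dt.values >= D.values - 1e-12).all()


def test_pathway_order_propagates_from_gmt(tmp_path):
    (tmp_path / "s.gmt").write_text(
        "PB\tx\tg1\tg2\nPA\tx\tg2\tg3\nPC\tx\tg1\tg3\n"
    )
    from pathsyn.io_formats import read_gmt

    sets = read_gmt(tmp_path / "s.gmt")
    drugs = [_drug(0, {"g1"}), _drug(1, {"g2"})]
    D = build_drug_pathway_matrix(drugs, sets)
    P = build_pathway_similarity(sets)
    assert list(D.columns) == ["PB", "PA", "PC"] == list(P.columns)


def test_canonical_pair_rejects_self_pair():
    with pytest.raises(ValueError):
        canonical_pair("d1", "d1")
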