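"""Relationship-matrix construction: tabular NRM, blended GRM, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from xbreed.kinship import (
    ConfigurationError,
    GenotypeMatrix,
    Pedigree,
    PedigreeError,
    RelationshipMatrix,
    allele_frequencies,
    build_grm,
    build_nrm,
    relationship_summary,
)

from conftest import nrm_oracle, random_pedigree_frame


def make_pedigree(rows):
    return Pedigree(pd.DataFrame(rows, columns=["animal", "sire", "dam", "breed", "sex"]))


def make_genotypes(codes, ids=None):
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    markers = pd.DataFrame(
        {
            "marker": [f"m{j}" for j in range(m)],
            "chrom": 1,
            "pos": np.arange(m),
            "allele1": "A",
            "allele2": "B",
        }
    )
    ids = ids if ids is not None else [f"a{i}" for i in range(n)]
    return GenotypeMatrix(ids=np.asarray(ids, dtype=object), markers=markers, codes=codes)


# ---------------------------------------------------------------------------
# NRM
# ---------------------------------------------------------------------------


class TestBuildNrm:
    def test_parent_offspring_trio(self):
        ped = make_pedigree(
            [("S", "0", "0", "BB", "M"), ("D", "0", "0", "BB", "F"), ("O", "S", "D", "BB", "F")]
        )
        A = build_nrm(ped)
        ids = list(A.ids)
        a = pd.DataFrame(A.values, index=ids, columns=ids)
        assert a.loc["S", "O"] == 0.5
        assert a.loc["D", "O"] == 0.5
        assert a.loc["O", "O"] == 1.0
        assert a.loc["S", "D"] == 0.0

    def test_full_sibs_and_inbred_offspring(self):
        # full sibs from unrelated parents relate at 0.5; a sire-daughter
        # mating gives an inbred offspring with diagonal 1.25
        ped = make_pedigree(
            [
                ("S", "0", "0", "BB", "M"),
                ("D", "0", "0", "BB", "F"),
                ("O1", "S", "D", "BB", "F"),
                ("O2", "S", "D", "BB", "M"),
                ("X", "S", "O1", "BB", "F"),
            ]
        )
        a = pd.DataFrame(build_nrm(ped).values, index=list(ped.animals), columns=list(ped.animals))
        assert a.loc["O1", "O2"] == 0.5
        assert a.loc["X", "X"] == 1.25

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_recursive_oracle(self, seed):
        table = random_pedigree_frame(np.random.default_rng(seed), n=30)
        A = build_nrm(Pedigree(table), max_ancestor_generations=100)
        np.testing.assert_allclose(A.values, nrm_oracle(table), atol=1e-12)

    def test_truncation_forgets_deep_ancestors(self):
        # chain F0 -> F1 -> F2 -> F3 -> subject; with 2 ancestor
        # generations the subject's great-grandparent link is cut
        rows = [("F0", "0", "0", "BB", "M")]
        for k in range(1, 5):
            rows.append((f"F{k}", f"F{k-1}", "0", "BB", "M"))
        ped = make_pedigree(rows)
        full = build_nrm(ped, max_ancestor_generations=10, subjects=["F0", "F4"])
        trunc = build_nrm(ped, max_ancestor_generations=2, subjects=["F0", "F4"])
        assert full.values[0, 1] == pytest.approx(0.5 ** 4)
        assert trunc.values[0, 1] == 0.0

    def test_disconnected_breeds_relate_at_zero(self, small_dataset, small_matrices):
        A = small_matrices["A"]
        breed = small_dataset["pedigree"].breed_of()
        lab = np.array([breed[a] for a in A.ids])
        cross = A.values[np.ix_(lab == "BB", lab == "TC")]
        assert np.abs(cross).max() == 0.0

    def test_cycle_raises(self):
        with pytest.raises(PedigreeError, match="cycle"):
            make_pedigree([("A", "B", "0", "BB", "M"), ("B", "A", "0", "BB", "M")])

    def test_unknown_parent_id_named(self):
        with pytest.raises(PedigreeError, match="GHOST"):
            make_pedigree([("A", "GHOST", "0", "BB", "M")])

    def test_permutation_consistency(self):
        rng = np.random.default_rng(3)
        table = random_pedigree_frame(rng, n=25)
        A1 = build_nrm(Pedigree(table), max_ancestor_generations=100)
        # same animals, shuffled subject order
        perm = rng.permutation(len(table))
        subjects = table["animal"].to_numpy()[perm]
        A2 = build_nrm(Pedigree(table), max_ancestor_generations=100, subjects=subjects)
        np.testing.assert_allclose(A2.values, A1.values[np.ix_(perm, perm)], atol=1e-12)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


class TestAlleleFrequencies:
    def test_simple_mean_halved(self):
        p, n_obs = allele_frequencies(make_genotypes([[0], [1], [2]]))
        assert p[0] == 0.5
        assert n_obs[0] == 3

    def test_monomorphic_flagged_at_one(self):
        p, _ = allele_frequencies(make_genotypes([[2], [2], [2]]))
        assert p[0] == 1.0  # fixed for the second allele

    def test_missing_calls_excluded(self):
        p, n_obs = allele_frequencies(make_genotypes([[0], [2], [-1]]))
        assert p[0] == 0.5
        assert n_obs[0] == 2

    def test_combined_equals_weighted_mean(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, size=(40, 25)).astype(np.int8)
        g = make_genotypes(codes)
        a, b = g.ids[:15], g.ids[15:]
        pa, na = allele_frequencies(g, animals=a)
        pb, nb = allele_frequencies(g, animals=b)
        pc, _ = allele_frequencies(g)
        np.testing.assert_allclose(pc, (pa * na + pb * nb) / (na + nb), atol=1e-12)


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------


class TestBuildGrm:
    def test_hand_computed_fixture(self):
        # 3 animals x 2 SNPs, p = (0.5, 0.5): centred S = [[-1,1],[0,0],[1,-1]],
        # denominator 2 * (0.25 + 0.25) = 1
        g = make_genotypes([[0, 2], [1, 1], [2, 0]])
        G = build_grm(g, blend=0.95)
        ghat = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
        np.testing.assert_allclose(G.values, 0.95 * ghat + 0.05 * np.eye(3), atol=1e-12)

    def test_all_heterozygous_collapses_to_blend_identity(self):
        g = make_genotypes(np.ones((4, 10), dtype=np.int8))
        G = build_grm(g, blend=0.95)
        np.testing.assert_allclose(G.values, 0.05 * np.eye(4), atol=1e-12)

    @given(st.integers(0, 10_000))
    def test_smallest_eigenvalue_bounded_by_blend(self, seed):
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, 3, size=(rng.integers(3, 12), rng.integers(4, 30))).astype(np.int8)
        try:
            G = build_grm(make_genotypes(codes), blend=0.95)
        except ConfigurationError:
            return  # all-monomorphic draw
        assert np.linalg.eigvalsh(G.values).min() >= 0.05 - 1e-8

    def test_unblended_diagonal_near_one_under_hwe(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.9, size=2000)
        codes = rng.binomial(2, p, size=(300, 2000)).astype(np.int8)
        G = build_grm(make_genotypes(codes), blend=1.0)
        assert abs(G.values.diagonal().mean() - 1.0) < 0.05

    def test_missing_genotypes_mean_imputed(self):
        g1 = make_genotypes([[0, 2], [1, 1], [2, 0]])
        codes = np.array([[0, 2], [1, -1], [2, 0]], dtype=np.int8)
        g2 = make_genotypes(codes)
        p1, _ = allele_frequencies(g1)
        G2 = build_grm(g2, frequencies=np.array([0.5, 0.5]), blend=0.95)
        # animal 1's missing SNP contributes 0 after centring
        assert G2.values[1, 1] == pytest.approx(0.95 * 0.0 + 0.05)

    def test_monomorphic_snps_dropped(self):
        codes = np.array([[0, 2], [1, 2], [2, 2]], dtype=np.int8)
        G = build_grm(make_genotypes(codes), blend=1.0)
        expect = build_grm(make_genotypes(codes[:, :1]), blend=1.0)
        np.testing.assert_allclose(G.values, expect.values, atol=1e-12)

    def test_all_monomorphic_raises(self):
        with pytest.raises(ConfigurationError, match="monomorphic"):
            build_grm(make_genotypes([[2, 0], [2, 0]]))

    def test_bad_blend_raises(self):
        g = make_genotypes([[0], [1], [2]])
        with pytest.raises(ConfigurationError, match="blend"):
            build_grm(g, blend=0.0)

    def test_permutation_consistency(self):
        rng = np.random.default_rng(11)
        codes = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        g = make_genotypes(codes)
        G1 = build_grm(g)
        perm = rng.permutation(10)
        g2 = GenotypeMatrix(ids=g.ids[perm], markers=g.markers, codes=codes[perm])
        G2 = build_grm(g2)
        np.testing.assert_allclose(G2.values, G1.values[np.ix_(perm, perm)], atol=1e-12)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


class TestRelationshipSummary:
    def test_pedigree_cross_block_mean_zero(self, small_dataset, small_matrices):
        rep = relationship_summary(small_matrices["A"], small_dataset["pedigree"].breed_of())
        row = rep[rep.block == "BB x TC"].iloc[0]
        assert row["mean"] == 0.0

    def test_genomic_cross_block_has_spread(self, small_dataset, small_matrices):
        rep = relationship_summary(small_matrices["G"], small_dataset["pedigree"].breed_of())
        row = rep[rep.block == "BB x TC"].iloc[0]
        assert row["sd"] > 0.0

    def test_single_breed_counts(self):
        V = np.eye(5) + 0.01
        m = RelationshipMatrix(ids=[f"a{i}" for i in range(5)], values=V, kind="genomic")
        rep = relationship_summary(m, pd.Series(["BB"] * 5, index=m.ids))
        within = rep[rep.block == "BB x BB"].iloc[0]
        assert within["n_pairs"] == 5 * 4 // 2
        assert not (rep.block.str.contains(" x ") & (rep.block != "BB x BB")).any()
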