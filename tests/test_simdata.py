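"""Synthetic-data generator: pedigree structure, gene drop, variance partition."""

import numpy as np
import pandas as pd
import pytest

from xbreed.kinship import ConfigurationError, Pedigree, build_grm, build_nrm
from xbreed.simdata import (
    FixedEffectSpec,
    SimConfig,
    simulate_dataset,
    simulate_genotypes,
    simulate_pedigree,
)

NO_FIXED = FixedEffectSpec(
    contemporary_group_sd=0.0, age_of_dam_sd=0.0, breed_composition_slope=0.0
)


class TestSimulatePedigree:
    def test_counts_and_disconnection(self):
        cfg = SimConfig(
            seed=1, n_sires=5, n_dams=50, n_offspring_cows=75, n_offspring_bulls=70,
            n_snps=10, n_qtl=5,
        )
        ped = simulate_pedigree(cfg)
        assert ped.n_animals == 2 * (55 + 145)
        t = ped.table
        # no cross-breed parentage
        breed_of = t.set_index("animal")["breed"]
        for col in ("sire", "dam"):
            known = t[t[col] != "0"]
            assert (breed_of[known[col]].to_numpy() == known["breed"].to_numpy()).all()
        # cows calibrate, their sons validate
        bulls = t[t.role == "validation"]
        cows = set(t.loc[t.role == "calibration", "animal"])
        assert set(bulls["dam"]) <= cows

    def test_pedigree_relationship_across_breeds_is_zero(self):
        cfg = SimConfig(
            seed=2, n_sires=4, n_dams=20, n_offspring_cows=40, n_offspring_bulls=30,
            n_snps=10, n_qtl=5,
        )
        A = build_nrm(simulate_pedigree(cfg))
        lab = np.array([str(a)[:2] for a in A.ids])
        assert np.abs(A.values[np.ix_(lab == "BB", lab == "TC")]).max() == 0.0

    def test_sons_per_dam_respects_litter_limit(self):
        cfg = SimConfig(
            seed=3, n_sires=5, n_dams=40, n_offspring_cows=100, n_offspring_bulls=90,
            n_snps=10, n_qtl=5, litter_limit=3,
        )
        t = simulate_pedigree(cfg).table
        sons = t[t.role == "validation"].groupby("dam").size()
        assert sons.max() <= 3 and sons.min() >= 1
        assert 1.0 <= sons.mean() <= 3.0

    def test_infeasible_design_raises(self):
        with pytest.raises(ConfigurationError, match="litter"):
            SimConfig(
                seed=1, n_sires=5, n_dams=10, n_offspring_cows=100,
                n_offspring_bulls=10, n_snps=10, n_qtl=5, litter_limit=2,
            )


class TestSimulateGenotypes:
    def test_no_divergence_limit(self):
        # fst = 0 with a large founder generation: breed frequencies coincide
        cfg = SimConfig(
            seed=4, n_sires=2000, n_dams=3000, n_offspring_cows=1, n_offspring_bulls=1,
            n_snps=150, n_qtl=10, fst_divergence=0.0,
        )
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        breed = ped.table.set_index("animal")["breed"]
        lab = np.array([breed[a] for a in geno.ids])
        p_bb = geno.codes[lab == "BB"].mean(axis=0) / 2
        p_tc = geno.codes[lab == "TC"].mean(axis=0) / 2
        assert np.abs(p_bb - p_tc).mean() < 0.02

    def test_divergence_separates_frequencies(self, small_dataset):
        geno = small_dataset["genotypes"]
        breed = small_dataset["pedigree"].breed_of()
        lab = np.array([breed[a] for a in geno.ids])
        p_bb = geno.codes[lab == "BB"].mean(axis=0) / 2
        p_tc = geno.codes[lab == "TC"].mean(axis=0) / 2
        assert np.abs(p_bb - p_tc).mean() > 0.05  # fst 0.10 default

    def test_mendelian_consistency(self, small_dataset):
        ped = small_dataset["pedigree"]
        geno = small_dataset["genotypes"]
        codes = geno.codes[geno.animal_indexer(ped.animals)]
        parents = ped.parent_indices()
        rng = np.random.default_rng(0)
        for i in rng.choice(ped.n_animals, size=60, replace=False):
            s, d = parents[i]
            if s < 0 or d < 0:
                continue
            c, gs, gd = codes[i], codes[s], codes[d]
            lo = (gs == 2).astype(int) + (gd == 2).astype(int)
            hi = 2 - (gs == 0).astype(int) - (gd == 0).astype(int)
            assert ((c >= lo) & (c <= hi)).all()

    def test_full_sib_genomic_relationship_near_half(self):
        # 600 founder pairs, two full sibs each: unblended GRM averages 0.5
        rows = []
        for k in range(600):
            rows += [
                (f"S{k}", "0", "0", "BB", "M"),
                (f"D{k}", "0", "0", "BB", "F"),
                (f"O{k}a", f"S{k}", f"D{k}", "BB", "F"),
                (f"O{k}b", f"S{k}", f"D{k}", "BB", "M"),
            ]
        ped = Pedigree(pd.DataFrame(rows, columns=["animal", "sire", "dam", "breed", "sex"]))
        cfg = SimConfig(
            seed=8, n_sires=2, n_dams=2, n_offspring_cows=2, n_offspring_bulls=1,
            n_snps=2000, n_qtl=10,
        )
        geno = simulate_genotypes(ped, cfg)
        G = build_grm(geno, blend=1.0)
        pos = pd.Index(list(G.ids))
        ia = pos.get_indexer([f"O{k}a" for k in range(600)])
        ib = pos.get_indexer([f"O{k}b" for k in range(600)])
        sib_rel = G.values[ia, ib]
        assert abs(sib_rel.mean() - 0.5) < 0.05


class TestEffectsAndPhenotypes:
    def test_degenerate_perfect_correlation(self):
        cfg = SimConfig(
            seed=5, n_sires=4, n_dams=20, n_offspring_cows=40, n_offspring_bulls=10,
            n_snps=300, n_qtl=200, rho_qtl=1.0, fst_divergence=0.0,
        )
        *_, truth = simulate_dataset(cfg)
        assert truth.realized_rho == pytest.approx(1.0, abs=1e-9)

    def test_independent_effects_near_zero_correlation(self):
        cfg = SimConfig(
            seed=6, n_sires=4, n_dams=20, n_offspring_cows=40, n_offspring_bulls=10,
            n_snps=600, n_qtl=500, rho_qtl=0.0,
        )
        *_, truth = simulate_dataset(cfg)
        assert abs(truth.realized_rho) < 0.1

    def test_variance_partition_slope_and_r2(self):
        cfg = SimConfig(
            seed=7, n_sires=20, n_dams=300, n_offspring_cows=1000, n_offspring_bulls=1,
            n_snps=800, n_qtl=200, h2_marked=0.5, h2_polygenic=0.0,
            fixed_effects=NO_FIXED,
        )
        ped, geno, pheno, truth = simulate_dataset(cfg)
        cows = pheno[(pheno.role == "calibration") & (pheno.breed == "BB")]
        y = cows["trait"].to_numpy()
        g = truth.marked_breeding_values.loc[cows["animal"], "F"].to_numpy()
        slope = np.cov(y, g, ddof=1)[0, 1] / np.var(g, ddof=1)
        r2 = np.corrcoef(y, g)[0, 1] ** 2
        assert slope == pytest.approx(1.0, abs=0.05)
        assert r2 == pytest.approx(0.5, abs=0.05)

    def test_sex_specific_values_correlate_at_rg(self):
        cfg = SimConfig(
            seed=9, n_sires=10, n_dams=100, n_offspring_cows=300, n_offspring_bulls=150,
            n_snps=500, n_qtl=400, rg_sexes=0.6, h2_polygenic=0.0,
        )
        *_, truth = simulate_dataset(cfg)
        # within one breed: pooling breeds would mix in the between-breed
        # difference of breeding-value means and attenuate the correlation
        tbv = truth.marked_breeding_values
        bb = [a for a in tbv.index if str(a).startswith("BB")]
        r = np.corrcoef(tbv.loc[bb, "F"], tbv.loc[bb, "M"])[0, 1]
        assert r == pytest.approx(0.6, abs=0.1)

    def test_infeasible_partition_rejected(self):
        with pytest.raises(ConfigurationError, match="h2"):
            SimConfig(seed=1, h2_marked=0.7, h2_polygenic=0.4)

    def test_truth_variances_match_partition(self, small_dataset):
        truth = small_dataset["truth"]
        cfg = small_dataset["config"]
        pheno = small_dataset["phenotypes"]
        tbv = truth.true_breeding_values.loc[
            pheno.loc[pheno.breed == "BB", "animal"], "F"
        ]
        total = cfg.h2_marked + cfg.h2_polygenic
        assert np.var(tbv, ddof=1) == pytest.approx(total, rel=0.25)


class TestDeterminism:
    def test_identical_seed_bit_identical_outputs(self):
        cfg = SimConfig(
            seed=12, n_sires=4, n_dams=20, n_offspring_cows=50, n_offspring_bulls=30,
            n_snps=200, n_qtl=50,
        )
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(a[0].table, b[0].table)
        np.testing.assert_array_equal(a[1].codes, b[1].codes)
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_different_seeds_differ(self):
        kw = dict(
            n_sires=4, n_dams=20, n_offspring_cows=50, n_offspring_bulls=30,
            n_snps=200, n_qtl=50,
        )
        a = simulate_dataset(SimConfig(seed=12, **kw))
        b = simulate_dataset(SimConfig(seed=13, **kw))
        assert not np.array_equal(a[1].codes, b[1].codes)


class TestCrossBreedGenomicConnection:
    def test_grm_cross_block_varies_while_nrm_is_null(self, small_dataset, small_matrices):
        breed = small_dataset["pedigree"].breed_of()
        G = small_matrices["G"]
        lab = np.array([breed[a] for a in G.ids])
        cross = G.values[np.ix_(lab == "BB", lab == "TC")]
        assert cross.std() > 0.0
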