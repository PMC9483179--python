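"""Synthetic population generator: structure, determinism, planted truth."""

import numpy as np
import pandas as pd
import pytest

from lactgwas.genotypes import read_vcf
from lactgwas.pedigree import UNKNOWN, nrm
from lactgwas.simdata import (
    SimConfig,
    simulate_dataset,
    simulate_genotypes,
    simulate_pedigree,
    simulate_rr_coefficients,
    simulate_test_day_records,
    write_dataset,
    read_phenotypes,
)


def cfg_small(**kw):
    defaults = dict(n_founders=20, n_generations=2, offspring_per_dam=2,
                    basis_order=1, n_snps=50, n_qtl=0, seed=1)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfigValidation:
    def test_psd_required(self):
        with pytest.raises(ValueError, match="G_true"):
            SimConfig(basis_order=1, G_true=np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_schedule_must_increase_in_range(self):
        with pytest.raises(ValueError):
            SimConfig(test_day_schedule=(50, 40))
        with pytest.raises(ValueError):
            SimConfig(test_day_schedule=(2, 40))

    def test_qtl_bounded_by_snps(self):
        with pytest.raises(ValueError):
            SimConfig(n_snps=5, n_qtl=6)

    def test_maf_range_checked(self):
        with pytest.raises(ValueError):
            SimConfig(maf_range=(0.0, 0.5))


class TestPedigree:
    def test_founders_only(self):
        ped = simulate_pedigree(cfg_small(n_founders=10, n_generations=0))
        assert len(ped) == 10
        assert (ped.entries["sire_id"] == UNKNOWN).all()

    def test_deterministic(self):
        p1 = simulate_pedigree(cfg_small())
        p2 = simulate_pedigree(cfg_small())
        pd.testing.assert_frame_equal(p1.entries, p2.entries)

    def test_animal_count_matches_mating_design(self):
        # 20 founders -> 10 dams; gen1: 10*2=20 offspring (10 F);
        # gen2: 10 dams * 2 = 20.  Hand count: 20+20+20 = 60.
        cfg = cfg_small(n_founders=20, n_generations=2, offspring_per_dam=2)
        assert len(simulate_pedigree(cfg)) == 60

    def test_impossible_mating_design_errors(self):
        # offspring_per_dam=1 with alternating sexes yields all-male
        # generations, so generation 2 has no dams
        cfg = cfg_small(n_founders=6, n_generations=2, offspring_per_dam=1)
        with pytest.raises(ValueError, match="mating design"):
            simulate_pedigree(cfg)


class TestGenotypes:
    def test_founder_frequencies_in_binomial_bounds(self):
        cfg = cfg_small(n_founders=400, n_generations=0, n_snps=1000,
                        maf_range=(0.3, 0.5))
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        freq = g.dosages.mean(axis=0) / 2
        # each SNP's sample frequency within 5 binomial SDs of its draw range
        se = np.sqrt(0.5 * 0.5 / (2 * 400))
        assert freq.min() > 0.3 - 5 * se
        assert freq.max() < 0.5 + 5 * se

    def test_mendelian_consistency(self):
        cfg = cfg_small(n_snps=300)
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        par = ped.parent_indices()
        D = g.dosages
        for i in range(len(ped)):
            s, d = par[i]
            if s < 0:
                continue
            # homozygous-alt parent passes at least one alt allele
            assert (D[i][D[s] == 2] >= 1).all()
            assert (D[i][D[d] == 2] >= 1).all()

    def test_parent_offspring_genomic_relationship(self):
        from lactgwas.gwas import grm_vanraden

        cfg = cfg_small(n_founders=60, n_generations=1, offspring_per_dam=2,
                        n_snps=2000)
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        G = grm_vanraden(g)
        par = ped.parent_indices()
        rel = [G[i, par[i, 0]] for i in range(len(ped)) if par[i, 0] >= 0]
        assert np.mean(rel) == pytest.approx(0.5, abs=0.05)

    def test_deterministic(self):
        cfg = cfg_small()
        ped = simulate_pedigree(cfg)
        g1 = simulate_genotypes(ped, cfg)
        g2 = simulate_genotypes(ped, cfg)
        assert np.array_equal(g1.dosages, g2.dosages)


class TestCoefficients:
    def test_zero_G_zero_coefficients(self):
        k2 = np.zeros((2, 2))
        cfg = cfg_small(G_true=k2, P_true=np.eye(2), sigma_e2_true=1.0)
        ped = simulate_pedigree(cfg)
        truth = simulate_rr_coefficients(ped, cfg)
        assert np.allclose(truth.a_coef, 0.0)

    def test_founder_coefficient_covariance(self):
        G = np.diag([4.0, 1.0])
        cfg = cfg_small(n_founders=4000, n_generations=0, G_true=G,
                        P_true=np.eye(2), seed=5)
        ped = simulate_pedigree(cfg)
        truth = simulate_rr_coefficients(ped, cfg)
        S = np.cov(truth.a_coef.T)
        assert np.allclose(S, G, atol=0.25)

    def test_twin_like_pair_correlation(self):
        # repeated draws for a parent-offspring pair: correlation 0.5 across
        # replicates; a full A-matrix entry of 1 would give 1
        cfg = cfg_small(n_founders=2, n_generations=1, offspring_per_dam=2,
                        G_true=np.eye(2), P_true=np.eye(2))
        ped = simulate_pedigree(cfg)
        A = nrm(ped).values
        vals = []
        for s in range(600):
            c = cfg_small(n_founders=2, n_generations=1, offspring_per_dam=2,
                          G_true=np.eye(2), P_true=np.eye(2), seed=s)
            t = simulate_rr_coefficients(ped, c)
            vals.append(t.a_coef[[0, 2], 0])
        vals = np.array(vals)
        r = np.corrcoef(vals.T)[0, 1]
        assert r == pytest.approx(A[0, 2], abs=0.12)

    def test_qtl_variance_planted(self):
        cfg = cfg_small(n_founders=3000, n_generations=0, n_snps=100, n_qtl=10,
                        qtl_var_fraction=0.4, G_true=np.diag([6.0, 1.0]),
                        P_true=np.eye(2), seed=7)
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        truth = simulate_rr_coefficients(ped, cfg, g)
        assert len(truth.qtl_positions) == 10
        # total intercept variance still ~ G00
        assert truth.a_coef[:, 0].var() == pytest.approx(6.0, rel=0.15)
        # QTL content explains the requested fraction
        M = g.dosages[:, truth.qtl_positions]
        qtl_part = (M - M.mean(axis=0)) @ truth.qtl_effects[:, 0]
        assert qtl_part.var() == pytest.approx(0.4 * 6.0, rel=0.2)


class TestRecords:
    def test_all_zero_when_everything_zero(self):
        k2 = np.zeros((2, 2))
        cfg = cfg_small(G_true=k2, P_true=k2, sigma_e2_true=1e-300,
                        fixed_effect_spec={"htd_sd": 0, "age_sd": 0, "season_sd": 0},
                        trait_means={"my_kg": 0, "fp_pct": 0, "pp_pct": 0, "scs": 0},
                        clip_traits=False)
        rec, *_ = simulate_dataset(cfg)
        assert np.allclose(rec["my_kg"], 0.0, atol=1e-12)

    def test_construction_identity_without_noise(self):
        cfg = cfg_small(sigma_e2_true=1e-300, htd_mode="exact",
                        fixed_effect_spec={"htd_sd": 0, "age_sd": 0, "season_sd": 0},
                        trait_means={"my_kg": 0, "fp_pct": 0, "pp_pct": 0, "scs": 0},
                        clip_traits=False)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        truth = simulate_rr_coefficients(ped, cfg, geno)
        rec = simulate_test_day_records(truth, ped, cfg)
        basis = cfg.basis
        pos = {a: i for i, a in enumerate(truth.animal_ids)}
        cpos = {c: i for i, c in enumerate(truth.cow_ids)}
        for row in rec.itertuples(index=False):
            phi = basis.row(row.dim)
            expect = phi @ (truth.a_coef[pos[row.cow_id]]
                            + truth.p_coef[cpos[row.cow_id]])
            assert row.my_kg == pytest.approx(expect, abs=1e-9)

    def test_phenotypic_variance_decomposition(self):
        G = np.diag([6.0, 1.0])
        P = np.diag([10.0, 2.0])
        cfg = cfg_small(n_founders=500, n_generations=1, offspring_per_dam=2,
                        G_true=G, P_true=P, sigma_e2_true=5.0, htd_mode="exact",
                        fixed_effect_spec={"htd_sd": 0, "age_sd": 0, "season_sd": 0},
                        trait_means={"my_kg": 0, "fp_pct": 0, "pp_pct": 0, "scs": 0},
                        clip_traits=False, seed=9)
        rec, ped, geno, truth = simulate_dataset(cfg)
        basis = cfg.basis
        for dim in (20, 140, 285):
            sub = rec[rec["dim"] == dim]["my_kg"]
            phi = basis.row(dim)
            expect = phi @ G @ phi + phi @ P @ phi + 5.0
            assert sub.var() == pytest.approx(expect, rel=0.2)

    def test_out_of_range_emission(self):
        cfg = cfg_small(out_of_range_fraction=0.1)
        rec, *_ = simulate_dataset(cfg)
        assert (rec["dim"] > 305).any()

    def test_fy_py_follow_product_formulas(self):
        rec, *_ = simulate_dataset(cfg_small())
        fy = rec["fp_pct"] * rec["my_kg"] / 100
        assert np.allclose(rec["fy_kg"], fy, atol=0.05)


class TestWriteDataset(object):
    def test_round_trip(self, tmp_path):
        rec, ped, geno, truth = simulate_dataset(cfg_small())
        paths = write_dataset(rec, ped, geno, truth, tmp_path)
        back = read_phenotypes(paths["phenotypes"])
        assert len(back) == len(rec)
        assert np.allclose(back["my_kg"], rec["my_kg"])
        assert list(back["test_date"]) == list(rec["test_date"])
        ped2 = pd.read_csv(paths["pedigree"])
        assert len(ped2) == len(ped)

    def test_vcf_format_and_round_trip(self, tmp_path):
        rec, ped, geno, truth = simulate_dataset(cfg_small())
        paths = write_dataset(rec, ped, geno, truth, tmp_path)
        text = open(paths["genotypes"]).read()
        assert text.startswith("##fileformat=VCFv4.2")
        for c in geno.variants["chrom"].unique():
            assert f"##contig=<ID={c}>" in text
        back = read_vcf(paths["genotypes"])
        assert back.samples == geno.samples
        assert np.array_equal(back.dosages, geno.dosages)
        assert list(back.variants["pos"]) == list(geno.variants["pos"])

    def test_truth_rows_equal_phenotyped_cows(self, tmp_path):
        rec, ped, geno, truth = simulate_dataset(cfg_small())
        paths = write_dataset(rec, ped, geno, truth, tmp_path)
        tdf = pd.read_csv(paths["truth"], sep="\t")
        assert len(tdf) == len(truth.cow_ids)
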