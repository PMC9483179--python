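"""Random-regression model: MME assembly, REML behavior, DIM summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest

from lactgwas.basis import LegendreBasis
from lactgwas.pedigree import nrm, trace_and_sort
from lactgwas.rrm import (
    RandomRegressionModel,
    VarianceComponents,
    build_mme,
    ebv_at_dim,
    genetic_correlation,
    genetic_correlation_grid,
    heritability_curve,
    reml_fit,
    variance_at,
)
from lactgwas.simdata import SimConfig, simulate_dataset


def small_dataset(seed=3, order=1, **kw):
    defaults = dict(n_founders=30, n_generations=2, basis_order=order,
                    n_snps=10, n_qtl=0, seed=seed)
    defaults.update(kw)
    cfg = SimConfig(**defaults)
    rec, ped, _, truth = simulate_dataset(cfg)
    rec["value"] = rec["my_kg"]
    return rec, ped, truth, cfg


@pytest.fixture(scope="module")
def basis1():
    return LegendreBasis(order=1)


class TestVarianceSummaries:
    def setup_method(self):
        self.basis = LegendreBasis(order=2)
        G = np.array([[4.0, 1.0, 0.2], [1.0, 2.0, 0.1], [0.2, 0.1, 0.5]])
        P = np.eye(3) * 2.0
        self.comp = VarianceComponents(G, P, 3.0)

    def test_zero_G_zero_additive(self):
        comp = VarianceComponents(np.zeros((3, 3)), np.eye(3), 1.0)
        for dim in (5, 100, 305):
            v_a, _, _ = variance_at(comp, self.basis, dim)
            assert v_a == 0.0

    def test_order0_constant_over_dim(self):
        b = LegendreBasis(order=0)
        comp = VarianceComponents([[4.0]], [[2.0]], 1.0)
        vals = [variance_at(comp, b, d)[0] for d in (5, 100, 200, 305)]
        assert np.allclose(vals, vals[0])
        assert vals[0] == pytest.approx(4.0 * 0.5)  # phi0^2 = 1/2

    def test_phenotypic_dominates_additive(self):
        for dim in (5, 50, 150, 305):
            v_a, _, v_p = variance_at(self.comp, self.basis, dim)
            assert v_p >= v_a

    def test_heritability_bounds_and_zero(self):
        h = heritability_curve(self.comp, self.basis, (7, 35, 50, 140, 280))
        assert ((h >= 0) & (h <= 1)).all()
        comp0 = VarianceComponents(np.zeros((3, 3)), np.eye(3), 1.0)
        assert (heritability_curve(comp0, self.basis).to_numpy() == 0).all()

    def test_heritability_limit_one(self):
        comp = VarianceComponents(np.eye(3) * 5, np.eye(3) * 1e-12, 1e-10)
        h = heritability_curve(comp, self.basis)
        assert (h > 0.999).all()

    def test_correlation_identity_and_symmetry(self):
        assert genetic_correlation(self.comp, self.basis, 50, 50) == pytest.approx(1.0)
        r1 = genetic_correlation(self.comp, self.basis, 20, 250)
        r2 = genetic_correlation(self.comp, self.basis, 250, 20)
        assert r1 == pytest.approx(r2)

    def test_rank_one_G_perfect_correlation(self):
        v = np.array([2.0, 0.5, -0.3])
        comp = VarianceComponents(np.outer(v, v), np.eye(3), 1.0)
        for d1, d2 in [(5, 305), (35, 140), (7, 280)]:
            assert abs(genetic_correlation(comp, self.basis, d1, d2)) == pytest.approx(1.0)

    def test_correlation_grid_is_valid_correlation_matrix(self):
        R = genetic_correlation_grid(self.comp, self.basis).to_numpy()
        assert np.allclose(np.diag(R), 1.0)
        assert np.linalg.eigvalsh(R).min() > -1e-10


class TestBuildMME:
    def test_matches_dense_gls_oracle(self, basis1):
        rec, ped, _, _ = small_dataset()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sys_ = build_mme(rec, ped, basis1, on_singular="drop")
        comp = VarianceComponents(np.diag([4.0, 1.0]), np.diag([6.0, 2.0]), 5.0)
        sol = sys_.solve(comp)
        A = nrm(trace_and_sort(ped.entries[sys_.kept_mask])).values
        X = sys_.X
        Za, Zp = sys_.Za.toarray(), sys_.Zp.toarray()
        V = (Za @ np.kron(A, comp.G) @ Za.T
             + Zp @ np.kron(np.eye(sys_.n_cows), comp.P) @ Zp.T
             + comp.sigma_e2 * np.eye(sys_.N))
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ sys_.y)
        a_blup = np.kron(A, comp.G) @ Za.T @ Vi @ (sys_.y - X @ beta)
        assert np.allclose(sol["beta"], beta, atol=1e-8)
        assert np.allclose(sol["a_hat"].ravel(), a_blup, atol=1e-8)

    def test_duplicated_records_equal_double_weight(self, basis1):
        rec, ped, _, _ = small_dataset()
        dup = pd.concat([rec, rec.iloc[:5]], ignore_index=True)
        comp = VarianceComponents(np.diag([4.0, 1.0]), np.diag([6.0, 2.0]), 5.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = build_mme(dup, ped, basis1, on_singular="drop").solve(comp)
            # same system built from weights: duplicating a row adds its
            # normal-equation contribution twice; verify against dense GLS
            sys_ = build_mme(dup, ped, basis1, on_singular="drop")
        A = nrm(trace_and_sort(ped.entries[sys_.kept_mask])).values
        X, Za, Zp = sys_.X, sys_.Za.toarray(), sys_.Zp.toarray()
        V = (Za @ np.kron(A, comp.G) @ Za.T
             + Zp @ np.kron(np.eye(sys_.n_cows), comp.P) @ Zp.T
             + comp.sigma_e2 * np.eye(sys_.N))
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ sys_.y)
        assert np.allclose(s1["beta"], beta, atol=1e-8)

    def test_confounded_levels_named(self, basis1):
        rec, ped, _, _ = small_dataset()
        rec = rec.copy()
        rec["clone"] = rec["htd"]  # perfectly aliased factor
        with pytest.raises(ValueError, match="confounded"):
            build_mme(rec, ped, basis1, factors=("htd", "clone"))

    def test_missing_cow_in_pedigree_rejected(self, basis1):
        rec, ped, _, _ = small_dataset()
        rec = rec.copy()
        rec.loc[0, "cow_id"] = 99999
        with pytest.raises(ValueError, match="missing from pedigree"):
            build_mme(rec, ped, basis1)


class TestREML:
    def test_em_loglik_monotone(self, basis1):
        rec, ped, _, _ = small_dataset(seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(rec, ped, basis1, tol=1e-8, max_iter=25, use_ai=False)
        assert np.all(np.diff(fit.loglik_path) >= -1e-7)

    def test_record_permutation_invariance(self, basis1):
        rec, ped, _, _ = small_dataset(seed=9)
        perm = rec.sample(frac=1.0, random_state=0).reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = reml_fit(rec, ped, basis1, tol=1e-6, max_iter=15)
            f2 = reml_fit(perm, ped, basis1, tol=1e-6, max_iter=15)
        assert np.allclose(f1.components.G, f2.components.G, atol=1e-8)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)

    def test_nonconvergence_flagged_not_raised(self, basis1):
        rec, ped, _, _ = small_dataset(seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(rec, ped, basis1, tol=1e-14, max_iter=2)
        assert fit.converged is False

    def test_pure_noise_gives_small_G_and_correct_residual(self):
        # truth: G = P = 0, sigma_e2 = 4, order 0
        cfg = SimConfig(n_founders=60, n_generations=1, offspring_per_dam=6,
                        basis_order=0, G_true=np.zeros((1, 1)),
                        P_true=np.zeros((1, 1)), sigma_e2_true=4.0,
                        n_snps=10, n_qtl=0,
                        fixed_effect_spec={"htd_sd": 0, "age_sd": 0, "season_sd": 0},
                        trait_means={"my_kg": 0.0}, clip_traits=False, seed=2)
        rec, ped, _, _ = simulate_dataset(cfg)
        rec["value"] = rec["my_kg"]
        rec["mu"] = "1"
        basis = LegendreBasis(order=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(rec, ped, basis, factors=("mu",), tol=1e-6, max_iter=60)
        n = len(rec)
        assert fit.components.sigma_e2 == pytest.approx(4.0, rel=0.15)
        assert fit.components.G[0, 0] * 0.5 < 0.4  # additive variance near zero
        assert fit.components.P[0, 0] * 0.5 < 0.4


class TestEBV:
    def test_zero_coefficients_zero_ebv(self, basis1):
        rec, ped, _, _ = small_dataset()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(rec, ped, basis1, tol=1e-4, max_iter=5)
        fit.a_hat[:] = 0.0
        for d in (5, 150, 305):
            assert ebv_at_dim(fit, basis1, fit.animal_ids[0], d) == 0.0

    def test_order0_ebv_constant_in_dim(self):
        rec, ped, _, _ = small_dataset(order=0)
        basis = LegendreBasis(order=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(rec, ped, basis, tol=1e-4, max_iter=5)
        a = fit.animal_ids[3]
        vals = [ebv_at_dim(fit, basis, a, d) for d in (5, 100, 305)]
        assert np.allclose(vals, vals[0])

    def test_unknown_animal_rejected(self, basis1):
        rec, ped, _, _ = small_dataset()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(rec, ped, basis1, tol=1e-4, max_iter=3)
        with pytest.raises(KeyError):
            ebv_at_dim(fit, basis1, -1, 100)

    def test_every_pedigree_animal_has_solution(self, basis1):
        rec, ped, _, _ = small_dataset()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(rec, ped, basis1, tol=1e-4, max_iter=3)
        assert fit.a_hat.shape[0] == len(ped)


class TestEstimator:
    def test_sklearn_interface(self):
        rec, ped, _, _ = small_dataset()
        model = RandomRegressionModel(basis_order=1, value_col="my_kg",
                                      tol=1e-4, max_iter=5)
        assert model.get_params()["basis_order"] == 1
        model.set_params(max_iter=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(rec, pedigree=ped)
        assert hasattr(model, "components_")
        assert model.a_hat_.shape[1] == 2
        h = model.heritability((50, 150))
        assert ((h >= 0) & (h <= 1)).all()

    def test_ebv_table_shape(self):
        rec, ped, _, _ = small_dataset()
        model = RandomRegressionModel(basis_order=1, value_col="my_kg",
                                      tol=1e-4, max_iter=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(rec, pedigree=ped)
        tab = model.ebv_table(dims=(7, 280))
        assert list(tab.columns) == ["animal_id", "ebv_dim7", "ebv_dim280"]
        assert len(tab) == len(ped)
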