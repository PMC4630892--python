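"""REML engine: oracle agreement, MME solutions, derived genetic parameters."""

import numpy as np
import pandas as pd
import pytest

from xbreed import SimConfig, build_nrm, simulate_dataset
from xbreed.kinship import RelationshipMatrix
from xbreed.mixedmodel import (
    IdentifiabilityError,
    ModelSpec,
    RandomTerm,
    VarianceComponents,
    genomic_correlation,
    missing_heritability,
    reml_fit,
    solve_mme,
)


def ll_trace_nondecreasing(vc: VarianceComponents) -> bool:
    t = vc.ll_trace
    return bool(np.all(np.diff(t) >= -1e-6 * np.maximum(1.0, np.abs(t[:-1]))))


def profile_grid_oracle(y, X, A, grid):
    """Independent restricted-likelihood oracle, profiled over total variance.

    For each h2 on the grid, V0 = h2 A + (1-h2) I; the total variance
    maximises in closed form and the profiled restricted log-likelihood
    is evaluated directly with slogdet/inv -- no code shared with the
    production engine.
    """
    n, p = X.shape
    out = []
    for h2 in grid:
        V0 = h2 * A + (1.0 - h2) * np.eye(n)
        V0inv = np.linalg.inv(V0)
        C = X.T @ V0inv @ X
        XtVy = X.T @ (V0inv @ y)
        P0y = V0inv @ y - V0inv @ X @ np.linalg.solve(C, XtVy)
        ypy = float(y @ P0y)
        s2 = ypy / (n - p)
        _, ld0 = np.linalg.slogdet(V0)
        _, ldC = np.linalg.slogdet(C)
        out.append(-0.5 * ((n - p) * (1.0 + np.log(s2)) + ld0 + ldC))
    return np.asarray(out)


def univariate_pedigree_data(seed, n_cows, h2, n_sires=12, n_dams=110):
    """One breed's cows from the generator, polygenic-only heritability h2."""
    cfg = SimConfig(
        seed=seed,
        n_sires=n_sires,
        n_dams=n_dams,
        n_offspring_cows=n_cows,
        n_offspring_bulls=1,
        n_snps=60,
        n_qtl=30,
        h2_marked=0.0,
        h2_polygenic=h2,
    )
    ped, geno, pheno, truth = simulate_dataset(cfg)
    A = build_nrm(ped)
    data = pheno[(pheno.breed == "BB") & (pheno.role == "calibration")]
    return data, A


UNI_FIXED = dict(factors=("contemporary_group", "age_of_dam"), covariates=("breed_composition",))


class TestRemlAgainstGridOracle:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_univariate_estimate_matches_grid_argmax(self, seed):
        data, A = univariate_pedigree_data(seed, n_cows=150, h2=0.5)
        spec = ModelSpec(
            response="trait",
            random_terms=(RandomTerm("pedigree", A, "diagonal"),),
            **UNI_FIXED,
        )
        vc = reml_fit(spec, data)
        h2_hat = vc.terms["pedigree"][0, 0] / (vc.terms["pedigree"][0, 0] + vc.residual[0])

        from xbreed.mixedmodel import build_design

        design = build_design(spec, data)
        a_idx = A.indexer(design["animals"])
        Asub = A.values[np.ix_(a_idx, a_idx)]
        grid = np.arange(0.01, 1.0, 0.01)
        ll = profile_grid_oracle(design["y"], design["X"], Asub, grid)
        h2_grid = grid[np.argmax(ll)]
        assert abs(h2_hat - h2_grid) <= 0.011
        # the engine's maximum cannot fall below the grid's
        assert vc.loglik >= ll.max() - 1e-4
        assert ll_trace_nondecreasing(vc)

    def test_pure_noise_estimates_at_floor(self):
        data, A = univariate_pedigree_data(9, n_cows=800, h2=0.0, n_dams=250)
        spec = ModelSpec(
            response="trait",
            random_terms=(RandomTerm("pedigree", A, "diagonal"),),
            **UNI_FIXED,
        )
        vc = reml_fit(spec, data)
        h2_hat = vc.terms["pedigree"][0, 0] / (vc.terms["pedigree"][0, 0] + vc.residual[0])
        assert h2_hat < 0.05


class TestSolveMme:
    def _toy(self):
        # one sire with two offspring (dams unknown), known components
        A = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.25], [0.5, 0.25, 1.0]])
        K = RelationshipMatrix(ids=["S", "O1", "O2"], values=A, kind="pedigree")
        data = pd.DataFrame(
            {"animal": ["S", "O1", "O2"], "trait": [1.0, 2.0, 3.0]}
        )
        spec = ModelSpec(response="trait", random_terms=(RandomTerm("pedigree", K, "diagonal"),))
        vc = VarianceComponents(
            traits=("trait",),
            terms={"pedigree": np.array([[0.4]])},
            residual=np.array([0.6]),
        )
        return A, data, spec, vc

    def test_matches_hand_built_henderson_equations(self):
        A, data, spec, vc = self._toy()
        sol = solve_mme(spec, data, vc)
        # independent route: assemble the 4x4 MME with A^-1 explicitly
        y = data["trait"].to_numpy()
        X = np.ones((3, 1))
        Z = np.eye(3)
        lam = 0.6 / 0.4
        lhs = np.block(
            [[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * np.linalg.inv(A)]]
        )
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        sol_hand = np.linalg.solve(lhs, rhs)
        assert sol.beta.iloc[0] == pytest.approx(sol_hand[0], abs=1e-10)
        np.testing.assert_allclose(
            sol.random["pedigree"]["trait"].to_numpy(), sol_hand[1:], atol=1e-10
        )

    def test_translation_invariance_of_predictions(self):
        A, data, spec, vc = self._toy()
        base = solve_mme(spec, data, vc).random["pedigree"]["trait"]
        shifted = data.assign(trait=data["trait"] + 100.0)
        moved = solve_mme(spec, shifted, vc).random["pedigree"]["trait"]
        np.testing.assert_allclose(moved.to_numpy(), base.to_numpy(), atol=1e-8)

    def test_zero_residual_limit_interpolates(self):
        A, data, spec, _ = self._toy()
        vc = VarianceComponents(
            traits=("trait",),
            terms={"pedigree": np.array([[1.0]])},
            residual=np.array([1e-6]),
        )
        sol = solve_mme(spec, data, vc)
        fitted = sol.fitted_fixed.to_numpy()
        adj = data["trait"].to_numpy() - fitted
        pred = sol.random["pedigree"]["trait"].to_numpy()
        np.testing.assert_allclose(pred, adj, rtol=1e-3)

    def test_masked_records_still_predicted(self):
        A, data, spec, vc = self._toy()
        masked = data.copy()
        masked.loc[masked.animal == "O2", "trait"] = np.nan
        sol = solve_mme(spec, masked, vc)
        assert "O2" in sol.random["pedigree"].index
        assert np.isfinite(sol.random["pedigree"].loc["O2", "trait"])


class TestModelStructure:
    def test_aliased_random_terms_rejected(self):
        A = RelationshipMatrix(ids=["a", "b"], values=np.eye(2), kind="pedigree")
        with pytest.raises(IdentifiabilityError):
            ModelSpec(
                response="y",
                random_terms=(RandomTerm("t1", A, "diagonal"), RandomTerm("t2", A, "diagonal")),
            )

    def test_free_cross_covariance_never_fits_worse(self, small_dataset, small_matrices):
        # the diagonal-structure fit is nested in the full-structure fit
        cows = small_dataset["phenotypes"].query("role == 'calibration'")
        common = dict(
            response="trait",
            trait_column="breed",
            traits=("BB", "TC"),
            **UNI_FIXED,
        )
        A, G = small_matrices["A"], small_matrices["G"]
        free = reml_fit(
            ModelSpec(random_terms=(RandomTerm("pedigree", A, "diagonal"),
                                    RandomTerm("genomic", G, "full")), **common),
            cows,
        )
        fixed0 = reml_fit(
            ModelSpec(random_terms=(RandomTerm("pedigree", A, "diagonal"),
                                    RandomTerm("genomic", G, "diagonal")), **common),
            cows,
        )
        assert free.loglik >= fixed0.loglik - 1e-6
        assert ll_trace_nondecreasing(free) and ll_trace_nondecreasing(fixed0)


class TestDerivedParameters:
    def _vc(self, genomic, pedigree=((0.2, 0.0), (0.0, 0.2)), floor=1e-8):
        return VarianceComponents(
            traits=("BB", "TC"),
            terms={
                "pedigree": np.asarray(pedigree, dtype=float),
                "genomic": np.asarray(genomic, dtype=float),
            },
            residual=np.array([0.4, 0.4]),
            variance_floor=np.array([floor, floor]),
        )

    def test_genomic_correlation_arithmetic(self):
        vc = self._vc([[0.8, 0.5], [0.5, 0.5]])
        assert genomic_correlation(vc) == pytest.approx(0.5 / np.sqrt(0.4), abs=1e-4)

    def test_zero_covariance_gives_zero(self):
        vc = self._vc([[0.8, 0.0], [0.0, 0.5]])
        assert genomic_correlation(vc) == 0.0

    def test_floored_variance_flagged_undefined(self):
        vc = self._vc([[1e-8, 0.0], [0.0, 0.5]])
        with pytest.warns(RuntimeWarning, match="floor"):
            assert np.isnan(genomic_correlation(vc))

    @pytest.mark.parametrize(
        "h2p, h2g, expected",
        [(0.18, 0.58, 0.24), (0.36, 0.39, 0.48), (0.0, 0.5, 0.0)],
    )
    def test_missing_heritability_fraction(self, h2p, h2g, expected):
        vc = self._vc(
            genomic=[[h2g if h2g else 1e-6, 0.0], [0.0, 0.5]],
            pedigree=[[h2p if h2p else 1e-7, 0.0], [0.0, 0.2]],
        )
        assert missing_heritability(vc, "BB") == pytest.approx(expected, abs=0.005)

    def test_all_genomic_variance_missing(self):
        vc = self._vc(genomic=[[1e-8, 0.0], [0.0, 0.5]], pedigree=[[0.3, 0.0], [0.0, 0.2]])
        assert missing_heritability(vc, "BB") == pytest.approx(1.0, abs=1e-4)

    def test_summary_invariants_on_fitted_study(self, small_study):
        for name, ps in small_study.parameters.items():
            t = ps.table
            assert ((t[["h2_P", "h2_G"]] >= 0).all().all()) and (
                (t[["h2_P", "h2_G"]] <= 1).all().all()
            )
            assert ((t["h2_P"] + t["h2_G"]) <= 1 + 1e-9).all()
            assert t["C_miss"].between(0, 1).all()
            assert -1.0 <= ps.r_G <= 1.0

    def test_every_study_fit_has_monotone_trace(self, small_study):
        for vc in small_study.components.values():
            assert ll_trace_nondecreasing(vc)
            assert vc.converged
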