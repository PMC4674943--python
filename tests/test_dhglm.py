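"""DHGLM building blocks and the iterative fit.

The single-iteration oracle assembles the weighted bivariate mixed model by
hand (dense matrices) and must agree with the engine; the full loop is
exercised on small simulated data against its generating parameters.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from vargwas.dhglm import (
    gcv_sde,
    h2_residual_variance,
    run_dhglm,
    update_weights,
    working_response,
)
from vargwas.errors import DomainError
from vargwas.mixed_model import (
    IDENTITY,
    PEDIGREE,
    ModelDesign,
    RandomEffect,
    VarianceComponents,
    solve_mme,
)
from vargwas.pedigree import Pedigree, build_relationship
from vargwas.simulate import PhenotypeParams, simulate_pedigree, simulate_phenotypes


class TestWorkingResponse:
    def test_identity_case(self):
        # e^2 = (1-h) s2 makes the correction vanish
        assert working_response(np.sqrt(0.9 * 4.0), 0.1, 4.0) == pytest.approx(np.log(4.0))

    def test_zero_residual(self):
        assert working_response(0.0, 0.2, 2.0) == pytest.approx(np.log(2.0) - 1.0)

    def test_arithmetic(self):
        assert working_response(np.sqrt(3.0), 0.0, 1.0) == pytest.approx(2.0)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            working_response(1.0, 1.0, 1.0)
        with pytest.raises(DomainError):
            working_response(1.0, 0.1, 0.0)


class TestWeights:
    @pytest.mark.parametrize("psi,expected", [(0.0, 1.0), (np.log(4.0), 0.25)])
    def test_mean_part_weight(self, psi, expected):
        w, _ = update_weights(psi, 0.3)
        assert w == pytest.approx(expected)

    def test_dispersion_weight(self):
        _, wv = update_weights(0.0, 0.0)
        assert wv == pytest.approx(0.5)


class TestDispersionSummaries:
    @pytest.mark.parametrize("av2,expected", [(0.03, 0.087), (0.0, 0.0), (0.04, 0.1)])
    def test_gcv_sde(self, av2, expected):
        assert gcv_sde(av2) == pytest.approx(expected, abs=5e-4)

    def test_gcv_rejects_negative(self):
        with pytest.raises(DomainError):
            gcv_sde(-0.01)

    def test_h2v_zero_numerator(self):
        assert h2_residual_variance(0.0, 0.1, 3.0) == 0.0

    def test_h2v_formula_value(self):
        # direct evaluation of av2 / (2 sigmaP^4 + 3 (av2 + pev2))
        assert h2_residual_variance(0.03, 0.15, 8.37) == pytest.approx(2.13e-4, rel=0.01)

    def test_h2v_monotone_in_genetic_variance(self):
        vals = [h2_residual_variance(a, 0.15, 8.37) for a in (0.01, 0.03, 0.1, 0.3)]
        assert np.all(np.diff(vals) > 0)


class TestSingleIterationOracle:
    def test_matches_hand_assembled_weighted_bivariate_fit(self):
        """One DHGLM inner fit on a 20-record toy equals the dense
        mixed-model solution assembled from scratch."""
        rng = np.random.default_rng(19)
        ped = Pedigree.from_records(
            [("s1", None, None), ("s2", None, None), ("d1", None, None), ("d2", None, None)]
            + [(f"c{k}", "s1" if k % 2 else "s2", "d1" if k < 3 else "d2", ) for k in range(5)]
        )
        sows = [f"c{k}" for k in range(5)]
        idx = {a: i for i, a in enumerate(ped.ids)}
        codes = np.array([idx[s] for s in np.repeat(sows, 4)])
        sow_codes = np.repeat(np.arange(5), 4)
        n = 20
        y = rng.normal(12, 2.5, n)
        psi = rng.normal(1.8, 1.0, n)
        w = rng.uniform(0.1, 0.4, n)
        wv = rng.uniform(0.3, 0.5, n)
        fixed = pd.DataFrame({"par": np.tile(["1", "2", "3", "4"], 5)})
        design = ModelDesign(
            response=np.column_stack([y, psi]),
            fixed=fixed,
            random=[
                RandomEffect("a", codes, len(ped), covariance=PEDIGREE, ped=ped),
                RandomEffect("pe", sow_codes, 5, covariance=IDENTITY),
            ],
            weights=np.column_stack([w, wv]),
        )
        Sa = np.array([[1.1, 0.2], [0.2, 0.06]])
        Sp = np.array([[0.6, -0.15], [-0.15, 0.12]])
        vc = VarianceComponents(residual=np.array([1.0, 1.0]), terms={"a": Sa, "pe": Sp})
        fit = solve_mme(design, vc)

        # dense oracle: C theta = W' R^-1 y with G^-1 = inv(S) kron inv(K)
        A = build_relationship(ped).values
        X = fit._problem.X.toarray()
        Za = np.zeros((n, len(ped)))
        Za[np.arange(n), codes] = 1
        Zp = np.zeros((n, 5))
        Zp[np.arange(n), sow_codes] = 1
        W1 = np.hstack([X, np.zeros_like(X), Za, np.zeros_like(Za), Zp, np.zeros_like(Zp)])
        W2 = np.hstack([np.zeros_like(X), X, np.zeros_like(Za), Za, np.zeros_like(Zp), Zp])
        Wfull = np.vstack([W1, W2])
        Rinv = np.diag(np.concatenate([w, wv]))
        Ginv = linalg.block_diag(
            np.zeros((2 * X.shape[1], 2 * X.shape[1])),
            np.kron(linalg.inv(Sa), linalg.inv(A)),
            np.kron(linalg.inv(Sp), np.eye(5)),
        )
        C = Wfull.T @ Rinv @ Wfull + Ginv
        rhs = Wfull.T @ Rinv @ np.concatenate([y, psi])
        theta = linalg.solve(C, rhs)

        p = X.shape[1]
        np.testing.assert_allclose(fit.fixed_effects(0).to_numpy(), theta[:p], atol=1e-8)
        np.testing.assert_allclose(fit.fixed_effects(1).to_numpy(), theta[p : 2 * p], atol=1e-8)
        np.testing.assert_allclose(fit.random_effects("a", 0).to_numpy(), theta[2 * p : 2 * p + len(ped)], atol=1e-8)
        np.testing.assert_allclose(
            fit.random_effects("pe", 1).to_numpy(), theta[2 * p + 2 * len(ped) + 5 :], atol=1e-8
        )


@pytest.fixture(scope="module")
def small_heterogeneous_run():
    """DHGLM on ~500 sows simulated with heterogeneous residual variance."""
    ped, info = simulate_pedigree(n_founders=115, n_generations=1, litters_per_dam=5, seed=23, male_fraction=0.13)
    sows = info.loc[info["generation"] == 1, "animal"]
    rec, truth = simulate_phenotypes(ped, PhenotypeParams(), parities_per_sow=5, seed=24, sows=sows)
    res = run_dhglm(rec, ped, compute_se=False, max_iter=60)
    return rec, ped, res, truth


class TestIterativeFit:
    def test_converges_with_sane_state(self, small_heterogeneous_run):
        _, _, res, _ = small_heterogeneous_run
        assert res.converged
        assert np.all(res.weights_mean > 0) and np.all(res.weights_dispersion > 0)
        assert np.all(res.predicted_resvar > 0)
        assert np.all((res.leverage >= 0) & (res.leverage < 1))

    def test_scaling_variances_near_one(self, small_heterogeneous_run):
        _, _, res, _ = small_heterogeneous_run
        assert np.all((res.scaling_variances() > 0.8) & (res.scaling_variances() < 1.2))

    def test_standardized_squared_residuals_calibrated(self, small_heterogeneous_run):
        _, _, res, _ = small_heterogeneous_run
        z = res.residuals**2 / ((1 - res.leverage) * res.predicted_resvar)
        assert 0.9 < z.mean() < 1.1

    def test_null_dispersion_variance_detected_as_null(self):
        """Data simulated homoscedastic: estimated genetic variance of the
        residual variance stays near zero."""
        ped, info = simulate_pedigree(n_founders=130, n_generations=1, litters_per_dam=5, seed=31, male_fraction=0.12)
        sows = info.loc[info["generation"] == 1, "animal"]
        params = PhenotypeParams(sigma_av2=1e-9, sigma_pev2=1e-9, r_a=0.0, r_pe=0.0)
        rec, _ = simulate_phenotypes(ped, params, parities_per_sow=5, seed=32, sows=sows)
        res = run_dhglm(rec, ped, compute_se=False, max_iter=60)
        assert res.sigma_av2 < 0.005

    def test_scale_equivariance_of_dispersion_intercept(self, small_heterogeneous_run):
        """Doubling all deviations from the mean multiplies residual
        variances by 4: the dispersion intercept shifts by log 4 and the
        genetic correlation is unchanged."""
        rec, ped, res, _ = small_heterogeneous_run
        rec2 = rec.copy()
        center = rec2["tnb"].mean()
        rec2["tnb"] = center + 2.0 * (rec2["tnb"] - center)
        res2 = run_dhglm(rec2, ped, compute_se=False, max_iter=60)
        shift = np.log(res2.predicted_resvar).mean() - np.log(res.predicted_resvar).mean()
        assert shift == pytest.approx(np.log(4.0), abs=0.1)
        assert res2.r_a == pytest.approx(res.r_a, abs=0.1)
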