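"""Mixed-model engine: MME solutions, leverages, REML, scalar helpers.

Dense generalized-least-squares and closed-form balanced-ANOVA estimators
serve as independent oracles for the sparse machinery.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from vargwas.errors import DomainError, RankDeficiencyError, ValidationError
from vargwas.mixed_model import (
    IDENTITY,
    PEDIGREE,
    ModelDesign,
    RandomEffect,
    VarianceComponents,
    covariance_from_correlation,
    estimate_reml,
    heritability,
    solve_mme,
)
from vargwas.pedigree import build_relationship
from vargwas.simulate import PhenotypeParams, simulate_pedigree, simulate_phenotypes


@pytest.fixture(scope="module")
def toy_animal_design(random_pedigree):
    """30 observations on 10 animals from a 50-animal pedigree, with
    weights and one fixed factor."""
    rng = np.random.default_rng(7)
    ped = random_pedigree
    animals = rng.choice(len(ped), 10, replace=False)
    codes = np.repeat(animals, 3)
    n = len(codes)
    fixed = pd.DataFrame({"batch": np.tile(["a", "b", "c"], n // 3)})
    y = rng.normal(12.0, 2.0, n)
    w = rng.uniform(0.5, 2.0, n)
    design = ModelDesign(
        response=y,
        fixed=fixed,
        random=[RandomEffect("animal", codes, len(ped), covariance=PEDIGREE, ped=ped)],
        weights=w,
    )
    return design, codes


class TestSolveMme:
    def test_intercept_only_leverage_is_one_over_n(self):
        n = 12
        design = ModelDesign(
            response=np.arange(n, dtype=float),
            fixed=pd.DataFrame(index=range(n)),
            random=[],
            weights=np.ones(n),
        )
        fit = solve_mme(design, VarianceComponents(residual=[3.0], terms={}))
        np.testing.assert_allclose(fit.leverage(0), np.full(n, 1 / n))
        assert fit.mme_residual_norm() < 1e-10

    def test_matches_dense_gls_oracle(self, toy_animal_design, random_pedigree):
        design, codes = toy_animal_design
        va, ve = 1.5, 4.0
        vc = VarianceComponents(residual=[ve], terms={"animal": [[va]]})
        fit = solve_mme(design, vc)

        A = build_relationship(random_pedigree).values
        n = design.n_obs
        Z = np.zeros((n, len(random_pedigree)))
        Z[np.arange(n), codes] = 1
        X = fit._problem.X.toarray()
        V = va * Z @ A @ Z.T + ve * np.diag(1.0 / design.weights[:, 0])
        Vi = linalg.inv(V)
        y = design.response[:, 0]
        beta = linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = va * A @ Z.T @ Vi @ (y - X @ beta)

        np.testing.assert_allclose(fit.fixed_effects(0).to_numpy(), beta, atol=1e-8)
        np.testing.assert_allclose(fit.random_effects("animal", 0).to_numpy(), u, atol=1e-8)

    def test_leverage_sums_to_effective_parameters(self, toy_animal_design, random_pedigree):
        """Sum of leverages equals the trace of the influence map, computed
        densely."""
        design, codes = toy_animal_design
        vc = VarianceComponents(residual=[4.0], terms={"animal": [[1.5]]})
        fit = solve_mme(design, vc)
        h = fit.leverage(0)
        assert np.all((h >= 0) & (h < 1))

        A = build_relationship(random_pedigree).values
        n = design.n_obs
        Z = np.zeros((n, len(random_pedigree)))
        Z[np.arange(n), codes] = 1
        X = fit._problem.X.toarray()
        V = 1.5 * Z @ A @ Z.T + 4.0 * np.diag(1.0 / design.weights[:, 0])
        Vi = linalg.inv(V)
        y = design.response[:, 0]
        R = 4.0 * np.diag(1.0 / design.weights[:, 0])
        # influence: dy_hat/dy = I - R P with P = Vi - Vi X (X'ViX)^-1 X'Vi
        P = Vi - Vi @ X @ linalg.solve(X.T @ Vi @ X, X.T @ Vi)
        H = np.eye(n) - R @ P
        np.testing.assert_allclose(h, np.diag(H), atol=1e-8)
        assert fit.effective_parameters() == pytest.approx(np.trace(H), abs=1e-6)

    def test_vanishing_genetic_variance_shrinks_ebv_to_zero(self, toy_animal_design):
        design, _ = toy_animal_design
        vc = VarianceComponents(residual=[4.0], terms={"animal": [[1e-8]]})
        fit = solve_mme(design, vc)
        assert np.abs(fit.random_effects("animal", 0)).max() < 1e-4

    def test_confounded_factors_raise(self):
        n = 10
        f = np.tile(["u", "v"], n // 2)
        design = ModelDesign(
            response=np.arange(n, dtype=float),
            fixed=pd.DataFrame({"f1": f, "f2": f}),
            random=[],
            weights=np.ones(n),
        )
        with pytest.raises(RankDeficiencyError, match="confounded"):
            solve_mme(design, VarianceComponents(residual=[1.0], terms={}))


class TestReml:
    def test_balanced_halfsib_matches_anova_closed_form(self):
        """On a balanced one-way design REML equals the ANOVA estimators
        MSW and (MSB - MSW)/n."""
        rng = np.random.default_rng(11)
        s, n = 40, 8
        sire_eff = rng.normal(0, np.sqrt(0.8), s)
        y = (sire_eff[:, None] + rng.normal(0, np.sqrt(3.0), (s, n))).ravel()
        codes = np.repeat(np.arange(s), n)
        design = ModelDesign(
            response=y,
            fixed=pd.DataFrame(index=range(s * n)),
            random=[RandomEffect("sire", codes, s, covariance=IDENTITY)],
            weights=np.ones(s * n),
        )
        start = VarianceComponents(residual=[2.0], terms={"sire": [[0.5]]})
        vc, _, _ = estimate_reml(design, start, compute_se=False, strict=False, polish=True)

        ybar = y.reshape(s, n).mean(axis=1)
        msb = n * np.var(ybar, ddof=1)
        msw = np.sum((y.reshape(s, n) - ybar[:, None]) ** 2) / (s * (n - 1))
        assert vc.residual[0] == pytest.approx(msw, rel=1e-6)
        assert vc.variance("sire") == pytest.approx((msb - msw) / n, rel=1e-6)

    def test_reordering_observations_leaves_estimates_unchanged(self, toy_animal_design):
        design, codes = toy_animal_design
        start = VarianceComponents(residual=[3.0], terms={"animal": [[1.0]]})
        vc1, _, _ = estimate_reml(design, start, compute_se=False, strict=False)
        perm = np.random.default_rng(3).permutation(design.n_obs)
        design2 = ModelDesign(
            response=design.response[perm, 0],
            fixed=design.fixed.iloc[perm].reset_index(drop=True),
            random=[RandomEffect("animal", codes[perm], design.random[0].n_levels, covariance=PEDIGREE, ped=design.random[0].ped)],
            weights=design.weights[perm, 0],
        )
        vc2, _, _ = estimate_reml(design2, start, compute_se=False, strict=False)
        assert vc1.variance("animal") == pytest.approx(vc2.variance("animal"), rel=1e-4)
        assert vc1.residual[0] == pytest.approx(vc2.residual[0], rel=1e-4)

    def test_recovers_simulated_components_within_2se(self):
        """Univariate repeatability animal model on ~900 sows with 5 litters
        each recovers the generating components."""
        ped, info = simulate_pedigree(n_founders=200, n_generations=1, litters_per_dam=5, seed=3, male_fraction=0.1)
        sows = info.loc[info["generation"] == 1, "animal"]
        params = PhenotypeParams(sigma_av2=1e-9, sigma_pev2=1e-9, r_a=0.0, r_pe=0.0)
        rec, _ = simulate_phenotypes(ped, params, parities_per_sow=5, seed=4, sows=sows)
        from vargwas.dhglm import _mean_design, _prepare

        y, fixed, ac, sc, sl = _prepare(rec, ped)
        design = _mean_design(y, fixed, ac, sc, sl, ped, np.ones_like(y))
        start = VarianceComponents(residual=[4.0], terms={"additive": [[0.5]], "pe": [[0.5]]})
        vc, _, _ = estimate_reml(design, start, compute_se=True, strict=False)
        for name, key, truth in [
            ("additive", "additive_var", 1.2),
            ("pe", "pe_var", 0.7),
        ]:
            est, se = vc.variance(name), vc.se[key]
            assert abs(est - truth) < 2 * se, f"{name}: {est} vs {truth} (se {se})"
        assert abs(vc.residual[0] - 6.5) < 2.5 * vc.se["residual_var"]

    def test_zero_variance_response_rejected(self):
        design = ModelDesign(
            response=np.ones(10),
            fixed=pd.DataFrame(index=range(10)),
            random=[],
            weights=np.ones(10),
        )
        with pytest.raises(ValidationError, match="zero empirical variance"):
            estimate_reml(design, VarianceComponents(residual=[1.0], terms={}))


class TestScalarHelpers:
    @pytest.mark.parametrize(
        "va,vpe,ve,expected",
        [(1.31, 0.87, 7.14, 0.14), (1.18, 0.69, 6.5, 0.14), (0.0, 0.5, 3.0, 0.0)],
    )
    def test_heritability(self, va, vpe, ve, expected):
        assert round(heritability(va, vpe, ve), 2) == pytest.approx(expected)

    def test_heritability_zero_total_undefined(self):
        with pytest.raises(DomainError):
            heritability(0.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "r,v1,v2,expected",
        [(-0.83, 0.69, 0.15, -0.27), (0.0, 5.0, 9.0, 0.0), (1.0, 4.0, 9.0, 6.0)],
    )
    def test_covariance_from_correlation(self, r, v1, v2, expected):
        assert covariance_from_correlation(r, v1, v2) == pytest.approx(expected, abs=0.005)

    def test_covariance_rejects_negative_variance(self):
        with pytest.raises(ValidationError):
            covariance_from_correlation(0.5, -1.0, 2.0)


class TestConventionalBivariate:
    """Sow-level weighted bivariate analysis of (mean TNB, log var TNB)."""

    @staticmethod
    def _simulate_summaries(seed, r_g=0.6, n_founders=160, litters_per_dam=5):
        from vargwas.mixed_model import fit_conventional_bivariate
        from vargwas.pedigree import mendelian_sampling_variance

        rng = np.random.default_rng(seed)
        ped, info = simulate_pedigree(
            n_founders=n_founders, n_generations=1, litters_per_dam=litters_per_dam,
            seed=seed, male_fraction=0.12,
        )
        sows = info.loc[info["generation"] == 1, "animal"].tolist()
        idx = {a: i for i, a in enumerate(ped.ids)}
        Sa = np.array([[1.2, r_g * np.sqrt(1.2 * 0.05)], [r_g * np.sqrt(1.2 * 0.05), 0.05]])
        d = mendelian_sampling_variance(ped)
        L = np.linalg.cholesky(Sa + 1e-12 * np.eye(2))
        u = np.empty((len(ped), 2))
        z = rng.standard_normal((len(ped), 2))
        for i in range(len(ped)):
            pa = np.zeros(2)
            for p in (ped.sire[i], ped.dam[i]):
                if p >= 0:
                    pa += 0.5 * u[p]
            u[i] = pa + np.sqrt(d[i]) * (L @ z[i])
        n_lit = rng.integers(3, 9, len(sows))
        fys = rng.integers(0, 10, len(sows))
        e1 = rng.normal(0, np.sqrt(8.0 / n_lit))
        e2 = rng.normal(0, np.sqrt(2.0 / ((n_lit - 1) / 2)))
        rows = pd.DataFrame(
            {
                "sow": sows,
                "n_litters": n_lit,
                "mean_tnb": 13.5 + u[[idx[s] for s in sows], 0] + e1,
                "log_var_tnb": 1.8 + u[[idx[s] for s in sows], 1] + e2,
                "fys": [f"f{k}" for k in fys],
            }
        )
        return rows, ped

    def test_recovers_genetic_correlation(self):
        from vargwas.mixed_model import fit_conventional_bivariate

        summaries, ped = self._simulate_summaries(seed=71, r_g=0.6)
        vc, _ = fit_conventional_bivariate(summaries, ped, compute_se=True)
        r = vc.correlation("additive")
        se = vc.se.get("additive_corr", 0.3)
        assert abs(r - 0.6) < 2 * max(se, 0.05), f"r_g {r} (se {se})"
        assert abs(vc.variance("additive", 0) - 1.2) < 2 * max(vc.se["additive_var_1"], 0.05)

    def test_null_genetic_covariance(self):
        from vargwas.mixed_model import fit_conventional_bivariate

        summaries, ped = self._simulate_summaries(seed=73, r_g=0.0)
        vc, _ = fit_conventional_bivariate(summaries, ped, compute_se=True)
        r = vc.correlation("additive")
        assert abs(r) < 2 * max(vc.se.get("additive_corr", 0.3), 0.1)

    def test_requires_three_litters(self):
        summaries, ped = self._simulate_summaries(seed=75)
        summaries.loc[0, "n_litters"] = 2
        from vargwas.mixed_model import fit_conventional_bivariate

        with pytest.raises(ValidationError):
            fit_conventional_bivariate(summaries, ped)
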