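"""Iterative double hierarchical GLM for a trait's mean and residual variance.

The DHGLM couples two linear mixed models over the same litter records:

* mean part:        y_ij = x_ij' b + a_i + pe_i + e_ij
* dispersion part:  psi_ij = x_ij' b_v + a_v,i + pe_v,i + e_v,ij

where psi is a first-order linearization of log(e^2/(1-h)), the log of the
squared level-part residual corrected for leverage,

    psi_i = log(s2_i) + (e_i^2/(1-h_i) - s2_i) / s2_i ,

with s2_i the residual variance predicted for observation i from the
previous iteration's dispersion effects, s2_i = exp(x'b_v + a_v + pe_v).
The additive pairs (a, a_v) are jointly normal with a 2x2 covariance matrix
kronecker the pedigree A, and the permanent sow pairs (pe, pe_v) with a 2x2
matrix kronecker identity, so the model estimates the genetic (r_a) and
permanent-environment (r_pe) correlations between the trait's level and the
log of its residual variance.  Residuals of the two parts are taken
independent; mean-part observations get weight w = exp(psi_hat)^-1 and
dispersion-part observations w_v = (1-h)/2 (the reciprocals of the
approximate sampling variances), with two residual scaling variances that
should both converge to ~1.

The algorithm alternates a weighted bivariate REML fit of (y, psi) with the
recomputation of residuals, leverages, predicted variances, psi and weights,
until every variance component is stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vargwas.errors import ConvergenceError, DomainError, ValidationError
from vargwas.mixed_model import (
    IDENTITY,
    PEDIGREE,
    MixedModelFit,
    ModelDesign,
    RandomEffect,
    VarianceComponents,
    estimate_reml,
)
from vargwas.pedigree import Pedigree

log = logging.getLogger(__name__)

MEAN_TRAIT = "mean"
DISPERSION_TRAIT = "dispersion"


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------
def working_response(e, h, s2):
    """Linearized log residual variance, the dispersion-part response.

    psi = log(s2) + (e^2/(1-h) - s2)/s2.  ``e`` are mean-part residuals,
    ``h`` their leverages in [0, 1) and ``s2`` the predicted residual
    variances (> 0).
    """
    e = np.asarray(e, float)
    h = np.asarray(h, float)
    s2 = np.asarray(s2, float)
    if np.any((h < 0) | (h >= 1)):
        raise DomainError("leverage must lie in [0, 1)")
    if np.any(s2 <= 0):
        raise DomainError("predicted residual variance must be positive")
    return np.log(s2) + (e**2 / (1.0 - h) - s2) / s2


def update_weights(psi_hat, h):
    """Weights for the next iteration: w = exp(psi_hat)^-1 for the mean part
    and w_v = (1-h)/2 for the dispersion part."""
    psi_hat = np.asarray(psi_hat, float)
    h = np.asarray(h, float)
    if np.any((h < 0) | (h >= 1)):
        raise DomainError("leverage must lie in [0, 1)")
    return np.exp(-psi_hat), (1.0 - h) / 2.0


def gcv_sde(sigma_av2: float) -> float:
    """Genetic coefficient of variation at residual-SD level, ~ sigma_av / 2.

    The genetic standard deviation in residual standard deviation divided by
    the mean residual SD of the trait; measures scope for selection on
    variability (a value of 0.09 means the residual SD can shift by ~9% per
    genetic-SD of selection).
    """
    if sigma_av2 < 0:
        raise DomainError("sigma_av2 must be non-negative")
    return 0.5 * float(np.sqrt(sigma_av2))


def h2_residual_variance(sigma_av2: float, sigma_pev2: float, sigma_p2: float) -> float:
    """Heritability of residual variance at the squared-phenotype level,

        h_v2 = sigma_av2 / (2 sigma_P^4 + 3 (sigma_av2 + sigma_pev2)) .

    A reliability measure of single-record EBVs for the variance trait, not
    a response-to-selection measure.
    """
    if min(sigma_av2, sigma_pev2, sigma_p2) < 0:
        raise DomainError("inputs must be non-negative")
    denom = 2.0 * sigma_p2**2 + 3.0 * (sigma_av2 + sigma_pev2)
    if denom <= 0:
        raise DomainError("zero denominator; h_v2 undefined")
    return sigma_av2 / denom


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------
def _prepare(records: pd.DataFrame, ped: Pedigree):
    for col in ("sow", "parity", "fys", "tnb"):
        if col not in records.columns:
            raise ValidationError(f"litter records missing column {col!r}")
    rec = records.reset_index(drop=True)
    idx = {a: i for i, a in enumerate(ped.ids)}
    sows = rec["sow"].astype(str)
    missing = sorted(set(sows) - set(idx))
    if missing:
        raise ValidationError(f"{len(missing)} sows not in the pedigree (first: {missing[:5]})")
    animal_codes = sows.map(idx).to_numpy(np.int64)
    sow_levels = pd.Index(sorted(sows.unique()))
    sow_codes = sow_levels.get_indexer(sows)
    fixed = rec[["parity", "fys"]].astype(str)
    y = rec["tnb"].to_numpy(float)
    return y, fixed, animal_codes, sow_codes, sow_levels


def _mean_design(y, fixed, animal_codes, sow_codes, sow_levels, ped, weights):
    return ModelDesign(
        response=y,
        fixed=fixed,
        random=[
            RandomEffect("additive", animal_codes, len(ped), covariance=PEDIGREE, ped=ped),
            RandomEffect("pe", sow_codes, len(sow_levels), covariance=IDENTITY, level_ids=list(sow_levels)),
        ],
        weights=weights,
    )


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------
@dataclass
class DhglmResult:
    """Converged DHGLM state: components, correlations, EBVs and diagnostics."""

    vc: VarianceComponents
    fit: MixedModelFit
    n_iterations: int
    converged: bool
    psi: np.ndarray
    weights_mean: np.ndarray
    weights_dispersion: np.ndarray
    residuals: np.ndarray
    leverage: np.ndarray
    predicted_resvar: np.ndarray
    trace: list = field(default_factory=list)
    start_univariate: VarianceComponents | None = None

    @property
    def sigma_a2(self) -> float:
        return self.vc.variance("additive", 0)

    @property
    def sigma_av2(self) -> float:
        return self.vc.variance("additive", 1)

    @property
    def sigma_pe2(self) -> float:
        return self.vc.variance("pe", 0)

    @property
    def sigma_pev2(self) -> float:
        return self.vc.variance("pe", 1)

    @property
    def r_a(self) -> float:
        return self.vc.correlation("additive")

    @property
    def r_pe(self) -> float:
        return self.vc.correlation("pe")

    @property
    def mean_residual_variance(self) -> float:
        """Average predicted residual variance of the mean part, the
        DHGLM analogue of a homoscedastic sigma_e2."""
        return float(np.mean(self.predicted_resvar))

    @property
    def gcv_sde(self) -> float:
        return gcv_sde(self.sigma_av2)

    def heritability_mean(self) -> float:
        total = self.sigma_a2 + self.sigma_pe2 + self.mean_residual_variance
        return self.sigma_a2 / total

    def h2_residual_variance(self) -> float:
        sigma_p2 = self.sigma_a2 + self.sigma_pe2 + self.mean_residual_variance
        return h2_residual_variance(self.sigma_av2, self.sigma_pev2, sigma_p2)

    def ebv(self, part: str = MEAN_TRAIT) -> pd.Series:
        return self.fit.random_effects("additive", 0 if part == MEAN_TRAIT else 1)

    def ebv_table(self) -> pd.DataFrame:
        a = self.fit.random_effects("additive", 0)
        av = self.fit.random_effects("additive", 1)
        return pd.DataFrame({"animal": a.index, "ebv_mean": a.to_numpy(), "ebv_dispersion": av.to_numpy()})

    def scaling_variances(self) -> np.ndarray:
        """Residual scaling variances of the two parts; ~1 at convergence."""
        return self.vc.residual.copy()


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------
def run_dhglm(
    records: pd.DataFrame,
    ped: Pedigree,
    start: VarianceComponents | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    constrain_pe_cov: bool = False,
    constrain_a_cov: bool = False,
    compute_se: bool = True,
    inner_first: int = 60,
    inner: int = 4,
    relax: float = 0.5,
    jackknife_clusters: bool = True,
) -> DhglmResult:
    """Run the iterative DHGLM on edited litter records.

    Parameters
    ----------
    records : edited litter table (``sow, parity, fys, tnb``).
    ped : pedigree covering every sow.
    start : variance components of a converged univariate analysis of the
        mean trait; fitted here when not supplied.
    tol : relative-change convergence tolerance applied to every variance
        component (and the scaling variances).
    constrain_pe_cov / constrain_a_cov : pin the permanent-environment or
        additive between-part covariance at zero (sensitivity analyses).
    inner_first / inner : quasi-Newton iteration caps for the first / the
        warm-started subsequent bivariate REML fits.
    relax : relaxation factor for the dispersion-predictor update (1 = no
        damping); successive log-variance predictions are averaged, which
        suppresses the two-cycle the raw fixed-point iteration is prone to.
    jackknife_clusters : deflate each sow's dispersion prediction to its
        leave-own-sow-out value before it re-enters the working response and
        weights.  Without this, the prediction tracks the sow's own
        chi-square noise, which biases the permanent dispersion variance
        upward and the dispersion scaling variance below 1.

    Raises :class:`ConvergenceError` when components still move after
    ``max_iter`` outer iterations.
    """
    y, fixed, animal_codes, sow_codes, sow_levels, = _prepare(records, ped)

    # step 0: conventional univariate fit of the mean trait
    if start is None:
        vy = float(np.var(y))
        start0 = VarianceComponents(
            residual=[0.6 * vy],
            terms={"additive": [[0.15 * vy]], "pe": [[0.1 * vy]]},
        )
        d0 = _mean_design(y, fixed, animal_codes, sow_codes, sow_levels, ped, np.ones_like(y))
        start, fit0, _ = estimate_reml(d0, start0, max_iter=60, compute_se=False, strict=False)
    else:
        d0 = _mean_design(y, fixed, animal_codes, sow_codes, sow_levels, ped, np.ones_like(y))
        fit0 = None
        from vargwas.mixed_model import solve_mme

        fit0 = solve_mme(d0, start)
    e = fit0.residuals(0)
    h = fit0.leverage(0)
    sigma_e2_uni = float(start.residual[0])
    s2 = np.full_like(y, sigma_e2_uni)
    psi_hat = np.log(s2)

    fix = []
    if constrain_pe_cov:
        fix.append("pe")
    if constrain_a_cov:
        fix.append("additive")

    vc = VarianceComponents(
        residual=np.array([1.0, 1.0]),
        terms={
            "additive": np.array([[start.variance("additive"), 0.0], [0.0, 0.02]]),
            "pe": np.array([[start.variance("pe"), 0.0], [0.0, 0.05]]),
        },
    )
    warm_h = None
    trace = []
    converged = False
    fit = None
    psi = w = w_v = None
    prev_psi_hat = None
    prev_delta_psi = None
    for iteration in range(1, max_iter + 1):
        psi = working_response(e, h, s2)
        w, w_v = update_weights(psi_hat, h)
        design = ModelDesign(
            response=np.column_stack([y, psi]),
            fixed=fixed,
            random=[
                RandomEffect("additive", animal_codes, len(ped), covariance=PEDIGREE, ped=ped),
                RandomEffect("pe", sow_codes, len(sow_levels), covariance=IDENTITY, level_ids=list(sow_levels)),
            ],
            weights=np.column_stack([w, w_v]),
        )
        prev = _component_vector(vc)
        vc, fit, opt = estimate_reml(
            design,
            vc,
            max_iter=inner_first if iteration == 1 else inner,
            fix_covariance=tuple(fix),
            warm_hessian=warm_h,
            compute_se=False,
            strict=False,
        )
        warm_h = opt["hessian"]
        cur = _component_vector(vc)
        delta = np.max(np.abs(cur - prev) / (np.abs(prev) + 1e-3))
        trace.append({"iteration": iteration, "max_rel_change": delta, **_component_dict(vc)})
        log.info("DHGLM iteration %d: max relative component change %.3g", iteration, delta)

        # refresh the linearization; the predicted residual variance is the
        # dispersion linear predictor times the mean-part scaling variance
        # (the scaling then stays ~1 instead of chasing the intercept)
        # the influence quantities (leverages, cluster self-influence) move
        # slowly once the weights settle; refresh them on a schedule to keep
        # the per-iteration cost down
        refresh = iteration <= 4 or iteration % 3 == 0 or delta < 100 * tol
        e = fit.residuals(0)
        if refresh:
            h = fit.leverage(0)
        psi_lin = fit.fitted(1)
        if jackknife_clusters:
            # deflate each sow's dispersion prediction to its
            # leave-own-sow-out value: the raw cluster prediction tracks the
            # sow's realized chi-square noise, which deflates the within-sow
            # variance of psi and inflates the permanent dispersion variance
            if refresh:
                S = np.clip(fit.group_influence(1, sow_codes), 0.0, 0.95)
            resid_psi = fit.residuals(1)
            mean_resid = np.bincount(sow_codes, weights=resid_psi) / np.bincount(sow_codes)
            psi_lin = psi_lin - (S / (1.0 - S))[sow_codes] * mean_resid[sow_codes]
        psi_lin = psi_lin + np.log(vc.residual[0])
        psi_hat_new = (1.0 - relax) * psi_hat + relax * psi_lin
        # Aitken-style vector extrapolation of the slow geometric mode of
        # the damped fixed-point iteration
        delta_psi = psi_hat_new - psi_hat
        if prev_delta_psi is not None and iteration >= 4:
            denom = float(prev_delta_psi @ prev_delta_psi)
            lam = float(delta_psi @ prev_delta_psi) / denom if denom > 0 else 0.0
            if 0.05 < lam < 0.9:
                psi_hat_new = psi_hat_new + delta_psi * (lam / (1.0 - lam))
        prev_delta_psi = delta_psi
        psi_hat = psi_hat_new
        # guard the exponential against transient overshoot early on
        psi_hat = np.clip(psi_hat, np.log(sigma_e2_uni) - 8.0, np.log(sigma_e2_uni) + 8.0)
        s2 = np.exp(psi_hat)
        if delta < tol and iteration > 1 and opt["converged"]:
            converged = True
            break
    if not converged:
        tail = [t["max_rel_change"] for t in trace[-5:]]
        raise ConvergenceError(
            f"DHGLM did not converge in {max_iter} iterations (recent component changes: {tail})",
            trace=trace,
        )
    if compute_se:
        # one last fully converged fit with standard errors
        vc, fit, _ = estimate_reml(
            design,
            vc,
            max_iter=30,
            fix_covariance=tuple(fix),
            warm_hessian=warm_h,
            compute_se=True,
            strict=False,
        )
    return DhglmResult(
        vc=vc,
        fit=fit,
        n_iterations=iteration,
        converged=converged,
        psi=psi,
        weights_mean=w,
        weights_dispersion=w_v,
        residuals=e,
        leverage=h,
        predicted_resvar=s2,
        trace=trace,
        start_univariate=start,
    )


def _component_vector(vc: VarianceComponents) -> np.ndarray:
    a = vc.terms["additive"]
    p = vc.terms["pe"]
    return np.array([a[0, 0], a[1, 1], a[0, 1], p[0, 0], p[1, 1], p[0, 1], vc.residual[0], vc.residual[1]])


def _component_dict(vc: VarianceComponents) -> dict:
    return {
        "sigma_a2": vc.variance("additive", 0),
        "sigma_av2": vc.variance("additive", 1),
        "r_a": vc.correlation("additive"),
        "sigma_pe2": vc.variance("pe", 0),
        "sigma_pev2": vc.variance("pe", 1),
        "r_pe": vc.correlation("pe"),
        "scale_mean": float(vc.residual[0]),
        "scale_dispersion": float(vc.residual[1]),
    }


def univariate_refits(result: DhglmResult, records: pd.DataFrame, ped: Pedigree, compute_se: bool = False):
    """Univariate REML re-fits of the mean trait and of the working response
    at the final DHGLM weights.

    EBVs for deregression come from these single-trait fits so that each
    trait's proof is not influenced by the other trait through the
    between-part covariances.  Returns ``((vc_mean, fit_mean),
    (vc_disp, fit_disp))``.
    """
    y, fixed, animal_codes, sow_codes, sow_levels = _prepare(records, ped)
    out = []
    for resp, wts, v_start, pe_start, res_start in (
        (y, result.weights_mean, result.sigma_a2, result.sigma_pe2, result.vc.residual[0]),
        (result.psi, result.weights_dispersion, result.sigma_av2, result.sigma_pev2, result.vc.residual[1]),
    ):
        design = _mean_design(resp, fixed, animal_codes, sow_codes, sow_levels, ped, wts)
        start = VarianceComponents(
            residual=[max(res_start, 1e-4)],
            terms={"additive": [[max(v_start, 1e-6)]], "pe": [[max(pe_start, 1e-6)]]},
        )
        vc, fit, _ = estimate_reml(design, start, max_iter=50, compute_se=compute_se, strict=False)
        out.append((vc, fit))
    return tuple(out)
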