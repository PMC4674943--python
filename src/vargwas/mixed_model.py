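"""Pedigree-based linear mixed models: MME solving, REML, BLUP, leverages.

The engine handles one- and two-trait Gaussian mixed models

    y_t = X_t b_t + sum_k Z_k u_{k,t} + e_t ,

with each random term k tagged with a covariance driver (numerator
relationship matrix A from a pedigree, or identity) and, for two traits, a
full 2x2 covariance matrix between the traits' effects (G_k = S_k (x) K_k).
Residuals are weighted, var(e_{t,i}) = sigma_et^2 / w_{t,i}; two-trait models
may optionally carry a within-observation residual correlation (used by the
conventional sow-level bivariate analysis, where the two responses of a sow
are a mean and a log-variance computed from the same litters).

Everything is estimated from Henderson's mixed-model equations

    C theta = W' R^-1 y,     C = W' R^-1 W + G^-1 ,

factorized sparsely (SuperLU, symmetric-mode minimum-degree ordering).  REML
estimates maximize the restricted log-likelihood

    -2 l_R = log|R| + log|G| + log|C| + y' P y   (+ const)

directly, via a quasi-Newton (BFGS) search with finite-difference gradients
on an unconstrained parametrization (log variances, atanh correlations).
The BFGS curvature can be warm-started, which the DHGLM outer loop exploits.
Approximate standard errors come from a finite-difference observed-
information matrix on the natural (variance/covariance) scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from vargwas.errors import ConvergenceError, DomainError, RankDeficiencyError, ValidationError
from vargwas.pedigree import Pedigree, a_inverse, log_det_a

log = logging.getLogger(__name__)

PEDIGREE = "pedigree"
IDENTITY = "identity"
_VAR_FLOOR = 1e-8
_CORR_CAP = 0.999


# ---------------------------------------------------------------------------
# design containers
# ---------------------------------------------------------------------------
@dataclass
class RandomEffect:
    """One random term of a model.

    ``codes`` maps each observation to a level index; for a pedigree-driven
    term the levels are the pedigree animals (in pedigree order) and
    ``n_levels`` equals the pedigree size, so ancestors without records still
    receive breeding values.
    """

    name: str
    codes: np.ndarray
    n_levels: int
    covariance: str = IDENTITY
    ped: Pedigree | None = None
    level_ids: list | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.covariance not in (PEDIGREE, IDENTITY):
            raise ValidationError(f"unknown covariance driver {self.covariance!r}")
        if self.covariance == PEDIGREE:
            if self.ped is None:
                raise ValidationError(f"term {self.name!r}: pedigree covariance requires a pedigree")
            self.n_levels = len(self.ped)
            self.level_ids = list(self.ped.ids)
        if self.codes.min(initial=0) < 0 or self.codes.max(initial=0) >= self.n_levels:
            raise ValidationError(f"term {self.name!r}: level codes out of range")

    def kernel_inverse(self) -> sp.csr_matrix:
        if not hasattr(self, "_kinv"):
            if self.covariance == PEDIGREE:
                self._kinv = a_inverse(self.ped)
                self._logdet_k = log_det_a(self.ped)
            else:
                self._kinv = sp.eye(self.n_levels, format="csr")
                self._logdet_k = 0.0
        return self._kinv

    @property
    def logdet_kernel(self) -> float:
        self.kernel_inverse()
        return self._logdet_k


@dataclass
class ModelDesign:
    """Observations, fixed factors, random terms and residual weights.

    ``response`` and ``weights`` are (n,) for one trait or (n, 2) for two
    traits sharing observation rows.  ``fixed`` holds categorical factor
    columns; every trait gets its own coefficients for every factor plus an
    intercept.
    """

    response: np.ndarray
    fixed: pd.DataFrame
    random: list
    weights: np.ndarray
    residual_correlated: bool = False

    def __post_init__(self):
        self.response = np.atleast_2d(np.asarray(self.response, float).T).T
        if self.response.ndim != 2:
            raise ValidationError("response must be (n,) or (n, n_traits)")
        self.weights = np.atleast_2d(np.asarray(self.weights, float).T).T
        if self.weights.shape != self.response.shape:
            raise ValidationError("weights must match response shape")
        if np.any(self.weights <= 0):
            raise ValidationError("weights must be strictly positive")
        if not np.all(np.isfinite(self.response)):
            raise ValidationError("non-finite response values")
        if self.residual_correlated and self.n_traits != 2:
            raise ValidationError("residual correlation requires exactly two traits")
        if len(self.fixed) != self.n_obs:
            raise ValidationError("fixed-effect table does not match response length")
        for term in self.random:
            if len(term.codes) != self.n_obs:
                raise ValidationError(f"term {term.name!r}: codes do not match response length")

    @property
    def n_obs(self) -> int:
        return self.response.shape[0]

    @property
    def n_traits(self) -> int:
        return self.response.shape[1]


@dataclass
class VarianceComponents:
    """Variance components of a fit: residual variances per trait and a
    (t x t) covariance matrix per random term; optional residual correlation
    for paired two-trait residuals and a matching structure of approximate
    standard errors."""

    residual: np.ndarray
    terms: dict
    residual_corr: float = 0.0
    se: dict | None = None

    def __post_init__(self):
        self.residual = np.atleast_1d(np.asarray(self.residual, float))
        self.terms = {k: np.atleast_2d(np.asarray(v, float)) for k, v in self.terms.items()}
        for name, m in self.terms.items():
            if np.any(np.diag(m) < 0):
                raise ValidationError(f"negative variance for term {name!r}")
        if np.any(self.residual <= 0):
            raise ValidationError("residual variances must be positive")

    def variance(self, term: str, trait: int = 0) -> float:
        return float(self.terms[term][trait, trait])

    def covariance(self, term: str) -> float:
        return float(self.terms[term][0, 1])

    def correlation(self, term: str) -> float:
        m = self.terms[term]
        denom = np.sqrt(m[0, 0] * m[1, 1])
        return float(m[0, 1] / denom) if denom > 0 else 0.0

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(
            residual=self.residual.copy(),
            terms={k: v.copy() for k, v in self.terms.items()},
            residual_corr=self.residual_corr,
            se=None if self.se is None else dict(self.se),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.terms.items():
            t = m.shape[0]
            for i in range(t):
                rows.append((f"{name}_var_{i + 1}" if t > 1 else f"{name}_var", m[i, i]))
            if t > 1:
                rows.append((f"{name}_cov", m[0, 1]))
                rows.append((f"{name}_corr", self.correlation(name)))
        for i, v in enumerate(self.residual):
            rows.append((f"residual_var_{i + 1}" if len(self.residual) > 1 else "residual_var", v))
        if self.residual_corr:
            rows.append(("residual_corr", self.residual_corr))
        df = pd.DataFrame(rows, columns=["component", "estimate"])
        if self.se:
            df["se"] = [self.se.get(c, np.nan) for c in df["component"]]
        return df


# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------
def heritability(sigma_a2: float, sigma_pe2: float, sigma_e2: float) -> float:
    """Narrow-sense heritability h2 = sigma_a2 / (sigma_a2 + sigma_pe2 + sigma_e2)."""
    for v in (sigma_a2, sigma_pe2, sigma_e2):
        if v < 0:
            raise DomainError("variance components must be non-negative")
    total = sigma_a2 + sigma_pe2 + sigma_e2
    if total <= 0:
        raise DomainError("total variance is zero; heritability undefined")
    return sigma_a2 / total


def covariance_from_correlation(r: float, v1: float, v2: float) -> float:
    """Covariance implied by a correlation and two variances, r sqrt(v1 v2)."""
    if abs(r) > 1:
        raise ValidationError("correlation outside [-1, 1]")
    if v1 < 0 or v2 < 0:
        raise ValidationError("variances must be non-negative")
    return r * np.sqrt(v1 * v2)


# ---------------------------------------------------------------------------
# the REML problem: assembly and likelihood
# ---------------------------------------------------------------------------
class _REMLProblem:
    """Precomputed design structures plus likelihood evaluation."""

    def __init__(self, design: ModelDesign):
        self.design = design
        self.T = design.n_traits
        self.n = design.n_obs
        self._build_design_matrices()

    # -- structure ---------------------------------------------------------
    def _build_design_matrices(self):
        d = self.design
        X, labels = _fixed_design(d.fixed, self.n)
        self.X = X
        self.fixed_labels = labels
        p = X.shape[1]
        self.p = p

        # global column layout: per trait fixed blocks, then per term per trait
        offset = 0
        self.offsets = {}
        for t in range(self.T):
            self.offsets[("fixed", t)] = offset
            offset += p
        for k, term in enumerate(d.random):
            for t in range(self.T):
                self.offsets[("term", k, t)] = offset
                offset += term.n_levels
        self.ncols = offset

        ii = np.arange(self.n)
        Zs = []
        for term in d.random:
            Z = sp.coo_matrix((np.ones(self.n), (ii, term.codes)), shape=(self.n, term.n_levels)).tocsr()
            Zs.append(Z)
        self.Zs = Zs

        # W_t: rows of trait t against the global column layout
        self.W = []
        for t in range(self.T):
            blocks = []
            for t2 in range(self.T):
                blocks.append(X if t2 == t else sp.csr_matrix((self.n, p)))
            for k, term in enumerate(d.random):
                for t2 in range(self.T):
                    blocks.append(Zs[k] if t2 == t else sp.csr_matrix((self.n, term.n_levels)))
            self.W.append(sp.hstack(blocks).tocsr())

        w = d.weights
        y = d.response
        if not d.residual_correlated:
            self.M = [(self.W[t].T.multiply(w[:, t])) @ self.W[t] for t in range(self.T)]
            self.M = [m.tocsc() for m in self.M]
            self.r = [self.W[t].T @ (w[:, t] * y[:, t]) for t in range(self.T)]
            self.yty = [float(np.sum(w[:, t] * y[:, t] ** 2)) for t in range(self.T)]
            self.logw = [float(np.sum(np.log(w[:, t]))) for t in range(self.T)]
        else:
            # paired residual: keep stacked W and y for per-eval R^-1 products
            self.W_stacked = sp.vstack(self.W).tocsr()
            self.y_stacked = np.concatenate([y[:, t] for t in range(self.T)])

        self._perm_cache = None

    # -- per-evaluation assembly -------------------------------------------
    def _g_inverse(self, vc: VarianceComponents):
        blocks = []
        logdet_g = 0.0
        d = self.design
        rows, cols, vals = [], [], []
        for k, term in enumerate(d.random):
            S = vc.terms[term.name]
            K = term.kernel_inverse().tocoo()
            if self.T == 1:
                v = max(float(S[0, 0]), _VAR_FLOOR)
                coef = np.array([[1.0 / v]])
                logdet_g += term.n_levels * np.log(v) + term.logdet_kernel
            else:
                Sm = S.copy()
                Sm[0, 0] = max(Sm[0, 0], _VAR_FLOOR)
                Sm[1, 1] = max(Sm[1, 1], _VAR_FLOOR)
                # cap the implied correlation so the matrix stays invertible
                cap = _CORR_CAP * np.sqrt(Sm[0, 0] * Sm[1, 1])
                Sm[0, 1] = Sm[1, 0] = np.clip(Sm[0, 1], -cap, cap)
                det = Sm[0, 0] * Sm[1, 1] - Sm[0, 1] ** 2
                if det <= 0:
                    raise DomainError(f"term {term.name!r}: covariance matrix not positive definite")
                coef = np.array([[Sm[1, 1], -Sm[0, 1]], [-Sm[0, 1], Sm[0, 0]]]) / det
                logdet_g += term.n_levels * np.log(det) + self.T * term.logdet_kernel
            for t1 in range(self.T):
                for t2 in range(self.T):
                    c = coef[t1, t2]
                    if c == 0.0:
                        continue
                    o1 = self.offsets[("term", k, t1)]
                    o2 = self.offsets[("term", k, t2)]
                    rows.append(K.row + o1)
                    cols.append(K.col + o2)
                    vals.append(c * K.data)
        if rows:
            Ginv = sp.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(self.ncols, self.ncols),
            ).tocsc()
        else:
            Ginv = sp.csc_matrix((self.ncols, self.ncols))
        return Ginv, logdet_g

    def _data_part(self, vc: VarianceComponents):
        """Return (Cdata, rhs, y'R^-1 y, log|R|)."""
        d = self.design
        if not d.residual_correlated:
            Cdata = sum((1.0 / vc.residual[t]) * self.M[t] for t in range(self.T))
            rhs = sum((1.0 / vc.residual[t]) * self.r[t] for t in range(self.T))
            yry = sum(self.yty[t] / vc.residual[t] for t in range(self.T))
            logdet_r = sum(self.n * np.log(vc.residual[t]) - self.logw[t] for t in range(self.T))
            return Cdata.tocsc(), rhs, yry, logdet_r
        # paired 2x2 residual blocks per observation
        w = d.weights
        s1, s2 = vc.residual
        rho = np.clip(vc.residual_corr, -_CORR_CAP, _CORR_CAP)
        v1 = s1 / w[:, 0]
        v2 = s2 / w[:, 1]
        cv = rho * np.sqrt(v1 * v2)
        det = v1 * v2 - cv**2
        i11 = v2 / det
        i22 = v1 / det
        i12 = -cv / det
        n = self.n
        Rinv = sp.bmat([[sp.diags(i11), sp.diags(i12)], [sp.diags(i12), sp.diags(i22)]]).tocsr()
        Ws = self.W_stacked
        WtR = (Ws.T @ Rinv).tocsr()
        Cdata = (WtR @ Ws).tocsc()
        Ry = Rinv @ self.y_stacked
        rhs = Ws.T @ Ry
        yry = float(self.y_stacked @ Ry)
        logdet_r = float(np.sum(np.log(det)))
        return Cdata, rhs, yry, logdet_r

    def factorize(self, vc: VarianceComponents):
        Cdata, rhs, yry, logdet_r = self._data_part(vc)
        Ginv, logdet_g = self._g_inverse(vc)
        C = (Cdata + Ginv).tocsc()
        try:
            lu = splu(C, permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True))
        except RuntimeError as err:  # exactly singular
            raise RankDeficiencyError(self._rank_message(str(err))) from err
        udiag = np.abs(lu.U.diagonal())
        if udiag.min() < 1e-10 * max(udiag.max(), 1.0):
            raise RankDeficiencyError(self._rank_message("near-zero pivot"))
        logdet_c = float(np.sum(np.log(udiag)))
        sol = lu.solve(rhs)
        ypy = yry - float(rhs @ sol)
        neg2ll = logdet_r + logdet_g + logdet_c + ypy
        return {"lu": lu, "C": C, "rhs": rhs, "sol": sol, "neg2ll": neg2ll}

    def _rank_message(self, detail: str) -> str:
        return (
            "singular mixed-model equations (%s); fixed factors %s are likely confounded"
            % (detail, list(self.design.fixed.columns))
        )

    def neg2_reml(self, vc: VarianceComponents) -> float:
        return self.factorize(vc)["neg2ll"]


def _fixed_design(fixed: pd.DataFrame, n: int):
    """Intercept + treatment-coded dummies for each categorical factor."""
    cols = [np.ones((n, 1))]
    labels = ["intercept"]
    for name in fixed.columns:
        f = pd.Categorical(fixed[name])
        if len(f.categories) > 1:
            dummies = pd.get_dummies(f, drop_first=True).to_numpy(float)
            cols.append(dummies)
            labels += [f"{name}[{c}]" for c in f.categories[1:]]
    X = np.hstack(cols)
    return sp.csr_matrix(X), labels


# ---------------------------------------------------------------------------
# fitted model
# ---------------------------------------------------------------------------
class MixedModelFit:
    """Solutions of the mixed-model equations at given variance components."""

    def __init__(self, problem: _REMLProblem, vc: VarianceComponents, state: dict):
        self._problem = problem
        self.vc = vc
        self._state = state
        self._leverage = {}

    @property
    def design(self) -> ModelDesign:
        return self._problem.design

    @property
    def reml_loglik(self) -> float:
        n_total = self._problem.n * self._problem.T
        return -0.5 * (self._state["neg2ll"] + (n_total - self._problem.p * self._problem.T) * np.log(2 * np.pi))

    def mme_residual_norm(self) -> float:
        C, rhs, sol = self._state["C"], self._state["rhs"], self._state["sol"]
        return float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))

    def fixed_effects(self, trait: int = 0) -> pd.Series:
        pr = self._problem
        o = pr.offsets[("fixed", trait)]
        return pd.Series(self._state["sol"][o : o + pr.p], index=pr.fixed_labels, name=f"trait{trait}")

    def random_effects(self, term: str, trait: int = 0) -> pd.Series:
        pr = self._problem
        k = self._term_index(term)
        te = pr.design.random[k]
        o = pr.offsets[("term", k, trait)]
        idx = te.level_ids if te.level_ids is not None else np.arange(te.n_levels)
        return pd.Series(self._state["sol"][o : o + te.n_levels], index=pd.Index(idx, name=term), name=f"{term}_t{trait}")

    def _term_index(self, term: str) -> int:
        for k, te in enumerate(self._problem.design.random):
            if te.name == term:
                return k
        raise KeyError(term)

    def fitted(self, trait: int = 0) -> np.ndarray:
        pr = self._problem
        return np.asarray(pr.W[trait] @ self._state["sol"]).ravel()

    def residuals(self, trait: int = 0) -> np.ndarray:
        return self.design.response[:, trait] - self.fitted(trait)

    def dispersion_predictor(self, trait: int = 1) -> np.ndarray:
        """Linear predictor of a trait from fixed + random effects (used by
        the DHGLM as log predicted residual variance)."""
        return self.fitted(trait)

    # -- leverages and prediction-error variances --------------------------
    def leverage(self, trait: int = 0) -> np.ndarray:
        """Diagonal of the influence map of trait ``trait``'s observations
        onto their fitted values, h_i = [W C^-1 W' R^-1]_ii, each in [0, 1)."""
        if trait in self._leverage:
            return self._leverage[trait]
        pr = self._problem
        if pr.design.residual_correlated:
            raise ValidationError("leverage is only available for diagonal-residual models")
        cols = self._trait_columns(trait)
        Cinv_sub = self._selected_inverse_cached(trait, cols)
        B = pr.W[trait][:, cols].tocsr()
        w = pr.design.weights[:, trait] / self.vc.residual[trait]
        h = np.empty(pr.n)
        chunk = 4000
        for lo in range(0, pr.n, chunk):
            hi = min(lo + chunk, pr.n)
            Bc = B[lo:hi]
            h[lo:hi] = ((Bc @ Cinv_sub) * Bc.toarray()).sum(axis=1)
        h *= w
        self._leverage[trait] = h
        return h

    def effective_parameters(self) -> float:
        """Trace of the influence map over all traits, sum_i h_i."""
        return float(sum(self.leverage(t).sum() for t in range(self._problem.T)))

    def group_influence(self, trait: int, groups: np.ndarray) -> np.ndarray:
        """Self-influence S_k of each group's (e.g. sow's) observations on
        its own mean fitted value for one trait:

            S_k = (1/n_k) sum_{i,j in k} [W C^-1 W' R^-1]_ij ,

        the derivative of the group-mean prediction with respect to a common
        shift of the group's responses.  Used to deflate cluster-level
        predictions to their leave-own-group-out values."""
        pr = self._problem
        if pr.design.residual_correlated:
            raise ValidationError("group influence requires diagonal residuals")
        groups = np.asarray(groups)
        cols = self._trait_columns(trait)
        Cinv_sub = self._selected_inverse_cached(trait, cols)
        B = pr.W[trait][:, cols].tocsr()
        w = pr.design.weights[:, trait] / self.vc.residual[trait]
        n_groups = int(groups.max()) + 1
        G = sp.coo_matrix((np.ones(pr.n), (groups, np.arange(pr.n))), shape=(n_groups, pr.n)).tocsr()
        U = (G @ B).toarray()
        Vw = (G @ (B.multiply(w[:, None]))).toarray()
        sums = np.einsum("km,mn,kn->k", U, Cinv_sub, Vw, optimize=True)
        counts = np.asarray(G.sum(axis=1)).ravel()
        return sums / counts

    def _selected_inverse_cached(self, trait: int, cols: np.ndarray) -> np.ndarray:
        if not hasattr(self, "_cinv_cache"):
            self._cinv_cache = {}
        if trait not in self._cinv_cache:
            self._cinv_cache[trait] = self._selected_inverse(cols)
        return self._cinv_cache[trait]

    def _trait_columns(self, trait: int) -> np.ndarray:
        pr = self._problem
        cols = [np.arange(pr.offsets[("fixed", trait)], pr.offsets[("fixed", trait)] + pr.p)]
        for k, te in enumerate(pr.design.random):
            used = np.unique(te.codes)
            cols.append(pr.offsets[("term", k, trait)] + used)
        return np.concatenate(cols)

    def _selected_inverse(self, cols: np.ndarray) -> np.ndarray:
        """Dense sub-block C^-1[cols, cols] via chunked unit-vector solves."""
        lu = self._state["lu"]
        m = len(cols)
        N = self._problem.ncols
        out = np.empty((m, m))
        chunk = 512
        for lo in range(0, m, chunk):
            hi = min(lo + chunk, m)
            E = np.zeros((N, hi - lo))
            E[cols[lo:hi], np.arange(hi - lo)] = 1.0
            Y = lu.solve(E)
            out[:, lo:hi] = Y[cols, :]
        return out

    def random_effect_se(self, term: str, trait: int = 0) -> pd.Series:
        """Prediction-error standard errors, sqrt of diag(C^-1) on the term's
        block (C is in natural units, so C^-1 is the PEV matrix)."""
        pr = self._problem
        k = self._term_index(term)
        te = pr.design.random[k]
        o = pr.offsets[("term", k, trait)]
        cols = np.arange(o, o + te.n_levels)
        lu = self._state["lu"]
        diag = np.empty(te.n_levels)
        chunk = 512
        for lo in range(0, te.n_levels, chunk):
            hi = min(lo + chunk, te.n_levels)
            E = np.zeros((pr.ncols, hi - lo))
            E[cols[lo:hi], np.arange(hi - lo)] = 1.0
            Y = lu.solve(E)
            diag[lo:hi] = Y[cols[lo:hi], np.arange(hi - lo)]
        idx = te.level_ids if te.level_ids is not None else np.arange(te.n_levels)
        return pd.Series(np.sqrt(np.maximum(diag, 0.0)), index=pd.Index(idx, name=term), name=f"se_{term}_t{trait}")


def solve_mme(design: ModelDesign, vc: VarianceComponents) -> MixedModelFit:
    """Solve the mixed-model equations at fixed variance components."""
    problem = _REMLProblem(design)
    state = problem.factorize(vc)
    return MixedModelFit(problem, vc, state)


# ---------------------------------------------------------------------------
# REML estimation
# ---------------------------------------------------------------------------
class _ParamMap:
    """Bijective map between a VarianceComponents object and an unconstrained
    optimization vector (log variances, atanh correlations)."""

    def __init__(self, design: ModelDesign, template: VarianceComponents, fix_covariance=()):
        self.design = design
        self.T = design.n_traits
        self.entries = []  # (kind, term_name, trait)
        self.fix_covariance = set(fix_covariance)
        for term in design.random:
            for t in range(self.T):
                self.entries.append(("var", term.name, t))
            if self.T == 2 and term.name not in self.fix_covariance:
                self.entries.append(("corr", term.name, None))
        for t in range(self.T):
            self.entries.append(("rvar", None, t))
        if design.residual_correlated:
            self.entries.append(("rcorr", None, None))
        self.template = template

    def to_vector(self, vc: VarianceComponents) -> np.ndarray:
        x = []
        for kind, name, t in self.entries:
            if kind == "var":
                x.append(np.log(max(vc.terms[name][t, t], _VAR_FLOOR)))
            elif kind == "corr":
                m = vc.terms[name]
                r = m[0, 1] / np.sqrt(max(m[0, 0] * m[1, 1], _VAR_FLOOR**2))
                x.append(np.arctanh(np.clip(r, -_CORR_CAP, _CORR_CAP)))
            elif kind == "rvar":
                x.append(np.log(max(vc.residual[t], _VAR_FLOOR)))
            else:
                x.append(np.arctanh(np.clip(vc.residual_corr, -_CORR_CAP, _CORR_CAP)))
        return np.array(x)

    def to_vc(self, x: np.ndarray) -> VarianceComponents:
        vc = self.template.copy()
        corr = {}
        for (kind, name, t), xi in zip(self.entries, x):
            if kind == "var":
                vc.terms[name][t, t] = np.exp(np.clip(xi, -46, 46))
            elif kind == "corr":
                corr[name] = np.tanh(xi)
            elif kind == "rvar":
                vc.residual[t] = np.exp(np.clip(xi, -46, 46))
            else:
                vc.residual_corr = np.tanh(xi)
        if self.T == 2:
            for term in self.design.random:
                m = vc.terms[term.name]
                if term.name in self.fix_covariance:
                    r = 0.0
                else:
                    r = corr.get(term.name, 0.0)
                m[0, 1] = m[1, 0] = r * np.sqrt(m[0, 0] * m[1, 1])
        return vc


def _fd_gradient(fun, x, f0, eps):
    g = np.empty_like(x)
    for i in range(len(x)):
        xp = x.copy()
        xp[i] += eps
        g[i] = (fun(xp) - f0) / eps
    return g


def _bfgs(fun, x0, H0=None, maxiter=60, ftol=1e-9, gtol=1e-4, eps=1e-4):
    """Minimal BFGS with forward-difference gradients.

    Returns (x, f, H, n_evals, converged); H is the inverse-Hessian
    approximation, reusable as a warm start.
    """
    x = x0.copy()
    f = fun(x)
    nev = 1
    g = _fd_gradient(fun, x, f, eps)
    nev += len(x)
    H = np.eye(len(x)) * 0.1 if H0 is None else H0.copy()
    converged = False
    n_small = 0
    for _it in range(maxiter):
        p = -H @ g
        if not np.all(np.isfinite(p)):
            H = np.eye(len(x)) * 0.1
            p = -H @ g
        gp = float(g @ p)
        if gp > 0:  # not a descent direction; reset curvature
            H = np.eye(len(x)) * 0.1
            p = -H @ g
            gp = float(g @ p)
        # backtracking Armijo line search
        step = 1.0
        f_new = None
        for _ls in range(25):
            x_new = x + step * p
            f_try = fun(x_new)
            nev += 1
            if np.isfinite(f_try) and f_try <= f + 1e-4 * step * gp:
                f_new = f_try
                break
            step *= 0.5
        if f_new is None:
            converged = np.max(np.abs(g)) < gtol * 10
            break
        g_new = _fd_gradient(fun, x_new, f_new, eps)
        nev += len(x)
        s = x_new - x
        yv = g_new - g
        sy = float(s @ yv)
        if sy > 1e-12:
            rho = 1.0 / sy
            I = np.eye(len(x))
            H = (I - rho * np.outer(s, yv)) @ H @ (I - rho * np.outer(yv, s)) + rho * np.outer(s, s)
        rel_df = abs(f - f_new) / (abs(f) + 1.0)
        x, f, g = x_new, f_new, g_new
        # standard REML stop: relative change of the restricted
        # log-likelihood below tolerance (twice in a row, guarding against a
        # single short quasi-Newton step), or a vanishing gradient
        n_small = n_small + 1 if rel_df < ftol else 0
        if n_small >= 2 or (rel_df < ftol and np.max(np.abs(g)) < gtol):
            converged = True
            break
        if np.max(np.abs(g)) < gtol * 0.1:
            converged = True
            break
    return x, f, H, nev, converged


def estimate_reml(
    design: ModelDesign,
    start: VarianceComponents,
    tol: float = 1e-8,
    max_iter: int = 60,
    fix_covariance=(),
    warm_hessian: np.ndarray | None = None,
    compute_se: bool = True,
    strict: bool = True,
    polish: bool = False,
):
    """REML variance components by direct restricted-likelihood maximization.

    Parameters
    ----------
    start : positive starting components (e.g. phenotypic-variance splits).
    fix_covariance : term names whose between-trait covariance is pinned at 0.
    warm_hessian : inverse-Hessian approximation from a previous call, to
        warm-start the quasi-Newton search (used by the DHGLM outer loop).
    compute_se : attach finite-difference observed-information SEs.
    strict : raise :class:`ConvergenceError` when the search does not meet
        ``tol`` within ``max_iter`` BFGS iterations.

    Returns ``(vc, fit, state)`` where ``state`` carries the inverse Hessian
    and evaluation count.
    """
    y = design.response
    for t in range(design.n_traits):
        if np.var(y[:, t]) <= 0:
            raise ValidationError(f"response for trait {t} has zero empirical variance")
    problem = _REMLProblem(design)
    pmap = _ParamMap(design, start.copy(), fix_covariance=fix_covariance)
    trace = []

    def objective(x):
        try:
            val = problem.neg2_reml(pmap.to_vc(x))
        except (DomainError, RankDeficiencyError):
            return np.inf
        # soft barrier on the unbounded correlation scale: keeps a flat
        # likelihood from running to |r| = 1 (atanh(0.995) ~ 3)
        for (kind, _, _), xi in zip(pmap.entries, x):
            if kind in ("corr", "rcorr") and abs(xi) > 3.0:
                val += 10.0 * (abs(xi) - 3.0) ** 2
        trace.append((x.copy(), val))
        return val

    x0 = pmap.to_vector(start)
    f0 = objective(x0)
    if not np.isfinite(f0):
        raise ValidationError("restricted likelihood not finite at the starting values")
    x, f, H, nev, converged = _bfgs(objective, x0, H0=warm_hessian, maxiter=max_iter, ftol=tol)
    if polish:
        from scipy.optimize import minimize

        res = minimize(
            objective,
            x,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if np.isfinite(res.fun) and res.fun <= f:
            x, f = res.x, res.fun
            converged = converged or res.success
        nev += res.nfev
    if strict and not converged:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} quasi-Newton iterations ({nev} likelihood evaluations)",
            trace=trace[-20:],
        )
    vc = pmap.to_vc(x)
    state = problem.factorize(vc)
    fit = MixedModelFit(problem, vc, state)
    if compute_se:
        vc.se = _information_se(problem, vc, pmap)
    opt_state = {"hessian": H, "n_evals": nev, "converged": converged, "neg2ll": f}
    log.info("REML converged=%s after %d evaluations, -2logL=%.4f", converged, nev, f)
    return vc, fit, opt_state


def _natural_entries(pmap: _ParamMap):
    entries = []
    for kind, name, t in pmap.entries:
        if kind == "corr":
            entries.append(("cov", name, None))
        elif kind == "rcorr":
            entries.append(("rcov", None, None))
        else:
            entries.append((kind, name, t))
    return entries


def _information_se(problem, vc, pmap):
    """Approximate SEs from the finite-difference observed information on the
    natural (variance/covariance) scale, with delta-method SEs for the
    implied correlations."""
    entries = _natural_entries(pmap)

    def get(vc_, ent):
        kind, name, t = ent
        if kind == "var":
            return vc_.terms[name][t, t]
        if kind == "cov":
            return vc_.terms[name][0, 1]
        if kind == "rvar":
            return vc_.residual[t]
        s1, s2 = vc_.residual
        return vc_.residual_corr * np.sqrt(s1 * s2)

    def set_(vc_, ent, val):
        kind, name, t = ent
        if kind == "var":
            vc_.terms[name][t, t] = max(val, _VAR_FLOOR)
        elif kind == "cov":
            vc_.terms[name][0, 1] = vc_.terms[name][1, 0] = val
        elif kind == "rvar":
            vc_.residual[t] = max(val, _VAR_FLOOR)
        else:
            s1, s2 = vc_.residual
            vc_.residual_corr = val / np.sqrt(max(s1 * s2, _VAR_FLOOR**2))

    theta0 = np.array([get(vc, e) for e in entries])
    steps = 1e-3 * (np.abs(theta0) + 1e-3)

    def nll(theta):
        vc_ = vc.copy()
        for ent, val in zip(entries, theta):
            set_(vc_, ent, val)
        try:
            return 0.5 * problem.neg2_reml(vc_)
        except (DomainError, RankDeficiencyError):
            return np.nan

    k = len(theta0)
    Hm = np.full((k, k), np.nan)
    f0 = nll(theta0)
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        fp[i] = nll(theta0 + ei)
        fm[i] = nll(theta0 - ei)
        Hm[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = nll(theta0 + ei + ej)
            Hm[i, j] = Hm[j, i] = (fpp - fp[i] - fp[j] + f0) / (steps[i] * steps[j])
    try:
        cov = np.linalg.pinv(Hm)
    except np.linalg.LinAlgError:
        return None
    se = {}
    names = []
    for ent in entries:
        kind, name, t = ent
        if kind == "var":
            label = f"{name}_var_{t + 1}" if pmap.T > 1 else f"{name}_var"
        elif kind == "cov":
            label = f"{name}_cov"
        elif kind == "rvar":
            label = f"residual_var_{t + 1}" if pmap.T > 1 else "residual_var"
        else:
            label = "residual_cov"
        names.append(label)
    d = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se.update(dict(zip(names, d)))
    # delta-method SEs for correlations of 2x2 terms
    if pmap.T == 2:
        index = {ent: i for i, ent in enumerate(entries)}
        for term in problem.design.random:
            name = term.name
            if ("cov", name, None) not in index:
                continue
            i1, i2, ic = index[("var", name, 0)], index[("var", name, 1)], index[("cov", name, None)]
            v1, v2, c = theta0[i1], theta0[i2], theta0[ic]
            if v1 <= 0 or v2 <= 0:
                continue
            r = c / np.sqrt(v1 * v2)
            grad = np.zeros(k)
            grad[i1] = -r / (2 * v1)
            grad[i2] = -r / (2 * v2)
            grad[ic] = 1.0 / np.sqrt(v1 * v2)
            var_r = float(grad @ cov @ grad)
            se[f"{name}_corr"] = np.sqrt(max(var_r, 0.0))
    return se


# ---------------------------------------------------------------------------
# the conventional sow-level bivariate analysis
# ---------------------------------------------------------------------------
def fit_conventional_bivariate(
    summaries: pd.DataFrame,
    ped: Pedigree,
    compute_se: bool = True,
    max_iter: int = 80,
):
    """Weighted bivariate REML of (mean TNB, log var TNB) per sow.

    Random additive effects of the two traits follow a 2x2 covariance matrix
    kronecker the pedigree A; residuals are weighted per sow (mean response:
    weight n_litters; log-variance response: (n_litters - 1)/2, the inverse
    approximate sampling variances of a mean and of a log sample variance)
    and carry a within-sow residual correlation.  There is no permanent
    environment term because each sow contributes a single record per trait.

    ``summaries`` must come from :func:`vargwas.phenotype.summarize_sows`
    (sows with >= 3 litters).  Returns (VarianceComponents, MixedModelFit).
    """
    if (summaries["n_litters"] < 3).any():
        raise ValidationError("bivariate analysis requires sows with >= 3 litters")
    idx = {a: i for i, a in enumerate(ped.ids)}
    try:
        codes = np.array([idx[str(s)] for s in summaries["sow"]])
    except KeyError as err:
        raise ValidationError(f"sow {err} missing from the pedigree") from err
    y = np.column_stack([summaries["mean_tnb"].to_numpy(float), summaries["log_var_tnb"].to_numpy(float)])
    nlit = summaries["n_litters"].to_numpy(float)
    wts = np.column_stack([nlit, (nlit - 1.0) / 2.0])
    design = ModelDesign(
        response=y,
        fixed=summaries[["fys"]],
        random=[RandomEffect("additive", codes, len(ped), covariance=PEDIGREE, ped=ped)],
        weights=wts,
        residual_correlated=True,
    )
    v1, v2 = np.var(y[:, 0]), np.var(y[:, 1])
    start = VarianceComponents(
        residual=np.array([0.6 * v1, 0.6 * v2]),
        terms={"additive": np.array([[0.3 * v1, 0.0], [0.0, 0.3 * v2]])},
    )
    vc, fit, _ = estimate_reml(design, start, max_iter=max_iter, compute_se=compute_se, strict=False)
    return vc, fit
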