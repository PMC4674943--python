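"""Multi-SNP Bayesian variable-selection GWAS on deregressed EBVs.

The association model regresses weighted pseudo-phenotypes on all SNPs
simultaneously,

    y = mu + X beta + e,    e ~ N(0, sigma_e^2 W_t),

where W_t is diagonal with elements 1/w_i (w_i the deregression weights)
and each SNP effect follows a two-component normal mixture

    beta_j ~ pi_0 N(0, sigma_g0^2) + pi_1 N(0, sigma_g1^2),

with a small fixed null variance sigma_g0^2 and a large-effect variance
sigma_g1^2.  A Markov chain samples, per SNP, the mixture indicator and
effect from their conjugate conditionals (with the effect integrated out of
the indicator update), the intercept from its Gibbs conditional, and
sigma_g1^2 and sigma_e^2 by random-walk Metropolis-Hastings on the log
scale.  The posterior inclusion probability p_hat (fraction of post-burn-in
cycles a SNP spends in the large component) converts to a Bayes factor

    BF = (p_hat / (1 - p_hat)) / (pi_1 / pi_0),

with BF >= 30 labelled a very strong association and BF >= 150 decisive.
The variance explained by a SNP is its genic variance 2 p q beta_bar^2 as a
fraction of the total genetic variance captured by all SNPs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from vargwas.errors import ConfigurationError, DomainError, ValidationError

log = logging.getLogger(__name__)

BF_VERY_STRONG = 30.0
BF_DECISIVE = 150.0


@dataclass
class BvsConfig:
    """Sampler settings.

    pi1 : prior probability of the large-effect component (default 0.001,
        i.e. one SNP in a thousand per cycle).
    n_cycles : MCMC cycles (default 500,000).
    burn_in_fraction : fraction of cycles discarded (default 0.1).
    mh_step : SD of the log-scale random-walk proposals for sigma_g1^2 and
        sigma_e^2 (default 0.003; the sensitivity setting is 0.004).
    large_var_fraction : fraction of phenotypic variance assigned a priori
        to the large-effect component, used to initialize sigma_g1^2.
    sigma_g0_ratio : fixed null-component variance as a fraction of the
        initial sigma_g1^2.
    """

    pi1: float = 0.001
    n_cycles: int = 500_000
    burn_in_fraction: float = 0.1
    mh_step: float = 0.003
    seed: int = 0
    n_chains: int = 1
    large_var_fraction: float = 0.3
    sigma_g0_ratio: float = 1e-4

    def __post_init__(self):
        if not 0 < self.pi1 < 1:
            raise ConfigurationError("pi1 must lie in (0, 1)")
        if not 0 <= self.burn_in_fraction < 1:
            raise ConfigurationError("burn_in_fraction must lie in [0, 1)")
        if self.n_cycles <= self.burn_in():
            raise ConfigurationError("n_cycles must exceed the burn-in")
        if self.n_chains < 1:
            raise ConfigurationError("n_chains must be >= 1")

    def burn_in(self) -> int:
        return int(self.n_cycles * self.burn_in_fraction)


@dataclass
class BvsResult:
    """Per-SNP posterior summaries plus chain-level diagnostics."""

    snps: pd.DataFrame
    mu: float
    sigma_e2: float
    sigma_g1_2: float
    sigma_g0_2: float
    config: BvsConfig
    deviance: list = field(default_factory=list)
    mean_included: float = 0.0
    mh_acceptance: float = 0.0
    rhat: float | None = None

    def significant(self, cut: float = BF_VERY_STRONG) -> pd.DataFrame:
        return self.snps.loc[self.snps["bf"] >= cut].reset_index(drop=True)


# ---------------------------------------------------------------------------
# the sampler kernel
# ---------------------------------------------------------------------------
@njit(cache=True, fastmath=True)
def _bvs_kernel(XT, y, w, pi1, n_cycles, burn, mh_step, v0, v1_init, ve_init, seed):  # pragma: no cover
    np.random.seed(seed)
    m, n = XT.shape
    WXT = np.empty_like(XT)
    xtwx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            WXT[j, i] = w[i] * XT[j, i]
            s += w[i] * XT[j, i] * XT[j, i]
        xtwx[j] = s
    sw = np.sum(w)
    beta = np.zeros(m)
    delta = np.zeros(m, dtype=np.int64)
    mu = np.sum(w * y) / sw
    r = y - mu
    v1 = v1_init
    ve = ve_init
    log_pi1 = np.log(pi1)
    log_pi0 = np.log(1.0 - pi1)

    incl = np.zeros(m)
    beta_sum = np.zeros(m)
    mu_sum = 0.0
    v1_sum = 0.0
    ve_sum = 0.0
    n_incl_sum = 0.0
    deviance = np.empty(n_cycles)
    n_keep = n_cycles - burn
    accepts = 0.0
    proposals = 0.0
    logw_sum = np.sum(np.log(w))

    for cyc in range(n_cycles):
        # intercept
        r += mu
        mu_mean = np.sum(w * r) / sw
        mu = mu_mean + np.random.normal() * np.sqrt(ve / sw)
        r -= mu

        n_in = 0
        ss1 = 0.0
        for j in range(m):  # noqa: PLR1702 — hot loop kept flat for numba
            bj = beta[j]
            t = 0.0
            for i in range(n):
                t += WXT[j, i] * r[i]
            t = (t + xtwx[j] * bj) / ve
            q = xtwx[j] / ve
            V0 = 1.0 / (q + 1.0 / v0)
            V1 = 1.0 / (q + 1.0 / v1)
            l0 = log_pi0 + 0.5 * np.log(V0 / v0) + 0.5 * t * t * V0
            l1 = log_pi1 + 0.5 * np.log(V1 / v1) + 0.5 * t * t * V1
            p1 = 1.0 / (1.0 + np.exp(l0 - l1))
            if np.random.random() < p1:
                delta[j] = 1
                Vk = V1
            else:
                delta[j] = 0
                Vk = V0
            bnew = Vk * t + np.random.normal() * np.sqrt(Vk)
            db = bj - bnew
            if db != 0.0:
                for i in range(n):
                    r[i] += XT[j, i] * db
            beta[j] = bnew
            if delta[j] == 1:
                n_in += 1
                ss1 += bnew * bnew

        # burn-in adaptation: conjugate refresh of the variances so the
        # sampler finds the data scale before the posterior is accumulated
        if cyc < burn:
            if n_in >= 1:
                v1 = ss1 / np.random.chisquare(n_in)
                if v1 < 2.0 * v0:
                    v1 = 2.0 * v0
                elif v1 > 1e6:
                    v1 = 1e6
            rss0 = 0.0
            for i in range(n):
                rss0 += w[i] * r[i] * r[i]
            ve = rss0 / np.random.chisquare(n)

        # MH update of the large-effect variance (log-scale random walk)
        prop = v1 * np.exp(np.random.normal() * mh_step)
        if 1e-12 < prop < 1e9:
            ll_cur = -0.5 * (n_in * np.log(v1) + ss1 / v1)
            ll_new = -0.5 * (n_in * np.log(prop) + ss1 / prop)
            proposals += 1.0
            if np.log(np.random.random()) < ll_new - ll_cur:
                v1 = prop
                accepts += 1.0
        # MH update of the residual variance
        rss = 0.0
        for i in range(n):
            rss += w[i] * r[i] * r[i]
        prop = ve * np.exp(np.random.normal() * mh_step)
        if 1e-12 < prop < 1e9:
            ll_cur = -0.5 * (n * np.log(ve) + rss / ve)
            ll_new = -0.5 * (n * np.log(prop) + rss / prop)
            proposals += 1.0
            if np.log(np.random.random()) < ll_new - ll_cur:
                ve = prop
                accepts += 1.0
                rss_ve = rss / ve
            else:
                rss_ve = rss / ve
        else:
            rss_ve = rss / ve

        deviance[cyc] = n * np.log(2.0 * np.pi * ve) - logw_sum + rss_ve
        if cyc >= burn:
            for j in range(m):
                incl[j] += delta[j]
                beta_sum[j] += beta[j]
            mu_sum += mu
            v1_sum += v1
            ve_sum += ve
            n_incl_sum += n_in

    return (
        incl / n_keep,
        beta_sum / n_keep,
        mu_sum / n_keep,
        v1_sum / n_keep,
        ve_sum / n_keep,
        n_incl_sum / n_keep,
        deviance,
        accepts / max(proposals, 1.0),
    )


# ---------------------------------------------------------------------------
# public interface
# ---------------------------------------------------------------------------
def run_bvs(
    debv: pd.DataFrame,
    geno: pd.DataFrame,
    cfg: BvsConfig | None = None,
    total_gvar: float | None = None,
) -> BvsResult:
    """Run the Bayesian variable-selection GWAS.

    Parameters
    ----------
    debv : DataFrame ``animal, debv, weight`` of deregressed proofs.
    geno : imputed dosage matrix (animals x SNPs, no missing values); every
        animal in ``debv`` must be genotyped.
    total_gvar : denominator for the percentage of genetic variance; when
        None, the sum of genic variances 2 p q beta_bar^2 over all SNPs.

    The sampler is exactly reproducible for a given seed, cycle count and
    chain count.  Multiple chains (different seed offsets) are averaged for
    the point estimates and feed the Gelman-Rubin deviance diagnostic.
    """
    cfg = cfg or BvsConfig()
    for col in ("animal", "debv", "weight"):
        if col not in debv.columns:
            raise ValidationError(f"deregressed records missing column {col!r}")
    ids = debv["animal"].astype(str)
    geno_ids = set(map(str, geno.index))
    orphans = sorted(set(ids) - geno_ids)
    if orphans:
        raise ValidationError(f"{len(orphans)} animal(s) lack genotypes (first: {orphans[:5]})")
    y = debv["debv"].to_numpy(float)
    w = debv["weight"].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite deregressed EBVs")
    if np.any(w <= 0):
        raise ValidationError("weights must be strictly positive")
    X = geno.loc[ids].to_numpy(float)
    if np.isnan(X).any():
        raise ValidationError("genotype matrix contains missing values; impute first")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [str(c) for c, s in zip(geno.columns, sd) if s == 0][:5]
        raise ValidationError(f"constant SNP column(s) after QC (first: {bad}); filter before the GWAS")

    p = X.mean(axis=0) / 2.0
    XcT = np.ascontiguousarray((X - X.mean(axis=0)).T)

    vary = float(np.var(y))
    mean_2pq = float(np.mean(2.0 * p * (1.0 - p)))
    n_large = max(cfg.pi1 * XcT.shape[0], 1.0)
    v1_init = cfg.large_var_fraction * vary / (n_large * mean_2pq)
    v0 = cfg.sigma_g0_ratio * v1_init
    ve_init = 0.8 * vary

    p_hats, betas, stats, traces = [], [], [], []
    for chain in range(cfg.n_chains):
        seed = int(cfg.seed + chain) % (2**31 - 1)
        out = _bvs_kernel(
            XcT,
            y,
            w,
            cfg.pi1,
            cfg.n_cycles,
            cfg.burn_in(),
            cfg.mh_step,
            v0,
            v1_init,
            ve_init,
            seed,
        )
        p_hat, beta_bar, mu, v1, ve, n_incl, deviance, acc = out
        p_hats.append(p_hat)
        betas.append(beta_bar)
        stats.append((mu, v1, ve, n_incl, acc))
        traces.append(deviance[cfg.burn_in() :])

    p_hat = np.mean(p_hats, axis=0)
    beta_bar = np.mean(betas, axis=0)
    mu, v1, ve, n_incl, acc = (float(np.mean([s[k] for s in stats])) for k in range(5))
    rhat = gelman_rubin(traces) if cfg.n_chains >= 2 else None

    var_snp = 2.0 * p * (1.0 - p) * beta_bar**2
    denom = float(total_gvar) if total_gvar is not None else float(var_snp.sum())
    with np.errstate(invalid="ignore"):
        bf = bayes_factor(p_hat, cfg.pi1)
    snps = pd.DataFrame(
        {
            "snp": [str(c) for c in geno.columns],
            "freq": p,
            "maf": np.minimum(p, 1 - p),
            "p_hat": p_hat,
            "effect": beta_bar,
            "var_snp": var_snp,
            "pct_gvar": 100.0 * var_snp / denom if denom > 0 else np.nan,
            "bf": bf,
        }
    )
    snps["significance"] = [classify_bf(b) for b in snps["bf"]]
    return BvsResult(
        snps=snps,
        mu=mu,
        sigma_e2=ve,
        sigma_g1_2=v1,
        sigma_g0_2=v0,
        config=cfg,
        deviance=traces,
        mean_included=n_incl,
        mh_acceptance=acc,
        rhat=rhat,
    )


def bayes_factor(p_hat, pi1):
    """Posterior odds of the large component over prior odds."""
    p_hat = np.asarray(p_hat, float)
    if np.any((p_hat < 0) | (p_hat > 1)):
        raise DomainError("posterior probabilities must lie in [0, 1]")
    if not 0 < pi1 < 1:
        raise DomainError("pi1 must lie in (0, 1)")
    if np.any(p_hat == 1):
        warnings.warn("posterior inclusion probability of 1; Bayes factor is infinite", stacklevel=2)
    prior_odds = pi1 / (1.0 - pi1)
    with np.errstate(divide="ignore"):
        out = (p_hat / (1.0 - p_hat)) / prior_odds
    return out if out.ndim else float(out)


def classify_bf(bf: float) -> str:
    """Kass-Raftery-style label: >= 30 'very strong', >= 150 'decisive'."""
    if bf < 0:
        raise DomainError("Bayes factor must be non-negative")
    if bf >= BF_DECISIVE:
        return "decisive"
    if bf >= BF_VERY_STRONG:
        return "very strong"
    return "not significant"


def allele_substitution_effect(var_snp: float, p: float) -> float:
    """Per-allele-copy effect implied by a genic variance,
    alpha = sqrt(var_snp / (2 p q)); symmetric in p <-> 1-p."""
    if not 0 < p < 1:
        raise DomainError("allele frequency must lie strictly between 0 and 1")
    if var_snp < 0:
        raise DomainError("genic variance must be non-negative")
    return float(np.sqrt(var_snp / (2.0 * p * (1.0 - p))))


def variance_explained(beta_bar: float, p: float, total_gvar: float) -> float:
    """Percent of total genetic variance explained by one SNP,
    100 * 2 p q beta_bar^2 / total_gvar."""
    if total_gvar <= 0:
        raise DomainError("total genetic variance must be positive")
    if not 0 < p < 1:
        raise DomainError("allele frequency must lie strictly between 0 and 1")
    return 100.0 * 2.0 * p * (1.0 - p) * beta_bar**2 / total_gvar


def gelman_rubin(traces) -> float:
    """Potential-scale-reduction factor of >= 2 equal-length chains.

    R_hat = sqrt(((n-1)/n W + B/n) / W); convergence is usually declared at
    R_hat < 1.1.  For a single chain, split it in half and pass both pieces.
    """
    if len(traces) < 2:
        raise ValidationError(
            "Gelman-Rubin needs at least two chains; split a single chain in half and pass both pieces"
        )
    lengths = {len(t) for t in traces}
    if len(lengths) != 1:
        raise ValidationError("chains must have equal length")
    n = lengths.pop()
    if n < 2:
        raise ValidationError("chains too short")
    arr = np.asarray(traces, float)
    means = arr.mean(axis=1)
    W = float(np.mean(arr.var(axis=1, ddof=1)))
    B_over_n = float(np.var(means, ddof=1))
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B_over_n
    # the (n-1)/n factor can push the ratio marginally below 1; floor it
    return float(max(np.sqrt(var_plus / W), 1.0))


def chromosome_variance_summary(snps: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Percent of genetic variance per chromosome split into the three
    Bayes-factor strata (BF >= 30, 10 <= BF < 30, BF < 10)."""
    df = snps.merge(meta[["snp", "chrom"]], on="snp", how="left")
    df["stratum"] = np.select(
        [df["bf"] >= BF_VERY_STRONG, df["bf"] >= 10.0],
        ["BF>=30", "10<=BF<30"],
        default="BF<10",
    )
    out = df.pivot_table(index="chrom", columns="stratum", values="pct_gvar", aggfunc="sum", fill_value=0.0)
    return out.reset_index()
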