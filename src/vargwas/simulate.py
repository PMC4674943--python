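"""Ground-truth simulation of pedigrees, genotypes and repeated litter records.

The generative model mirrors the analysis model: litter size for sow i in
parity j is

    y_ij = mu + parity_j + fys_ij + a_i + pe_i + e_ij,
    e_ij ~ N(0, exp(eta_i)),   eta_i = mu_v + a_v,i + pe_v,i,

where the additive pairs (a, a_v) are sampled down the pedigree by bivariate
Mendelian sampling (so that their joint covariance is S_a kronecker A) and
the permanent sow pairs (pe, pe_v) are iid bivariate normal.  Planted QTL
add dosage effects to a (mean QTL) or to a_v (vQTL, additive on the
log-variance scale); the polygenic variance is reduced by the planted genic
variance so the totals stay at their nominal values.  Genotypes come from
gene dropping founder alleles drawn at frequencies uniform in a MAF range.

All randomness flows through numpy's integer-state PCG64 generator, so any
seed reproduces a dataset exactly, across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from vargwas.errors import ConfigurationError
from vargwas.pedigree import Pedigree, mendelian_sampling_variance

# parity profile of litter size (rise to mid parities, then decline), on the
# pooled 1..10 scale
PARITY_EFFECTS = np.array([0.0, 0.6, 0.9, 0.9, 0.7, 0.4, 0.1, -0.2, -0.5, -0.8])


@dataclass
class PhenotypeParams:
    """Generating parameters of the mean / residual-variance model.

    Defaults correspond to a litter-size-like trait: mean 13.5 piglets,
    additive variance 1.2, permanent sow variance 0.7, mean residual
    variance ~6.5 (set through mu_v), genetic variance in log residual
    variance 0.05 with genetic correlation +0.5 to the mean, permanent
    variance in log residual variance 0.15 with correlation -0.8.
    """

    mu: float = 13.5
    sigma_a2: float = 1.2
    sigma_av2: float = 0.05
    r_a: float = 0.5
    sigma_pe2: float = 0.7
    sigma_pev2: float = 0.15
    r_pe: float = -0.8
    mean_residual_variance: float = 6.5
    fys_sd: float = 0.3

    @property
    def mu_v(self) -> float:
        # E[exp(mu_v + a_v + pe_v)] = exp(mu_v + (sigma_av2 + sigma_pev2)/2)
        return float(np.log(self.mean_residual_variance) - 0.5 * (self.sigma_av2 + self.sigma_pev2))

    def cov_a(self) -> np.ndarray:
        c = self.r_a * np.sqrt(self.sigma_a2 * self.sigma_av2)
        return np.array([[self.sigma_a2, c], [c, self.sigma_av2]])

    def cov_pe(self) -> np.ndarray:
        c = self.r_pe * np.sqrt(self.sigma_pe2 * self.sigma_pev2)
        return np.array([[self.sigma_pe2, c], [c, self.sigma_pev2]])


@dataclass
class SimulationTruth:
    """Everything needed to score an analysis of a simulated dataset."""

    params: dict
    seed: int
    a: pd.Series | None = None
    a_v: pd.Series | None = None
    pe: pd.Series | None = None
    pe_v: pd.Series | None = None
    qtl: pd.DataFrame | None = None

    def to_yaml(self, path) -> None:
        doc = {"params": {k: float(v) if np.isscalar(v) else v for k, v in self.params.items()}, "seed": int(self.seed)}
        if self.qtl is not None and len(self.qtl):
            doc["qtl"] = self.qtl.to_dict(orient="records")
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------
def simulate_pedigree(
    n_founders: int = 450,
    n_generations: int = 1,
    litters_per_dam: int = 5,
    seed: int = 0,
    male_fraction: float = 0.1,
    final_generation_female: bool = True,
) -> tuple[Pedigree, pd.DataFrame]:
    """Random-mating pedigree with non-overlapping generations.

    Founders are unrelated; in each later generation every dam of the
    previous generation produces ``litters_per_dam`` offspring by a randomly
    drawn sire of that generation.  Returns the pedigree and a metadata
    table ``animal, sex, generation`` (sex in {'M','F'}).
    """
    if n_founders < 2:
        raise ConfigurationError("need at least two founders")
    if n_generations < 0:
        raise ConfigurationError("n_generations must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    meta = []
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"A{counter:06d}"

    n_males = max(1, int(round(n_founders * male_fraction)))
    founders = []
    for k in range(n_founders):
        aid = new_id()
        sex = "M" if k < n_males else "F"
        records.append((aid, None, None))
        meta.append((aid, sex, 0))
        founders.append((aid, sex))
    prev = founders
    for g in range(1, n_generations + 1):
        sires = [a for a, s in prev if s == "M"]
        dams = [a for a, s in prev if s == "F"]
        if not sires or not dams:
            raise ConfigurationError("a generation has no available sires or dams")
        cur = []
        for dam in dams:
            sire = sires[rng.integers(len(sires))]
            for _ in range(litters_per_dam):
                aid = new_id()
                if g == n_generations and final_generation_female:
                    sex = "F"
                else:
                    sex = "M" if rng.random() < male_fraction else "F"
                records.append((aid, sire, dam))
                meta.append((aid, sex, g))
                cur.append((aid, sex))
        prev = cur
    ped = Pedigree.from_records(records)
    info = pd.DataFrame(meta, columns=["animal", "sex", "generation"])
    return ped, info


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------
def simulate_genotypes(
    ped: Pedigree,
    n_snps: int = 1000,
    maf_range: tuple = (0.05, 0.5),
    n_qtl: int = 0,
    n_vqtl: int = 0,
    mean_effects=None,
    var_effects=None,
    n_chromosomes: int = 18,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene-drop genotypes for every pedigree animal.

    Founder alleles are Bernoulli draws at per-SNP frequencies uniform in
    ``maf_range``; descendants receive one random allele per parent per
    locus.  ``n_qtl`` mean-QTL and ``n_vqtl`` vQTL are planted on distinct
    SNPs with allele-substitution effects taken from ``mean_effects`` /
    ``var_effects`` (trait units, resp. log-variance units, per allele copy).

    Returns (dosages animals x SNPs, metadata ``snp, chrom, pos, score``,
    qtl table ``snp, kind, effect, freq``).
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ConfigurationError("maf_range must lie inside (0, 0.5]")
    if n_qtl + n_vqtl > n_snps:
        raise ConfigurationError("more planted QTL than SNPs")
    rng = np.random.default_rng(seed)
    n = len(ped)
    freqs = rng.uniform(lo, hi, n_snps)
    hap = np.empty((n, 2, n_snps), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        for slot, parent in ((0, s), (1, d)):
            if parent < 0:
                hap[i, slot] = rng.random(n_snps) < freqs
            else:
                pick = rng.integers(0, 2, n_snps)
                hap[i, slot] = hap[parent, pick, np.arange(n_snps)]
    geno = pd.DataFrame(
        hap.sum(axis=1, dtype=np.int16),
        index=pd.Index(ped.ids, name="animal"),
        columns=[f"SNP{j + 1:05d}" for j in range(n_snps)],
        dtype=float,
    )
    meta = pd.DataFrame(
        {
            "snp": geno.columns,
            "chrom": [str(1 + j % n_chromosomes) for j in range(n_snps)],
            "pos": np.arange(1, n_snps + 1) * 10_000,
            "score": 1.0,
        }
    )
    chosen = rng.choice(n_snps, size=n_qtl + n_vqtl, replace=False)
    rows = []
    realized = geno.mean(axis=0).to_numpy() / 2.0
    for k, j in enumerate(chosen[:n_qtl]):
        eff = 0.1 if mean_effects is None else float(np.atleast_1d(mean_effects)[k % len(np.atleast_1d(mean_effects))])
        rows.append((geno.columns[j], "mean", eff, realized[j]))
    for k, j in enumerate(chosen[n_qtl:]):
        eff = 0.05 if var_effects is None else float(np.atleast_1d(var_effects)[k % len(np.atleast_1d(var_effects))])
        rows.append((geno.columns[j], "variance", eff, realized[j]))
    qtl = pd.DataFrame(rows, columns=["snp", "kind", "effect", "freq"])
    return geno, meta, qtl


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------
def _sample_bivariate_pedigree(ped: Pedigree, cov: np.ndarray, rng) -> np.ndarray:
    """(n, 2) draws with covariance cov kronecker A, by Mendelian sampling."""
    d = mendelian_sampling_variance(ped)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    n = len(ped)
    out = np.empty((n, 2))
    z = rng.standard_normal((n, 2))
    for i in range(n):
        m = np.sqrt(d[i]) * (L @ z[i])
        parent_avg = np.zeros(2)
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                parent_avg += 0.5 * out[p]
        out[i] = parent_avg + m
    return out


def simulate_phenotypes(
    ped: Pedigree,
    params: PhenotypeParams | None = None,
    parities_per_sow: int = 5,
    n_fys_classes: int = 25,
    seed: int = 0,
    sows=None,
    qtl: pd.DataFrame | None = None,
    geno: pd.DataFrame | None = None,
    integer_counts: bool = False,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Repeated litter records under the mean + log-variance model.

    ``sows`` selects the phenotyped animals (default: all animals without
    recorded offspring in the pedigree, i.e. the youngest generation).  When
    a ``qtl`` table (from :func:`simulate_genotypes`) and matching ``geno``
    are given, the planted dosage effects are added to a (mean QTL) or a_v
    (vQTL) and the polygenic variances reduced by the planted genic variance.

    Returns (records ``sow, parity, fys, tnb``, :class:`SimulationTruth`).
    """
    params = params or PhenotypeParams()
    for name, r in (("r_a", params.r_a), ("r_pe", params.r_pe)):
        if abs(r) > 1:
            raise ConfigurationError(f"{name} outside [-1, 1]")
    rng = np.random.default_rng(seed)

    # split planted genic variance out of the polygenic components
    var_qtl_mean = var_qtl_disp = 0.0
    if qtl is not None and len(qtl):
        if geno is None:
            raise ConfigurationError("qtl effects given without genotypes")
        pq = 2.0 * qtl["freq"] * (1.0 - qtl["freq"])
        var_qtl_mean = float((pq * qtl["effect"] ** 2)[qtl["kind"] == "mean"].sum())
        var_qtl_disp = float((pq * qtl["effect"] ** 2)[qtl["kind"] == "variance"].sum())
        if var_qtl_mean >= params.sigma_a2 or var_qtl_disp >= params.sigma_av2:
            raise ConfigurationError("planted QTL variance exceeds the additive variance")
    poly = PhenotypeParams(**{**params.__dict__})
    poly.sigma_a2 = params.sigma_a2 - var_qtl_mean
    poly.sigma_av2 = params.sigma_av2 - var_qtl_disp
    try:
        np.linalg.cholesky(poly.cov_a() + 1e-12 * np.eye(2))
        np.linalg.cholesky(poly.cov_pe() + 1e-12 * np.eye(2))
    except np.linalg.LinAlgError as err:
        raise ConfigurationError("requested covariance matrices are not positive definite") from err

    av = _sample_bivariate_pedigree(ped, poly.cov_a(), rng)
    a = pd.Series(av[:, 0], index=pd.Index(ped.ids, name="animal"))
    a_v = pd.Series(av[:, 1], index=pd.Index(ped.ids, name="animal"))
    if qtl is not None and len(qtl):
        for _, row in qtl.iterrows():
            dos = geno[row["snp"]].reindex(a.index).to_numpy(float)
            centered = (dos - 2.0 * row["freq"]) * row["effect"]
            if row["kind"] == "mean":
                a += centered
            else:
                a_v += centered

    if sows is None:
        has_offspring = np.zeros(len(ped), bool)
        has_offspring[ped.sire[ped.sire >= 0]] = True
        has_offspring[ped.dam[ped.dam >= 0]] = True
        sows = [ped.ids[i] for i in range(len(ped)) if not has_offspring[i]]
    sows = [str(s) for s in sows]
    idx = {x: i for i, x in enumerate(ped.ids)}
    n_sows = len(sows)

    Lpe = np.linalg.cholesky(poly.cov_pe() + 1e-12 * np.eye(2))
    pe_pairs = rng.standard_normal((n_sows, 2)) @ Lpe.T
    pe = pd.Series(pe_pairs[:, 0], index=pd.Index(sows, name="animal"))
    pe_v = pd.Series(pe_pairs[:, 1], index=pd.Index(sows, name="animal"))

    fys_effects = rng.normal(0.0, params.fys_sd, n_fys_classes)
    rows = []
    for k, sow in enumerate(sows):
        i = idx[sow]
        eta = params.mu_v + a_v.iloc[i] + pe_pairs[k, 1]
        sd = np.sqrt(np.exp(eta))
        for parity in range(1, parities_per_sow + 1):
            f = int(rng.integers(n_fys_classes))
            pclass = min(parity, 10)
            y = params.mu + PARITY_EFFECTS[pclass - 1] + fys_effects[f] + av[i, 0] + pe_pairs[k, 0] + rng.normal(0.0, sd)
            rows.append((sow, parity, f"fys{f + 1:03d}", y))
    records = pd.DataFrame(rows, columns=["sow", "parity", "fys", "tnb"])
    if integer_counts:
        records["tnb"] = records["tnb"].round().clip(lower=0, upper=40).astype(int)

    truth = SimulationTruth(
        params={
            "mu": params.mu,
            "mu_v": params.mu_v,
            "sigma_a2": params.sigma_a2,
            "sigma_av2": params.sigma_av2,
            "r_a": params.r_a,
            "sigma_pe2": params.sigma_pe2,
            "sigma_pev2": params.sigma_pev2,
            "r_pe": params.r_pe,
            "mean_residual_variance": params.mean_residual_variance,
            "parities_per_sow": parities_per_sow,
            "n_fys_classes": n_fys_classes,
        },
        seed=seed,
        a=a,
        a_v=a_v,
        pe=pe,
        pe_v=pe_v,
        qtl=qtl,
    )
    return records, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------
def desk_preset(seed: int = 0, params: PhenotypeParams | None = None):
    """The standard desk-scale scenario: 50 founder sires + 400 founder dams,
    2,000 phenotyped sows with 5 parities each, 25 farm-year-season classes.

    Returns (pedigree, info, records, truth)."""
    ped, info = simulate_pedigree(
        n_founders=450, n_generations=1, litters_per_dam=5, seed=seed, male_fraction=50 / 450
    )
    sows = info.loc[info["generation"] == 1, "animal"]
    records, truth = simulate_phenotypes(
        ped, params=params, parities_per_sow=5, n_fys_classes=25, seed=seed + 1, sows=sows
    )
    return ped, info, records, truth
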