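"""End-to-end orchestration: edit -> REML -> DHGLM -> deregress -> QC -> GWAS.

Each stage writes self-describing TSV artifacts (header comments carry the
package version, the global seed and a hash of the configuration) into the
run's output directory, and any stage failure aborts the run with the stage
name.  The GWAS runs twice — once on deregressed proofs for the trait mean,
once for its residual variance — sharing one genotype QC pass.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import vargwas
from vargwas.deregression import deregress, filter_reliability, reliability
from vargwas.dhglm import run_dhglm, univariate_refits
from vargwas.errors import ConfigurationError, ValidationError
from vargwas.genotype_qc import (
    QcThresholds,
    filter_animals,
    filter_snps,
    impute_mean,
    read_dosage_csv,
    read_plink_text,
)
from vargwas.gwas import BvsConfig, chromosome_variance_summary, run_bvs
from vargwas.pedigree import Pedigree, compute_inbreeding
from vargwas.phenotype import edit_records
from vargwas.mixed_model import heritability

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    pedigree: str
    phenotypes: str
    genotypes: str  # dosage CSV, or "ped:<path>;map:<path>"
    snp_metadata: str | None
    outdir: str
    seed: int = 0
    dhglm_tol: float = 1e-6
    dhglm_max_iter: int = 100
    deregression_c: float = 0.5
    reliability_threshold: float = 0.05
    qc: QcThresholds = field(default_factory=QcThresholds)
    bvs: BvsConfig = field(default_factory=BvsConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        qc = QcThresholds(**doc.pop("qc", {}))
        bvs = BvsConfig(**doc.pop("bvs", {}))
        return cls(qc=qc, bvs=bvs, **doc)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k not in ("qc", "bvs")}
        d["qc"] = dict(self.qc.__dict__)
        d["bvs"] = dict(self.bvs.__dict__)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # analytic identity only; not where results land
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    header = f"# vargwas {vargwas.__version__} seed={cfg.seed} config={cfg.config_hash()}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


class _Stage:
    def __init__(self, name):
        self.name = name

    def __enter__(self):
        self.t0 = time.time()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.time() - self.t0
        if exc_type is not None:
            log.error("stage %s: FAILED after %.1fs (%s)", self.name, dt, exc)
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s: done in %.1fs", self.name, dt)


def _load_genotypes(cfg: PipelineConfig):
    if cfg.genotypes.startswith("ped:"):
        parts = dict(p.split(":", 1) for p in cfg.genotypes.split(";"))
        geno, meta = read_plink_text(parts["ped"], parts["map"])
    else:
        geno = read_dosage_csv(cfg.genotypes)
        meta = None
    if cfg.snp_metadata:
        meta = pd.read_csv(cfg.snp_metadata, dtype={"snp": str, "chrom": str})
    if meta is None:
        raise ConfigurationError("SNP metadata required when genotypes are a dosage CSV")
    return geno, meta


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns a report dict of stage summaries."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label, path in (("pedigree", cfg.pedigree), ("phenotypes", cfg.phenotypes)):
        if not Path(path).exists():
            raise ConfigurationError(f"{label} file not found: {path}")
    if not cfg.genotypes.startswith("ped:") and not Path(cfg.genotypes).exists():
        raise ConfigurationError(f"genotype file not found: {cfg.genotypes}")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    report: dict = {"config_hash": cfg.config_hash()}

    with _Stage("load"):
        ped = Pedigree.from_csv(cfg.pedigree)
        raw = pd.read_csv(cfg.phenotypes)
        geno, meta = _load_genotypes(cfg)
        orphans = sorted(set(raw["sow"].astype(str)) - set(ped.ids))
        if orphans:
            raise ValidationError(f"{len(orphans)} sows absent from pedigree (first: {orphans[:5]})")

    with _Stage("edit"):
        records, edit_report = edit_records(raw)
        edit_report.to_frame().pipe(_write_tsv, outdir / "edit_report.tsv", cfg)
        report["n_records"] = len(records)

    with _Stage("dhglm"):
        result = run_dhglm(records, ped, tol=cfg.dhglm_tol, max_iter=cfg.dhglm_max_iter)
        comp = result.vc.to_frame()
        extra = pd.DataFrame(
            {
                "component": ["heritability_mean", "gcv_sde", "h2_residual_variance", "n_iterations"],
                "estimate": [
                    result.heritability_mean(),
                    result.gcv_sde,
                    result.h2_residual_variance(),
                    result.n_iterations,
                ],
            }
        )
        comp = pd.concat([comp, extra], ignore_index=True)
        _write_tsv(comp, outdir / "dhglm_components.tsv", cfg)
        report["dhglm"] = {
            "sigma_a2": result.sigma_a2,
            "sigma_av2": result.sigma_av2,
            "r_a": result.r_a,
            "r_pe": result.r_pe,
            "iterations": result.n_iterations,
        }

    with _Stage("deregress"):
        f = compute_inbreeding(ped)
        refits = univariate_refits(result, records, ped)
        ped_frame = ped.to_frame().set_index("animal")
        debv_sets = {}
        for trait, (vc_t, fit_t) in zip(("mean", "dispersion"), refits):
            ebv = fit_t.random_effects("additive", 0)
            se = fit_t.random_effect_se("additive", 0)
            sigma_a2 = vc_t.variance("additive")
            r2 = reliability(se.to_numpy(), f.reindex(ebv.index).to_numpy(), sigma_a2)
            recs = pd.DataFrame(
                {
                    "animal": ebv.index,
                    "ebv": ebv.to_numpy(),
                    "r2": r2,
                    "sire": ped_frame["sire"].reindex(ebv.index).to_numpy(),
                    "dam": ped_frame["dam"].reindex(ebv.index).to_numpy(),
                }
            )
            if trait == "mean":
                h2 = heritability(sigma_a2, vc_t.variance("pe"), vc_t.residual[0] * result.mean_residual_variance)
            else:
                # single-record heritability of the working response: its
                # sampling variance is ~2
                h2 = sigma_a2 / (sigma_a2 + vc_t.variance("pe") + 2.0)
            h2 = min(max(h2, 1e-4), 0.99)
            dereg, dereg_report = deregress(recs, sigma_a2, h2=h2, c=cfg.deregression_c)
            kept = filter_reliability(dereg, cfg.reliability_threshold)
            debv_sets[trait] = kept
            _write_tsv(kept.assign(trait=trait), outdir / f"debv_{trait}.tsv", cfg)
            report[f"debv_{trait}"] = {"n": len(kept), "dropped": dereg_report.n_dropped_no_information}

    with _Stage("genotype_qc"):
        kept_animals, animal_report = filter_animals(geno, ped, cfg.qc)
        geno_a = geno.loc[kept_animals]
        kept_snps, snp_report = filter_snps(geno_a, meta, cfg.qc)
        geno_qc = impute_mean(geno_a[kept_snps])
        qc_frame = pd.concat([animal_report.to_frame(), snp_report.to_frame()], ignore_index=True)
        _write_tsv(qc_frame, outdir / "qc_report.tsv", cfg)
        report["qc"] = {"animals": len(kept_animals), "snps": len(kept_snps)}

    for trait in ("mean", "dispersion"):
        with _Stage(f"gwas_{trait}"):
            debv = debv_sets[trait]
            genotyped = debv["animal"].astype(str).isin(set(map(str, geno_qc.index)))
            debv = debv.loc[genotyped].reset_index(drop=True)
            if not len(debv):
                raise ValidationError(f"no genotyped animals with deregressed proofs for {trait}")
            bvs_cfg = BvsConfig(**{**cfg.bvs.__dict__, "seed": cfg.seed + (0 if trait == "mean" else 1)})
            bvs = run_bvs(debv, geno_qc, bvs_cfg)
            out = bvs.snps.merge(meta[["snp", "chrom", "pos"]], on="snp", how="left")
            out["pos_mb"] = out["pos"] / 1e6
            table = out[
                ["snp", "chrom", "pos_mb", "maf", "effect", "p_hat", "bf", "pct_gvar", "significance"]
            ]
            _write_tsv(table, outdir / f"gwas_{trait}.tsv", cfg)
            sig = table.loc[table["bf"] >= 30.0]
            _write_tsv(sig, outdir / f"gwas_{trait}_significant.tsv", cfg)
            _write_tsv(
                chromosome_variance_summary(bvs.snps, meta), outdir / f"gwas_{trait}_by_chromosome.tsv", cfg
            )
            np.savetxt(outdir / f"gwas_{trait}_deviance.txt", bvs.deviance[0][:: max(len(bvs.deviance[0]) // 2000, 1)])
            report[f"gwas_{trait}"] = {
                "n_animals": len(debv),
                "n_significant": int((table["bf"] >= 30.0).sum()),
                "top_snp": table.sort_values("bf", ascending=False)["snp"].iloc[0],
                "mean_included": bvs.mean_included,
            }

    with open(outdir / "report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
    return report
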