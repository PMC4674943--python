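"""SNP- and animal-level genotype quality control.

Genotypes are additive dosages in {0, 1, 2} (count of a designated allele)
with NaN for missing calls.  SNP filters run in a fixed order — assay
quality score, sex-chromosome / unknown-position, minor allele frequency —
and animal filters (call rate, then pedigree Mendelian-inconsistency rate
from opposing homozygotes) run before MAF is computed, so frequencies
reflect the retained animals.  Missing calls surviving QC are imputed to
the SNP mean dosage 2p for the association design matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vargwas.errors import ValidationError
from vargwas.pedigree import Pedigree

log = logging.getLogger(__name__)

SEX_CHROMOSOMES = {"X", "Y", "SSCX", "SSCY", "23", "MT"}


@dataclass
class QcThresholds:
    min_quality: float = 0.15
    min_maf: float = 0.01
    min_call_rate: float = 0.95
    max_mendel_rate: float = 0.01


@dataclass
class QcReport:
    counts: dict = field(default_factory=dict)

    def add(self, rule: str, n: int) -> None:
        self.counts[rule] = int(n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rule": list(self.counts), "count": list(self.counts.values())})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------
def read_dosage_csv(path) -> pd.DataFrame:
    """Additive-dosage CSV: column ``animal`` plus one column per SNP with
    values in {0, 1, 2} or empty for missing."""
    df = pd.read_csv(path)
    if "animal" not in df.columns:
        raise ValidationError("dosage CSV must have an 'animal' column")
    df = df.set_index(df["animal"].astype(str)).drop(columns=["animal"])
    geno = df.astype(float)
    bad = ~(geno.isin([0.0, 1.0, 2.0]) | geno.isna())
    if bad.to_numpy().any():
        raise ValidationError("dosage values outside {0, 1, 2, missing}")
    geno.index.name = "animal"
    return geno


def read_plink_text(ped_path, map_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read PLINK-style text .ped/.map files into (dosages, metadata).

    The counted allele per SNP is the alphabetically first allele observed;
    '0' marks a missing allele call.  Metadata gets ``snp, chrom, pos`` from
    the .map (quality scores are not part of .map and default to 1.0).
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None, names=["chrom", "snp", "cm", "pos"], dtype=str)
    snps = mp["snp"].tolist()
    rows = []
    animals = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * len(snps):
                raise ValidationError(
                    f".ped row for {parts[1] if len(parts) > 1 else '?'} has {len(parts) - 6} allele fields, "
                    f"expected {2 * len(snps)}"
                )
            animals.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype="U2").reshape(len(animals), len(snps), 2)
    geno = np.full((len(animals), len(snps)), np.nan)
    for j in range(len(snps)):
        a = alleles[:, j, :]
        observed = sorted(set(a.ravel()) - {"0"})
        if not observed:
            continue
        counted = observed[0]
        missing = (a == "0").any(axis=1)
        geno[:, j] = (a == counted).sum(axis=1).astype(float)
        geno[missing, j] = np.nan
    dosages = pd.DataFrame(geno, index=pd.Index(animals, name="animal"), columns=snps)
    meta = pd.DataFrame(
        {"snp": snps, "chrom": mp["chrom"], "pos": pd.to_numeric(mp["pos"], errors="coerce"), "score": 1.0}
    )
    return dosages, meta


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------
def allele_frequency(geno: pd.DataFrame) -> pd.Series:
    """Frequency of the counted allele per SNP over non-missing calls."""
    return geno.mean(axis=0, skipna=True) / 2.0


def minor_allele_frequency(geno: pd.DataFrame) -> pd.Series:
    p = allele_frequency(geno)
    return np.minimum(p, 1.0 - p)


def call_rate(geno: pd.DataFrame) -> pd.Series:
    """Per-animal fraction of non-missing calls."""
    return geno.notna().mean(axis=1)


def impute_mean(geno: pd.DataFrame) -> pd.DataFrame:
    """Fill missing calls with the SNP mean dosage 2p."""
    return geno.fillna(geno.mean(axis=0))


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------
def filter_snps(
    geno: pd.DataFrame,
    meta: pd.DataFrame,
    thresholds: QcThresholds | None = None,
) -> tuple[list, QcReport]:
    """SNP filters, in order: quality score, sex chromosome or unknown
    position, minor allele frequency.  Returns kept SNP ids and a report
    with per-rule removal counts."""
    thresholds = thresholds or QcThresholds()
    meta = meta.copy()
    meta["snp"] = meta["snp"].astype(str)
    missing = set(map(str, geno.columns)) - set(meta["snp"])
    if missing:
        raise ValidationError(f"{len(missing)} SNP(s) missing from metadata (first: {sorted(missing)[:5]})")
    meta = meta.set_index("snp").loc[[str(c) for c in geno.columns]]
    report = QcReport()

    keep = pd.Series(True, index=meta.index)
    low_q = meta["score"].astype(float) < thresholds.min_quality
    report.add(f"quality score < {thresholds.min_quality}", (keep & low_q).sum())
    keep &= ~low_q

    chrom = meta["chrom"].astype(str).str.upper()
    sex_or_unknown = chrom.isin(SEX_CHROMOSOMES) | meta["pos"].isna()
    report.add("sex chromosome or unknown position", (keep & sex_or_unknown).sum())
    keep &= ~sex_or_unknown

    maf = minor_allele_frequency(geno)
    maf.index = maf.index.astype(str)
    low_maf = maf < thresholds.min_maf
    report.add(f"MAF < {thresholds.min_maf}", (keep & low_maf).sum())
    keep &= ~low_maf

    kept = [snp for snp in geno.columns if keep[str(snp)]]
    report.add("SNPs kept", len(kept))
    return kept, report


def mendelian_inconsistencies(geno: pd.DataFrame, ped: Pedigree) -> pd.DataFrame:
    """Opposing-homozygote conflicts between each genotyped animal and its
    genotyped parents.

    Returns a DataFrame indexed by animal with ``conflicts`` (count of loci
    where the offspring is homozygous for one allele and a parent for the
    other) and ``compared`` (loci with both genotypes non-missing, summed
    over available parents).
    """
    idx = {a: i for i, a in enumerate(ped.ids)}
    G = geno.to_numpy(float)
    animals = [str(a) for a in geno.index]
    pos = {a: k for k, a in enumerate(animals)}
    conflicts = np.zeros(len(animals), dtype=np.int64)
    compared = np.zeros(len(animals), dtype=np.int64)
    for k, a in enumerate(animals):
        if a not in idx:
            continue
        i = idx[a]
        for p in (ped.sire[i], ped.dam[i]):
            if p < 0:
                continue
            pid = ped.ids[p]
            if pid not in pos:
                continue
            gp = G[pos[pid]]
            go = G[k]
            both = ~np.isnan(gp) & ~np.isnan(go)
            conflicts[k] += int(np.sum(both & ((go == 2) & (gp == 0) | (go == 0) & (gp == 2))))
            compared[k] += int(both.sum())
    return pd.DataFrame({"conflicts": conflicts, "compared": compared}, index=pd.Index(animals, name="animal"))


def filter_animals(
    geno: pd.DataFrame,
    ped: Pedigree | None = None,
    thresholds: QcThresholds | None = None,
) -> tuple[list, QcReport]:
    """Animal filters: call rate < threshold first, then Mendelian
    inconsistency rate (conflicts / compared loci) above threshold."""
    thresholds = thresholds or QcThresholds()
    report = QcReport()
    cr = call_rate(geno)
    keep = cr >= thresholds.min_call_rate
    report.add(f"call rate < {thresholds.min_call_rate}", int((~keep).sum()))

    if ped is not None:
        sub = geno.loc[keep]
        mi = mendelian_inconsistencies(sub, ped)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(mi["compared"] > 0, mi["conflicts"] / mi["compared"], 0.0)
        bad = pd.Series(rate > thresholds.max_mendel_rate, index=mi.index)
        report.add(f"Mendelian inconsistency rate > {thresholds.max_mendel_rate}", int(bad.sum()))
        keep &= ~keep.index.astype(str).map(bad).fillna(False).to_numpy(bool)
    else:
        report.add("Mendelian inconsistency rate (no pedigree)", 0)

    kept = list(geno.index[keep])
    report.add("animals kept", len(kept))
    return kept, report
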