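"""Reading/writing genotype, haplotype, phenotype and pedigree data, plus QC.

Supported formats
-----------------
* PLINK text ``.ped``/``.map`` (read + write).  ``.map`` has 4 columns
  (chrom, id, cM, bp); ``.ped`` has 6 leading columns then two allele
  columns per SNP; allele "0" is a missing call.
* Phased VCF 4.x (read via :mod:`cyvcf2`, write as plain text).  Only
  biallelic records are used; unphased genotypes are an error.
* Plain TSV for phenotypes (id, value), pedigree (id, sire, mgs) and
  ancestral-allele annotation (id, allele).

Everything is oriented to the minor allele on input: haplotype code 1 and
genotype codes count the minor allele.  Ties at frequency 0.5 break to the
lexicographically smaller allele string so runs are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    GenotypeTable,
    HaplotypePanel,
    Pedigree,
    PhenotypeVector,
    make_variant_frame,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PLINK text dialect
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path) -> GenotypeTable:
    """Read a PLINK text .ped/.map pair into a minor-allele-coded table."""
    vmap = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos_bp"],
        dtype={"chrom": str, "id": str},
    )
    if vmap.shape[1] != 4:
        raise ValueError(f"{map_path}: .map must have 4 columns")
    if vmap["id"].duplicated().any():
        raise ValueError(f"{map_path}: duplicate variant ids")
    m = len(vmap)

    rows = []
    ids = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} columns, got {len(fields)}"
                )
            ids.append(fields[1])
            rows.append(fields[6:])
    alleles = np.array(rows, dtype=object).reshape(len(ids), m, 2)

    codes = np.full((len(ids), m), MISSING, dtype=np.int8)
    major, minor, mafs = [], [], []
    for j in range(m):
        a = alleles[:, j, :]
        obs = a[(a != "0")]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise ValueError(f"variant {vmap['id'][j]}: more than two alleles")
        if len(uniq) == 0:
            major.append("."); minor.append("."); mafs.append(np.nan)
            continue
        if len(uniq) == 1:  # monomorphic: minor allele unobserved
            major.append(uniq[0]); minor.append("."); mafs.append(0.0)
            missing = (a == "0").any(axis=1)
            codes[:, j] = 0
            codes[missing, j] = MISSING
            continue
        order = np.argsort(counts, kind="stable")
        if counts[0] == counts[1]:  # tie: lexicographically smaller is minor
            mi, maj = sorted(uniq)
        else:
            mi, maj = uniq[order[0]], uniq[order[1]]
        missing = (a == "0").any(axis=1)
        codes[:, j] = (a == mi).sum(axis=1)
        codes[missing, j] = MISSING
        major.append(maj); minor.append(mi)
        nonmiss = ~missing
        mafs.append((a[nonmiss] == mi).mean() if nonmiss.any() else np.nan)

    variants = make_variant_frame(
        vmap["id"], vmap["chrom"], vmap["pos_bp"], major, minor, maf=mafs
    )
    return GenotypeTable(codes, variants, ids)


def write_plink_text(gt: GenotypeTable, ped_path, map_path) -> None:
    v = gt.variants
    with open(map_path, "w") as fh:
        for _, row in v.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['pos_bp']}\n")
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(gt.ids):
            cols = [str(ind), str(ind), "0", "0", "0", "-9"]
            for j in range(gt.n_snps):
                c = gt.codes[i, j]
                mi, ma = v["allele_minor"][j], v["allele_major"][j]
                pair = {0: (ma, ma), 1: (mi, ma), 2: (mi, mi)}.get(int(c), ("0", "0"))
                cols.extend(pair)
            fh.write(" ".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Phased VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(vcf_path) -> HaplotypePanel:
    """Read a phased VCF into a HaplotypePanel (1 = minor allele).

    Multiallelic records are skipped (count logged); an unphased genotype
    raises, naming the offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    hap_rows = []
    ids, chroms, pos, refs, alts = [], [], [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = rec.genotypes  # [a, b, phased] per sample
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for s, g in enumerate(gts):
            if len(g) < 3 or not g[2]:
                raise ValueError(
                    f"unphased genotype for sample {samples[s]} at "
                    f"{rec.CHROM}:{rec.POS} ({rec.ID})"
                )
            col[2 * s] = g[0]
            col[2 * s + 1] = g[1]
        hap_rows.append(col)
        ids.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        chroms.append(str(rec.CHROM))
        pos.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    if n_multi:
        log.info("skipped %d multiallelic records in %s", n_multi, vcf_path)
    alleles = np.array(hap_rows, dtype=np.uint8).T  # hap x snp (ALT count)
    alleles = np.ascontiguousarray(alleles)

    # orient to minor allele
    alt_freq = alleles.mean(axis=0)
    major, minor = [], []
    for j in range(alleles.shape[1]):
        flip = alt_freq[j] > 0.5 or (alt_freq[j] == 0.5 and alts[j] > refs[j])
        if flip:
            alleles[:, j] = 1 - alleles[:, j]
            major.append(alts[j]); minor.append(refs[j])
        else:
            major.append(refs[j]); minor.append(alts[j])
    maf = alleles.mean(axis=0)
    variants = make_variant_frame(ids, chroms, pos, major, minor, maf=maf)
    hap_ids = samples
    return HaplotypePanel(alleles, variants, hap_ids)


def write_phased_vcf(panel: HaplotypePanel, vcf_path) -> None:
    """Write a HaplotypePanel as a minimal phased VCF (REF=major, ALT=minor)."""
    v = panel.variants
    n_ind = panel.n_hap // 2
    samples = list(panel.individual_ids)[:n_ind]
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(v["chrom"]):
            length = int(v.loc[v["chrom"] == chrom, "pos_bp"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in range(panel.n_snps):
            row = v.iloc[j]
            gts = [
                f"{panel.alleles[2 * s, j]}|{panel.alleles[2 * s + 1, j]}"
                for s in range(n_ind)
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos_bp']}\t{row['id']}\t"
                f"{row['allele_major']}\t{row['allele_minor']}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSV side tables
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> PhenotypeVector:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return PhenotypeVector.from_values(df.iloc[:, 1], df.iloc[:, 0])


def write_phenotypes(pheno: PhenotypeVector, path) -> None:
    pd.DataFrame({"id": pheno.index, "value": pheno.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("0")
    df.columns = ["id", "sire", "mgs"]
    return Pedigree(df)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.table.to_csv(path, sep="\t", index=False)


def read_ancestral(path) -> pd.Series:
    """Ancestral-allele side table: variant id -> allele string."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["id", "allele"]
    return df.set_index("id")["allele"]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QcOptions:
    maf_min: float = 0.05
    snp_missing_max: float = 0.10
    indiv_callrate_min: float = 0.90
    autosomes_only: bool = True

    def __post_init__(self):
        for name in ("maf_min", "snp_missing_max", "indiv_callrate_min"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0,1), got {v}")


@dataclass
class QcReport:
    """Counts of individuals/SNPs removed per rule, in application order."""

    removed: dict = field(default_factory=dict)
    removed_individuals: list = field(default_factory=list)
    removed_snps: dict = field(default_factory=dict)

    def total_snps_removed(self) -> int:
        return sum(v for k, v in self.removed.items() if k != "individual_callrate")


def _is_autosome(chrom: str) -> bool:
    try:
        return int(str(chrom)) >= 1
    except ValueError:
        return False


def qc_filter(gt: GenotypeTable, panel: HaplotypePanel | None = None,
              opts: QcOptions | None = None):
    """Apply the QC cascade: individual call rate, autosome/position, SNP
    missingness, MAF — in that order, recomputing per-SNP statistics after
    the individual-level filter.

    Returns ``(gt_filtered, panel_filtered, report)``; ``panel_filtered``
    is None when no panel is supplied.  Raises if no SNP survives.
    """
    opts = opts or QcOptions()
    report = QcReport()

    # 1. individual call rate
    call = gt.call_rates()
    ind_keep = call >= opts.indiv_callrate_min
    report.removed["individual_callrate"] = int((~ind_keep).sum())
    report.removed_individuals = [i for i, k in zip(gt.ids, ind_keep) if not k]
    gt = gt.subset(ind_mask=ind_keep)

    v = gt.variants
    snp_keep = np.ones(gt.n_snps, dtype=bool)

    # 2. autosome / known position
    if opts.autosomes_only:
        auto = np.array([_is_autosome(c) for c in v["chrom"]]) & (
            v["pos_bp"].to_numpy() >= 1
        )
    else:
        auto = v["pos_bp"].to_numpy() >= 1
    report.removed["autosome"] = int((~auto).sum())
    report.removed_snps["autosome"] = v.loc[~auto, "id"].tolist()
    snp_keep &= auto

    # 3. SNP missingness (recomputed after individual filtering)
    missing = gt.snp_missingness()
    miss_fail = snp_keep & (missing >= opts.snp_missing_max)
    report.removed["snp_missing"] = int(miss_fail.sum())
    report.removed_snps["snp_missing"] = v.loc[miss_fail, "id"].tolist()
    snp_keep &= ~miss_fail

    # 4. MAF
    maf = gt.compute_maf()
    maf_fail = snp_keep & ~(maf > opts.maf_min)
    report.removed["maf"] = int(maf_fail.sum())
    report.removed_snps["maf"] = v.loc[maf_fail, "id"].tolist()
    snp_keep &= ~maf_fail

    if not snp_keep.any():
        raise ValueError("QC removed every SNP")

    gt_out = gt.subset(snp_mask=snp_keep)
    gt_out.variants["maf"] = maf[snp_keep]

    panel_out = None
    if panel is not None:
        id_keep = set(gt_out.variants["id"])
        pmask = panel.variants["id"].isin(id_keep).to_numpy()
        panel_out = panel.subset_variants(pmask)
    return gt_out, panel_out, report
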