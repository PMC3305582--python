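"""Shared data model: variants, haplotype panels, genotype tables, pedigrees.

Variant metadata travels as a :class:`pandas.DataFrame` with the canonical
columns ``id, chrom, pos_bp, allele_major, allele_minor, allele_ancestral,
maf`` (``allele_ancestral`` may be missing/NaN).  Alleles in a
:class:`HaplotypePanel` are coded 0/1 with 1 = minor allele; genotype codes
in a :class:`GenotypeTable` count copies of the minor allele (0/1/2, with
-1 for a missing call).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # genotype-code sentinel

VARIANT_COLUMNS = [
    "id",
    "chrom",
    "pos_bp",
    "allele_major",
    "allele_minor",
    "allele_ancestral",
    "maf",
]

UNKNOWN_PARENT = "0"


def make_variant_frame(
    ids,
    chrom,
    pos_bp,
    allele_major=None,
    allele_minor=None,
    allele_ancestral=None,
    maf=None,
) -> pd.DataFrame:
    """Assemble a canonical variant table; scalars broadcast."""
    n = len(ids)
    df = pd.DataFrame(
        {
            "id": list(ids),
            "chrom": np.broadcast_to(np.asarray(chrom, dtype=object), n).copy(),
            "pos_bp": np.asarray(pos_bp, dtype=np.int64),
            "allele_major": (
                np.broadcast_to(np.asarray(allele_major, dtype=object), n).copy()
                if allele_major is not None
                else ["A"] * n
            ),
            "allele_minor": (
                np.broadcast_to(np.asarray(allele_minor, dtype=object), n).copy()
                if allele_minor is not None
                else ["B"] * n
            ),
            "allele_ancestral": (
                np.broadcast_to(np.asarray(allele_ancestral, dtype=object), n).copy()
                if allele_ancestral is not None
                else [None] * n
            ),
            "maf": np.asarray(maf, dtype=float) if maf is not None else np.nan,
        }
    )
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate variant ids: {dups[:5]}")
    return df


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes for one chromosome.

    ``alleles`` is a (2n_hap x m) uint8 matrix over {0,1}, one row per
    haplotype (two consecutive rows per individual), 1 = minor allele.
    Positions must be strictly increasing.
    """

    alleles: np.ndarray
    variants: pd.DataFrame
    individual_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if len(self.variants) != self.alleles.shape[1]:
            raise ValueError("variant table does not match allele matrix width")
        pos = self.variants["pos_bp"].to_numpy()
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(self.alleles.shape[0] // 2)]

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.variants["pos_bp"].to_numpy()

    def allele1_freq(self) -> np.ndarray:
        return self.alleles.mean(axis=0)

    def subset_variants(self, mask) -> "HaplotypePanel":
        mask = np.asarray(mask)
        return HaplotypePanel(
            self.alleles[:, mask],
            self.variants.loc[mask].reset_index(drop=True),
            list(self.individual_ids),
        )


@dataclass
class GenotypeTable:
    """Diploid genotype codes: n individuals x m SNPs, minor-allele counts."""

    codes: np.ndarray
    variants: pd.DataFrame
    ids: list

    def __post_init__(self):
        self.codes = np.ascontiguousarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.ids), len(self.variants)):
            raise ValueError("codes shape does not match ids x variants")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def call_rates(self) -> np.ndarray:
        """Per-individual fraction of non-missing calls."""
        return 1.0 - self.missing_mask().mean(axis=1)

    def snp_missingness(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def compute_maf(self) -> np.ndarray:
        """Minor-allele (code-1) frequency from non-missing calls, folded to <= 0.5."""
        codes = self.codes.astype(float)
        codes[self.codes == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(codes, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset(self, ind_mask=None, snp_mask=None) -> "GenotypeTable":
        ind_mask = np.ones(self.n_individuals, bool) if ind_mask is None else np.asarray(ind_mask)
        snp_mask = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        return GenotypeTable(
            self.codes[np.ix_(ind_mask, snp_mask)],
            self.variants.loc[snp_mask].reset_index(drop=True),
            [i for i, keep in zip(self.ids, ind_mask) if keep],
        )


@dataclass
class Pedigree:
    """Individual -> sire and maternal-grandsire links; '0' marks unknown."""

    table: pd.DataFrame  # columns: id, sire, mgs

    def __post_init__(self):
        t = self.table
        for col in ("id", "sire", "mgs"):
            if col not in t.columns:
                raise ValueError(f"pedigree table lacks column {col!r}")
        if t["id"].duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        self_parent = (t["id"] == t["sire"]) | (t["id"] == t["mgs"])
        if self_parent.any():
            bad = t.loc[self_parent, "id"].tolist()
            raise ValueError(f"individuals listed as their own sire/MGS: {bad[:5]}")

    def aligned(self, ids) -> pd.DataFrame:
        out = self.table.set_index("id").reindex(list(ids))
        if out["sire"].isna().any():
            missing = [i for i, s in zip(ids, out["sire"]) if pd.isna(s)]
            raise KeyError(f"individuals missing from pedigree: {missing[:5]}")
        return out.reset_index()


class PhenotypeVector(pd.Series):
    """Per-individual quantitative phenotype (e.g. EBV in kg protein).

    A thin pandas Series subclass so alignment-by-id comes for free.
    """

    @property
    def _constructor(self):
        return PhenotypeVector

    @classmethod
    def from_values(cls, values, ids) -> "PhenotypeVector":
        v = cls(np.asarray(values, dtype=float), index=list(ids))
        if not np.all(np.isfinite(v.to_numpy())):
            raise ValueError("phenotypes must be finite")
        return v


@dataclass
class FamilyStructure:
    """Sire / maternal-grandsire assignment for n individuals.

    ``sire`` and ``mgs`` are integer family labels (0-based); the number of
    founder sires/MGS is the label-space size, not necessarily the number of
    families realized in the sample.
    """

    sire: np.ndarray
    mgs: np.ndarray
    n_sires: int
    n_mgs: int

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.mgs = np.asarray(self.mgs, dtype=np.int64)
        if self.sire.shape != self.mgs.shape:
            raise ValueError("sire and mgs assignments differ in length")
        if self.sire.max(initial=-1) >= self.n_sires or self.mgs.max(initial=-1) >= self.n_mgs:
            raise ValueError("family label exceeds declared family count")

    @property
    def n(self) -> int:
        return len(self.sire)

    def subset(self, idx) -> "FamilyStructure":
        idx = np.asarray(idx)
        return FamilyStructure(self.sire[idx], self.mgs[idx], self.n_sires, self.n_mgs)

    def sire_sizes(self) -> np.ndarray:
        return np.bincount(self.sire, minlength=self.n_sires)

    def mgs_sizes(self) -> np.ndarray:
        return np.bincount(self.mgs, minlength=self.n_mgs)

    def to_pedigree(self, ids=None) -> Pedigree:
        ids = ids if ids is not None else [f"ind{i}" for i in range(self.n)]
        return Pedigree(
            pd.DataFrame(
                {
                    "id": list(ids),
                    "sire": [f"sire{s}" for s in self.sire],
                    "mgs": [f"mgs{m}" for m in self.mgs],
                }
            )
        )
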