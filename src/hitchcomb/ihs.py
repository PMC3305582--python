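"""Standardized iHS statistics: bin-based (Voight-style) and locus-specific
permutation-based, with MAF correction and formal P-values.

Two routes from the unstandardized score uiHS to a test statistic:

* ``standardize_voight`` — subtract/divide the empirical mean/SD of uiHS in
  bins of derived-allele frequency (deciles by default).  Needs ancestral
  states; no formal significance.
* the permutation route — shuffle core-SNP alleles among haplotype rows
  (flanks untouched, allele counts preserved), giving each locus its own
  null SD:  siHS_P = uiHS / SD(iHS_P).  A genome-wide linear regression of
  siHS_P on MAF (continuous, with intercept) removes residual frequency
  dependence; residuals scaled by their global SD give the final iHS, which
  is approximately N(0,1), so P = 2(1 - Phi(|iHS|)).

All SD estimates use the sample (n-1) convention.  Per-locus permutation
seeds are stable hashes of (master seed, variant id), so subsetting SNPs
never changes another SNP's result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._kernel import core_ihh_many
from ._seeds import derive_seed
from .datatypes import HaplotypePanel
from .ehh import DEFAULT_CUTOFF

DEFAULT_N_PERM = 1000


# ---------------------------------------------------------------------------
# Voight-style bin standardization
# ---------------------------------------------------------------------------

@dataclass
class VoightBins:
    """Per-bin moments of uiHS over derived-allele frequency.

    ``edges`` are k+1 ascending bin edges spanning (0, 1]; bin i is the
    right-closed interval (edges[i], edges[i+1]].
    """

    edges: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray

    @classmethod
    def fit(cls, derived_freq, uihs, edges=None) -> "VoightBins":
        edges = np.asarray(edges if edges is not None else np.linspace(0, 1, 11))
        freq = np.asarray(derived_freq, dtype=float)
        vals = np.asarray(uihs, dtype=float)
        idx = cls._assign(freq, edges)
        k = len(edges) - 1
        mean = np.full(k, np.nan)
        sd = np.full(k, np.nan)
        count = np.zeros(k, dtype=int)
        for b in range(k):
            sel = vals[idx == b]
            count[b] = len(sel)
            if len(sel) >= 2:
                mean[b] = sel.mean()
                sd[b] = sel.std(ddof=1)
        return cls(edges, mean, sd, count)

    @staticmethod
    def _assign(freq, edges) -> np.ndarray:
        idx = np.digitize(freq, edges[1:-1], right=True)
        return idx

    def standardize(self, derived_freq, uihs) -> np.ndarray:
        freq = np.asarray(derived_freq, dtype=float)
        vals = np.asarray(uihs, dtype=float)
        idx = self._assign(freq, self.edges)
        bad = np.isnan(self.mean[idx]) & np.isfinite(vals)
        if bad.any():
            bins = sorted(set(idx[bad].tolist()))
            raise ValueError(f"no bin moments available for bins {bins}")
        return (vals - self.mean[idx]) / self.sd[idx]


def standardize_voight(records: pd.DataFrame, bins="fit",
                       freq_col: str = "derived_freq",
                       value_col: str = "uihs_ad") -> pd.DataFrame:
    """Add an ``ihs_voight`` column to a scan table.

    ``bins="fit"`` estimates the per-bin moments from the supplied
    (genome-wide) records; alternatively pass a :class:`VoightBins`.
    """
    out = records.copy()
    usable = np.isfinite(out[freq_col]) & np.isfinite(out[value_col])
    if bins == "fit":
        bins = VoightBins.fit(out.loc[usable, freq_col], out.loc[usable, value_col])
    out["ihs_voight"] = np.nan
    out.loc[usable, "ihs_voight"] = bins.standardize(
        out.loc[usable, freq_col], out.loc[usable, value_col]
    )
    return out


# ---------------------------------------------------------------------------
# Permutation standardization
# ---------------------------------------------------------------------------

def _permutation_sets(rng, n_hap: int, c_min: int, n_rows: int) -> np.ndarray:
    """Random minor-carrier index sets, each of size c_min."""
    keys = rng.random((n_rows, n_hap))
    return np.ascontiguousarray(
        np.argpartition(keys, c_min - 1, axis=1)[:, :c_min], dtype=np.int64
    )


def _core_uihs_and_perms(panel: HaplotypePanel, core: int, n_perm: int,
                         rng, cutoff: float):
    """Observed uiHS (minor/major) plus n_perm permuted values at one core.

    Returns (uihs_obs, ihh_minor_obs, ihh_major_obs, truncated_obs,
    perm_values, n_degenerate).
    """
    alleles = panel.alleles
    n_hap = panel.n_hap
    minor_idx = np.flatnonzero(alleles[:, core] == 1)
    c_min = len(minor_idx)
    if c_min == 0 or c_min == n_hap:
        raise ValueError(f"core {core} is monomorphic")

    sets = np.empty((1 + n_perm, c_min), dtype=np.int64)
    sets[0] = minor_idx
    sets[1:] = _permutation_sets(rng, n_hap, c_min, n_perm)
    ihh_min, ihh_maj, trunc = core_ihh_many(
        alleles, panel.positions, core, sets, cutoff
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log(ihh_min / ihh_maj)
    obs = vals[0]
    perm = vals[1:].copy()

    # redraw degenerate permutation draws (zero/invalid integral); capped
    n_degenerate = 0
    attempts = 0
    bad = ~np.isfinite(perm)
    while bad.any() and attempts < 10 * n_perm:
        attempts += int(bad.sum())
        redo = _permutation_sets(rng, n_hap, c_min, int(bad.sum()))
        imn, imj, _ = core_ihh_many(alleles, panel.positions, core, redo, cutoff)
        with np.errstate(divide="ignore", invalid="ignore"):
            perm[bad] = np.log(imn / imj)
        bad = ~np.isfinite(perm)
    n_degenerate = int(bad.sum())
    return obs, float(ihh_min[0]), float(ihh_maj[0]), bool(trunc[0]), perm, n_degenerate


def permute_core(panel: HaplotypePanel, core: int, n_perm: int = DEFAULT_N_PERM,
                 seed: int = 0, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """The permuted null sample iHS_P at one core SNP.

    Core alleles are reassigned to haplotype rows (allele counts preserved,
    flanks untouched) and uiHS recomputed for each draw.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    _, _, _, _, perm, _ = _core_uihs_and_perms(panel, core, n_perm, rng, cutoff)
    return perm


def sihs_p(uihs_value: float, perm_values) -> tuple:
    """Scale uiHS by the locus-specific permutation SD.

    Returns ``(sihs_p, sd_perm)``; a zero SD yields ``(nan, 0.0)`` so the
    caller can flag the locus as degenerate.
    """
    perm = np.asarray(perm_values, dtype=float)
    perm = perm[np.isfinite(perm)]
    if len(perm) < 2:
        raise ValueError("need at least 2 finite permutation values")
    sd = float(perm.std(ddof=1))
    if sd == 0.0:
        return float("nan"), 0.0
    return float((uihs_value - 0.0) / sd), sd


def maf_correct(records: pd.DataFrame, min_records: int = 10) -> pd.DataFrame:
    """Regress siHS_P on MAF (OLS with intercept) over unflagged records;
    residuals scaled by their global sample SD become the final iHS, with
    two-sided normal P-values."""
    out = records.copy()
    usable = (out["flags"] == "") & np.isfinite(out["sihs_p"])
    n = int(usable.sum())
    if n < min_records:
        raise ValueError(f"need >= {min_records} unflagged records, have {n}")
    maf = out.loc[usable, "maf"].to_numpy(dtype=float)
    y = out.loc[usable, "sihs_p"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(maf), maf])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd = resid.std(ddof=1)
    out["ihs"] = np.nan
    out["p_ihs"] = np.nan
    out.loc[usable, "ihs"] = resid / sd
    out.loc[usable, "p_ihs"] = 2.0 * stats.norm.sf(np.abs(resid / sd))
    return out


# ---------------------------------------------------------------------------
# Whole-panel scan
# ---------------------------------------------------------------------------

def scan_panel(panel: HaplotypePanel, n_perm: int = DEFAULT_N_PERM,
               seed: int = 0, cutoff: float = DEFAULT_CUTOFF,
               ancestral: pd.Series | None = None,
               progress: bool = False) -> pd.DataFrame:
    """Permutation-iHS selection scan over every polymorphic SNP of a panel.

    Returns one row per SNP with uiHS, the permutation SD, siHS_P, the
    MAF-corrected final iHS and its two-sided P, the empirical permutation
    tail probability, and (when ``ancestral`` annotation is given) the
    bin-standardized iHS^Voight with its derived-allele frequency.

    Flagged SNPs (monomorphic, truncated curves, zero integrals, degenerate
    permutation SD) are reported but excluded from standardization.
    Deterministic for a fixed ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    v = panel.variants
    n = panel.n_snps
    rows = []
    iterator = range(n)
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc="iHS scan")
        except ImportError:
            pass
    freq1 = panel.allele1_freq()
    for j in iterator:
        vid = v["id"].iloc[j]
        maf = min(freq1[j], 1 - freq1[j])
        rec = {
            "id": vid,
            "chrom": v["chrom"].iloc[j],
            "pos_bp": int(v["pos_bp"].iloc[j]),
            "maf": float(maf),
            "uihs": np.nan,
            "sd_perm": np.nan,
            "sihs_p": np.nan,
            "p_perm": np.nan,
            "ihh_minor": np.nan,
            "ihh_major": np.nan,
            "n_perm": n_perm,
            "flags": "",
        }
        if freq1[j] in (0.0, 1.0):
            rec["flags"] = "monomorphic"
            rows.append(rec)
            continue
        rng = np.random.default_rng(derive_seed(seed, vid))
        obs, ihh_min, ihh_maj, trunc, perm, n_degen = _core_uihs_and_perms(
            panel, j, n_perm, rng, cutoff
        )
        rec["ihh_minor"], rec["ihh_major"] = ihh_min, ihh_maj
        flags = []
        if not np.isfinite(obs):
            flags.append("zero_ihh")
        if trunc:
            flags.append("truncated")
        if n_degen:
            flags.append("degenerate_perm")
        finite_perm = perm[np.isfinite(perm)]
        if len(finite_perm) >= 2:
            s, sd = sihs_p(obs, finite_perm) if np.isfinite(obs) else (np.nan, float(finite_perm.std(ddof=1)))
            rec["sd_perm"] = sd
            rec["sihs_p"] = s
            if sd == 0.0:
                flags.append("degenerate_sd")
            if np.isfinite(obs):
                rec["p_perm"] = (1 + (np.abs(finite_perm) >= abs(obs)).sum()) / (
                    len(finite_perm) + 1
                )
        rec["uihs"] = obs if np.isfinite(obs) else np.nan
        rec["flags"] = ";".join(flags)
        rows.append(rec)

    df = pd.DataFrame(rows)
    df = maf_correct(df)

    if ancestral is not None:
        df = _attach_voight(df, v, ancestral)
    else:
        df["derived_freq"] = np.nan
        df["uihs_ad"] = np.nan
        df["ihs_voight"] = np.nan
    return df


def _attach_voight(df: pd.DataFrame, variants: pd.DataFrame,
                   ancestral: pd.Series) -> pd.DataFrame:
    """Polarize uiHS by ancestral state and bin-standardize.

    uiHS is computed minor/major; when the ancestral allele is the major
    allele the derived allele is the minor one, so
    ln(iHH_anc/iHH_der) = -uiHS, and the derived frequency is the MAF.
    SNPs lacking (or contradicting) the annotation are left NaN — they are
    excluded only from iHS^Voight, not from the permutation statistic.
    """
    out = df.copy()
    out["derived_freq"] = np.nan
    out["uihs_ad"] = np.nan
    anc = ancestral.reindex(out["id"]).to_numpy()
    minor = variants["allele_minor"].to_numpy()
    major = variants["allele_major"].to_numpy()
    maf = out["maf"].to_numpy(dtype=float)
    uihs_mm = out["uihs"].to_numpy(dtype=float)

    anc_is_major = (anc == major)
    anc_is_minor = (anc == minor)
    known = anc_is_major | anc_is_minor
    derived_freq = np.where(anc_is_major, maf, 1.0 - maf)
    uihs_ad = np.where(anc_is_major, -uihs_mm, uihs_mm)
    out.loc[known, "derived_freq"] = derived_freq[known]
    out.loc[known, "uihs_ad"] = uihs_ad[known]
    return standardize_voight(out)


# alias: orchestrate the scan over one chromosome
scan_chromosome = scan_panel
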