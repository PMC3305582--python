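"""Kinship-aware single-SNP association (MIX), the two-stage stratification
correction (MIXStrat), adaptive permutation P-values, and genomic control.

Model (per SNP):  y = 1*mu + x*beta + a + e,  a ~ N(0, G sigma_a^2),
e ~ N(0, I sigma_e^2).  Variance components are estimated once by REML
under the no-SNP null model and plugged into every per-SNP generalized
least squares fit (direct matrix inversion); the Wald statistic is
T^2 = beta^2 / Var(beta), referred to chi^2 with 1 df.

Var(beta) carries a per-SNP dispersion factor r_hat = RSS_V/(n-2) (the
V-weighted residual mean square), so the sigma_a^2 = 0 limit reproduces
textbook OLS exactly and E[r_hat] = 1 under a correctly specified model.

MIXStrat pre-corrects genotype codes for sire and maternal-grandsire
stratification: codes are regressed on the two family factors (families
smaller than ``min_family`` pooled per factor) and the residuals replace
the raw 0/1/2 codes in the design.

The kinship matrix G uses moment-based IBD estimates from identity-by-state
counts (pi_hat = P(IBD=1)/2 + P(IBD=2)) with diagonal 1 + F, F the
excess-homozygosity inbreeding estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import MISSING, GenotypeTable, Pedigree

log = logging.getLogger(__name__)

CHI2_1DF_MEDIAN = 0.456  # median of the chi-square 1-df distribution (2 s.f.)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    values: np.ndarray
    ids: list
    ridge: float = 0.0
    low_overlap_pairs: int = 0  # pairs estimated from < 50 shared SNPs

    @property
    def n(self) -> int:
        return self.values.shape[0]


def estimate_kinship(gt: GenotypeTable, min_snps: int = 100,
                     min_shared: int = 50) -> KinshipMatrix:
    """Moment-based IBD kinship from SNP data.

    Off-diagonals: per pair, observed IBS0/IBS1/IBS2 counts are equated to
    their expectations given IBD state (computed from sample allele
    frequencies) and solved for P(IBD=0/1/2);
    pi_hat = P(IBD=1)/2 + P(IBD=2), truncated to [0, 1].
    Diagonals: 1 + F with F = (O_hom - E_hom) / (L - E_hom).
    """
    codes = gt.codes
    n, m = codes.shape
    if n < 2:
        raise ValueError("need at least 2 individuals")
    valid = (codes != MISSING)
    if m < min_snps:
        raise ValueError(f"need at least {min_snps} SNPs, have {m}")
    c = codes.astype(np.float64)
    c[~valid] = np.nan
    p = np.nanmean(c, axis=0) / 2.0  # frequency of the counted (minor) allele
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic")
    c = c[:, poly]
    valid = valid[:, poly]
    p = p[poly]
    q = 1.0 - p
    m = len(p)

    # per-SNP expected IBS probabilities conditional on IBD state
    e0_ibd0 = 2 * p**2 * q**2
    e1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e2_ibd0 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibd1 = 2 * p**2 * q + 2 * p * q**2
    e2_ibd1 = p**3 + q**3 + p**2 * q + p * q**2

    # pairwise IBS counts via indicator matmuls
    V = valid.astype(np.float64)
    X = [np.where(valid, c == k, 0.0).astype(np.float64) for k in (0, 1, 2)]
    ibs2 = X[0] @ X[0].T + X[1] @ X[1].T + X[2] @ X[2].T
    ibs0 = X[0] @ X[2].T + X[2] @ X[0].T
    L = V @ V.T
    ibs1 = L - ibs0 - ibs2

    # pairwise expectation sums over shared non-missing SNPs
    def pair_sum(per_snp):
        return V @ (V * per_snp[None, :]).T

    E0_0 = pair_sum(e0_ibd0)
    E1_0 = pair_sum(e1_ibd0)
    E2_0 = pair_sum(e2_ibd0)
    E1_1 = pair_sum(e1_ibd1)
    E2_1 = pair_sum(e2_ibd1)

    with np.errstate(divide="ignore", invalid="ignore"):
        P0 = ibs0 / E0_0
        P1 = (ibs1 - P0 * E1_0) / E1_1
        P2 = (ibs2 - P0 * E2_0 - P1 * E2_1) / L
    # only the final pi-hat is truncated: clipping the intermediate state
    # probabilities would bias unrelated pairs upward
    pihat = np.clip(np.nan_to_num(P1) / 2.0 + np.nan_to_num(P2), 0.0, 1.0)

    # inbreeding from excess homozygosity
    hom = np.where(valid, (c == 0) | (c == 2), 0.0)
    o_hom = hom.sum(axis=1)
    e_hom = (valid * (1.0 - 2 * p * q)[None, :]).sum(axis=1)
    l_ind = valid.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (o_hom - e_hom) / (l_ind - e_hom)
    F = np.nan_to_num(F)

    G = pihat.copy()
    np.fill_diagonal(G, 1.0 + F)
    G = (G + G.T) / 2.0

    low = int(((L < min_shared) & ~np.eye(n, dtype=bool)).sum() // 2)
    if low:
        log.warning("%d pairs estimated from < %d shared SNPs", low, min_shared)

    return KinshipMatrix(G, list(gt.ids), low_overlap_pairs=low)


def repair_positive_definite(km: KinshipMatrix, floor: float = 1e-6) -> KinshipMatrix:
    """Add the minimal ridge delta*I so the smallest eigenvalue is >= floor."""
    w = np.linalg.eigvalsh(km.values)
    delta = max(0.0, floor - float(w[0]))
    if delta > 0:
        km.values = km.values + delta * np.eye(km.n)
        km.ridge = delta
        log.info("kinship ridge repair: added %.3g * I", delta)
    return km


def load_grm(path) -> KinshipMatrix:
    """Load an externally computed square GRM (whitespace-delimited, id header)."""
    df = pd.read_csv(path, sep=r"\s+")
    ids = list(df.columns)
    vals = df.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1]:
        raise ValueError("GRM file is not square")
    return repair_positive_definite(KinshipMatrix(vals, ids))


# ---------------------------------------------------------------------------
# Variance components (REML)
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    loglik: float
    ratio_flat: bool = False  # profiled likelihood flat (e.g. G = I)

    @property
    def heritability(self) -> float:
        tot = self.sigma2_a + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else 0.0


def fit_variance_components(y, G: KinshipMatrix | np.ndarray,
                            gamma_bounds=(1e-5, 1e5)) -> VarianceComponents:
    """REML estimates of (sigma_a^2, sigma_e^2) under the intercept-only
    model, by 1-D profile optimization of gamma = sigma_a^2/sigma_e^2 on
    the spectral decomposition of G."""
    Gm = G.values if isinstance(G, KinshipMatrix) else np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be finite")
    d, U = np.linalg.eigh(Gm)
    Uy = U.T @ y
    Ux = U.T @ np.ones(n)
    p = 1

    def reml_ll(log_gamma):
        g = np.exp(log_gamma)
        w = g * d + 1.0  # eigenvalues of V0 = gamma*G + I
        xtvx = (Ux**2 / w).sum()
        beta = (Ux * Uy / w).sum() / xtvx
        r = Uy - beta * Ux
        rss = (r**2 / w).sum()
        sigma2_e = rss / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * sigma2_e)
            + np.log(w).sum()
            + np.log(xtvx)
            + (n - p)
        )
        return ll, sigma2_e

    lo, hi = np.log(gamma_bounds[0]), np.log(gamma_bounds[1])
    grid = np.linspace(lo, hi, 101)
    lls = np.array([reml_ll(g)[0] for g in grid])
    if not np.all(np.isfinite(lls)):
        raise RuntimeError(f"REML likelihood not finite on grid: {lls}")
    flat = (lls.max() - lls.min()) < 1e-6 * max(1.0, abs(lls.max()))
    if flat:
        _, s2e = reml_ll(lo)
        return VarianceComponents(0.0, float(s2e), float(lls.max()), ratio_flat=True)
    best = grid[int(np.argmax(lls))]
    span = (grid[1] - grid[0])
    res = optimize.minimize_scalar(
        lambda x: -reml_ll(x)[0],
        bounds=(max(lo, best - 2 * span), min(hi, best + 2 * span)),
        method="bounded",
    )
    ll, s2e = reml_ll(res.x)
    gamma = float(np.exp(res.x))
    # boundary: essentially no polygenic variance
    if res.x <= lo + 1e-8 or gamma < 1e-4:
        ll0, s2e0 = reml_ll(lo)
        return VarianceComponents(0.0, float(s2e0), float(ll0))
    return VarianceComponents(gamma * float(s2e), float(s2e), float(ll))


# ---------------------------------------------------------------------------
# Per-SNP GLS
# ---------------------------------------------------------------------------

@dataclass
class AssocRecord:
    variant_id: str
    model: str
    beta: float
    var_beta: float
    t2: float
    p_asymptotic: float
    p_empirical: float | None = None
    n_perm_used: int = 0
    flags: str = ""


def _v_inverse(G, vc: VarianceComponents) -> np.ndarray:
    Gm = G.values if isinstance(G, KinshipMatrix) else np.asarray(G, dtype=float)
    n = Gm.shape[0]
    V = vc.sigma2_a * Gm + vc.sigma2_e * np.eye(n)
    return np.linalg.inv(V)


def gls_scan(y: np.ndarray, X: np.ndarray, W: np.ndarray,
             inject: np.ndarray | None = None,
             alpha: np.ndarray | None = None):
    """Vectorized per-SNP GLS with precision matrix W = V^-1.

    Tests each column of ``X`` (with an intercept) against the response.
    When ``inject``/``alpha`` are given, column i is tested against
    y_i = y + alpha_i * inject[:, i] (per-SNP phenotype injection for power
    simulations) — all cross-products reduce to cached terms.

    Returns (beta, var_beta, t2, p) arrays plus a monomorphic mask.
    """
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    one = np.ones(n)
    W1 = W @ one
    Wy = W @ y
    WX = W @ X
    a11 = float(one @ W1)
    a12 = W1 @ X            # (m,)
    a22 = np.einsum("ij,ij->j", X, WX)
    b1 = float(one @ Wy) * np.ones(m)
    b2 = y @ WX
    yy = float(y @ Wy) * np.ones(m)
    if inject is not None:
        g1 = W1 @ inject
        gy = y @ (W @ inject)
        gX = np.einsum("ij,ij->j", inject, WX)
        gg = np.einsum("ij,ij->j", inject, W @ inject)
        b1 = b1 + alpha * g1
        b2 = b2 + alpha * gX
        yy = yy + 2 * alpha * gy + alpha**2 * gg

    det = a11 * a22 - a12**2
    scale = a11 * np.maximum(a22, 1e-300)
    mono = det <= 1e-12 * scale
    det_safe = np.where(mono, 1.0, det)
    beta = (a11 * b2 - a12 * b1) / det_safe
    beta0 = (a22 * b1 - a12 * b2) / det_safe
    rss = yy - (beta0 * b1 + beta * b2)
    rss = np.maximum(rss, 0.0)
    r_hat = rss / max(n - 2, 1)
    var_beta = r_hat * a11 / det_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(var_beta > 0, beta**2 / var_beta, np.inf)
    t2 = np.where(mono, np.nan, t2)
    beta = np.where(mono, np.nan, beta)
    var_beta = np.where(mono, np.nan, var_beta)
    p = stats.chi2.sf(t2, df=1)
    return beta, var_beta, t2, p, mono


def fit_mix(y, x_snp, G, vc: VarianceComponents,
            variant_id: str = "snp", W: np.ndarray | None = None) -> AssocRecord:
    """Single-SNP mixed-model GLS fit (model MIX)."""
    W = _v_inverse(G, vc) if W is None else W
    x = np.asarray(x_snp, dtype=float)[:, None]
    beta, var_beta, t2, p, mono = gls_scan(np.asarray(y, float), x, W)
    if mono[0]:
        return AssocRecord(variant_id, "MIX", np.nan, np.nan, np.nan, np.nan,
                           flags="monomorphic")
    return AssocRecord(variant_id, "MIX", float(beta[0]), float(var_beta[0]),
                       float(t2[0]), float(p[0]))


# ---------------------------------------------------------------------------
# Stratification pre-correction (MIXStrat)
# ---------------------------------------------------------------------------

def _pool_small_families(labels: np.ndarray, min_family: int) -> np.ndarray:
    """Recode labels whose family size < min_family to one pooled level."""
    labels = np.asarray(labels)
    uniq, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    small = counts[inv] < min_family
    out = inv.astype(np.int64)
    if small.any():
        pooled = len(uniq)
        out[small] = pooled
    _, out = np.unique(out, return_inverse=True)
    return out


def family_design(sire_labels, mgs_labels, min_family: int = 5):
    """Orthonormal basis of the sire + MGS two-factor design (with
    intercept), after pooling small families.  Rank deficiencies from
    aliased levels are absorbed by the SVD basis (dropped directions are
    implicit)."""
    sire = _pool_small_families(np.asarray(sire_labels), min_family)
    mgs = _pool_small_families(np.asarray(mgs_labels), min_family)
    n = len(sire)
    D = np.zeros((n, 1 + sire.max() + 1 + mgs.max() + 1))
    D[:, 0] = 1.0
    D[np.arange(n), 1 + sire] = 1.0
    D[np.arange(n), 1 + sire.max() + 1 + mgs] = 1.0
    U, s, _ = np.linalg.svd(D, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum())
    return U[:, :rank], sire, mgs


def residualize_genotypes(codes, ped: Pedigree | None = None,
                          min_family: int = 5, ids=None,
                          sire_labels=None, mgs_labels=None) -> np.ndarray:
    """Residuals of genotype codes after removing sire + MGS family means
    (two-factor additive least squares; families < min_family pooled).

    ``codes`` may be a vector (one SNP) or an (n x m) matrix.  Family labels
    come either from a :class:`Pedigree` (aligned on ``ids``) or directly
    via ``sire_labels``/``mgs_labels``.
    """
    codes = np.asarray(codes, dtype=float)
    if ped is not None:
        aligned = ped.aligned(ids)
        sire_labels = aligned["sire"].to_numpy()
        mgs_labels = aligned["mgs"].to_numpy()
    if sire_labels is None or mgs_labels is None:
        raise ValueError("provide a pedigree or explicit family labels")
    U, _, _ = family_design(sire_labels, mgs_labels, min_family)
    flat = codes.ndim == 1
    Xm = codes[:, None] if flat else codes
    resid = Xm - U @ (U.T @ Xm)
    return resid[:, 0] if flat else resid


def fit_mixstrat(y, codes, ped: Pedigree, G, vc: VarianceComponents,
                 variant_id: str = "snp", min_family: int = 5,
                 ids=None, W: np.ndarray | None = None) -> AssocRecord:
    """MIX applied to sire/MGS-residualized genotype codes (model MIXStrat)."""
    x = residualize_genotypes(codes, ped, min_family, ids=ids)
    rec = fit_mix(y, x, G, vc, variant_id, W=W)
    rec.model = "MIXStrat"
    if np.allclose(x, 0.0, atol=1e-10):
        rec.flags = "monomorphic"
        rec.beta = rec.var_beta = rec.t2 = rec.p_asymptotic = np.nan
    return rec


# ---------------------------------------------------------------------------
# Adaptive permutation
# ---------------------------------------------------------------------------

DEFAULT_SCHEDULE = (1_000, 10_000, 100_000, 1_000_000)


def _adaptive_perm(observed: float, draw, schedule, min_exceed: int = 10):
    """Generic adaptive permutation engine.

    ``draw(k)`` returns k permuted test statistics.  At each stage the
    cumulative exceedance count r (>= observed) decides escalation: the
    next stage runs only while r < min_exceed.  Returns ((r+1)/(n+1), n).
    """
    r = 0
    n = 0
    for target in schedule:
        k = target - n
        if k > 0:
            vals = draw(k)
            r += int((vals >= observed).sum())
            n = target
        if r >= min_exceed:
            break
    return (r + 1) / (n + 1), n


def adaptive_permutation_p(y, x_snp, G, vc: VarianceComponents,
                           observed_t2: float,
                           schedule=DEFAULT_SCHEDULE, seed: int = 0,
                           batch: int = 2000, W: np.ndarray | None = None):
    """Empirical P by adaptively permuting the genotype vector among
    individuals (phenotypes and kinship fixed)."""
    rng = np.random.default_rng(seed)
    W = _v_inverse(G, vc) if W is None else W
    y = np.asarray(y, dtype=float)
    x = np.asarray(x_snp, dtype=float)

    def draw(k):
        out = np.empty(k)
        pos = 0
        while pos < k:
            b = min(batch, k - pos)
            Xp = rng.permuted(np.broadcast_to(x, (b, len(x))), axis=1).T
            _, _, t2, _, _ = gls_scan(y, np.ascontiguousarray(Xp), W)
            out[pos : pos + b] = t2
            pos += b
        return out

    return _adaptive_perm(float(observed_t2), draw, schedule)


# ---------------------------------------------------------------------------
# Genomic control
# ---------------------------------------------------------------------------

def inflation_factor(t2) -> float:
    """lambda = median(T^2) / 0.456 (the chi-square 1-df median)."""
    t2 = np.asarray(t2, dtype=float)
    t2 = t2[np.isfinite(t2)]
    if len(t2) < 10:
        raise ValueError("need at least 10 finite test statistics")
    return float(np.median(t2) / CHI2_1DF_MEDIAN)


def qq_table(p) -> pd.DataFrame:
    """Observed vs expected -log10 P order statistics (uniform quantiles
    (i - 0.5)/N)."""
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    n = len(p)
    obs = -np.log10(np.sort(p))
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"expected": exp, "observed": obs})


# ---------------------------------------------------------------------------
# Whole-table scans
# ---------------------------------------------------------------------------

def association_scan(gt: GenotypeTable, pheno, model: str = "MIXStrat",
                     ped: Pedigree | None = None, G: KinshipMatrix | None = None,
                     vc: VarianceComponents | None = None, min_family: int = 5,
                     permutation: bool = False, schedule=DEFAULT_SCHEDULE,
                     seed: int = 0) -> pd.DataFrame:
    """Genome-wide single-SNP association scan (MIX or MIXStrat).

    Estimates kinship and variance components when not supplied; returns a
    per-SNP table of beta, Var(beta), T^2 and P-values.
    """
    from ._seeds import derive_seed

    y = pheno.reindex(gt.ids).to_numpy(dtype=float) if hasattr(pheno, "reindex") \
        else np.asarray(pheno, dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype missing for some genotyped individuals")
    if G is None:
        G = repair_positive_definite(estimate_kinship(gt))
    if vc is None:
        vc = fit_variance_components(y, G)
    W = _v_inverse(G, vc)

    codes = gt.codes.astype(float)
    codes[gt.codes == MISSING] = np.nan
    # mean-impute missing calls for the design (missingness is < 10% post-QC)
    col_mean = np.nanmean(codes, axis=0)
    nanmask = np.isnan(codes)
    codes[nanmask] = np.take(col_mean, np.where(nanmask)[1])

    if model == "MIXStrat":
        X = residualize_genotypes(codes, ped, min_family, ids=gt.ids)
    elif model == "MIX":
        X = codes
    else:
        raise ValueError(f"unknown model {model!r}")

    beta, var_beta, t2, p, mono = gls_scan(y, X, W)
    df = pd.DataFrame(
        {
            "id": gt.variants["id"],
            "chrom": gt.variants["chrom"],
            "pos_bp": gt.variants["pos_bp"],
            "model": model,
            "beta": beta,
            "var_beta": var_beta,
            "t2": t2,
            "p_asymptotic": p,
            "p_empirical": np.nan,
            "n_perm_used": 0,
            "flags": np.where(mono, "monomorphic", ""),
        }
    )
    if permutation:
        for i in range(len(df)):
            if mono[i]:
                continue
            pe, used = adaptive_permutation_p(
                y, X[:, i], G, vc, t2[i], schedule,
                seed=derive_seed(seed, df["id"].iloc[i]), W=W,
            )
            df.loc[i, "p_empirical"] = pe
            df.loc[i, "n_perm_used"] = used
    return df
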