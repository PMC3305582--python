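"""Stouffer combination of selection-scan and association P-values, with
tail-area FDR calls.

Each P is transformed to an upper-tail normal quantile z(P) = Phi^-1(1-P);
the combined statistic Z = sum z(P_i) / sqrt(k) is standard normal when the
k inputs are independent uniforms, and P_COMB = 1 - Phi(Z).  Sign
information (direction of selection vs direction of the allele effect) is
reported separately as a concordance flag rather than folded into Z.

q-values use a tail-area FDR: the null proportion eta0 is estimated from
the fraction of P above 1/2, and Fdr(p_(i)) = eta0 * N * p_(i) / i with
step-up monotonicity enforcement; ``method="bh"`` fixes eta0 = 1
(Benjamini-Hochberg).  Significance is declared at q < 0.10.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

Q_THRESHOLD = 0.10
_EPS = 1e-300


def _clamp_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    n_bad = int(((p <= 0) | (p >= 1)).sum())
    if n_bad:
        log.info("clamped %d boundary P-values into the open interval", n_bad)
    return np.clip(p, _EPS, 1 - 1e-16)


def stouffer(p_values, k: int | None = None):
    """Combine P-values: Z = sum Phi^-1(1 - P_i) / sqrt(k).

    ``p_values`` may be a 1-D sequence (one combination) or a 2-D array of
    shape (n, k) (rowwise combinations).  Returns ``(z_comb, p_comb)``.
    """
    p = _clamp_p(p_values)
    if p.ndim == 1:
        kk = k if k is not None else len(p)
        z = stats.norm.isf(p).sum() / np.sqrt(kk)
        return float(z), float(stats.norm.sf(z))
    kk = k if k is not None else p.shape[1]
    z = stats.norm.isf(p).sum(axis=1) / np.sqrt(kk)
    return z, stats.norm.sf(z)


def tail_fdr(p_comb, method: str = "tail_area", min_for_tail: int = 20) -> np.ndarray:
    """Tail-area q-values for a vector of combined P-values.

    eta0_hat = min(1, frac(P > 0.5) / 0.5);  Fdr(p_(i)) = eta0 * N * p_(i) / i,
    made monotone by the step-up pass.  With fewer than ``min_for_tail``
    P-values the eta0 estimate is unusable and the method falls back to
    Benjamini-Hochberg (eta0 = 1) with a warning.
    """
    p = _clamp_p(p_comb)
    n = len(p)
    if method not in ("tail_area", "bh"):
        raise ValueError(f"unknown FDR method {method!r}")
    if method == "tail_area" and n < min_for_tail:
        log.warning("only %d P-values: falling back to BH for the FDR step", n)
        method = "bh"
    eta0 = 1.0
    if method == "tail_area":
        eta0 = min(1.0, float((p > 0.5).mean()) / 0.5)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = eta0 * n * ranked / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def combine_scan(ihs_records: pd.DataFrame, assoc_records: pd.DataFrame,
                 fdr_method: str = "tail_area",
                 q_threshold: float = Q_THRESHOLD):
    """Join the two scans on variant id and combine per SNP.

    The association P is the empirical permutation P when available, else
    the asymptotic P (recorded per SNP in ``p_wga_source``).  Returns
    ``(table, summary)`` where the summary carries join bookkeeping and the
    Pearson correlations between the final iHS and the allele-substitution
    effect beta, overall and within the top 1% / 0.1% of |iHS|.
    """
    ih = ihs_records.dropna(subset=["p_ihs"])[["id", "chrom", "pos_bp", "ihs", "p_ihs"]]
    use_emp = (
        assoc_records["p_empirical"].notna()
        if "p_empirical" in assoc_records
        else pd.Series(False, index=assoc_records.index)
    )
    aw = assoc_records.copy()
    aw["p_wga"] = np.where(use_emp, aw.get("p_empirical", np.nan), aw["p_asymptotic"])
    aw["p_wga_source"] = np.where(use_emp, "empirical", "asymptotic")
    aw = aw.dropna(subset=["p_wga"])[["id", "beta", "p_wga", "p_wga_source"]]

    merged = ih.merge(aw, on="id", how="inner")
    if merged.empty:
        raise ValueError("no SNPs shared between the selection and association scans")
    n_excluded = len(ihs_records) + len(assoc_records) - 2 * len(merged)

    z, p_comb = stouffer(merged[["p_ihs", "p_wga"]].to_numpy(), k=2)
    merged["z_comb"] = z
    merged["p_comb"] = p_comb
    merged["q_value"] = tail_fdr(p_comb, fdr_method)
    merged["significant"] = merged["q_value"] < q_threshold
    merged["sign_concordant"] = np.sign(merged["ihs"]) == np.sign(merged["beta"])

    def _cor(frame):
        if len(frame) < 3:
            return np.nan
        return float(np.corrcoef(frame["ihs"], frame["beta"])[0, 1])

    by_abs = merged.reindex(
        merged["ihs"].abs().sort_values(ascending=False).index
    )
    top1 = by_abs.head(max(3, int(np.ceil(0.01 * len(merged)))))
    top01 = by_abs.head(max(3, int(np.ceil(0.001 * len(merged)))))
    summary = {
        "n_combined": len(merged),
        "n_excluded": int(n_excluded),
        "n_significant": int(merged["significant"].sum()),
        "cor_ihs_beta": _cor(merged),
        "cor_ihs_beta_top1pct": _cor(top1),
        "cor_ihs_beta_top01pct": _cor(top01),
    }
    return merged.reset_index(drop=True), summary
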