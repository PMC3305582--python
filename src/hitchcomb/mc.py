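"""Monte Carlo machinery: null genotypes over a sire/MGS half-sib design,
QTL injection, and false-positive / power rates for MIX vs MIXStrat.

The simulated population mimics an artificial-insemination dairy-cattle
design: each individual inherits one allele from its sire (Mendelian), and
its maternal allele comes from the maternal grandsire with probability 1/2,
otherwise from the population allele frequency (the dam's own maternal
contribution).  Per-SNP allele frequencies are uniform on (0,1).  No LD is
simulated between SNPs.

Phenotypes are family-structured (sire + MGS + individual terms) and
selectively genotyped: only the highest ``n_top`` and lowest ``n_bottom``
of the candidate pool are retained, reproducing the bimodal,
family-confounded phenotype of extreme-selected designs.

QTL effects use the allele-substitution parameterization
alpha_QTL = sqrt(sigma2_EBV * QTL_SIZE / (2 p (1-p))), so a locus at
frequency p explains QTL_SIZE of the phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed
from .datatypes import FamilyStructure, GenotypeTable, PhenotypeVector, make_variant_frame
from .wga import (
    VarianceComponents,
    _v_inverse,
    estimate_kinship,
    family_design,
    fit_variance_components,
    gls_scan,
    inflation_factor,
    repair_positive_definite,
)

# the reference study design: 973 candidate bulls, 90 sires, 121 maternal
# grandsires; 140 highest + 148 lowest EBVs genotyped, one individual
# later dropped for low call rate -> 287 analyzed
BROWNSWISS = dict(
    n_candidates=973, n_sires=90, n_mgs=121, n_top=140, n_bottom=148, n_drop=1
)

DEFAULT_ALPHA_BONF = 2.5e-5  # conventional 5% Bonferroni threshold


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def candidate_structure(n_candidates: int, n_sires: int, n_mgs: int,
                        rng, concentration: float = 1.0) -> FamilyStructure:
    """Assign candidates to sire and MGS families with Dirichlet-multinomial
    sizes (every family non-empty), giving the uneven family sizes of AI
    breeding schemes."""
    def assign(k):
        w = rng.dirichlet(np.full(k, concentration))
        lab = rng.choice(k, size=n_candidates - k, p=w)
        lab = np.concatenate([np.arange(k), lab])  # guarantee non-empty
        return rng.permuted(lab)

    return FamilyStructure(assign(n_sires), assign(n_mgs), n_sires, n_mgs)


def simulate_null_genotypes(fs: FamilyStructure, n_snps: int = 10_000,
                            seed=0, dam_mode: str = "half_mgs") -> GenotypeTable:
    """Null genotypes (no phenotype effect) over a half-sib structure.

    Per SNP: allele-1 frequency p ~ U(0,1); every sire and MGS founder
    carries two Bernoulli(p) alleles; the paternal allele is a random one
    of the sire's two; the maternal allele is an MGS allele with
    probability 1/2 else a fresh population draw (``dam_mode="half_mgs"``),
    or always a population draw (``dam_mode="population_only"``, the
    strictly literal reading of the sampling scheme).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = fs.n
    p = rng.uniform(0.0, 1.0, size=n_snps)
    sire_alleles = rng.random((fs.n_sires, 2, n_snps)) < p
    mgs_alleles = rng.random((fs.n_mgs, 2, n_snps)) < p

    pick_pat = rng.integers(0, 2, size=(n, n_snps))
    paternal = sire_alleles[fs.sire[:, None], pick_pat, np.arange(n_snps)[None, :]]

    pick_mgs = rng.integers(0, 2, size=(n, n_snps))
    from_mgs = mgs_alleles[fs.mgs[:, None], pick_mgs, np.arange(n_snps)[None, :]]
    pop_draw = rng.random((n, n_snps)) < p
    if dam_mode == "half_mgs":
        use_mgs = rng.random((n, n_snps)) < 0.5
        maternal = np.where(use_mgs, from_mgs, pop_draw)
    elif dam_mode == "population_only":
        maternal = pop_draw
    else:
        raise ValueError(f"unknown dam_mode {dam_mode!r}")

    codes = (paternal.astype(np.int8) + maternal.astype(np.int8))
    variants = make_variant_frame(
        [f"sim{j}" for j in range(n_snps)],
        "1",
        np.arange(1, n_snps + 1) * 1000,
        maf=np.minimum(p, 1 - p),
    )
    variants["sim_freq"] = p  # the drawn allele-1 frequency (truth)
    return GenotypeTable(codes, variants, [f"ind{i}" for i in range(n)])


def qtl_effect(sigma2_ebv: float, qtl_size: float, p) -> np.ndarray:
    """Allele substitution effect alpha_QTL = sqrt(sigma2 * size / (2p(1-p))).

    Adding alpha_QTL per allele copy makes the locus explain ``qtl_size``
    of sigma2_ebv:  2p(1-p) * alpha^2 = qtl_size * sigma2.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ZeroDivisionError("allele frequency must lie strictly in (0,1)")
    if not (0 < qtl_size < 1):
        raise ValueError("qtl_size must lie in (0,1)")
    if sigma2_ebv <= 0:
        raise ValueError("sigma2_ebv must be positive")
    return np.sqrt(sigma2_ebv * qtl_size / (2.0 * p * (1.0 - p)))


def simulate_phenotypes(fs: FamilyStructure, h2_family: float = 0.5,
                        n_top: int = 140, n_bottom: int = 148, seed=0):
    """Family-structured candidate phenotypes with selective genotyping.

    Candidate value = sire effect + MGS effect + individual term, emulating
    EBVs of progeny-tested bulls (reliability near 1, so the phenotype is
    essentially the additive merit itself).  ``h2_family`` is the
    heritability of the candidate trait: an individual carries half of its
    sire's and a quarter of its maternal grandsire's breeding value, so the
    family effects have variance shares h2_family/4 (sire) and h2_family/16
    (MGS) — exactly the transmission expectation, which also matches the
    genotypic relatedness of the simulated half-sib design (pi = 1/4 and
    1/16).  The individual term (Mendelian sampling + environment) carries
    the remainder.  Keeping the family shares transmission-consistent makes
    the pre-selection phenotype representable by an additive kinship model;
    the stratification the association models must cope with then comes
    from selective genotyping: only the top ``n_top`` and bottom
    ``n_bottom`` candidates are retained, which concentrates extreme family
    effects and inflates between-family variance beyond what relatedness
    explains.

    Returns ``(values, retained_idx)`` where ``values`` is a
    :class:`PhenotypeVector` over the retained candidates (original order).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = fs.n
    if n_top + n_bottom > n:
        raise ValueError("cannot retain more candidates than exist")
    s_eff = rng.normal(0.0, np.sqrt(h2_family / 4.0), fs.n_sires)
    m_eff = rng.normal(0.0, np.sqrt(h2_family / 16.0), fs.n_mgs)
    e = rng.normal(0.0, np.sqrt(1.0 - h2_family * 5.0 / 16.0), n)
    value = s_eff[fs.sire] + m_eff[fs.mgs] + e
    order = np.argsort(value)
    retained = np.sort(np.concatenate([order[:n_bottom], order[-n_top:]]))
    values = PhenotypeVector.from_values(
        value[retained], [f"ind{i}" for i in retained]
    )
    return values, retained


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def false_positive_rate(p_matrix, threshold: float = 0.05) -> float:
    """Fraction of (replicate, SNP) P-values below the threshold:
    alpha_P = sum 1{P < t} / n_snps / m.  NaN P-values (untestable SNPs)
    count in the denominator but never as positives."""
    p = np.asarray(p_matrix, dtype=float)
    return float(np.sum(p < threshold) / p.size)


def power(p_matrix, alpha_bonf: float = DEFAULT_ALPHA_BONF) -> float:
    """Detection power over causal SNPs at the Bonferroni threshold."""
    return false_positive_rate(p_matrix, threshold=alpha_bonf)


# ---------------------------------------------------------------------------
# Full evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalConfig:
    models: tuple = ("MIX", "MIXStrat")
    n_snps: int = 10_000
    m: int = 10
    qtl_sizes: tuple = ()
    h2_family: float = 0.5
    alpha: float = 0.05
    alpha_bonf: float = DEFAULT_ALPHA_BONF
    min_family: int = 5
    dam_mode: str = "half_mgs"
    seed: int = 0
    preset: dict = field(default_factory=lambda: dict(BROWNSWISS))


@dataclass
class SimResult:
    config: EvalConfig
    alpha_p: dict            # model -> false-positive rate at config.alpha
    lambda_gc: dict          # model -> genomic inflation factor
    power: dict              # model -> {qtl_size: power}
    p_null: dict             # model -> (m x n_snps) asymptotic P matrix
    t2_null: dict            # model -> (m x n_snps) Wald statistics
    p_qtl: dict              # (model, qtl_size) -> (m x n_snps) causal P matrix


def _replicate(cfg: EvalConfig, rep: int):
    """One Monte Carlo replicate: structure, phenotypes, genotypes, scans."""
    pr = cfg.preset
    rng = np.random.default_rng(derive_seed(cfg.seed, "mc", rep))
    fs_cand = candidate_structure(pr["n_candidates"], pr["n_sires"], pr["n_mgs"], rng)
    values, retained = simulate_phenotypes(
        fs_cand, cfg.h2_family, pr["n_top"], pr["n_bottom"], rng
    )
    if pr.get("n_drop", 0):
        drop = rng.choice(len(retained), size=pr["n_drop"], replace=False)
        keep = np.setdiff1d(np.arange(len(retained)), drop)
        retained = retained[keep]
        values = values.iloc[keep]
    fs = fs_cand.subset(retained)
    y = values.to_numpy()

    gt = simulate_null_genotypes(fs, cfg.n_snps, rng, cfg.dam_mode)
    G = repair_positive_definite(estimate_kinship(gt))
    vc = fit_variance_components(y, G)
    W = _v_inverse(G, vc)

    codes = gt.codes.astype(float)
    U, _, _ = family_design(fs.sire, fs.mgs, cfg.min_family)
    resid = codes - U @ (U.T @ codes)

    p_freq = gt.variants["sim_freq"].to_numpy()
    sigma2_ebv = float(np.var(y, ddof=1))

    out = {}
    for model in cfg.models:
        X = codes if model == "MIX" else resid
        _, _, t2, p, _ = gls_scan(y, X, W)
        out[model] = {"t2": t2, "p": p, "qtl": {}}
        for size in cfg.qtl_sizes:
            ok = (p_freq > 0) & (p_freq < 1)
            alpha_qtl = np.zeros_like(p_freq)
            alpha_qtl[ok] = qtl_effect(sigma2_ebv, size, p_freq[ok])
            # every SNP acts as the causal locus of its own phenotype
            # y_i = y + codes_i * alpha_i; cross-products stay cached
            _, _, _, p_c, _ = gls_scan(y, X, W, inject=codes, alpha=alpha_qtl)
            p_c = np.where(ok, p_c, np.nan)
            out[model]["qtl"][size] = p_c
    return out


def run_evaluation(config: EvalConfig | None = None, **overrides) -> SimResult:
    """Run the full Monte Carlo study (null rates + power per QTL size).

    Structure, phenotypes and genotypes are regenerated each replicate;
    both models are fitted on identical data.  Deterministic per seed.
    """
    cfg = config or EvalConfig(**overrides)
    if config is not None and overrides:
        raise ValueError("pass either a config or keyword overrides, not both")

    p_null = {mdl: [] for mdl in cfg.models}
    t2_null = {mdl: [] for mdl in cfg.models}
    p_qtl = {(mdl, s): [] for mdl in cfg.models for s in cfg.qtl_sizes}
    for rep in range(cfg.m):
        res = _replicate(cfg, rep)
        for mdl in cfg.models:
            p_null[mdl].append(res[mdl]["p"])
            t2_null[mdl].append(res[mdl]["t2"])
            for s in cfg.qtl_sizes:
                p_qtl[(mdl, s)].append(res[mdl]["qtl"][s])

    p_null = {m_: np.vstack(v) for m_, v in p_null.items()}
    t2_null = {m_: np.vstack(v) for m_, v in t2_null.items()}
    p_qtl = {k: np.vstack(v) for k, v in p_qtl.items()}

    alpha_p = {m_: false_positive_rate(p, cfg.alpha) for m_, p in p_null.items()}
    lambda_gc = {m_: inflation_factor(t.ravel()) for m_, t in t2_null.items()}
    pwr = {
        m_: {s: power(p_qtl[(m_, s)], cfg.alpha_bonf) for s in cfg.qtl_sizes}
        for m_ in cfg.models
    }
    return SimResult(cfg, alpha_p, lambda_gc, pwr, p_null, t2_null, p_qtl)
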