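"""Synthetic data generators: neutral recombining haplotype panels,
forward-simulated selective sweeps, and pedigreed genotype/phenotype sets.

These generators define the study conditions for calibration and power
experiments.  All are pure functions of (configuration, seed).

* ``neutral_panel`` builds sample haplotypes as recombinant mosaics of a
  founder pool with exponential segment lengths — realistic LD decay, no
  systematic EHH asymmetry between alleles.  Panels default to 600
  haplotypes so that a SNP at the 5% MAF floor still has ~30 minor-allele
  carriers, comfortably above the 1/cutoff = 20 carriers below which the
  plug-in EHH cannot decay past the 0.05 cutoff.
* ``sweep_panel`` runs a forward Wright-Fisher simulation with additive
  selection (fitness 1, 1+s, 1+2s) and recombination on top of a neutral
  base population, stopping when the beneficial allele reaches the target
  frequency band — the incomplete-sweep regime where haplotype tests are
  most powerful.
* ``pedigree_fixture`` bundles the Monte Carlo generators into a ready
  dataset with the half-sib family structure and selective genotyping of
  the dairy-cattle design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import mc
from ._seeds import derive_seed
from .datatypes import FamilyStructure, HaplotypePanel, make_variant_frame


def _positions(n_snps: int, region_bp: int, rng) -> np.ndarray:
    gaps = rng.uniform(0.4, 1.6, n_snps) * (region_bp / n_snps)
    pos = np.cumsum(np.maximum(1, np.round(gaps))).astype(np.int64)
    return pos


def _mosaic_haplotypes(founders: np.ndarray, positions: np.ndarray,
                       n_hap: int, seg_len: float, rng) -> np.ndarray:
    """Sample haplotypes as founder mosaics with exponential segment lengths."""
    k, m = founders.shape
    gaps = np.diff(positions, prepend=positions[0])
    p_switch = 1.0 - np.exp(-gaps / seg_len)
    p_switch[0] = 0.0
    switches = rng.random((n_hap, m)) < p_switch[None, :]
    seg_id = np.cumsum(switches, axis=1)
    max_seg = int(seg_id.max()) + 1
    founder_choice = rng.integers(0, k, size=(n_hap, max_seg))
    path = np.take_along_axis(founder_choice, seg_id, axis=1)
    return founders[path, np.arange(m)[None, :]]


def neutral_panel(n_hap: int = 600, n_snps: int = 5000,
                  region_bp: int = 25_000_000, mosaic_k: int = 24,
                  seg_len: float = 50_000.0, seed: int = 0,
                  maf_min: float = 0.05, chrom: str = "1") -> HaplotypePanel:
    """Neutral haplotype panel with mosaic LD structure.

    Founder allele frequencies are U(0.05, 0.5) per SNP; columns whose
    realized sample MAF falls below ``maf_min`` are re-drawn.
    """
    if n_hap % 2:
        raise ValueError("n_hap must be even (two haplotypes per individual)")
    if mosaic_k < 2:
        raise ValueError("need at least 2 founder haplotypes")
    rng = np.random.default_rng(seed)
    pos = _positions(n_snps, region_bp, rng)
    freq = rng.uniform(maf_min, 0.5, n_snps)
    founders = (rng.random((mosaic_k, n_snps)) < freq[None, :]).astype(np.uint8)
    alleles = _mosaic_haplotypes(founders, pos, n_hap, seg_len, rng)

    alleles, founders = _redraw_low_maf(
        alleles, founders, freq, pos, n_hap, seg_len, rng, maf_min
    )

    f = alleles.mean(axis=0)
    # orient so code 1 is the minor allele
    flip = f > 0.5
    alleles[:, flip] = 1 - alleles[:, flip]
    maf = alleles.mean(axis=0)
    variants = make_variant_frame(
        [f"n{j}" for j in range(n_snps)], chrom, pos, maf=maf
    )
    return HaplotypePanel(alleles, variants)


def _redraw_low_maf(alleles, founders, freq, pos, n_hap, seg_len, rng, maf_min):
    """Re-draw founder columns whose sampled MAF fell under the floor.

    The mosaic paths cannot be reused cheaply, so redraw re-samples the
    column through fresh per-column paths; after 50 rounds a stubborn
    column is replaced by an i.i.d. Bernoulli(0.25) column.
    """
    m = alleles.shape[1]
    for _ in range(50):
        f = alleles.mean(axis=0)
        bad = np.flatnonzero(np.minimum(f, 1 - f) < maf_min)
        if len(bad) == 0:
            return alleles, founders
        k = founders.shape[0]
        freq_new = rng.uniform(maf_min, 0.5, len(bad))
        founders[:, bad] = (rng.random((k, len(bad))) < freq_new[None, :]).astype(np.uint8)
        sub_pos = pos[bad]
        cols = _mosaic_haplotypes(
            founders[:, bad], sub_pos, n_hap, seg_len, rng
        )
        alleles[:, bad] = cols
    f = alleles.mean(axis=0)
    bad = np.flatnonzero(np.minimum(f, 1 - f) < maf_min)
    for j in bad:
        alleles[:, j] = rng.random(n_hap) < 0.25
    return alleles, founders


# ---------------------------------------------------------------------------
# Selective sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepConfig:
    n_pop: int = 200                 # diploid population size
    region_bp: int = 1_000_000
    n_snps: int = 300
    recomb_rate: float = 1e-6        # per bp per generation (rescaled for desk-scale N)
    s: float = 0.05                  # selection coefficient (1, 1+s, 1+2s)
    start_freq: float = 0.10
    band: tuple = (0.5, 0.8)
    sample_size: int = 240           # haplotypes sampled at the end
    mosaic_k: int = 24
    seg_len: float = 50_000.0
    max_generations: int = 500
    max_restarts: int = 100
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.band[0] < self.band[1] < 1):
            raise ValueError("target band must lie inside (0,1)")
        if self.recomb_rate < 0 or self.s < 0:
            raise ValueError("rates must be non-negative")
        if self.sample_size > 2 * self.n_pop:
            raise ValueError("cannot sample more haplotypes than exist")


def _recombine(pop: np.ndarray, parent_idx: np.ndarray, positions: np.ndarray,
               region_bp: int, rate: float, rng) -> np.ndarray:
    """Produce one gamete per entry of parent_idx by crossing over the
    parent's two haplotypes (Poisson number of breakpoints)."""
    n_gam = len(parent_idx)
    m = pop.shape[1]
    n_x = rng.poisson(rate * region_bp, n_gam)
    start = rng.integers(0, 2, n_gam)
    gametes = np.empty((n_gam, m), dtype=np.uint8)
    plain = n_x == 0
    gametes[plain] = pop[2 * parent_idx[plain] + start[plain]]
    for g in np.flatnonzero(~plain):
        bp = np.sort(rng.uniform(0, region_bp, n_x[g]))
        parity = (np.searchsorted(bp, positions) + start[g]) % 2
        h0 = pop[2 * parent_idx[g]]
        h1 = pop[2 * parent_idx[g] + 1]
        gametes[g] = np.where(parity == 0, h0, h1)
    return gametes


def sweep_panel(cfg: SweepConfig):
    """Forward Wright-Fisher sweep simulation.

    Returns ``(panel, selected_pos)``: a sampled haplotype panel (columns
    with sample MAF < 0.05 dropped) and the physical position of the
    selected site.  Restarts on allele loss/overshoot, capped.
    """
    for restart in range(cfg.max_restarts):
        rng = np.random.default_rng(derive_seed(cfg.seed, "sweep", restart))
        base = neutral_panel(
            n_hap=2 * cfg.n_pop, n_snps=cfg.n_snps, region_bp=cfg.region_bp,
            mosaic_k=cfg.mosaic_k, seg_len=cfg.seg_len,
            seed=derive_seed(cfg.seed, "base", restart),
        )
        pos = base.positions
        pop = base.alleles.copy()
        # selected site: the middle-third SNP nearest the region centre.
        # The beneficial allele is introduced at start_freq as identical
        # copies of one founder haplotype — a hard sweep from a recent
        # mutation; recombination during the rise then erodes the flanks.
        third = slice(cfg.n_snps // 3, 2 * cfg.n_snps // 3)
        cand = np.arange(cfg.n_snps)[third]
        centre = (pos[0] + pos[-1]) / 2
        sel = int(cand[np.argmin(np.abs(pos[third] - centre))])
        n_copies = max(1, int(round(cfg.start_freq * 2 * cfg.n_pop)))
        donor = int(rng.integers(2 * cfg.n_pop))
        carriers = rng.choice(2 * cfg.n_pop, n_copies, replace=False)
        pop[:, sel] = 0
        pop[carriers] = pop[donor]
        pop[carriers, sel] = 1

        ok = _evolve(pop, pos, sel, cfg, rng)
        if not ok:
            continue
        take = rng.choice(2 * cfg.n_pop, cfg.sample_size, replace=False)
        alleles = pop[np.sort(take)].copy()
        f = alleles.mean(axis=0)
        keep = np.minimum(f, 1 - f) >= 0.05
        keep[sel] = np.minimum(f[sel], 1 - f[sel]) > 0
        flip = f > 0.5
        alleles[:, flip] = 1 - alleles[:, flip]
        panel = HaplotypePanel(
            alleles[:, keep],
            make_variant_frame(
                [f"s{j}" for j in np.flatnonzero(keep)], "1", pos[keep],
                maf=alleles[:, keep].mean(axis=0),
            ),
        )
        return panel, int(pos[sel])
    raise RuntimeError(
        f"sweep did not reach the target band in {cfg.max_restarts} restarts"
    )


def _evolve(pop, pos, sel, cfg: SweepConfig, rng) -> bool:
    """Evolve in place until the beneficial-allele frequency reaches a
    sampling target drawn uniformly from the band (so sampled sweeps span
    the whole incomplete-sweep regime, not just the band edge); False on
    loss, overshoot past the band or generation cap."""
    n = cfg.n_pop
    lo, hi = cfg.band
    target = rng.uniform(lo, hi)
    for _ in range(cfg.max_generations):
        freq = pop[:, sel].mean()
        if target <= freq <= hi:
            return True
        if freq == 0.0 or freq > hi:
            return False
        g = pop[0::2, sel].astype(np.int64) + pop[1::2, sel]
        w = 1.0 + cfg.s * g
        prob = w / w.sum()
        parents = rng.choice(n, size=2 * n, p=prob)
        pop[:] = _recombine(pop, parents, pos, cfg.region_bp, cfg.recomb_rate, rng)
    return False


# ---------------------------------------------------------------------------
# Pedigreed genotype/phenotype bundles
# ---------------------------------------------------------------------------

def pedigree_fixture(preset: str | dict = "brownswiss", seed: int = 0,
                     n_snps: int = 10_000, h2_family: float = 0.5):
    """Half-sib family dataset with selective genotyping.

    The "brownswiss" preset uses the reference design: 973 candidates over
    90 sires and 121 maternal grandsires, the 140 highest and 148 lowest
    phenotypes genotyped, one individual dropped (call-rate analogue),
    leaving 287.

    Returns ``(family_structure, genotypes, phenotypes, pedigree)``.
    """
    pr = dict(mc.BROWNSWISS) if preset == "brownswiss" else dict(preset)
    rng = np.random.default_rng(derive_seed(seed, "pedigree_fixture"))
    fs_cand = mc.candidate_structure(pr["n_candidates"], pr["n_sires"], pr["n_mgs"], rng)
    values, retained = mc.simulate_phenotypes(
        fs_cand, h2_family, pr["n_top"], pr["n_bottom"], rng
    )
    if pr.get("n_drop", 0):
        drop = rng.choice(len(retained), size=pr["n_drop"], replace=False)
        keep = np.setdiff1d(np.arange(len(retained)), drop)
        retained = retained[keep]
        values = values.iloc[keep]
    fs = fs_cand.subset(retained)
    gt = mc.simulate_null_genotypes(fs, n_snps, rng)
    pheno = values.copy()
    pheno.index = list(gt.ids)
    ped = fs.to_pedigree(gt.ids)
    return fs, gt, pheno, ped
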