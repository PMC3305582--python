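"""Extended haplotype homozygosity (EHH), integrated EHH and uiHS.

The EHH of a core allele at distance d is the haplotype homozygosity of the
carriers of that allele over the interval [core, core +/- d]:

    EHH_i = sum_j e_ij^2 / c_i^2

with c_i the number of carrier haplotypes and e_ij the count of the j-th
distinct extended haplotype among them.  This plug-in form is the default;
the unbiased variant sum_j C(e_ij,2) / C(c_i,2) is available via
``estimator="unbiased"``.

The integrated EHH (iHH) is the trapezoid area under the EHH-versus-distance
curve, walked outward SNP by SNP in each direction until EHH drops below a
cutoff (default 0.05); the last segment is integrated only to the linearly
interpolated crossing point.  Distances are physical (bp).

Note the plug-in EHH can never fall below 1/c_i, so a core allele with
c_i <= 1/cutoff carriers cannot reach the cutoff and its curve is flagged
truncated at the chromosome end.

uiHS = ln(iHH_A / iHH_B) where (A, B) is (ancestral, derived) or
(minor, major) depending on mode; positive minor/major values mean the
minor allele rides the longer haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import HaplotypePanel

DEFAULT_CUTOFF = 0.05


# ---------------------------------------------------------------------------
# Point and curve computations (reference implementations)
# ---------------------------------------------------------------------------

def ehh_at(panel: HaplotypePanel, core: int, allele: int, upto: int,
           estimator: str = "plugin") -> float:
    """EHH of ``allele`` carriers at ``core`` over the span core..upto.

    Groups carrier haplotypes by exact identity of the substring between
    core and ``upto`` (inclusive) and applies the homozygosity formula.
    """
    carriers = panel.alleles[:, core] == allele
    c = int(carriers.sum())
    if c == 0:
        raise ValueError(f"no carriers of allele {allele} at core index {core}")
    lo, hi = min(core, upto), max(core, upto)
    seg = panel.alleles[carriers, lo : hi + 1]
    _, counts = np.unique(seg, axis=0, return_counts=True)
    if estimator == "plugin":
        return float((counts.astype(float) ** 2).sum() / c**2)
    if estimator == "unbiased":
        if c < 2:
            return 1.0
        num = (counts * (counts - 1) / 2).sum()
        return float(num / (c * (c - 1) / 2))
    raise ValueError(f"unknown estimator {estimator!r}")


@dataclass
class EhhCurve:
    """EHH decay curve for one core allele, walked in both directions.

    ``points_*`` hold the recorded curve: the distance-0 point plus every
    point with EHH >= cutoff.  The first observation below the cutoff (the
    stopping point) is kept separately in ``crossing_*`` so the integral can
    interpolate to the exact cutoff crossing; a direction that hits the
    chromosome end before crossing is flagged truncated.
    """

    core_index: int
    allele_group: str
    carrier_count: int
    points_left: list = field(default_factory=list)   # (distance_bp, ehh)
    points_right: list = field(default_factory=list)
    crossing_left: tuple | None = None
    crossing_right: tuple | None = None
    truncated_left: bool = False
    truncated_right: bool = False


def ehh_curve(panel: HaplotypePanel, core: int, allele: int,
              cutoff: float = DEFAULT_CUTOFF, estimator: str = "plugin",
              allele_group: str | None = None) -> EhhCurve:
    """Walk outward from the core, recording (distance, EHH) per SNP.

    Each direction stops after the first point with EHH < cutoff, or at the
    chromosome end (which sets the direction's truncation flag).
    """
    pos = panel.positions
    carriers = panel.alleles[:, core] == allele
    c = int(carriers.sum())
    if c == 0:
        raise ValueError(f"no carriers of allele {allele} at core index {core}")
    curve = EhhCurve(core, allele_group or str(allele), c)
    for direction, sign in (("left", -1), ("right", +1)):
        points = [(0, 1.0)]
        crossing = None
        truncated = True
        j = core + sign
        while 0 <= j < panel.n_snps:
            e = ehh_at(panel, core, allele, j, estimator)
            d = abs(int(pos[j] - pos[core]))
            if e < cutoff:
                crossing = (d, e)
                truncated = False
                break
            points.append((d, e))
            j += sign
        if direction == "left":
            curve.points_left, curve.crossing_left = points, crossing
            curve.truncated_left = truncated
        else:
            curve.points_right, curve.crossing_right = points, crossing
            curve.truncated_right = truncated
    return curve


def _integrate_points(points, crossing, cutoff: float) -> float:
    """Trapezoid area under one direction's curve; the final segment (into
    ``crossing``, if any) is integrated only to the interpolated point where
    EHH equals the cutoff."""
    area = 0.0
    for (d0, e0), (d1, e1) in zip(points, points[1:]):
        area += 0.5 * (e0 + e1) * (d1 - d0)
    if crossing is not None:
        d0, e0 = points[-1]
        d1, e1 = crossing
        dc = d0 + (d1 - d0) * (e0 - cutoff) / (e0 - e1)
        area += 0.5 * (e0 + cutoff) * (dc - d0)
    return area


def integrate_ihh(curve: EhhCurve, cutoff: float = DEFAULT_CUTOFF):
    """Integrated EHH over both directions; returns ``(ihh, truncated)``."""
    area = _integrate_points(
        curve.points_left, curve.crossing_left, cutoff
    ) + _integrate_points(curve.points_right, curve.crossing_right, cutoff)
    return float(area), bool(curve.truncated_left or curve.truncated_right)


def uihs(panel: HaplotypePanel, core: int, mode: str = "minor_major",
         cutoff: float = DEFAULT_CUTOFF, ancestral_is_minor: bool | None = None):
    """Unstandardized iHS at a core SNP.

    mode "minor_major": ln(iHH_minor / iHH_major) — positive values mean the
    minor allele carries the longer haplotypes.  mode "ancestral_derived":
    ln(iHH_ancestral / iHH_derived); requires ``ancestral_is_minor``.

    Returns ``(uihs, flags)`` where flags is a set drawn from
    {"truncated", "zero_ihh", "monomorphic"}.  A zero/invalid integral sets
    a flag instead of raising.
    """
    flags = set()
    freq1 = panel.alleles[:, core].mean()
    if freq1 in (0.0, 1.0):
        return np.nan, {"monomorphic"}
    if mode == "minor_major":
        a_allele, b_allele = 1, 0  # 1 = minor by panel convention
        groups = ("minor", "major")
    elif mode == "ancestral_derived":
        if ancestral_is_minor is None:
            raise ValueError("ancestral_derived mode requires ancestral_is_minor")
        a_allele = 1 if ancestral_is_minor else 0
        b_allele = 1 - a_allele
        groups = ("ancestral", "derived")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ihh = {}
    for allele, grp in ((a_allele, groups[0]), (b_allele, groups[1])):
        curve = ehh_curve(panel, core, allele, cutoff, allele_group=grp)
        val, trunc = integrate_ihh(curve, cutoff)
        if trunc:
            flags.add("truncated")
        ihh[grp] = val
    if ihh[groups[0]] <= 0 or ihh[groups[1]] <= 0:
        flags.add("zero_ihh")
        return np.nan, flags
    return float(np.log(ihh[groups[0]] / ihh[groups[1]])), flags


# ---------------------------------------------------------------------------
# Bifurcation trees (haplotype branching diagrams)
# ---------------------------------------------------------------------------

@dataclass
class BifurcationNode:
    snp_index: int
    weight: int
    children: list = field(default_factory=list)


@dataclass
class BifurcationTree:
    """One branching diagram per direction from the core SNP.

    The root carries all haplotypes with the given core allele; at each
    successive SNP a node splits when its haplotypes carry both alleles.
    Child weights always sum to the parent's weight.
    """

    core_index: int
    allele: int
    left: BifurcationNode = None
    right: BifurcationNode = None


def _grow(panel, members, j, sign, steps_left) -> BifurcationNode:
    node = BifurcationNode(j - sign, int(len(members)))  # index of previous SNP
    if steps_left == 0 or not (0 <= j < panel.n_snps):
        return node
    col = panel.alleles[members, j]
    for allele in (0, 1):
        sub = members[col == allele]
        if len(sub):
            node.children.append(_grow(panel, sub, j + sign, sign, steps_left - 1))
    return node


def bifurcation_tree(panel: HaplotypePanel, core: int, allele: int,
                     max_steps: int) -> BifurcationTree:
    carriers = np.flatnonzero(panel.alleles[:, core] == allele)
    if len(carriers) == 0:
        raise ValueError(f"no carriers of allele {allele} at core index {core}")
    tree = BifurcationTree(core, allele)
    tree.left = _grow(panel, carriers, core - 1, -1, max_steps)
    tree.left.snp_index = core
    tree.right = _grow(panel, carriers, core + 1, +1, max_steps)
    tree.right.snp_index = core
    return tree


def leaf_weights(node: BifurcationNode) -> list:
    if not node.children:
        return [node.weight]
    out = []
    for ch in node.children:
        out.extend(leaf_weights(ch))
    return out
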