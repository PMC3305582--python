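"""Fast joint EHH/iHH evaluation for a core SNP and many core-allele
assignments (the observed one plus permuted ones).

The trick: permuting core alleles leaves the flanking haplotype structure
untouched, so the partition of haplotypes into identity classes over the
span core..j can be precomputed once per step.  For a minor-carrier set S of
size c and class sizes m_j with counts x_j = |class_j ∩ S|:

    EHH_minor = sum x_j^2 / c^2
    EHH_major = (sum m_j^2 - 2 sum m_j x_j + sum x_j^2) / (n - c)^2

so only the classes actually hit by S need to be touched — O(c) per row per
step.  The inner loop is JIT-compiled with numba when available.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _step_ehh_numba(ids, sets, scratch, class_sizes, sum_m2, n_hap, e_min, e_maj):
    n_rows, c_min = sets.shape
    c_maj = n_hap - c_min
    for r in range(n_rows):
        for t in range(c_min):
            scratch[ids[sets[r, t]]] += 1
        sx2 = 0.0
        smx = 0.0
        for t in range(c_min):
            c = ids[sets[r, t]]
            x = scratch[c]
            if x > 0:
                sx2 += x * x
                smx += x * class_sizes[c]
                scratch[c] = 0
        e_min[r] = sx2 / (c_min * c_min)
        e_maj[r] = (sum_m2 - 2.0 * smx + sx2) / (c_maj * c_maj)


def _step_ehh_numpy(ids, sets, class_sizes, sum_m2, n_hap):
    """Vectorised fallback used when numba is unavailable."""
    n_rows, c_min = sets.shape
    c_maj = n_hap - c_min
    n_classes = len(class_sizes)
    hit = ids[sets]  # n_rows x c_min class labels
    flat = hit + (np.arange(n_rows)[:, None] * n_classes)
    counts = np.bincount(flat.ravel(), minlength=n_rows * n_classes).reshape(
        n_rows, n_classes
    )
    sx2 = (counts.astype(np.float64) ** 2).sum(axis=1)
    smx = (counts * class_sizes[None, :]).sum(axis=1).astype(np.float64)
    e_min = sx2 / (c_min * c_min)
    e_maj = (sum_m2 - 2.0 * smx + sx2) / (c_maj * c_maj)
    return e_min, e_maj


class _DirectionWalker:
    """Accumulates per-row trapezoid integrals for one direction."""

    def __init__(self, n_rows: int, cutoff: float):
        self.cutoff = cutoff
        # group 0 = minor, 1 = major
        self.prev_e = np.ones((n_rows, 2))
        self.ihh = np.zeros((n_rows, 2))
        self.done = np.zeros((n_rows, 2), dtype=bool)
        self.truncated = np.zeros((n_rows, 2), dtype=bool)
        self.d_prev = 0.0

    def step(self, d: float, e_min: np.ndarray, e_maj: np.ndarray) -> bool:
        """Advance one SNP; returns True when every row/group has crossed."""
        cutoff = self.cutoff
        for g, e in ((0, e_min), (1, e_maj)):
            active = ~self.done[:, g]
            if not active.any():
                continue
            prev = self.prev_e[:, g]
            cross = active & (e < cutoff)
            cont = active & ~cross
            if cross.any():
                denom = prev[cross] - e[cross]
                dc = self.d_prev + (d - self.d_prev) * (prev[cross] - cutoff) / denom
                self.ihh[cross, g] += 0.5 * (prev[cross] + cutoff) * (dc - self.d_prev)
                self.done[cross, g] = True
            if cont.any():
                self.ihh[cont, g] += 0.5 * (prev[cont] + e[cont]) * (d - self.d_prev)
                self.prev_e[cont, g] = e[cont]
        self.d_prev = d
        return bool(self.done.all())

    def finish(self):
        """Chromosome end reached with rows still above the cutoff."""
        open_rows = ~self.done
        self.truncated[open_rows] = True


def core_ihh_many(alleles: np.ndarray, positions: np.ndarray, core: int,
                  sets: np.ndarray, cutoff: float = 0.05):
    """iHH of minor and major groups for many core-allele assignments.

    Parameters
    ----------
    alleles : (n_hap, m) uint8 panel matrix
    positions : (m,) physical positions (bp)
    core : core SNP column index
    sets : (n_rows, c_min) int32 matrix; row r lists the haplotype indices
        assigned the minor allele in assignment r (row 0 is conventionally
        the observed assignment)
    cutoff : EHH stopping threshold

    Returns
    -------
    ihh_minor, ihh_major : (n_rows,) integrals (bp units)
    truncated : (n_rows,) bool — some group's curve hit a chromosome end
        before decaying below the cutoff
    """
    n_hap, m = alleles.shape
    n_rows = sets.shape[0]
    sets = np.ascontiguousarray(sets, dtype=np.int64)
    ihh = np.zeros((n_rows, 2))
    truncated = np.zeros((n_rows, 2), dtype=bool)

    for sign in (-1, +1):
        walker = _DirectionWalker(n_rows, cutoff)
        ids = np.zeros(n_hap, dtype=np.int64)
        j = core + sign
        while 0 <= j < m:
            # refine identity classes by the allele at SNP j
            ids = ids * 2 + alleles[:, j]
            _, ids = np.unique(ids, return_inverse=True)
            ids = np.ascontiguousarray(ids, dtype=np.int64)
            class_sizes = np.bincount(ids).astype(np.int64)
            sum_m2 = float((class_sizes.astype(np.float64) ** 2).sum())
            d = float(abs(int(positions[j]) - int(positions[core])))
            if _HAVE_NUMBA:
                e_min = np.empty(n_rows)
                e_maj = np.empty(n_rows)
                scratch = np.zeros(len(class_sizes), dtype=np.int64)
                _step_ehh_numba(
                    ids, sets, scratch, class_sizes, sum_m2, n_hap, e_min, e_maj
                )
            else:
                e_min, e_maj = _step_ehh_numpy(ids, sets, class_sizes, sum_m2, n_hap)
            if walker.step(d, e_min, e_maj):
                break
            j += sign
        if not (0 <= j < m):  # chromosome end reached before every crossing
            walker.finish()
        ihh += walker.ihh
        truncated |= walker.truncated

    return ihh[:, 0], ihh[:, 1], truncated.any(axis=1)
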