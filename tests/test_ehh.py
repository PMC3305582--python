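"""EHH statistics against brute-force oracles and their exact invariants."""

from collections import Counter

import numpy as np
import pytest

from hitchcomb.ehh import (
    bifurcation_tree,
    ehh_at,
    ehh_curve,
    integrate_ihh,
    leaf_weights,
    uihs,
)
from tests.conftest import make_panel, random_micro_panel


def brute_force_ehh(panel, core, allele, upto):
    """Independent oracle: group carrier substrings with a Counter and
    apply sum(e^2)/c^2 directly."""
    lo, hi = min(core, upto), max(core, upto)
    carriers = [
        tuple(row[lo : hi + 1])
        for row in panel.alleles
        if row[core] == allele
    ]
    c = len(carriers)
    counts = Counter(carriers).values()
    return sum(e * e for e in counts) / c**2


class TestEhhAt:
    def test_identical_carriers_give_one(self):
        panel = make_panel(np.tile([1, 0, 1, 1, 0], (4, 1)))
        assert ehh_at(panel, 2, 1, 4) == 1.0

    def test_two_carriers_diverging_at_first_flank(self):
        # formula: (1^2 + 1^2) / 2^2 = 0.5
        panel = make_panel([[1, 0], [1, 1], [0, 0]])
        assert ehh_at(panel, 0, 1, 1) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_micro_panels(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(300):
            panel = random_micro_panel(rng)
            core = int(rng.integers(panel.n_snps))
            upto = int(rng.integers(panel.n_snps))
            for allele in (0, 1):
                if (panel.alleles[:, core] == allele).sum() == 0:
                    continue
                assert ehh_at(panel, core, allele, upto) == pytest.approx(
                    brute_force_ehh(panel, core, allele, upto), abs=1e-15
                )
                checked += 1
        assert checked > 300

    def test_no_carriers_raises(self):
        panel = make_panel([[0, 0], [0, 1]])
        with pytest.raises(ValueError, match="carriers"):
            ehh_at(panel, 0, 1, 1)

    def test_unbiased_estimator_on_split_pair(self):
        # 2 carriers, distinct haplotypes: C(1,2)=0 -> unbiased EHH 0
        panel = make_panel([[1, 0], [1, 1], [0, 0]])
        assert ehh_at(panel, 0, 1, 1, estimator="unbiased") == 0.0


class TestEhhCurve:
    def test_monomorphic_flank_stays_at_one_and_truncates(self):
        alleles = np.zeros((4, 11), dtype=np.uint8)
        alleles[:2, 0] = 1
        panel = make_panel(alleles)
        curve = ehh_curve(panel, 0, 1)
        assert len(curve.points_right) == 11
        assert all(e == 1.0 for _, e in curve.points_right)
        assert curve.truncated_right

    def test_curve_non_increasing_everywhere(self, rng):
        for _ in range(20):
            panel = random_micro_panel(rng)
            core = int(rng.integers(panel.n_snps))
            for allele in (0, 1):
                if (panel.alleles[:, core] == allele).sum() == 0:
                    continue
                curve = ehh_curve(panel, core, allele, cutoff=0.0)
                for pts in (curve.points_left, curve.points_right):
                    ehh = [e for _, e in pts]
                    assert all(a >= b - 1e-12 for a, b in zip(ehh, ehh[1:]))

    def test_degenerate_cutoff_keeps_only_core_point(self):
        panel = make_panel([[1, 0], [1, 1], [0, 1]])
        curve = ehh_curve(panel, 0, 1, cutoff=1.0)
        assert curve.points_right == [(0, 1.0)]
        assert not curve.truncated_right

    def test_terminal_core_direction_is_flagged(self):
        panel = make_panel([[1, 0], [1, 1], [0, 1]])
        curve = ehh_curve(panel, 0, 1)
        assert curve.points_left == [(0, 1.0)]
        assert curve.truncated_left


class TestIntegrateIhh:
    def test_hand_computed_trapezoid_with_interpolated_tail(self):
        # EHH 1 over a 1000 bp flank, dropping to 0 at the next SNP 100 bp
        # away: area = 1000 + trapezoid from 1 down to 0.05 over 95 bp
        from hitchcomb.ehh import EhhCurve

        curve = EhhCurve(
            core_index=0, allele_group="minor", carrier_count=20,
            points_left=[(0, 1.0)],
            points_right=[(0, 1.0), (500, 1.0), (1000, 1.0)],
            crossing_right=(1100, 0.0),
            truncated_left=True,
        )
        ihh, truncated = integrate_ihh(curve)
        assert ihh == pytest.approx(1000 + 49.875)
        assert truncated  # the left side never reached the cutoff

    def test_panel_curve_interpolates_to_its_own_crossing(self):
        alleles = np.zeros((4, 4), dtype=np.uint8)
        alleles[:2, 0] = 1
        alleles[0, 3] = 1  # carriers split at the last SNP: EHH 1 -> 0.5
        panel = make_panel(alleles, positions=[1, 501, 1001, 1101])
        curve = ehh_curve(panel, 0, 1, cutoff=0.6)
        assert curve.points_right[-1] == (1000, 1.0)
        assert curve.crossing_right == (1100, 0.5)
        ihh, _ = integrate_ihh(curve, cutoff=0.6)
        d_c = 1000 + 100 * (1 - 0.6) / (1 - 0.5)
        assert ihh == pytest.approx(1000 + 0.5 * (1 + 0.6) * (d_c - 1000))

    def test_symmetric_curve_splits_area_equally(self):
        alleles = np.zeros((4, 5), dtype=np.uint8)
        alleles[:2, 2] = 1
        alleles[0, 0] = alleles[0, 4] = 1
        panel = make_panel(alleles, positions=[100, 200, 300, 400, 500])
        curve = ehh_curve(panel, 2, 1, cutoff=0.4)
        left = curve.points_left, curve.crossing_left
        right = curve.points_right, curve.crossing_right
        assert [d for d, _ in left[0]] == [d for d, _ in right[0]]
        assert left[1] == right[1]

    def test_position_doubling_doubles_integral(self, rng):
        panel = random_micro_panel(rng)
        doubled = make_panel(panel.alleles, positions=2 * panel.positions)
        core = panel.n_snps // 2
        c1 = ehh_curve(panel, core, panel.alleles[0, core], cutoff=0.0)
        c2 = ehh_curve(doubled, core, panel.alleles[0, core], cutoff=0.0)
        assert integrate_ihh(c1, 0.0)[0] * 2 == pytest.approx(
            integrate_ihh(c2, 0.0)[0]
        )


class TestUihs:
    def test_equal_integrals_give_zero(self):
        # perfectly symmetric alleles: swapping 0<->1 off-core maps one
        # group's haplotypes onto the other's
        alleles = np.array(
            [[1, 1, 0], [1, 0, 1], [0, 0, 1], [0, 1, 0]], dtype=np.uint8
        )
        panel = make_panel(alleles)
        val, flags = uihs(panel, 1)
        assert val == pytest.approx(0.0)

    def test_ancestral_swap_flips_sign_only(self, rng):
        panel = random_micro_panel(rng, max_hap=10, max_snps=8)
        core = panel.n_snps // 2
        col = panel.alleles[:, core]
        if col.min() == col.max():
            pytest.skip("monomorphic core in this draw")
        a, _ = uihs(panel, core, "ancestral_derived", cutoff=0.0,
                    ancestral_is_minor=True)
        b, _ = uihs(panel, core, "ancestral_derived", cutoff=0.0,
                    ancestral_is_minor=False)
        assert a == pytest.approx(-b)

    def test_minor_major_antisymmetry_under_relabel(self, rng):
        # flipping the core column turns minor carriers into major ones
        panel = random_micro_panel(rng, max_hap=10, max_snps=8)
        core = panel.n_snps // 2
        col = panel.alleles[:, core]
        if col.min() == col.max():
            pytest.skip("monomorphic core in this draw")
        v1, _ = uihs(panel, core, cutoff=0.0)
        flipped = panel.alleles.copy()
        flipped[:, core] = 1 - flipped[:, core]
        v2, _ = uihs(make_panel(flipped, positions=panel.positions), core,
                     cutoff=0.0)
        assert v1 == pytest.approx(-v2)

    def test_haplotype_row_permutation_invariance(self, rng):
        panel = random_micro_panel(rng, max_hap=10, max_snps=8)
        core = panel.n_snps // 2
        if panel.alleles[:, core].min() == panel.alleles[:, core].max():
            pytest.skip("monomorphic core in this draw")
        perm = rng.permutation(panel.n_hap)
        shuffled = make_panel(panel.alleles[perm], positions=panel.positions)
        v1, _ = uihs(panel, core, cutoff=0.0)
        v2, _ = uihs(shuffled, core, cutoff=0.0)
        assert v1 == pytest.approx(v2)

    def test_flank_allele_relabel_invariance(self, rng):
        # uiHS depends only on identity classes, not on flank labels
        panel = random_micro_panel(rng, max_hap=10, max_snps=8)
        core = panel.n_snps // 2
        if panel.alleles[:, core].min() == panel.alleles[:, core].max():
            pytest.skip("monomorphic core in this draw")
        relabeled = panel.alleles.copy()
        for j in range(panel.n_snps):
            if j != core:
                relabeled[:, j] = 1 - relabeled[:, j]
        v1, _ = uihs(panel, core, cutoff=0.0)
        v2, _ = uihs(make_panel(relabeled, positions=panel.positions), core,
                     cutoff=0.0)
        assert v1 == pytest.approx(v2)

    def test_uihs_is_log_ratio_of_reference_integrals(self):
        # hand-checkable panel: minor iHH 175 bp, major iHH 112.5 bp
        alleles = np.array(
            [
                [1, 1, 1],
                [1, 1, 0],
                [0, 0, 0],
                [0, 0, 1],
                [0, 1, 0],
                [0, 1, 1],
            ],
            dtype=np.uint8,
        )
        panel = make_panel(alleles, positions=[100, 200, 300])
        val, flags = uihs(panel, 0, cutoff=0.0)
        assert val == pytest.approx(np.log(175.0 / 112.5))
        ihh_minor = integrate_ihh(ehh_curve(panel, 0, 1, cutoff=0.0), 0.0)[0]
        ihh_major = integrate_ihh(ehh_curve(panel, 0, 0, cutoff=0.0), 0.0)[0]
        assert (ihh_minor, ihh_major) == (175.0, 112.5)

    def test_missing_ancestral_annotation_is_an_error(self, tiny_panel):
        with pytest.raises(ValueError, match="ancestral"):
            uihs(tiny_panel, 2, "ancestral_derived")


class TestBifurcation:
    def test_identical_carriers_yield_path_graph(self):
        alleles = np.tile([1, 0, 1, 0], (3, 1)).astype(np.uint8)
        panel = make_panel(alleles)
        tree = bifurcation_tree(panel, 1, 0, max_steps=2)
        node = tree.right
        while node.children:
            assert len(node.children) == 1
            node = node.children[0]
        assert leaf_weights(tree.right) == [3]

    def test_divergent_pair_branches_into_two_unit_children(self):
        panel = make_panel([[1, 0], [1, 1], [0, 0]])
        tree = bifurcation_tree(panel, 0, 1, max_steps=1)
        weights = sorted(ch.weight for ch in tree.right.children)
        assert weights == [1, 1]

    def test_leaf_weights_conserve_carrier_count(self, rng):
        for _ in range(10):
            panel = random_micro_panel(rng)
            core = int(rng.integers(panel.n_snps))
            for allele in (0, 1):
                carriers = int((panel.alleles[:, core] == allele).sum())
                if carriers == 0:
                    continue
                tree = bifurcation_tree(panel, core, allele, max_steps=3)
                assert sum(leaf_weights(tree.left)) == carriers
                assert sum(leaf_weights(tree.right)) == carriers
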