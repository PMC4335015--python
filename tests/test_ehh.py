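import itertools

import numpy as np
import pytest

import sweepwatch as sw
from sweepwatch.ehh import bifurcation_tree, ehh_at, ehh_curve
from sweepwatch.hapio import CoreVariant
from conftest import make_matrix, random_matrix


def ehh_bruteforce(hap, core, allele_class, target_pos):
    """Independent oracle: enumerate all pairs, compare allele strings."""
    j_core = hap.site_index(core.chrom, core.pos)
    j_tgt = hap.site_index(core.chrom, target_pos)
    lo, hi = min(j_core, j_tgt), max(j_core, j_tgt)
    rows = [
        i for i in range(hap.n_chrom)
        if (hap.data[i, j_core] == core.derived_allele_code)
        == (allele_class == "derived")
    ]
    same = 0
    pairs = list(itertools.combinations(rows, 2))
    for a, b in pairs:
        if all(hap.data[a, j] == hap.data[b, j] for j in range(lo, hi + 1)):
            same += 1
    return same / len(pairs)


class TestEhhAt:
    def core(self, pos=100):
        return CoreVariant("chr1", pos, 1, "recessive")

    def test_at_core_is_one(self):
        hap = make_matrix(["100", "110", "101", "000"])
        assert ehh_at(hap, self.core(), "derived", 100) == 1.0

    def test_four_chromosomes_one_shared_pair(self):
        # extended haplotypes {A, A, B, C} -> 1 identical pair of 6
        hap = make_matrix(["1000", "1000", "1010", "1001"])
        assert ehh_at(hap, self.core(), "derived", 400) == pytest.approx(1 / 6)

    def test_all_distinct_is_zero(self):
        hap = make_matrix(["100", "110", "101", "111"])
        assert ehh_at(hap, self.core(), "derived", 300) == 0.0

    def test_class_of_one_raises(self):
        hap = make_matrix(["100", "000", "000"])
        with pytest.raises(ValueError, match="undefined"):
            ehh_at(hap, self.core(), "derived", 300)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(4, 13)), int(rng.integers(3, 20))
        hap = random_matrix(rng, n, m)
        j_core = int(rng.integers(0, m))
        core = CoreVariant("chr1", int(hap.positions[j_core]), 1, "recessive")
        col = hap.data[:, j_core]
        for cls, size in (("derived", (col == 1).sum()),
                          ("ancestral", (col == 0).sum())):
            if size < 2:
                continue
            for j_tgt in range(m):
                tgt = int(hap.positions[j_tgt])
                assert ehh_at(hap, core, cls, tgt) == pytest.approx(
                    ehh_bruteforce(hap, core, cls, tgt), abs=1e-15
                )

    def test_label_swap_at_non_core_site_invariant(self):
        rng = np.random.default_rng(9)
        hap = random_matrix(rng, 8, 10)
        core = CoreVariant("chr1", int(hap.positions[4]), 1, "recessive")
        base = [ehh_at(hap, core, "derived", int(p)) for p in hap.positions]
        flipped = hap.data.copy()
        flipped[:, 7] = 1 - flipped[:, 7]
        hap2 = make_matrix(flipped, positions=hap.positions,
                           ids=list(hap.chrom_ids))
        swapped = [ehh_at(hap2, core, "derived", int(p)) for p in hap.positions]
        assert swapped == pytest.approx(base)


class TestEhhCurve:
    def test_monotone_non_increasing_and_core_is_one(self):
        rng = np.random.default_rng(2)
        hap = random_matrix(rng, 12, 30)
        core = CoreVariant("chr1", int(hap.positions[15]), 1, "recessive")
        if not 2 <= hap.data[:, 15].sum() <= 10:
            pytest.skip("unbalanced core draw")
        up, down = ehh_curve(hap, core)
        for curve in (up, down):
            for col in ("ehh_derived", "ehh_ancestral"):
                vals = curve.points[col].to_numpy()
                assert vals[0] == 1.0
                assert np.all(np.diff(vals) <= 1e-12)

    def test_no_recombination_no_mutation_derived_ehh_is_one(self):
        p = sw.SweepSimParams(seed=8, rG=0.0, muG=0.0, n_anc=10, n_der=10,
                              n_sites=60, L=50_000, core_pos=25_000)
        anc = sw.simulate_ancestral_panel(p)
        der, _ = sw.simulate_sweep_class(p, anc)
        merged = sw.merge_panels(anc, der)
        core = CoreVariant("chr1", p.core_pos, 1, "recessive")
        up, down = ehh_curve(merged, core)
        for curve in (up, down):
            assert np.all(curve.points["ehh_derived"].to_numpy() == 1.0)

    def test_rel_ehh_undefined_when_ancestral_zero(self):
        # ancestral class fully distinct beyond first flanking site
        hap = make_matrix(
            ["1000", "1000", "0010", "0001", "0111"],
            positions=[100, 200, 300, 400],
        )
        core = CoreVariant("chr1", 100, 1, "recessive")
        _, down = ehh_curve(hap, core)
        pts = down.points
        assert np.isnan(
            pts.loc[pts["ehh_ancestral"] == 0, "rel_ehh"]
        ).all()
        assert down.truncated_at is not None


class TestBifurcationTree:
    def test_identical_chromosomes_give_path_graph(self):
        hap = make_matrix(["1010"] * 4)
        core = CoreVariant("chr1", 100, 1, "recessive")
        tree = bifurcation_tree(hap, core, "derived", "downstream")
        node, depth = tree.root, 0
        while node.children:
            assert len(node.children) == 1
            assert node.count == 4
            node = next(iter(node.children.values()))
            depth += 1
        assert node.count == 4 and depth == 3

    def test_hand_enumerated_splits(self):
        # haplotypes {00, 01, 11} rightward of the core
        hap = make_matrix(["100", "100", "101", "111"])
        core = CoreVariant("chr1", 100, 1, "recessive")
        tree = bifurcation_tree(hap, core, "derived", "downstream")
        assert tree.root.count == 4
        first = tree.root.children
        assert first[0].count == 3 and first[1].count == 1
        second0 = first[0].children
        assert second0[0].count == 2 and second0[1].count == 1
        assert first[1].children[1].count == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_counts_conserved_at_every_level(self, seed):
        rng = np.random.default_rng(seed)
        hap = random_matrix(rng, 10, 15)
        core = CoreVariant("chr1", int(hap.positions[7]), 1, "recessive")
        for cls in ("derived", "ancestral"):
            n = int((hap.data[:, 7] == (cls == "derived")).sum())
            if n == 0:
                continue
            for direction in ("upstream", "downstream"):
                tree = bifurcation_tree(hap, core, cls, direction)
                for level in tree.levels():
                    assert sum(node.count for node in level) == n
                for node in [x for lvl in tree.levels() for x in lvl]:
                    if node.children:
                        assert node.count == sum(
                            c.count for c in node.children.values()
                        )

    def test_tree_ehh_matches_curve(self):
        """EHH recomputed from bifurcation node counts equals ehh_curve."""
        rng = np.random.default_rng(5)
        hap = random_matrix(rng, 12, 20)
        core = CoreVariant("chr1", int(hap.positions[10]), 1, "recessive")
        col = hap.data[:, 10]
        if (col == 1).sum() < 2 or (col == 0).sum() < 2:
            pytest.skip("unbalanced core draw")
        up, down = ehh_curve(hap, core)
        for cls, ehh_col in (("derived", "ehh_derived"),
                             ("ancestral", "ehh_ancestral")):
            for direction, curve in (("upstream", up), ("downstream", down)):
                tree = bifurcation_tree(hap, core, cls, direction)
                from_tree = tree.ehh_by_depth()
                from_curve = curve.points[ehh_col].tolist()
                assert from_tree == pytest.approx(from_curve)

    def test_max_sites_caps_depth(self):
        hap = make_matrix(["10101", "10011", "11100", "10110"])
        core = CoreVariant("chr1", 100, 1, "recessive")
        tree = bifurcation_tree(hap, core, "derived", "downstream", max_sites=2)
        assert len(tree.levels()) == 3  # root + 2 site levels
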