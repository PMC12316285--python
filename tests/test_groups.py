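import numpy as np
import pytest

from pulhaplo.groups import (
    GeneGroupAssignment,
    assign_gene_group,
    bootstrap_supports,
    build_nj,
    call_haplotype,
    nj_from_sequences,
    p_distance_matrix,
    scan_breakpoint,
)
from pulhaplo.reference import GENE_ROLES

from _oracles import parent_likelihood_breakpoint, random_additive_tree

GENES = [g[0] for g in GENE_ROLES]


def _assign(gene_id, group):
    return GeneGroupAssignment(gene_id, group, 99.0, 5.0)


class TestAssignGeneGroup:
    def test_representative_maps_to_own_group(self, profiles):
        for g in ("GI", "GII", "GIII"):
            a = assign_gene_group(profiles[g].nt["bacple_01703"],
                                  "bacple_01703", profiles)
            assert a.best_group == g
            assert a.identity_to_best == pytest.approx(100.0)
            assert a.margin > 0

    def test_giii_band_gene_assigned_giii(self, base_ref, profiles, group_refs):
        seq = group_refs["GIII"].gene("bacple_01705").nt_seq
        a = assign_gene_group(seq, "bacple_01705", profiles)
        assert a.best_group == "GIII"
        base_identity = assign_gene_group(
            seq, "bacple_01705", {"GI": profiles["GI"]}).identity_to_best
        assert 92.0 - 8 <= base_identity <= 98.0 + 2  # nt identity near aa band

    def test_equidistant_sequence_is_tied(self, profiles):
        """A sequence exactly midway between GI and GII reps is unassigned."""
        gi = profiles["GI"].nt["bacple_01703"]
        gii = profiles["GII"].nt["bacple_01703"]
        diff = [i for i in range(len(gi)) if gi[i] != gii[i]]
        half = diff[: len(diff) // 2]
        mid = "".join(gii[i] if i in set(half) else gi[i] for i in range(len(gi)))
        only = {"GI": profiles["GI"], "GII": profiles["GII"]}
        a = assign_gene_group(mid, "bacple_01703", only)
        if len(diff) % 2 == 0:
            assert a.best_group is None and a.margin == pytest.approx(0.0)

    def test_divergent_sequence_unassigned(self, profiles, rng):
        junk = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1122)])
        a = assign_gene_group(junk, "bacple_01703", profiles)
        assert a.best_group is None


class TestCallHaplotype:
    def test_concordant_genes_single_group(self):
        call = call_haplotype({"c1": [_assign(g, "GI") for g in GENES]})
        assert call.groups == frozenset({"GI"})
        assert not call.recombinant

    def test_giiirec_mosaic_pattern(self):
        labels = ["GIII", "GIII", "GIII", "GI", "GI", "GI"]
        call = call_haplotype({"c1": [_assign(g, l) for g, l in zip(GENES, labels)]})
        assert call.groups == frozenset({"GIIIrec"})
        assert call.recombinant

    def test_mosaic_with_unassigned_gh16(self):
        assigns = [_assign(GENES[0], "GIII"), _assign(GENES[1], "GIII"),
                   GeneGroupAssignment(GENES[2], None, 96.0, 0.1),
                   _assign(GENES[3], "GI"), _assign(GENES[4], "GI"),
                   _assign(GENES[5], "GI")]
        call = call_haplotype({"c1": assigns})
        assert call.groups == frozenset({"GIIIrec"})

    def test_gii_gi_mosaic_is_outgroup_gi_recombinant(self):
        labels = ["GII", "GII", "GII", "GI", "GI", "GI"]
        call = call_haplotype({"c1": [_assign(g, l) for g, l in zip(GENES, labels)]})
        assert call.groups == frozenset({"GIrec"})
        assert call.recombinant

    def test_two_single_group_contigs_give_multi_group(self):
        call = call_haplotype({
            "c1": [_assign(g, "GI") for g in GENES],
            "c2": [_assign(g, "GII") for g in GENES],
        })
        assert call.groups == frozenset({"GI", "GII"})
        assert not call.recombinant

    def test_fragmented_single_locus_reassembled(self):
        """One locus split over two contigs is labelled as a whole, not as
        multi-group."""
        call = call_haplotype({
            "c1": [_assign(g, "GIII") for g in GENES[:2]],
            "c2": [_assign(g, "GI") for g in GENES[3:]],
        }, complete=False)
        assert call.groups == frozenset({"GIIIrec"})

    def test_partial_locus_majority_with_flag(self):
        call = call_haplotype({"c1": [_assign(g, "GI") for g in GENES[:3]]},
                              complete=False)
        assert call.groups == frozenset({"GI"})
        assert call.partial

    def test_nothing_assignable_is_outgroup(self):
        call = call_haplotype(
            {"c1": [GeneGroupAssignment(g, None, 50.0, 0.0) for g in GENES]})
        assert call.groups == frozenset({"outgroup"})

    def test_empty_assignments_rejected(self):
        with pytest.raises(ValueError):
            call_haplotype({})


class TestScanBreakpoint:
    def _parents(self, rng, n=1122, divergence=0.08):
        pa = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        pb = list(pa)
        for pos in rng.choice(n, size=int(n * divergence), replace=False):
            pb[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[pb[pos]]
        return pa, "".join(pb)

    def test_pure_parent_has_no_breakpoint(self, rng):
        pa, pb = self._parents(rng)
        intervals, multi = scan_breakpoint(pa, pa, pb)
        assert intervals == [] and not multi

    def test_chimera_interval_contains_crossover(self, rng):
        pa, pb = self._parents(rng)
        bp = 500
        chim = pa[:bp] + pb[bp:]
        intervals, multi = scan_breakpoint(chim, pa, pb, window=60, step=3)
        assert len(intervals) == 1 and not multi
        lo, hi = intervals[0]
        assert lo <= bp <= hi

    def test_interval_agrees_with_likelihood_oracle(self, rng):
        """The window-scan interval contains the brute-force maximum-
        likelihood crossover position."""
        for _ in range(20):
            pa, pb = self._parents(rng)
            bp = int(rng.integers(150, 950))
            chim = pa[:bp] + pb[bp:]
            intervals, _ = scan_breakpoint(chim, pa, pb, window=60, step=3)
            est = parent_likelihood_breakpoint(chim, pa, pb)
            assert intervals
            assert any(lo <= est <= hi for lo, hi in intervals)

    def test_identical_parents_unidentifiable(self, rng):
        pa, _ = self._parents(rng)
        intervals, _ = scan_breakpoint(pa, pa, pa)
        assert intervals == []

    def test_double_crossover_flagged(self, rng):
        pa, pb = self._parents(rng)
        chim = pa[:300] + pb[300:700] + pa[700:]
        intervals, multi = scan_breakpoint(chim, pa, pb, window=60, step=3)
        assert multi and len(intervals) == 2

    def test_input_validation(self, rng):
        pa, pb = self._parents(rng)
        with pytest.raises(ValueError):
            scan_breakpoint(pa[:-3], pa, pb)
        with pytest.raises(ValueError):
            scan_breakpoint(pa, pa, pb, window=10)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        labels = ["a", "b", "c"]
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = build_nj(labels, d)
        tips, mat = tree.tip_distances()
        assert np.allclose(mat, d)
        # closed-form pendant lengths: a=2, b=3, c=7
        lengths = sorted(bl for _, bl in tree.root.children)
        assert lengths == pytest.approx([2.0, 3.0, 7.0])

    def test_additive_five_taxon_exact_recovery(self, rng):
        labels, d = random_additive_tree(5, rng)
        tree = build_nj(labels, d)
        tips, mat = tree.tip_distances()
        order = [tips.index(l) for l in labels]
        assert np.allclose(mat[np.ix_(order, order)][np.argsort(order)][:, np.argsort(order)],
                           mat[np.ix_(order, order)][np.argsort(order)][:, np.argsort(order)])
        sub = np.array([[mat[tips.index(x), tips.index(y)] for y in labels]
                        for x in labels])
        assert np.allclose(sub, d, atol=1e-9)

    def test_matches_independent_nj_implementation(self, rng):
        """Topology agrees with scikit-bio's neighbor joining on a random
        (noisy, non-additive) matrix."""
        skbio = pytest.importorskip("skbio")
        from io import StringIO
        n = 8
        labels, d = random_additive_tree(n, rng)
        d = d + rng.uniform(0, 0.02, size=d.shape)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        mine = build_nj(labels, d)
        dm = skbio.DistanceMatrix(d, ids=labels)
        theirs = skbio.tree.nj(dm)
        their_bips = set()
        for node in theirs.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < n - 1:
                anchor = min(labels)
                side = tips if anchor not in tips else frozenset(labels) - tips
                their_bips.add(side)
        assert mine.bipartitions() == their_bips

    def test_non_symmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3.1, 0]])
        with pytest.raises(ValueError):
            build_nj(["a", "b", "c"], d)

    def test_group_concatenates_form_clades(self, group_refs):
        """NJ on synthetic GI/GII/GIII concatenated proteins separates the
        three groups into clades."""
        seqs = {}
        rng = np.random.default_rng(3)
        for g in ("GI", "GII", "GIII"):
            aa = group_refs[g].concat_aa()
            for k in range(3):
                s = list(aa)
                for pos in rng.choice(len(s), size=5, replace=False):
                    s[pos] = "A" if s[pos] != "A" else "G"
                seqs[f"{g}_{k}"] = "".join(s)
        tree = nj_from_sequences(seqs)
        for g in ("GI", "GII", "GIII"):
            clade = frozenset(f"{g}_{k}" for k in range(3))
            assert tree.contains_split(clade), f"{g} not monophyletic"

    def test_p_distance_axioms(self, group_refs):
        seqs = {g: group_refs[g].concat_aa() for g in ("GI", "GII", "GIII")}
        labels, d = p_distance_matrix(seqs)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all(d[~np.eye(len(labels), dtype=bool)] > 0)


class TestBootstrap:
    def test_well_separated_groups_high_support(self, group_refs):
        rng = np.random.default_rng(5)
        seqs = {}
        for g in ("GI", "GII", "GIII"):
            aa = group_refs[g].concat_aa()
            for k in range(3):
                s = list(aa)
                for pos in rng.choice(len(s), size=4, replace=False):
                    s[pos] = "W"
                seqs[f"{g}_{k}"] = "".join(s)
        supports = bootstrap_supports(seqs, n_reps=50, seed=1)
        labels = frozenset(seqs)
        anchor = min(seqs)
        for g in ("GI", "GII", "GIII"):
            clade = frozenset(f"{g}_{k}" for k in range(3))
            canon = clade if anchor not in clade else labels - clade
            assert supports.get(canon, 0) >= 0.95

    def test_identical_sequences_trivially_supported(self, group_refs):
        seqs = {f"t{k}": "MKLVNNAQ" * 10 for k in range(5)}
        supports = bootstrap_supports(seqs, n_reps=5, seed=2)
        assert all(v == 1.0 for v in supports.values())
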