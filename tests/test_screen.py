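import numpy as np
import pytest

from pulhaplo.reference import revcomp
from pulhaplo.screen import (
    DetectionHit,
    collapse_redundant,
    protein_qc,
    screen_locus,
)


def _random_dna(n, rng):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def _exact_hit(gene):
    return DetectionHit("c0", gene.gene_id, 100.0, 100.0, "+", 0, len(gene),
                        gene.nt_seq, 0, len(gene), False)


class TestScreenLocus:
    def test_exact_locus_is_complete(self, base_ref, rng):
        contig = _random_dna(500, rng) + base_ref.seq + _random_dna(500, rng)
        call = screen_locus({"c1": contig}, base_ref, "gene_strict")
        assert call.complete and call.positive
        assert len(call.genes_present) == 6
        for h in call.hits:
            assert h.identity == pytest.approx(100.0)
            assert h.coverage == pytest.approx(100.0)

    def test_empty_contigs_negative(self, base_ref):
        call = screen_locus({}, base_ref, "gene_strict")
        assert not call.positive and not call.complete

    def test_identity_threshold_is_inclusive_boundary(self, base_ref, rng):
        """A gene just below 80% identity fails gene_strict but the sample
        stays positive in locus_scan through the other genes."""
        gh16 = base_ref.gh16
        n = len(gh16.nt_seq)
        n_sub = int(np.ceil(n * 0.201))  # 79.9% identity
        bad = _mutate(gh16.nt_seq, rng.choice(n, size=n_sub, replace=False))
        contig = base_ref.seq[: gh16.start] + bad + base_ref.seq[gh16.end :]
        strict = screen_locus({"c1": contig}, base_ref, "gene_strict")
        assert not strict.complete
        assert "bacple_01703" not in strict.genes_present
        scan = screen_locus({"c1": contig}, base_ref, "locus_scan")
        assert scan.positive

    def test_low_coverage_excluded_only_in_gene_strict(self, base_ref, rng):
        """A gene present at 90% coverage, full identity: dropped by the
        strict screen, kept by the permissive locus scan."""
        gh16 = base_ref.gh16
        partial = gh16.nt_seq[: int(len(gh16.nt_seq) * 0.9)]
        contig = _random_dna(300, rng) + partial + _random_dna(300, rng)
        strict = screen_locus({"c1": contig}, base_ref, "gene_strict")
        assert "bacple_01703" not in strict.genes_present
        assert any(r == "below_threshold" for g, r in strict.qc_failures
                   if g == "bacple_01703")
        scan = screen_locus({"c1": contig}, base_ref, "locus_scan")
        assert scan.positive
        assert "bacple_01703" in scan.genes_present

    def test_strand_symmetry(self, base_ref, rng):
        contig = _random_dna(200, rng) + base_ref.seq + _random_dna(200, rng)
        fwd = screen_locus({"c1": contig}, base_ref, "gene_strict")
        rev = screen_locus({"c1": revcomp(contig)}, base_ref, "gene_strict")
        assert fwd.complete and rev.complete
        f = {h.gene_id: h for h in fwd.hits}
        r = {h.gene_id: h for h in rev.hits}
        for gid in f:
            assert f[gid].identity == pytest.approx(r[gid].identity)
            assert f[gid].coverage == pytest.approx(r[gid].coverage)
            assert f[gid].strand != r[gid].strand

    def test_strict_positives_subset_of_scan_positives(self, base_ref, group_refs, rng):
        """gene_strict positivity implies locus_scan positivity, and raising
        the identity threshold never adds hits."""
        for ref in (base_ref, group_refs["GIII"]):
            contig = _random_dna(100, rng) + ref.seq + _random_dna(100, rng)
            strict = screen_locus({"c": contig}, base_ref, "gene_strict")
            scan = screen_locus({"c": contig}, base_ref, "locus_scan")
            if strict.positive:
                assert scan.positive
            loose = screen_locus({"c": contig}, base_ref, "locus_scan",
                                 identity_min=70.0)
            assert scan.genes_present <= loose.genes_present

    def test_multi_contig_jointly_complete(self, base_ref, rng):
        """Genes split across contigs (fragmented MAG) still complete the
        sample-level locus."""
        mid = base_ref.genes[2].end + 10
        contigs = {"c1": base_ref.seq[:mid], "c2": base_ref.seq[mid:]}
        call = screen_locus(contigs, base_ref, "gene_strict")
        assert call.complete

    def test_seeded_path_matches_exhaustive(self, base_ref, rng):
        """The k-mer seeded screen and the exhaustive DP screen agree on a
        diverged locus embedded in background."""
        mutated = _mutate(base_ref.seq,
                          rng.choice(len(base_ref.seq),
                                     size=len(base_ref.seq) // 25, replace=False))
        contig = _random_dna(400, rng) + mutated + _random_dna(400, rng)
        seeded = screen_locus({"c": contig}, base_ref, "gene_strict", exhaustive=False)
        exact = screen_locus({"c": contig}, base_ref, "gene_strict", exhaustive=True)
        assert seeded.complete == exact.complete
        s = {h.gene_id: h for h in seeded.hits}
        e = {h.gene_id: h for h in exact.hits}
        assert set(s) == set(e)
        for gid in s:
            assert s[gid].identity == pytest.approx(e[gid].identity, abs=0.2)


class TestProteinQC:
    def test_exact_gene_passes(self, base_ref):
        g = base_ref.gh16
        ok, reason = protein_qc(_exact_hit(g), g)
        assert ok and reason == "ok"

    def test_internal_stop_fails(self, base_ref):
        g = base_ref.gh16
        mid = (len(g.nt_seq) // 6) * 3
        nt = g.nt_seq[:mid] + "TAA" + g.nt_seq[mid + 3:]
        hit = DetectionHit("c0", g.gene_id, 99.9, 100.0, "+", 0, len(nt), nt,
                           0, len(nt), False)
        ok, reason = protein_qc(hit, g)
        assert not ok and reason == "internal_stop"

    def test_truncated_protein_fails(self, base_ref):
        g = base_ref.gh16
        frac = int(len(g.nt_seq) * 0.6) // 3 * 3
        nt = g.nt_seq[len(g.nt_seq) - frac:]  # 5'-truncated at 60% length
        qs = len(g.nt_seq) - frac
        hit = DetectionHit("c0", g.gene_id, 100.0, 60.0, "+", 0, len(nt), nt,
                           qs, len(g.nt_seq), False)
        ok, reason = protein_qc(hit, g)
        assert not ok and reason == "truncated"

    def test_indel_alignment_fails_as_frameshift(self, base_ref):
        g = base_ref.gh16
        hit = DetectionHit("c0", g.gene_id, 99.0, 100.0, "+", 0, len(g.nt_seq),
                           g.nt_seq, 0, len(g.nt_seq), True)
        ok, reason = protein_qc(hit, g)
        assert not ok and reason == "frameshift"

    def test_off_frame_start_translated_in_inferred_frame(self, base_ref):
        g = base_ref.gh16
        nt = g.nt_seq[1:]  # alignment starts at gene position 1
        hit = DetectionHit("c0", g.gene_id, 100.0, 99.9, "+", 0, len(nt), nt,
                           1, len(g.nt_seq), False)
        ok, reason = protein_qc(hit, g)
        assert ok, reason


class TestCollapseRedundant:
    def test_within_species_duplicates_collapse(self):
        entries = [("sp1", "AAA"), ("sp1", "AAA"), ("sp1", "AAA")]
        assert len(collapse_redundant(entries)) == 1

    def test_cross_species_duplicates_retained(self):
        entries = [("sp1", "AAA"), ("sp2", "AAA")]
        assert len(collapse_redundant(entries)) == 2

    def test_large_constructed_set_collapses_to_expected_count(self, rng):
        """245 entries built with 115 within-species duplicates reduce to 130
        non-redundant ones."""
        entries = []
        uniq = 0
        while uniq < 130:
            sp = f"sp{uniq % 40}"
            seq = _random_dna(60, rng)
            entries.append((sp, seq))
            uniq += 1
        dup_src = entries[:115]
        entries = entries + [d for d in dup_src]
        assert len(entries) == 245
        rng.shuffle(entries)
        assert len(collapse_redundant(entries)) == 130
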