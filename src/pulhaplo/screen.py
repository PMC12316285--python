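"""Assembly screening for PUL-PorB under the two survey regimes.

``locus_scan`` mirrors the permissive isolate survey: a sample is positive on
any hit at >=80% identity to PUL-PorB sequence, partial hits included, with no
coverage filter.  ``gene_strict`` mirrors the MAG survey: every one of the six
genes must be recovered at >=80% identity AND >=95% query coverage, and the
translated hits must pass protein QC (no internal stop, not truncated) for the
locus to count as complete.

Large contigs are screened by exact k-mer seeding followed by a gapless
comparison at the seeded offset; an edit-distance check (edlib) detects
indel-containing candidates, which are re-aligned with the full local DP of
:mod:`pulhaplo.align`.  Small inputs are aligned exhaustively.  A minimum
local-alignment score (default 40) stands in for BLAST's E-value cutoff so
that spurious short perfect matches in random sequence do not count as hits.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from pulhaplo.align import align_identity, hamming_identity, MATCH, MISMATCH
from pulhaplo.reference import GeneModel, LocusReference, revcomp, translate

SEED_K = 13
MIN_SCORE = 40.0          # E-value stand-in: reject sub-threshold local hits
GAP_DECISIVE = -4.0       # gapped alignment must beat gapless by > 2 gaps' cost
EXHAUSTIVE_CELLS = 4_000_000  # contig*query size below which full DP is used

WHOLE_LOCUS_ID = "whole_locus"


@dataclass(frozen=True)
class DetectionHit:
    """Best alignment of one query gene on one contig.

    ``aligned_nt_seq`` is reported in gene orientation (reverse-complemented
    for '-' strand hits) and ``query_start``/``query_end`` are gene
    coordinates, so the hit can be translated in the gene's frame directly.
    """

    contig_id: str
    gene_id: str
    identity: float
    coverage: float
    strand: str
    contig_start: int
    contig_end: int
    aligned_nt_seq: str
    query_start: int = 0
    query_end: int = 0
    has_indels: bool = False


@dataclass
class LocusCall:
    sample_id: str
    genes_present: set[str]
    complete: bool
    positive: bool
    hits: list[DetectionHit] = field(default_factory=list)
    qc_failures: list[tuple[str, str]] = field(default_factory=list)
    ambiguous_partial: bool = False


# --------------------------------------------------------------------------
# candidate generation (seed + gapless fast path, DP fallback)


def _seed_index(queries: dict[str, str]) -> dict[str, list[tuple[str, int, str]]]:
    idx: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
    for qid, seq in queries.items():
        rc = revcomp(seq)
        for i in range(len(seq) - SEED_K + 1):
            idx[seq[i : i + SEED_K]].append((qid, i, "+"))
            idx[rc[i : i + SEED_K]].append((qid, i, "-"))
    return idx


def _candidate_offsets(contig: str, idx) -> dict[tuple[str, str], dict[int, int]]:
    """Map (query_id, strand) -> {implied offset: seed count}."""
    cand: dict[tuple[str, str], dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for p in range(len(contig) - SEED_K + 1):
        hits = idx.get(contig[p : p + SEED_K])
        if not hits:
            continue
        for qid, qpos, strand in hits:
            cand[(qid, strand)][p - qpos] += 1
    return cand


def _best_gapless_segment(q_sub: str, window: str) -> tuple[int, int, int, float]:
    """Maximum-scoring run of the fixed-diagonal comparison (gapless local
    alignment): returns (start, end, matches, score) in overlap coordinates."""
    x = np.frombuffer(q_sub.encode(), dtype=np.uint8)
    y = np.frombuffer(window.encode(), dtype=np.uint8)
    eq = (x == y) & (x != ord("N")) & (y != ord("N"))
    s = np.where(eq, MATCH, MISMATCH)
    cum = np.concatenate([[0.0], np.cumsum(s)])
    runmin = np.minimum.accumulate(cum[:-1])
    gains = cum[1:] - runmin
    j = int(np.argmax(gains))
    i = int(np.argmin(cum[: j + 1]))
    matches = int(eq[i : j + 1].sum())
    return i, j + 1, matches, float(gains[j])


def _evaluate_candidate(contig: str, contig_id: str, query: str, qid: str,
                        strand: str, offset: int) -> DetectionHit | None:
    """Gapless comparison at a seeded offset, with DP fallback on indels."""
    q = query if strand == "+" else revcomp(query)
    L = len(q)
    ts = max(offset, 0)
    te = min(offset + L, len(contig))
    if te - ts < SEED_K:
        return None
    q_sub = q[ts - offset : te - offset]
    window = contig[ts:te]
    seg_s, seg_e, matches, score = _best_gapless_segment(q_sub, window)
    seg_len = seg_e - seg_s
    if seg_len < SEED_K or score < MIN_SCORE:
        return None
    mism = seg_len - matches
    margin = max(20, L // 10)
    ws = max(ts + seg_s - margin, 0)
    we = min(ts + seg_e + margin, len(contig))
    ed = edlib.align(q_sub[seg_s:seg_e], contig[ws:we], mode="HW",
                     task="distance")["editDistance"]
    if ed < 0:
        ed = mism
    ident = 100.0 * matches / seg_len
    a, b = ts + seg_s, ts + seg_e       # contig coordinates of the segment
    if strand == "+":
        qs, qe = a - offset, b - offset
        aligned = contig[a:b]
    else:
        qs, qe = L - (b - offset), L - (a - offset)
        aligned = revcomp(contig[a:b])
    gapless = DetectionHit(contig_id, qid, ident, 100.0 * seg_len / L,
                           strand, a, b, aligned, qs, qe, False)
    if ed + 1 >= mism:
        return gapless
    # Indels might help: run the full local DP, but keep the frame-preserving
    # gapless interpretation unless the gapped alignment is decisively better
    # (a genuine indel dwarfs the gapless score; marginal rearrangements of a
    # few mismatches around repeats do not justify calling a frameshift).
    res = align_identity(query, contig[ws:we])
    if res is not None and res.score > score + 2 * abs(GAP_DECISIVE):
        if res.score < MIN_SCORE:
            return None
        return _hit_from_alignment(res, contig, contig_id, query, qid, shift=ws)
    return gapless


def _hit_from_alignment(res, contig: str, contig_id: str, query: str, qid: str,
                        shift: int = 0) -> DetectionHit:
    ts, te = res.target_start + shift, res.target_end + shift
    aligned = contig[ts:te]
    if res.strand == "-":
        aligned = revcomp(aligned)
        qs = len(query) - res.query_end
        qe = len(query) - res.query_start
    else:
        qs, qe = res.query_start, res.query_end
    return DetectionHit(contig_id, qid, res.identity, res.coverage, res.strand,
                        ts, te, aligned, qs, qe, res.n_gap_columns > 0)


def _best_hits(contigs: dict[str, str], queries: dict[str, str],
               exhaustive: bool | None) -> dict[str, list[DetectionHit]]:
    """All candidate hits per query over all contigs."""
    hits: dict[str, list[DetectionHit]] = defaultdict(list)
    total = sum(len(c) for c in contigs.values())
    qmax = max((len(q) for q in queries.values()), default=0)
    if exhaustive is None:
        exhaustive = total * qmax <= EXHAUSTIVE_CELLS
    if exhaustive:
        for cid, contig in contigs.items():
            if not contig:
                continue
            for qid, q in queries.items():
                res = align_identity(q, contig)
                if res is not None and res.score >= MIN_SCORE:
                    hits[qid].append(_hit_from_alignment(res, contig, cid, q, qid))
        return hits
    idx = _seed_index(queries)
    for cid, contig in contigs.items():
        if len(contig) < SEED_K:
            continue
        cand = _candidate_offsets(contig, idx)
        for (qid, strand), offsets in cand.items():
            # cluster nearby offsets; evaluate each cluster once
            seen: list[int] = []
            for off in sorted(offsets, key=lambda o: (-offsets[o], o)):
                if any(abs(off - s) <= len(queries[qid]) // 2 for s in seen):
                    continue
                if offsets[off] < 2 and len(offsets) > 4:
                    continue  # lone random collision among many
                seen.append(off)
                h = _evaluate_candidate(contig, cid, queries[qid], qid, strand, off)
                if h is not None:
                    hits[qid].append(h)
    return hits


def _select_best(candidates: list[DetectionHit]) -> DetectionHit:
    # max identity; ties -> longer coverage, then leftmost
    return sorted(candidates,
                  key=lambda h: (-h.identity, -h.coverage, h.contig_start))[0]


# --------------------------------------------------------------------------
# public operations


def screen_locus(contigs: dict[str, str], locus: LocusReference,
                 mode: str = "gene_strict", *, identity_min: float = 80.0,
                 coverage_min: float = 95.0, truncation_frac: float = 0.95,
                 sample_id: str = "sample",
                 exhaustive: bool | None = None) -> LocusCall:
    """Screen a sample's contigs against the locus model.

    ``locus_scan``: positive on >=1 hit at ``identity_min`` to any PUL-PorB
    sequence (per-gene or whole-locus query), no coverage filter.
    ``gene_strict``: every gene needed at ``identity_min`` identity and
    ``coverage_min`` coverage; completeness additionally requires protein QC.
    An empty contig set yields a negative call.
    """
    if mode not in ("locus_scan", "gene_strict"):
        raise ValueError(f"unknown mode {mode!r}")
    queries = {g.gene_id: g.nt_seq for g in locus.genes}
    if mode == "locus_scan":
        queries[WHOLE_LOCUS_ID] = locus.seq
    raw = _best_hits(contigs, queries, exhaustive)
    best: dict[str, DetectionHit] = {
        qid: _select_best(c) for qid, c in raw.items() if c
    }
    gene_ids = [g.gene_id for g in locus.genes]
    call = LocusCall(sample_id, set(), False, False)
    call.hits = [best[g] for g in gene_ids if g in best]
    if WHOLE_LOCUS_ID in best:
        call.hits.append(best[WHOLE_LOCUS_ID])
    if mode == "locus_scan":
        passing = [h for h in call.hits if h.identity >= identity_min]
        call.positive = bool(passing)
        call.genes_present = {h.gene_id for h in passing if h.gene_id != WHOLE_LOCUS_ID}
        min_gene = min(len(g.nt_seq) for g in locus.genes)
        if call.positive and all(
                (h.contig_end - h.contig_start) < min_gene for h in passing):
            call.ambiguous_partial = True
        return call
    # gene_strict
    for g in locus.genes:
        h = best.get(g.gene_id)
        if h is None:
            call.qc_failures.append((g.gene_id, "absent"))
            continue
        if h.identity < identity_min or h.coverage < coverage_min:
            call.qc_failures.append((g.gene_id, "below_threshold"))
            continue
        ok, reason = protein_qc(h, g, truncation_frac=truncation_frac)
        if not ok:
            call.qc_failures.append((g.gene_id, reason))
            continue
        call.genes_present.add(g.gene_id)
    call.complete = call.genes_present == set(gene_ids)
    call.positive = call.complete
    return call


def protein_qc(hit: DetectionHit, gene: GeneModel, *,
               truncation_frac: float = 0.95) -> tuple[bool, str]:
    """Translated-hit quality control.

    Fails on frame-ambiguous (indel-containing) alignments, on internal stop
    codons, and on proteins shorter than ``truncation_frac`` of the reference
    protein.  The frame is inferred from the alignment's start on the gene.
    """
    if hit.has_indels:
        return False, "frameshift"
    lead = (3 - hit.query_start % 3) % 3
    sub = hit.aligned_nt_seq[lead:]
    sub = sub[: len(sub) // 3 * 3]
    if not sub:
        return False, "truncated"
    aa = translate(sub)
    if "*" in aa:
        return False, "internal_stop"
    if len(aa) < truncation_frac * len(gene.aa_seq):
        return False, "truncated"
    return True, "ok"


def collapse_redundant(entries: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Drop within-species duplicates of the concatenated locus sequence.

    ``entries`` are (species_label, concatenated nt sequence) in locus gene
    order; one representative is kept per identical sequence within a species,
    while identical sequences from *different* species are all retained.
    """
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    for species, seq in entries:
        key = (species, seq)
        if key in seen:
            continue
        seen.add(key)
        out.append((species, seq))
    return out
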