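"""BLAST-like local nucleotide alignment: identity/coverage of the best
local alignment of a query gene against a target contig, over both strands.

Identity is computed over the columns of the best local alignment (so partial
hits score their aligned region only) and coverage is the fraction of the
query involved in that alignment — the two quantities every screen in the
package thresholds on.  The dynamic programme itself is Smith-Waterman with
linear gap costs (match +1, mismatch -2, gap -2); ``N`` never matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from pulhaplo.reference import revcomp

# gap strictly costlier than mismatch, so substitution-only alignments are
# never tied (or cheaply beaten) by gapped ones
MATCH, MISMATCH, GAP = 1.0, -2.0, -4.0

_VALID = set("ACGTN")


@dataclass(frozen=True)
class AlignmentResult:
    identity: float          # percent over alignment columns
    coverage: float          # percent of query positions aligned
    target_start: int        # 0-based half-open on the forward target
    target_end: int
    strand: str              # strand of the query match: '+' or '-'
    query_start: int = 0     # on the (possibly reverse-complemented) query
    query_end: int = 0
    aligned_target_seq: str = ""
    n_gap_columns: int = 0
    score: float = 0.0


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            mat[a, b] = MATCH if (a == b and a != "N") else MISMATCH
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = mat
    al.open_gap_score = GAP
    al.extend_gap_score = GAP
    return al


def _clean(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    seq = seq.upper()
    if not set(seq) <= _VALID:
        seq = "".join(c if c in _VALID else "N" for c in seq)
    return seq


def _one_strand(query: str, target: str):
    al = _aligner()
    alns = al.align(query, target)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    qs, qe = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
    ts, te = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])
    identity = 100.0 * counts.identities / columns if columns else 0.0
    coverage = 100.0 * (qe - qs) / len(query)
    return AlignmentResult(identity, coverage, ts, te, "+", qs, qe,
                           target[ts:te], counts.gaps, float(aln.score))


def align_identity(query: str, target: str) -> AlignmentResult | None:
    """Best local alignment of ``query`` (either strand) against ``target``.

    Returns ``None`` when no positive-scoring local alignment exists.  On a
    tie between strands the forward strand wins.  Target coordinates always
    refer to the forward target.
    """
    query = _clean(query, "query")
    target = _clean(target, "target")
    fwd = _one_strand(query, target)
    rev = _one_strand(revcomp(query), target)
    if rev is not None:
        rev = AlignmentResult(rev.identity, rev.coverage, rev.target_start,
                              rev.target_end, "-", rev.query_start, rev.query_end,
                              rev.aligned_target_seq, rev.n_gap_columns, rev.score)
    if fwd is None:
        return rev
    if rev is None or fwd.score >= rev.score:
        return fwd
    return rev


# --------------------------------------------------------------------------
# gapless comparison helper used by the seeded screen fast path


def hamming_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length strings (N matches nothing)."""
    if len(a) != len(b):
        raise ValueError("hamming_identity requires equal lengths")
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    n_mask = (x == ord("N")) | (y == ord("N"))
    matches = int(((x == y) & ~n_mask).sum())
    return 100.0 * matches / len(a) if a else 0.0
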