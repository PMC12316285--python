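"""Haplotype-group assignment, recombination breakpoint scanning and
neighbor-joining phylogenetics for detected PUL-PorB loci.

Groups GI/GII/GIII are defined by per-gene representative sequences; a
detected gene is assigned to the nearest representative by percent identity.
A contig whose upstream genes (sulfatase, GH29) match one group while the
downstream genes (SusD, SusC, GH2) match another is a recombinant: the
GIII->GI mosaic is the GIIIrec clade, the GII->GI mosaic the "outgroup GI"
(GIrec) pattern, in both of which the crossover sits inside GH16 and is
localized by a sliding-window parent-identity scan.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from pulhaplo.align import align_identity, hamming_identity
from pulhaplo.reference import GENE_ROLES, GH16_GENE_ID, LocusReference

GENE_ORDER = tuple(g[0] for g in GENE_ROLES)
UPSTREAM = ("bacple_01701", "bacple_01702")           # sulfatase, GH29
DOWNSTREAM = ("bacple_01704", "bacple_01705", "bacple_01706")  # SusD, SusC, GH2

DEFAULT_TIE_MARGIN = 0.5   # percentage points; below it a gene stays unassigned


@dataclass(frozen=True)
class GroupProfile:
    """Per-gene representative sequences of one haplotype group."""

    group: str
    nt: dict[str, str]   # gene_id -> nt CDS
    aa: dict[str, str]   # gene_id -> protein

    @classmethod
    def from_reference(cls, group: str, ref: LocusReference) -> "GroupProfile":
        return cls(group,
                   {g.gene_id: g.nt_seq for g in ref.genes},
                   {g.gene_id: g.aa_seq for g in ref.genes})


@dataclass(frozen=True)
class GeneGroupAssignment:
    gene_id: str
    best_group: str | None
    identity_to_best: float
    margin: float          # percentage points down to the runner-up


@dataclass
class PULHaplotypeCall:
    sample_id: str
    contig_groups: dict[str, str]        # contig_id -> group label
    groups: frozenset[str]               # sample-level label set
    recombinant: bool
    breakpoint_interval: tuple[int, int] | None = None
    partial: bool = False
    multi_crossover: bool = False


def _identity(a: str, b: str) -> float:
    """Percent identity; gapless when lengths agree, local DP otherwise."""
    if len(a) == len(b):
        return hamming_identity(a, b)
    res = align_identity(a, b)
    return res.identity * res.coverage / 100.0 if res is not None else 0.0


def assign_gene_group(gene_seq: str, gene_id: str,
                      profiles: dict[str, GroupProfile], *,
                      identity_min: float = 80.0,
                      tie_margin: float = DEFAULT_TIE_MARGIN) -> GeneGroupAssignment:
    """Nearest-representative assignment of one detected gene.

    Identity is computed against every group's representative of that gene;
    the argmax wins unless all identities fall below ``identity_min``
    (divergent -> unassigned) or the margin to the runner-up is below
    ``tie_margin`` (tie -> unassigned).
    """
    scores = {g: _identity(gene_seq, p.nt[gene_id]) for g, p in profiles.items()}
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_group, best = ranked[0]
    margin = best - ranked[1][1] if len(ranked) > 1 else 100.0
    if best < identity_min or margin < tie_margin:
        return GeneGroupAssignment(gene_id, None, best, margin)
    return GeneGroupAssignment(gene_id, best_group, best, margin)


def _contig_label(assigned: list[GeneGroupAssignment]) -> tuple[str, bool]:
    """Group label for one contig from its ordered gene assignments.

    Returns (label, is_recombinant).  Two contiguous discordant blocks in
    locus order are a recombinant; the GIII->GI mosaic is 'GIIIrec', the
    GII->GI one 'GIrec'; anything else unresolvable is 'outgroup'.
    """
    order = {g: i for i, g in enumerate(GENE_ORDER)}
    labs = [(order[a.gene_id], a.best_group) for a in assigned
            if a.best_group is not None]
    labs.sort()
    seq = [g for _, g in labs]
    if not seq:
        return "outgroup", False
    distinct = set(seq)
    if len(distinct) == 1:
        return seq[0], False
    # collapse runs; a single switch between two groups = two contiguous blocks
    runs = [k for k, _ in itertools.groupby(seq)]
    if len(runs) == 2:
        first, second = runs
        if (first, second) == ("GIII", "GI"):
            return "GIIIrec", True
        if (first, second) == ("GII", "GI"):
            return "GIrec", True
        return "outgroup", True
    return "outgroup", False


def call_haplotype(contig_assignments: dict[str, list[GeneGroupAssignment]],
                   complete: bool = True,
                   sample_id: str = "sample") -> PULHaplotypeCall:
    """Sample-level haplotype call from per-contig gene assignments.

    Concordant genes give a single group; the recognized mosaic patterns give
    recombinant labels; a partial locus is called by its majority group with
    a ``partial`` flag (which slightly under-calls recombinants, whose
    diagnosis needs genes from both blocks); nothing assignable gives
    'outgroup'; discordant single-group contigs give a multi-group set.
    """
    if not contig_assignments or all(not v for v in contig_assignments.values()):
        raise ValueError("no gene assignments supplied")
    contig_groups: dict[str, str] = {}
    recombinant = False
    n_assigned = 0
    for cid, assigned in contig_assignments.items():
        if not assigned:
            continue
        n_assigned += sum(1 for a in assigned if a.best_group is not None)
        label, rec = _contig_label(assigned)
        contig_groups[cid] = label
        recombinant = recombinant or rec
    labels = set(contig_groups.values()) - {"outgroup"}
    if not labels:
        groups = frozenset({"outgroup"})
    elif recombinant:
        groups = frozenset(labels)
    elif len(labels) > 1:
        # discordant concordant contigs: fragments of one locus whose pieces
        # fall on different contigs, or a true multi-group individual
        joint = _merge_fragmented(contig_assignments)
        groups = frozenset({joint}) if joint else frozenset(labels)
        if joint in ("GIIIrec", "GIrec"):
            recombinant = True
    else:
        groups = frozenset(labels)
    partial = not complete and n_assigned < len(GENE_ORDER)
    return PULHaplotypeCall(sample_id, contig_groups, groups, recombinant,
                            partial=partial)


def _merge_fragmented(contig_assignments) -> str | None:
    """If each gene appears once across contigs, interpret the union as one
    fragmented locus and label it as a whole."""
    merged: dict[str, GeneGroupAssignment] = {}
    for assigned in contig_assignments.values():
        for a in assigned:
            if a.gene_id in merged:
                return None  # genuinely multiple loci
            merged[a.gene_id] = a
    label, _ = _contig_label(list(merged.values()))
    return label


# --------------------------------------------------------------------------
# recombination breakpoint scanning


def scan_breakpoint(gh16_seq: str, parent_a: str, parent_b: str, *,
                    window: int = 60, step: int = 3,
                    ) -> tuple[list[tuple[int, int]], bool]:
    """Localize crossovers in a (putatively chimeric) GH16 sequence.

    Along a fixed end-to-end comparison, each ``window``-nt window is scored
    against both parents; a crossover interval spans from the start of the
    last window where parent A is strictly closer to the end of the first
    window where parent B is strictly closer (an interval, never a point — it
    is guaranteed to contain the true crossover when the parents diverge on
    both sides).  Returns ``(intervals, multi_crossover)``; no switch gives
    ``([], False)``.
    """
    if window < 30:
        raise ValueError("window must be >= 30")
    if not (len(gh16_seq) == len(parent_a) == len(parent_b)):
        raise ValueError("scan_breakpoint requires end-to-end alignable "
                         "(equal-length) sequences")
    n = len(gh16_seq)
    if n < window:
        return [], False
    x = np.frombuffer(gh16_seq.encode(), dtype=np.uint8)
    a = np.frombuffer(parent_a.encode(), dtype=np.uint8)
    b = np.frombuffer(parent_b.encode(), dtype=np.uint8)
    ma = (x == a).astype(np.int32)
    mb = (x == b).astype(np.int32)
    ca = np.concatenate([[0], np.cumsum(ma)])
    cb = np.concatenate([[0], np.cumsum(mb)])
    offsets = list(range(0, n - window + 1, step))
    signs: list[tuple[int, int]] = []  # (offset, +1 A closer / -1 B closer)
    for off in offsets:
        sa = ca[off + window] - ca[off]
        sb = cb[off + window] - cb[off]
        if sa > sb:
            signs.append((off, 1))
        elif sb > sa:
            signs.append((off, -1))
    intervals: list[tuple[int, int]] = []
    prev_off, prev_sign = None, 0
    for off, sign in signs:
        if prev_sign and sign != prev_sign:
            intervals.append((prev_off, off + window))
        prev_off, prev_sign = off, sign
    return intervals, len(intervals) > 1


# --------------------------------------------------------------------------
# distances, neighbor joining, bootstrap


def p_distance_matrix(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distances (mismatch fraction) of equal-length sequences."""
    labels = sorted(seqs)
    arrs = {l: np.frombuffer(seqs[l].encode(), dtype=np.uint8) for l in labels}
    n = len(labels)
    if len({a.size for a in arrs.values()}) > 1:
        raise ValueError("p-distance requires equal-length sequences")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(arrs[labels[i]] != arrs[labels[j]])
    return labels, d


@dataclass
class _Node:
    label: str | None = None
    children: list[tuple["_Node", float]] = field(default_factory=list)

    def leaves(self) -> frozenset[str]:
        if self.label is not None:
            return frozenset({self.label})
        out: set[str] = set()
        for c, _ in self.children:
            out |= c.leaves()
        return frozenset(out)

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.label is not None:
            return self.label
        inner = ",".join(f"{c._nwk()}:{round(bl, 10):.10g}" for c, bl in self.children)
        return f"({inner})"


@dataclass
class NJTree:
    root: _Node          # arbitrary trifurcating root of the unrooted tree
    labels: list[str]

    def newick(self) -> str:
        return self.root.newick()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the leaf set of one side (the side not
        containing the alphabetically first taxon, for a canonical form)."""
        anchor = min(self.labels)
        all_leaves = frozenset(self.labels)
        out: set[frozenset[str]] = set()

        def visit(node: _Node):
            for child, _ in node.children:
                if child.label is None:
                    ls = child.leaves()
                    side = ls if anchor not in ls else all_leaves - ls
                    if 1 < len(side) < len(all_leaves) - 1:
                        out.add(side)
                    visit(child)
        visit(self.root)
        return out

    def contains_split(self, leaves) -> bool:
        """True if the tree has an edge separating ``leaves`` from the rest."""
        side = frozenset(leaves)
        comp = frozenset(self.labels) - side
        bips = self.bipartitions()
        return side in bips or comp in bips

    def tip_distances(self) -> tuple[list[str], np.ndarray]:
        """Pairwise path lengths between all tips (additivity check)."""
        labels = sorted(self.labels)
        pos = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def below(node: _Node) -> dict[str, float]:
            if node.label is not None:
                return {node.label: 0.0}
            acc: dict[str, float] = {}
            child_maps = []
            for c, bl in node.children:
                m = {k: v + bl for k, v in below(c).items()}
                child_maps.append(m)
                acc.update(m)
            for m1, m2 in itertools.combinations(child_maps, 2):
                for l1, v1 in m1.items():
                    for l2, v2 in m2.items():
                        d[pos[l1], pos[l2]] = d[pos[l2], pos[l1]] = v1 + v2
            return acc
        below(self.root)
        return labels, d


def build_nj(labels: list[str], dist: np.ndarray) -> NJTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Pair selection minimizes the Q criterion, ties broken lexicographically
    by cluster label; negative branch lengths are clamped to zero with the
    excess moved to the sister edge (pair path length is preserved, so
    additive matrices are still recovered exactly).  The final three clusters
    are joined at one internal node by the three-point closed form.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if dist.shape != (n, n) or not np.allclose(dist, dist.T) or np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if len(set(labels)) != n:
        raise ValueError("duplicate taxon labels")
    nodes: dict[str, _Node] = {l: _Node(label=l) for l in labels}
    d: dict[frozenset[str], float] = {}
    active = sorted(labels)
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((labels[i], labels[j]))] = float(dist[i, j])

    def D(a: str, b: str) -> float:
        return d[frozenset((a, b))]

    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(D(a, b) for b in active if b != a) for a in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * D(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = D(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0:
            la, lb = 0.0, dab
        elif lb < 0:
            la, lb = dab, 0.0
        new = _Node(children=[(nodes[a], la), (nodes[b], lb)])
        new_label = f"\x00{counter}"   # internal; sorts before taxa, unique
        counter += 1
        nodes[new_label] = new
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new_label, c))] = 0.5 * (D(a, c) + D(b, c) - dab)
        active = sorted([c for c in active if c not in (a, b)] + [new_label])
    a, b, c = active
    la = 0.5 * (D(a, b) + D(a, c) - D(b, c))
    lb = 0.5 * (D(a, b) + D(b, c) - D(a, c))
    lc = 0.5 * (D(a, c) + D(b, c) - D(a, b))
    root = _Node(children=[(nodes[a], max(la, 0.0)),
                           (nodes[b], max(lb, 0.0)),
                           (nodes[c], max(lc, 0.0))])
    return NJTree(root, list(labels))


def nj_from_sequences(seqs: dict[str, str]) -> NJTree:
    """NJ tree from p-distances of (typically concatenated protein) sequences."""
    labels, d = p_distance_matrix(seqs)
    return build_nj(labels, d)


def bootstrap_supports(seqs: dict[str, str], n_reps: int = 100,
                       seed: int = 0) -> dict[frozenset[str], float]:
    """Column-resampled bootstrap supports for the NJ tree of ``seqs``.

    Support of each bipartition of the original tree = fraction of replicate
    trees (NJ on column-resampled alignments) containing it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = sorted(seqs)
    L = len(seqs[labels[0]])
    if L < 1:
        raise ValueError("alignment must have >= 1 column")
    mat = np.vstack([np.frombuffer(seqs[l].encode(), dtype=np.uint8) for l in labels])
    original = nj_from_sequences(seqs)
    target = original.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    n = len(labels)
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        sub = mat[:, cols]
        dm = np.zeros((n, n))
        for i in range(n):
            neq = sub[i + 1:] != sub[i]
            if neq.size:
                dm[i, i + 1:] = dm[i + 1:, i] = neq.mean(axis=1)
        rep = build_nj(labels, dm)
        got = rep.bipartitions()
        for bp in target:
            if bp in got:
                counts[bp] += 1
    return {bp: c / n_reps for bp, c in counts.items()}
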