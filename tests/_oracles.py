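"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives the checked quantity from first principles (plain DP
recurrences, exhaustive scans), sharing no code path with the package
implementation it validates.
"""

import numpy as np
from numba import njit

MATCH, MISMATCH, GAP = 1.0, -2.0, -4.0

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


@njit
def _sw_score(q, t):  # pragma: no cover - jitted
    n, m = q.shape[0], t.shape[0]
    prev = np.zeros(m + 1)
    best = 0.0
    for i in range(1, n + 1):
        cur = np.zeros(m + 1)
        for j in range(1, m + 1):
            if q[i - 1] == t[j - 1] and q[i - 1] != 78:  # 78 == ord('N')
                s = MATCH
            else:
                s = MISMATCH
            v = prev[j - 1] + s
            if prev[j] + GAP > v:
                v = prev[j] + GAP
            if cur[j - 1] + GAP > v:
                v = cur[j - 1] + GAP
            if v < 0.0:
                v = 0.0
            cur[j] = v
            if v > best:
                best = v
        prev = cur
    return best


def local_score(query: str, target: str) -> float:
    """Best local alignment score of query (either strand) vs target."""
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    f = _sw_score(np.frombuffer(query.encode(), dtype=np.uint8), t)
    r = _sw_score(np.frombuffer(rc(query).encode(), dtype=np.uint8), t)
    return max(f, r)


def naive_probe_counts(reads, probes):
    """O(n*m) per-read substring scan; one count per read, first probe wins."""
    counts = {p.probe_id: 0 for p in probes}
    multi = 0
    for r in reads:
        if isinstance(r, bytes):
            r = r.decode()
        if len(r) < len(probes[0].seq):
            continue
        matched = []
        for p in probes:
            hit = False
            for i in range(len(r) - len(p.seq) + 1):
                w = r[i : i + len(p.seq)]
                if w == p.seq or w == rc(p.seq):
                    hit = True
                    break
            if hit:
                matched.append(p.probe_id)
        if matched:
            counts[matched[0]] += 1
            if len(matched) > 1:
                multi += 1
    return counts, multi


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random unrooted binary tree and its exact tip path-length matrix.

    Tree is built by random sequential joining; returns (labels, matrix).
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # dist to every taxon maintained per active cluster
    paths = {l: {l: 0.0} for l in labels}
    active = list(labels)
    full = np.zeros((n_taxa, n_taxa))
    pos = {l: i for i, l in enumerate(labels)}

    def blen():
        return float(rng.uniform(0.05, 1.0))

    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[int(i)], active[int(j)]
        la, lb = blen(), blen()
        if len(active) == 2:  # final edge: join directly
            la, lb = la, 0.0
        for x, dx in paths[a].items():
            for y, dy in paths[b].items():
                d = dx + la + dy + lb
                full[pos[x], pos[y]] = full[pos[y], pos[x]] = d
        merged = {x: d + la for x, d in paths[a].items()}
        merged.update({y: d + lb for y, d in paths[b].items()})
        new = f"__{a}"
        paths[new] = merged
        active = [c for c in active if c not in (a, b)] + [new]
    return labels, full


def parent_likelihood_breakpoint(chimera: str, pa: str, pb: str) -> int:
    """Brute-force best single-crossover position: argmax over all split
    points of (matches to A left of the split + matches to B right of it)."""
    n = len(chimera)
    ma = np.array([chimera[i] == pa[i] for i in range(n)], dtype=np.int32)
    mb = np.array([chimera[i] == pb[i] for i in range(n)], dtype=np.int32)
    ca = np.concatenate([[0], np.cumsum(ma)])
    cb = np.concatenate([[0], np.cumsum(mb)])
    scores = [ca[k] + (cb[n] - cb[k]) for k in range(n + 1)]
    return int(np.argmax(scores))
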