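"""54-nt group-diagnostic probes and exact-match short-read screening.

The probes are windows of the GH16 methyl-porphyranase gene, which carries
mutations specific to each haplotype group (including the GIIIrec mosaic,
whose window must straddle its crossover so that it differs from both GI and
GIII).  Reads are screened by exact full-length substring matching on both
strands — the 100% identity / 100% coverage rule — so a single sequencing
error inside the probe footprint loses the read, and reads shorter than the
probe are skipped rather than partially matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pulhaplo.reference import revcomp

PROBE_LEN = 54


@dataclass(frozen=True)
class Probe:
    probe_id: str
    group: str
    seq: str
    gh16_offset: int

    def __post_init__(self):
        if len(self.seq) != PROBE_LEN:
            raise ValueError(f"probe {self.probe_id}: length {len(self.seq)} != {PROBE_LEN}")
        if not set(self.seq) <= set("ACGT"):
            raise ValueError(f"probe {self.probe_id}: non-ACGT characters")


@dataclass
class ReadScreenResult:
    sample_id: str
    counts: dict[str, int]
    total_reads: int
    positive: bool
    rel_abundance: float | None
    group_profile: dict[str, float]
    call: str                      # negative | single | dominant | multi | low_count
    n_skipped_short: int = 0
    n_multi_probe: int = 0


class ProbeDesignError(ValueError):
    pass


def design_probes(group_gh16: dict[str, str], k: int = PROBE_LEN,
                  within_group: dict[str, list[str]] | None = None,
                  ) -> list[Probe]:
    """Choose one shared k-window of the aligned GH16 sequences that tells all
    groups apart, and emit each group's window as its probe.

    Among windows where every pair of groups differs by >=1 substitution (and
    which are conserved across any supplied within-group training sequences),
    the one with the most diagnostic columns wins.  If no single window
    discriminates all groups an error reports the best achievable
    discrimination.
    """
    groups = sorted(group_gh16)
    if len(groups) < 2:
        raise ProbeDesignError("need >= 2 groups to design diagnostic probes")
    L = len(group_gh16[groups[0]])
    if any(len(group_gh16[g]) != L for g in groups):
        raise ProbeDesignError("GH16 sequences must be aligned to equal length")
    mats = {g: np.frombuffer(group_gh16[g].encode(), dtype=np.uint8) for g in groups}
    # column is diagnostic if not all groups agree there
    stack = np.vstack([mats[g] for g in groups])
    diag = (stack != stack[0]).any(axis=0).astype(np.int32)
    cdiag = np.concatenate([[0], np.cumsum(diag)])
    pair_diff = {}
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            neq = (mats[a] != mats[b]).astype(np.int32)
            pair_diff[(a, b)] = np.concatenate([[0], np.cumsum(neq)])
    conserved = np.ones(L, dtype=bool)
    if within_group:
        for g, train in within_group.items():
            for t in train:
                conserved &= mats[g] == np.frombuffer(t.encode(), dtype=np.uint8)
    ccons = np.concatenate([[0], np.cumsum((~conserved).astype(np.int32))])
    best_off, best_score = None, -1
    max_pairs_ok = -1
    for off in range(L - k + 1):
        if ccons[off + k] - ccons[off] > 0:
            continue
        ok = sum(1 for cum in pair_diff.values() if cum[off + k] - cum[off] >= 1)
        max_pairs_ok = max(max_pairs_ok, ok)
        if ok < len(pair_diff):
            continue
        score = int(cdiag[off + k] - cdiag[off])
        if score > best_score:
            best_off, best_score = off, score
    if best_off is None:
        raise ProbeDesignError(
            f"no {k}-nt window discriminates all {len(groups)} groups "
            f"(best window separates {max_pairs_ok}/{len(pair_diff)} pairs)")
    probes = [Probe(f"probe_{g}", g, group_gh16[g][best_off : best_off + k], best_off)
              for g in groups]
    _validate_probes(probes, group_gh16)
    return probes


def _validate_probes(probes: list[Probe], group_gh16: dict[str, str]) -> None:
    for p in probes:
        if p.seq not in group_gh16[p.group]:
            raise ProbeDesignError(f"{p.probe_id} does not match its own group")
        for g, ref in group_gh16.items():
            if g != p.group and (p.seq in ref or revcomp(p.seq) in ref):
                raise ProbeDesignError(f"{p.probe_id} also matches group {g}")


def match_reads(reads, probes: list[Probe]) -> tuple[dict[str, int], int, int, int]:
    """Exact full-length probe matching over both strands.

    A read counts for a probe iff the probe or its reverse complement occurs
    as an exact substring of the read; each read counts at most once, for the
    first matching probe in the given probe order (reads matching more than
    one probe are tallied separately).  Reads shorter than the probe are
    skipped.

    Returns ``(counts per probe_id, total_reads, n_skipped_short, n_multi)``.
    """
    patterns = [(p.probe_id, p.seq.encode(), revcomp(p.seq).encode()) for p in probes]
    counts = {p.probe_id: 0 for p in probes}
    total = 0
    skipped = 0
    multi = 0
    sep = b"\n"
    chunk: list[bytes] = []
    offsets: list[int] = []
    pos = 0
    for r in reads:
        if isinstance(r, str):
            r = r.encode()
        total += 1
        if len(r) < PROBE_LEN:
            skipped += 1
            continue
        offsets.append(pos)
        chunk.append(r)
        pos += len(r) + 1
    buf = sep.join(chunk)
    starts = np.array(offsets, dtype=np.int64)
    hit_sets: dict[int, set[int]] = {}
    for pi, (_, fwd, rc) in enumerate(patterns):
        for pat in ({fwd, rc}):
            at = buf.find(pat)
            while at != -1:
                ridx = int(np.searchsorted(starts, at, side="right")) - 1
                hit_sets.setdefault(ridx, set()).add(pi)
                at = buf.find(pat, at + 1)
    for ridx, pset in hit_sets.items():
        first = min(pset)
        counts[patterns[first][0]] += 1
        if len(pset) > 1:
            multi += 1
    return counts, total, skipped, multi


def call_sample(counts: dict[str, int], total_reads: int, *,
                min_reads: int = 10, dom_threshold: float = 0.80,
                sample_id: str = "sample", n_skipped_short: int = 0,
                n_multi_probe: int = 0) -> ReadScreenResult:
    """Per-sample positivity, abundance and group-dominance call.

    Positivity needs a single matching read; group characterization needs at
    least ``min_reads`` matches (otherwise ``low_count``); ``single`` if one
    group holds every read, ``dominant`` if the major group's fraction is
    strictly above ``dom_threshold``, else ``multi``.
    """
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    by_group: dict[str, int] = {}
    for pid, c in counts.items():
        g = pid.removeprefix("probe_")
        by_group[g] = by_group.get(g, 0) + c
    s = sum(by_group.values())
    rel = abundance(by_group, total_reads) if total_reads > 0 else None
    if s == 0:
        return ReadScreenResult(sample_id, by_group, total_reads, False, rel,
                                {}, "negative", n_skipped_short, n_multi_probe)
    profile = {g: c / s for g, c in by_group.items()}
    if s < min_reads:
        call = "low_count"
    else:
        nonzero = [c for c in by_group.values() if c > 0]
        if len(nonzero) == 1:
            call = "single"
        elif max(profile.values()) > dom_threshold:
            call = "dominant"
        else:
            call = "multi"
    return ReadScreenResult(sample_id, by_group, total_reads, True, rel,
                            profile, call, n_skipped_short, n_multi_probe)


def abundance(counts: dict[str, int], total_reads: int) -> float:
    """Relative abundance: probe-matching reads over total reads."""
    if total_reads <= 0:
        raise ValueError("abundance undefined for total_reads <= 0")
    return sum(counts.values()) / total_reads


def dominant_group(result: ReadScreenResult) -> str | None:
    """Major group of a single/dominant call; None otherwise."""
    if result.call not in ("single", "dominant"):
        return None
    return max(result.group_profile.items(), key=lambda kv: (kv[1], kv[0]))[0]
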