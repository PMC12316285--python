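"""Seeded synthetic cohorts with known truth labels.

The generator emulates the statistical structure the downstream analyses
assume: haplotype groups at calibrated protein-identity bands to the GI
reference (GII 96-100%, GIII 92-98%), a GI x GIII recombinant (GIIIrec) with
its crossover inside the GH16 gene, per-sample within-group micro-variation,
metagenome-assembled-genome (MAG) incompleteness via per-gene dropout, and
single-end short-read sampling with log-uniform per-sample depth and uniform
substitution errors.

Backgrounds are i.i.d. uniform ATGC and reads are substitution-only: the
screens rely on identity thresholds and exact probe matching, not on
compositional or indel realism.  Within-group micro-variation is placed
outside GH16 so that the group-diagnostic window of GH16 stays conserved
within a group, which is the empirical property that makes exact-match 54-nt
probes viable in the first place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from pulhaplo.reference import (
    GH16_GENE_ID,
    GeneModel,
    LocusReference,
    is_stop,
    nonsyn_codon,
    syn_codon,
    revcomp,
)

GROUPS = ("GI", "GII", "GIII", "GIIIrec")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_freqs() -> dict[str, float]:
    return {"GI": 0.45, "GII": 0.35, "GIII": 0.15, "GIIIrec": 0.05}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 0
    n_samples: int = 300
    prevalence: float = 0.3
    group_freqs: dict[str, float] = field(default_factory=_default_freqs)
    gii_identity_band: tuple[float, float] = (0.96, 1.00)
    giii_identity_band: tuple[float, float] = (0.92, 0.98)
    within_group_identity: float = 0.995
    read_length: int = 150
    depth_bounds: tuple[int, int] = (5_000, 50_000)  # log-uniform per sample
    seq_error_rate: float = 0.0
    assembly_error_rate: float = 0.0
    background_genome_size: int = 30_000
    mag_dropout: float = 0.0
    recombinant_breakpoint: int | None = None  # GH16-internal nt; None -> drawn

    def validate(self) -> None:
        for name in ("prevalence", "within_group_identity", "seq_error_rate",
                     "assembly_error_rate", "mag_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if abs(sum(self.group_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("group_freqs must sum to 1")
        for g, f in self.group_freqs.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"group frequency {g}={f} outside [0,1]")
        for band in (self.gii_identity_band, self.giii_identity_band):
            if not (0.0 <= band[0] <= band[1] <= 1.0):
                raise ValueError(f"identity band {band} not ordered in [0,1]")
        if self.read_length < 54:
            raise ValueError("read_length must be >= 54 (probe length)")
        if self.depth_bounds[0] < 1 or self.depth_bounds[0] > self.depth_bounds[1]:
            raise ValueError("depth_bounds must be ordered and positive")


@dataclass
class TruthRecord:
    sample_id: str
    carries_pul: bool
    true_groups: frozenset[str]
    true_breakpoint: int | None
    true_abundance: float

    def __post_init__(self):
        if not self.carries_pul and self.true_groups:
            raise ValueError("non-carrier with non-empty true_groups")
        if "GIIIrec" in self.true_groups and self.true_breakpoint is None:
            raise ValueError("GIIIrec truth requires a breakpoint")


# --------------------------------------------------------------------------
# group reference construction


def _diverge_gene(gene: GeneModel, band: tuple[float, float],
                  rng: np.random.Generator) -> str:
    """Mutate a CDS so its protein identity to ``gene`` lands inside ``band``.

    Exactly ``n`` amino-acid positions are replaced (codon swaps to a
    different, non-stop residue), so the realized protein identity is
    ``1 - n/n_aa`` by construction; roughly n/2 additional synonymous codon
    swaps diversify the nucleotide sequence without moving protein identity.
    """
    lo, hi = band
    n_aa = len(gene.aa_seq)
    n_min = math.ceil((1.0 - hi) * n_aa - 1e-9)
    n_max = math.floor((1.0 - lo) * n_aa + 1e-9)
    if n_max < n_min or (hi < 1.0 and n_max < 1):
        raise ValueError(
            f"{gene.gene_id}: identity band ({lo},{hi}) infeasible for a "
            f"{n_aa}-residue protein (required substitutions < 1)")
    n_sub = int(rng.integers(n_min, n_max + 1))
    codons = [gene.nt_seq[i : i + 3] for i in range(0, len(gene.nt_seq), 3)]
    # never touch the start codon
    targets = rng.choice(np.arange(1, n_aa), size=n_sub, replace=False) if n_sub else []
    for i in targets:
        codons[i] = nonsyn_codon(codons[i], rng)
    n_syn = n_sub // 2
    free = [i for i in range(1, n_aa) if i not in set(int(t) for t in targets)]
    if n_syn and free:
        for i in rng.choice(free, size=min(n_syn, len(free)), replace=False):
            codons[i] = syn_codon(codons[i], rng)
    return "".join(codons)


def make_group_references(base: LocusReference, cfg: SimulationConfig,
                          ) -> dict[str, LocusReference]:
    """Derive the four group references from the base (GI) locus.

    GI is the base itself; GII and GIII are per-gene divergent copies whose
    protein identity to GI falls inside the configured bands; GIIIrec is a
    GI x GIII mosaic joined inside GH16 (see :func:`join_recombinant`).
    Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng([int(cfg.seed), 0x6F0])
    refs: dict[str, LocusReference] = {"GI": replace(base, locus_id="GI")}
    for group, band in (("GII", cfg.gii_identity_band), ("GIII", cfg.giii_identity_band)):
        new = {g.gene_id: _diverge_gene(g, band, rng) for g in base.genes}
        refs[group] = base.with_genes(new, locus_id=group)
    gh16_len = len(base.gh16.nt_seq)
    bp = cfg.recombinant_breakpoint
    if bp is None:
        # Drawn codon-aligned from the central 80% of GH16, restricted to
        # crossovers that a single 54-nt window can straddle and still tell
        # all four groups apart — the observed mosaic is, by construction of
        # the published probes, exactly of that kind.
        bp = _draw_diagnosable_breakpoint(refs, gh16_len, rng)
    refs["GIIIrec"] = join_recombinant(refs["GI"], refs["GIII"], bp)
    return refs


def _draw_diagnosable_breakpoint(refs: dict[str, LocusReference], gh16_len: int,
                                 rng: np.random.Generator) -> int:
    from pulhaplo.probes import ProbeDesignError, design_probes

    gi = refs["GI"].gh16.nt_seq
    giii = refs["GIII"].gh16.nt_seq
    gh16 = {g: refs[g].gh16.nt_seq for g in ("GI", "GII", "GIII")}
    lo, hi = gh16_len // 10, gh16_len - gh16_len // 10
    candidates = np.arange(lo // 3 * 3, hi, 3)
    rng.shuffle(candidates)
    for bp in candidates:
        bp = int(bp)
        gh16["GIIIrec"] = giii[:bp] + gi[bp:]
        try:
            design_probes(gh16)
        except ProbeDesignError:
            continue
        return bp
    # No fully probe-diagnosable crossover (e.g. degenerate zero-divergence
    # bands).  Prefer one at least flanked by GI/GIII differences so the
    # breakpoint scan stays informative; otherwise draw centrally.  Probe
    # design itself will report the discrimination failure if attempted.
    diffs = np.array([i for i in range(gh16_len) if gi[i] != giii[i]])
    for bp in candidates:
        bp = int(bp)
        if diffs.size and ((diffs < bp) & (diffs >= bp - 27)).any() \
                and ((diffs >= bp) & (diffs < bp + 27)).any():
            return bp
    return int(candidates[0])


def join_recombinant(gi: LocusReference, giii: LocusReference,
                     breakpoint_gh16: int) -> LocusReference:
    """Build the GIIIrec mosaic: sulfatase, GH29 and GH16[:bp] from GIII;
    GH16[bp:], SusD, SusC and GH2 (and the spacers) from GI.

    A breakpoint off a codon boundary is shifted to the nearest one so the
    chimeric GH16 stays stop-free; the realized position is recorded on the
    returned locus (``breakpoint_gh16`` attribute).
    """
    gh16_len = len(gi.gh16.nt_seq)
    if not 0 <= breakpoint_gh16 <= gh16_len:
        raise ValueError(f"breakpoint {breakpoint_gh16} outside GH16 [0,{gh16_len}]")
    bp = int(round(breakpoint_gh16 / 3)) * 3
    bp = min(max(bp, 0), gh16_len)
    chimera = giii.gh16.nt_seq[:bp] + gi.gh16.nt_seq[bp:]
    new = {
        "bacple_01701": giii.gene("bacple_01701").nt_seq,
        "bacple_01702": giii.gene("bacple_01702").nt_seq,
        GH16_GENE_ID: chimera,
        # SusD/SusC/GH2 stay GI
    }
    out = gi.with_genes(new, locus_id="GIIIrec")
    object.__setattr__(out, "breakpoint_gh16", bp)
    return out


# --------------------------------------------------------------------------
# per-sample locus variation


def _mutate_within_group(ref: LocusReference, rate: float,
                         rng: np.random.Generator) -> str:
    """Apply within-group nucleotide substitutions to a locus, resampling any
    substitution that would create an internal stop codon and leaving the
    GH16 CDS untouched (its diagnostic window is conserved within groups)."""
    if rate <= 0.0:
        return ref.seq
    seq = list(ref.seq)
    gh16 = ref.gh16
    gene_spans = [(g.start, g.end) for g in ref.genes]
    n = len(seq)
    k = rng.binomial(n, rate)
    positions = rng.choice(n, size=k, replace=False)
    for pos in positions:
        pos = int(pos)
        if gh16.start <= pos < gh16.end:
            continue
        gene = next(((s, e) for s, e in gene_spans if s <= pos < e), None)
        old = seq[pos]
        choices = [b for b in "ACGT" if b != old]
        rng.shuffle(choices)
        for b in choices:
            seq[pos] = b
            if gene is None:
                break
            s, _ = gene
            cstart = s + (pos - s) // 3 * 3
            if not is_stop("".join(seq[cstart : cstart + 3])):
                break
            seq[pos] = old  # this base makes a stop; try next
    return "".join(seq)


def _substitution_noise(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Uniform substitution errors (sequencing/assembly noise; may create stops)."""
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = _encode(arr)
    mask = rng.random(arr.size) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()))
    idx[mask] = (idx[mask] + shift) % 4
    return _decode(idx).tobytes().decode()


def _encode(ascii_arr: np.ndarray) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    lut[ord("C")] = 1
    lut[ord("G")] = 2
    lut[ord("T")] = 3
    return lut[ascii_arr]


def _decode(idx: np.ndarray) -> np.ndarray:
    return _BASES[idx]


# --------------------------------------------------------------------------
# cohort simulation


@dataclass
class SampleRecord:
    sample_id: str
    truth: TruthRecord
    genome: str
    contigs: dict[str, str]
    locus_start: int | None
    locus_strand: str | None
    depth: int


@dataclass
class Cohort:
    """A simulated cohort.  Assemblies and truth are materialized; reads are
    regenerated deterministically per sample on demand (same seed, same
    bytes), which keeps even deep cohorts cheap to hold."""

    cfg: SimulationConfig
    samples: list[SampleRecord]

    def truth_records(self) -> list[TruthRecord]:
        return [s.truth for s in self.samples]

    def reads_for(self, sample: SampleRecord | str) -> list[bytes]:
        if isinstance(sample, str):
            sample = next(s for s in self.samples if s.sample_id == sample)
        return _simulate_reads(sample, self.cfg)

    def write(self, outdir) -> None:
        import os

        os.makedirs(os.path.join(outdir, "assemblies"), exist_ok=True)
        os.makedirs(os.path.join(outdir, "reads"), exist_ok=True)
        with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
            fh.write("sample_id\tcarries_pul\tgroups\tbreakpoint\tabundance\n")
            for s in self.samples:
                t = s.truth
                fh.write("\t".join([
                    t.sample_id,
                    "1" if t.carries_pul else "0",
                    ",".join(sorted(t.true_groups)),
                    "" if t.true_breakpoint is None else str(t.true_breakpoint),
                    f"{t.true_abundance:.6g}",
                ]) + "\n")
        for s in self.samples:
            with open(os.path.join(outdir, "assemblies", f"{s.sample_id}.fasta"), "w") as fh:
                for cid, seq in s.contigs.items():
                    fh.write(f">{cid}\n")
                    for i in range(0, len(seq), 80):
                        fh.write(seq[i : i + 80] + "\n")
            qual = "I" * self.cfg.read_length
            with open(os.path.join(outdir, "reads", f"{s.sample_id}.fastq"), "w") as fh:
                for i, r in enumerate(self.reads_for(s)):
                    fh.write(f"@{s.sample_id}.r{i}\n{r.decode()}\n+\n{qual}\n")


def _simulate_reads(sample: SampleRecord, cfg: SimulationConfig) -> list[bytes]:
    rng = np.random.default_rng([int(cfg.seed), 2, _sample_index(sample.sample_id)])
    g = np.frombuffer(sample.genome.encode(), dtype=np.uint8)
    idx = _encode(g)
    L = cfg.read_length
    n_starts = len(idx) - L + 1
    if n_starts < 1 or sample.depth < 1:
        return []
    starts = rng.integers(0, n_starts, size=sample.depth)
    reads = idx[starts[:, None] + np.arange(L)]
    rc = rng.random(sample.depth) < 0.5
    reads[rc] = 3 - reads[rc, ::-1]
    if cfg.seq_error_rate > 0.0:
        mask = rng.random(reads.shape) < cfg.seq_error_rate
        reads[mask] = (reads[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    buf = _decode(reads.reshape(-1)).tobytes()
    return [buf[i * L : (i + 1) * L] for i in range(sample.depth)]


def _sample_index(sample_id: str) -> int:
    return int(sample_id.rsplit("S", 1)[1])


def simulate_cohort(cfg: SimulationConfig,
                    refs: dict[str, LocusReference]) -> Cohort:
    """Simulate ``cfg.n_samples`` independent individuals.

    Each sample carries the PUL with probability ``prevalence``; carriers draw
    one group from ``group_freqs``, receive a within-group variant of that
    group's reference embedded at a random position and strand in an i.i.d.
    ATGC background, then per-gene MAG dropout fragments the assembly.  Reads
    are drawn uniformly from the full genome at a log-uniform depth with
    uniform substitution errors.  Fully reproducible from ``cfg.seed``.
    """
    cfg.validate()
    for g, f in cfg.group_freqs.items():
        if f > 0 and g not in refs:
            raise ValueError(f"missing reference for group {g}")
    rng = np.random.default_rng([int(cfg.seed), 1])
    groups = sorted(cfg.group_freqs)
    probs = np.array([cfg.group_freqs[g] for g in groups])
    samples: list[SampleRecord] = []
    log_lo, log_hi = math.log(cfg.depth_bounds[0]), math.log(cfg.depth_bounds[1])
    noise = 1.0 - cfg.within_group_identity
    for i in range(cfg.n_samples):
        sid = f"S{i:04d}"
        depth = int(round(math.exp(rng.uniform(log_lo, log_hi))))
        carries = bool(rng.random() < cfg.prevalence)
        bg = _decode(rng.integers(0, 4, cfg.background_genome_size, dtype=np.uint8)).tobytes().decode()
        if not carries:
            genome = bg
            contigs = {f"{sid}_c0": _substitution_noise(genome, cfg.assembly_error_rate, rng)}
            truth = TruthRecord(sid, False, frozenset(), None, 0.0)
            samples.append(SampleRecord(sid, truth, genome, contigs, None, None, depth))
            continue
        group = groups[int(rng.choice(len(groups), p=probs))]
        ref = refs[group]
        locus = _mutate_within_group(ref, noise, rng)
        pos = int(rng.integers(0, len(bg) + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        ins = locus if strand == "+" else revcomp(locus)
        genome = bg[:pos] + ins + bg[pos:]
        contigs = _fragment(sid, genome, ref, pos, strand, cfg, rng)
        n_starts = len(genome) - cfg.read_length + 1
        abund = min(1.0, (len(locus) + cfg.read_length - 1) / max(n_starts, 1))
        bp = getattr(ref, "breakpoint_gh16", None) if group == "GIIIrec" else None
        truth = TruthRecord(sid, True, frozenset({group}), bp, abund)
        samples.append(SampleRecord(sid, truth, genome, contigs, pos, strand, depth))
    return Cohort(cfg, samples)


def _fragment(sid: str, genome: str, ref: LocusReference, pos: int, strand: str,
              cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    """Split the genome into contigs, deleting each gene's span with
    probability ``mag_dropout`` (incomplete-MAG emulation)."""
    L = ref.total_length
    drop_spans: list[tuple[int, int]] = []
    for g in ref.genes:
        if rng.random() < cfg.mag_dropout:
            if strand == "+":
                drop_spans.append((pos + g.start, pos + g.end))
            else:
                drop_spans.append((pos + L - g.end, pos + L - g.start))
    drop_spans.sort()
    contigs: dict[str, str] = {}
    cur, n = 0, 0
    for s, e in drop_spans + [(len(genome), len(genome))]:
        if s > cur:
            piece = genome[cur:s]
            contigs[f"{sid}_c{n}"] = _substitution_noise(piece, cfg.assembly_error_rate, rng)
            n += 1
        cur = max(cur, e)
    return contigs
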