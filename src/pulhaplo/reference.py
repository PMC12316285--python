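"""The six-gene PUL-PorB locus model.

PUL-PorB is the 12,888-nt porphyran polysaccharide utilization locus segment of
*Bacteroides plebeius* used as the detection unit throughout the package.  Its
six genes are, in locus order: a S1_11 family sulfatase (bacple_01701), an
alpha-L-fucosidase family GH29 (bacple_01702), the methyl-porphyranase GH16
(bacple_01703) that carries the group-diagnostic variation, the outer-membrane
SusD-like and SusC-like transporters (bacple_01704/01705), and a
beta-galactosidase family GH2 (bacple_01706).

Real reference sequences are not redistributed; :func:`build_reference`
synthesizes a locus with the authentic gene order, realistic gene lengths and
the authentic total span, which is what every identity-threshold-based screen
in the package actually depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

# locus order is fixed: (gene_id, role, CDS length in nt excluding stop codon)
GENE_ROLES = (
    ("bacple_01701", "sulfatase", 1506),
    ("bacple_01702", "GH29", 1704),
    ("bacple_01703", "GH16", 1122),
    ("bacple_01704", "SusD", 1647),
    ("bacple_01705", "SusC", 3096),
    ("bacple_01706", "GH2", 2532),
)

#: total locus span in nucleotides (genes + intergenic spacers)
LOCUS_LENGTH = 12_888

# intergenic spacer lengths between consecutive genes (sum = 12,888 - sum(genes))
_SPACERS = (257, 256, 256, 256, 256)

GH16_GENE_ID = "bacple_01703"

_STOPS = set(standard_dna_table.stop_codons)
_CODON_TO_AA = dict(standard_dna_table.forward_table)
_NONSTOP_CODONS = sorted(_CODON_TO_AA)
_AA_TO_CODONS: dict[str, list[str]] = {}
for _c, _a in _CODON_TO_AA.items():
    _AA_TO_CODONS.setdefault(_a, []).append(_c)
for _v in _AA_TO_CODONS.values():
    _v.sort()


def translate(nt: str) -> str:
    """Translate a CDS (standard code); internal stops appear as ``*``."""
    return str(Seq(nt).translate())


def revcomp(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


@dataclass(frozen=True)
class GeneModel:
    """One CDS of the locus, in 0-based half-open locus coordinates."""

    gene_id: str
    role: str
    nt_seq: str
    start: int
    end: int
    strand: str = "+"
    aa_seq: str = field(default="", compare=False)

    def __post_init__(self):
        if len(self.nt_seq) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {len(self.nt_seq)} not divisible by 3")
        if self.end - self.start != len(self.nt_seq):
            raise ValueError(f"{self.gene_id}: coordinates span != sequence length")
        aa = translate(self.nt_seq)
        if "*" in aa:
            raise ValueError(f"{self.gene_id}: internal stop codon in CDS")
        object.__setattr__(self, "aa_seq", aa)

    def __len__(self) -> int:
        return len(self.nt_seq)


@dataclass(frozen=True)
class LocusReference:
    """An ordered six-gene PUL-PorB model with its full nucleotide sequence.

    ``genes`` are in fixed locus order and their coordinates index into
    ``seq`` (gene ``nt_seq == seq[start:end]``); intergenic spacers are the
    complement of the gene spans.
    """

    locus_id: str
    genes: tuple[GeneModel, ...]
    seq: str

    def __post_init__(self):
        if len(self.genes) != 6:
            raise ValueError("PUL-PorB model requires exactly 6 genes")
        expected = [g[0] for g in GENE_ROLES]
        if [g.gene_id for g in self.genes] != expected:
            raise ValueError(f"gene order must be {expected}")
        prev_end = 0
        for g in self.genes:
            if g.start < prev_end:
                raise ValueError(f"{g.gene_id}: overlapping/descending coordinates")
            if self.seq[g.start : g.end] != g.nt_seq:
                raise ValueError(f"{g.gene_id}: sequence/coordinate mismatch")
            prev_end = g.end

    @property
    def total_length(self) -> int:
        return len(self.seq)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def gh16(self) -> GeneModel:
        return self.gene(GH16_GENE_ID)

    def concat_nt(self) -> str:
        return "".join(g.nt_seq for g in self.genes)

    def concat_aa(self) -> str:
        return "".join(g.aa_seq for g in self.genes)

    def intergenic(self) -> list[str]:
        """Spacer sequences between consecutive genes (len 5)."""
        out = []
        for a, b in zip(self.genes, self.genes[1:]):
            out.append(self.seq[a.end : b.start])
        return out

    def with_genes(self, new_nt: dict[str, str], locus_id: str | None = None) -> "LocusReference":
        """Rebuild the locus substituting gene CDSs (lengths must be preserved)."""
        parts: list[str] = []
        genes: list[GeneModel] = []
        pos = 0
        spacers = self.intergenic()
        for i, g in enumerate(self.genes):
            nt = new_nt.get(g.gene_id, g.nt_seq)
            if len(nt) != len(g.nt_seq):
                raise ValueError(f"{g.gene_id}: replacement CDS changes length")
            genes.append(GeneModel(g.gene_id, g.role, nt, pos, pos + len(nt), g.strand))
            parts.append(nt)
            pos += len(nt)
            if i < 5:
                parts.append(spacers[i])
                pos += len(spacers[i])
        return LocusReference(locus_id or self.locus_id, tuple(genes), "".join(parts))


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    codons = ["ATG"] + [_NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), n_codons - 1)]
    return "".join(codons)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def build_reference(seed: int = 0, locus_id: str = "PUL-PorB") -> LocusReference:
    """Synthesize the base (GI) PUL-PorB reference: six ordered genes spanning
    12,888 nt with intergenic spacers, all CDSs stop-free.  Deterministic given
    ``seed``."""
    rng = np.random.default_rng([int(seed), 0xB1E])
    parts: list[str] = []
    genes: list[GeneModel] = []
    pos = 0
    for i, (gid, role, length) in enumerate(GENE_ROLES):
        nt = _random_cds(length // 3, rng)
        genes.append(GeneModel(gid, role, nt, pos, pos + length, "+"))
        parts.append(nt)
        pos += length
        if i < 5:
            parts.append(_random_dna(_SPACERS[i], rng))
            pos += _SPACERS[i]
    ref = LocusReference(locus_id, tuple(genes), "".join(parts))
    assert ref.total_length == LOCUS_LENGTH
    return ref


# --- codon-level mutation helpers shared by the simulator ------------------


def nonsyn_codon(codon: str, rng: np.random.Generator) -> str:
    """A codon encoding a different, non-stop amino acid."""
    aa = _CODON_TO_AA[codon]
    choices = [a for a in _AA_TO_CODONS if a != aa]
    new_aa = choices[rng.integers(0, len(choices))]
    cods = _AA_TO_CODONS[new_aa]
    return cods[rng.integers(0, len(cods))]


def syn_codon(codon: str, rng: np.random.Generator) -> str:
    """A synonymous codon if one exists, else the codon unchanged."""
    cods = [c for c in _AA_TO_CODONS[_CODON_TO_AA[codon]] if c != codon]
    if not cods:
        return codon
    return cods[rng.integers(0, len(cods))]


def is_stop(codon: str) -> bool:
    return codon in _STOPS
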