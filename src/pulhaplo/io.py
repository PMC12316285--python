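"""FASTA/FASTQ readers and writers (plain or gzip) on top of Bio.SeqIO."""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    out: dict[str, str] = {}
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path, records: dict[str, str], width: int = 80) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in records.items()]
    with _open(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq(path, replace_invalid: bool = True):
    """Yield (read_id, sequence) from plain or gzipped FASTQ; characters
    outside ACGTN are replaced with N (with a warning) when
    ``replace_invalid`` is set, otherwise rejected."""
    warned = False
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            seq = str(rec.seq).upper()
            if not set(seq) <= _VALID:
                if not replace_invalid:
                    raise ValueError(f"{rec.id}: non-ACGTN base")
                if not warned:
                    warnings.warn(f"{path}: non-ACGTN bases replaced with N")
                    warned = True
                seq = "".join(c if c in _VALID else "N" for c in seq)
            yield rec.id, seq


def write_probe_fasta(path, probes) -> None:
    """Probe set as FASTA with the group label in the header."""
    with _open(path, "wt") as fh:
        for p in probes:
            fh.write(f">{p.probe_id} group={p.group} gh16_offset={p.gh16_offset}\n{p.seq}\n")


def read_probe_fasta(path):
    from pulhaplo.probes import Probe

    probes = []
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            fields = dict(kv.split("=") for kv in rec.description.split()[1:] if "=" in kv)
            probes.append(Probe(rec.id, fields.get("group", rec.id),
                                str(rec.seq).upper(), int(fields.get("gh16_offset", 0))))
    return probes


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
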