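"""FASTA and tabular readers/writers (thin wrappers over Biopython)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .index import PeptideDatabase, Provenance

__all__ = ["read_fasta", "write_fasta", "database_from_fasta", "database_to_fasta",
           "write_provenance_tsv", "read_provenance_tsv"]


def read_fasta(path) -> dict:
    """Ordered mapping of record id -> upper-cased sequence string."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(path, items, descriptions: dict | None = None) -> None:
    records = []
    for rid, seq in (items.items() if isinstance(items, dict) else items):
        desc = (descriptions or {}).get(rid, "")
        records.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(records, str(path), "fasta")


def database_from_fasta(path, provenance: dict | None = None) -> PeptideDatabase:
    seqs = read_fasta(path)
    return PeptideDatabase(list(seqs.values()), list(seqs.keys()), provenance)


def database_to_fasta(db: PeptideDatabase, path) -> None:
    write_fasta(path, list(zip(db.read_ids, db.reads)))


def write_provenance_tsv(db: PeptideDatabase, path) -> None:
    lines = ["read_id\tsource_id\tstart\tend\tsampled_fraction"]
    for rid in db.read_ids:
        p = db.provenance.get(rid)
        if p is None:
            continue
        lines.append(f"{rid}\t{p.source_id}\t{p.start}\t{p.end}\t{p.sampled_fraction:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_provenance_tsv(path) -> dict:
    out = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        rid, sid, start, end, frac = line.split("\t")
        out[rid] = Provenance(sid, int(start), int(end), float(frac))
    return out
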