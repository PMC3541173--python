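"""FASTA / TSV plumbing shared by all pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .errors import FastaParseError

__all__ = ["ProteinRecord", "read_fasta", "write_fasta", "read_proteome_fasta",
           "read_locus_map"]


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein, keyed genome | locus | gene model."""

    genome: str
    locus: str
    model: str
    seq: str

    @property
    def seq_id(self) -> str:
        return f"{self.genome}|{self.locus}|{self.model}"


def read_fasta(path) -> dict[str, str]:
    """Read amino-acid FASTA into an ordered id -> sequence mapping.

    Sequences are uppercased, '*' stop symbols stripped, line wraps joined.
    Malformed or empty records raise :class:`FastaParseError` with the line
    number.
    """
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    start_line = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seq = "".join(chunks)
                    if not seq:
                        raise FastaParseError(f"record {name!r} has no sequence",
                                              start_line)
                    records[name] = seq
                header = line[1:].strip()
                if not header:
                    raise FastaParseError("empty FASTA header", lineno)
                name = header.split()[0]
                if name in records:
                    raise FastaParseError(f"duplicate record id {name!r}", lineno)
                chunks = []
                start_line = lineno
            else:
                if name is None:
                    raise FastaParseError("sequence data before any header", lineno)
                chunks.append(line.upper().replace("*", ""))
    if name is not None:
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"record {name!r} has no sequence", start_line)
        records[name] = seq
    return records


def write_fasta(records: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_proteome_fasta(path, genome: str | None = None) -> list[ProteinRecord]:
    """Read a proteome whose headers follow the ``genome|locus|model`` scheme.

    Headers without the pipe scheme are adapted: the whole id becomes the
    locus, the gene model defaults to ``m1`` and the genome to the file stem,
    so any predicted-proteome FASTA can enter the pipeline.
    """
    path = Path(path)
    default_genome = genome or path.stem
    out = []
    for name, seq in read_fasta(path).items():
        parts = name.split("|")
        if len(parts) == 3:
            out.append(ProteinRecord(parts[0], parts[1], parts[2], seq))
        else:
            out.append(ProteinRecord(default_genome, name, "m1", seq))
    return out


def read_locus_map(path) -> dict[str, tuple[str, str]]:
    """Optional TSV mapping sequence id -> (locus, gene model)."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            seq_id, locus, model = line.split("\t")[:3]
            out[seq_id] = (locus, model)
    return out
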