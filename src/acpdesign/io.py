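"""File input/output: FASTA peptide lists, CSV/TSV tables, model JSON."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AcpClassifierResults
from .peptide import Peptide


class FastaFormatError(ValueError):
    """A FASTA file could not be parsed into peptide records."""


def read_fasta(path) -> list[Peptide]:
    """Read peptides from a (multi-record) FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    peptides = []
    for rec in records:
        if len(rec.seq) == 0:
            raise FastaFormatError(f"empty sequence for record {rec.id!r}")
        peptides.append(Peptide(rec.id, str(rec.seq)))
    return peptides


def write_fasta(peptides: Iterable[Peptide], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


def read_sequence_list(path) -> list[Peptide]:
    """Read a newline-delimited plain list of sequences."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    seqs = [ln for ln in lines if ln and not ln.startswith("#")]
    if not seqs:
        raise FastaFormatError(f"no sequences found in {path}")
    return [Peptide(f"seq{k}", s) for k, s in enumerate(seqs)]


def read_peptides(path) -> list[Peptide]:
    """Read peptides from FASTA or a plain sequence list, by sniffing."""
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        return read_fasta(path)
    return read_sequence_list(path)


def read_table(path) -> pd.DataFrame:
    """Read a CSV/TSV table (delimiter by extension, header mandatory)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=index)


def save_model(results: AcpClassifierResults, path) -> None:
    results.save(path)


def load_model(path) -> AcpClassifierResults:
    return AcpClassifierResults.load(path)
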