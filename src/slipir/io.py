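"""Plain-text readers/writers shared by every stage.

FASTA and FASTQ (Phred+33) go through Biopython; count matrices are
tab-delimited with the feature ID in the first column, the RNA type in the
second, and one column per sample, written with LF line endings so a
round-trip is bit-exact.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """A malformed record in an input file."""


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(id, sequence, quality_string)`` from a Phred+33 FASTQ file.

    Raises :class:`FormatError` naming the record index on malformed input
    (e.g. sequence/quality length mismatch).
    """
    try:
        for i, (title, seq, qual) in enumerate(_fastq_iter(path)):
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}: record {i + 1} ({title!r}): sequence length "
                    f"{len(seq)} != quality length {len(qual)} (line {4 * i + 1})"
                )
            yield title.split()[0], seq.upper(), qual
    except ValueError as exc:  # Biopython parse failure
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: {exc}") from exc


def _fastq_iter(path):
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, seq, qual in records:
            if len(seq) != len(qual):
                raise FormatError(f"record {name!r}: sequence/quality length mismatch")
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def phred_scores(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


def phred_string(scores: Iterable[int]) -> str:
    return "".join(chr(min(q, 60) + 33) for q in scores)


# --- count matrix TSV -------------------------------------------------------

FEATURE_COL = "feature_id"
TYPE_COL = "rna_type"


def write_matrix_tsv(counts: pd.DataFrame, rna_types: pd.Series, path) -> None:
    """Write a features x samples integer count matrix as TSV.

    Layout: feature_id, rna_type, then one column per sample.
    """
    out = counts.copy()
    out.insert(0, TYPE_COL, rna_types.reindex(counts.index))
    out.index.name = FEATURE_COL
    with open(path, "w", newline="\n") as fh:
        out.to_csv(fh, sep="\t", lineterminator="\n")


def read_matrix_tsv(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read the TSV layout of :func:`write_matrix_tsv`.

    Returns ``(counts, rna_types)`` with integer counts and preserved
    feature order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if TYPE_COL not in df.columns:
        raise FormatError(f"{path}: missing '{TYPE_COL}' column")
    rna_types = df[TYPE_COL]
    counts = df.drop(columns=[TYPE_COL])
    try:
        counts = counts.astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer counts ({exc})") from exc
    return counts, rna_types


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Generic TSV writer with LF endings (deterministic round-trips)."""
    with open(path, "w", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")
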