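"""Demultiplexing and read trimming.

Reads are assigned to samples by exact match of the first 8 nt of R2
against the barcode table; R2 is discarded afterwards (its insert is
poly-T and uninformative).  R1 is trimmed back to the clean cfRNA insert:
the adapter (located by its first 10 nt, or a >= 6 nt prefix at the read
end) is cut together with the preceding 8-nt sample index, then the
maximal trailing poly-A run is removed.  Reads shorter than 15 nt or with
mean Phred < 20 after trimming are rejected, matching the clean-read
definition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from slipir import io as sio

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TrimSpec:
    adapter_seq: str
    barcode_table: Mapping[str, str] = field(default_factory=dict)  # barcode -> sample
    min_len: int = 15
    min_mean_q: float = 20.0
    polyA_min: int = 4
    adapter_seed_len: int = 10
    partial_min: int = 6  # min adapter-prefix length trimmed at the read end

    def __post_init__(self):
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        bcs = list(self.barcode_table)
        if len(set(bcs)) != len(bcs):
            raise ValueError("duplicate barcodes")
        for bc in bcs:
            if len(bc) != 8:
                raise ValueError(f"barcode {bc!r} is not 8 nt")


@dataclass
class TrimResult:
    insert: str | None
    qual: str | None
    reason: str | None  # None when accepted; 'too_short' | 'low_quality'

    @property
    def accepted(self) -> bool:
        return self.reason is None


def _find_adapter(seq: str, spec: TrimSpec) -> int | None:
    """Position of the adapter start in ``seq``, or None if no evidence."""
    seed = spec.adapter_seq[: spec.adapter_seed_len]
    pos = seq.find(seed)
    if pos != -1:
        return pos
    # partial adapter running off the read end
    max_k = min(len(spec.adapter_seq), len(seq), spec.adapter_seed_len - 1)
    for k in range(max_k, spec.partial_min - 1, -1):
        if seq.endswith(spec.adapter_seq[:k]):
            return len(seq) - k
    return None


def trim_read(r1_seq: str, r1_qual: str, spec: TrimSpec) -> TrimResult:
    """Trim one R1 read to its clean insert, or reject it with a reason.

    Rejections are returned (never raised): ``too_short`` for inserts
    < ``min_len`` nt, ``low_quality`` for mean Phred < ``min_mean_q``.
    """
    pos = _find_adapter(r1_seq, spec)
    if pos is not None:
        cut = max(pos - 8, 0)  # the 8-nt sample index precedes the adapter
        seq, qual = r1_seq[:cut], r1_qual[:cut]
    else:
        seq, qual = r1_seq, r1_qual
    # maximal trailing A-homopolymer, only when long enough to be the tail
    n_a = len(seq) - len(seq.rstrip("A"))
    if n_a >= spec.polyA_min:
        seq, qual = seq[: len(seq) - n_a], qual[: len(qual) - n_a]
    if len(seq) < spec.min_len:
        return TrimResult(None, None, "too_short")
    mean_q = sum(sio.phred_scores(qual)) / len(qual)
    if mean_q < spec.min_mean_q:
        return TrimResult(None, None, "low_quality")
    return TrimResult(seq, qual, None)


@dataclass
class PreprocessSummary:
    """Per-sample read accounting; totals conserve the input read count."""

    per_sample: pd.DataFrame  # index sample; columns total_reads, clean_reads, discarded_reads
    unassigned_reads: int = 0

    @property
    def total_reads(self) -> int:
        return int(self.per_sample["total_reads"].sum()) + self.unassigned_reads


def demultiplex(r1_path, r2_path, spec: TrimSpec, out_dir=None):
    """Split paired FASTQ files by the R2 barcode and trim R1 inserts.

    Returns ``(per_sample_reads, summary)`` where ``per_sample_reads`` maps
    sample id to a list of clean ``(read_id, insert, qual)`` tuples.  When
    ``out_dir`` is given, per-sample FASTQ files and a TSV summary are also
    written there.  Record-count mismatch between R1 and R2 is an error.
    """
    table = dict(spec.barcode_table)
    samples = list(table.values())
    reads: dict[str, list] = {s: [] for s in samples}
    counts = {s: Counter() for s in samples}
    unassigned = 0

    r1_iter = sio.read_fastq(r1_path)
    r2_iter = sio.read_fastq(r2_path)
    _SENTINEL = object()
    while True:
        r1 = next(r1_iter, _SENTINEL)
        r2 = next(r2_iter, _SENTINEL)
        if r1 is _SENTINEL and r2 is _SENTINEL:
            break
        if r1 is _SENTINEL or r2 is _SENTINEL:
            raise ValueError("R1/R2 files are not record-paired (count mismatch)")
        rid, r1_seq, r1_qual = r1
        barcode = r2[1][:8]
        sample = table.get(barcode)
        if sample is None:
            unassigned += 1
            continue
        counts[sample]["total_reads"] += 1
        res = trim_read(r1_seq, r1_qual, spec)
        if res.accepted:
            counts[sample]["clean_reads"] += 1
            reads[sample].append((rid, res.insert, res.qual))
        else:
            counts[sample]["discarded_reads"] += 1

    per_sample = pd.DataFrame(
        [
            {
                "sample": s,
                "total_reads": counts[s]["total_reads"],
                "clean_reads": counts[s]["clean_reads"],
                "discarded_reads": counts[s]["discarded_reads"],
            }
            for s in samples
        ]
    ).set_index("sample")
    summary = PreprocessSummary(per_sample=per_sample, unassigned_reads=unassigned)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in samples:
            sio.write_fastq(reads[s], out_dir / f"{s}.clean.fastq")
        sio.write_table(per_sample, out_dir / "preprocess_summary.tsv")
    return reads, summary
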