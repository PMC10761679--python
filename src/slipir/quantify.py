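"""Read counting and the feature x sample count matrix.

Two counting rules, mirroring the per-RNA-type workflows:

* :func:`count_exact` — tsRNA/rsRNA/ysRNA: a read counts only when it is
  100% identical (full length) to a reference entry.
* :func:`count_contained` — miRNA/piRNA and the transcript classes: a read
  of at least ``min_len`` nt counts for an entry when it is an exact sense
  substring of that entry's sequence; reads contained in more than one
  distinct feature are dropped as ambiguous (the multi-overlap discard of
  feature-level counting).

Length gates: 19 nt for miRNA, 23 nt for mRNA/lncRNA/snRNA/snoRNA, none for
piRNA.  The matrix carries RPM (columns scaled to 1e6) and log2(RPM+1)
views.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from slipir import io as sio
from slipir.reference import ReferenceSet

MIN_LEN_BY_TYPE = {
    "miRNA": 19,
    "piRNA": 0,
    "mRNA": 23,
    "lncRNA": 23,
    "snRNA": 23,
    "snoRNA": 23,
}


class CountMatrix:
    """Integer counts (features x samples) plus feature/sample metadata."""

    def __init__(self, counts: pd.DataFrame, rna_types: pd.Series,
                 sample_class: pd.Series | None = None,
                 sample_cohort: pd.Series | None = None):
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.index.duplicated().any():
            raise ValueError("duplicate feature IDs")
        self.counts = counts
        self.rna_types = rna_types.reindex(counts.index)
        self.sample_class = (
            sample_class.reindex(counts.columns) if sample_class is not None else None
        )
        self.sample_cohort = (
            sample_cohort.reindex(counts.columns) if sample_cohort is not None else None
        )

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def rpm(self) -> pd.DataFrame:
        return rpm_normalize(self.counts)

    def log2rpm(self) -> pd.DataFrame:
        return np.log2(self.rpm() + 1.0)

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(samples)],
            self.rna_types,
            self.sample_class[list(samples)] if self.sample_class is not None else None,
            self.sample_cohort[list(samples)] if self.sample_cohort is not None else None,
        )

    def to_tsv(self, path) -> None:
        sio.write_matrix_tsv(self.counts, self.rna_types, path)

    @classmethod
    def from_tsv(cls, path, sample_class: pd.Series | None = None) -> "CountMatrix":
        counts, rna_types = sio.read_matrix_tsv(path)
        return cls(counts, rna_types, sample_class)


def count_exact(reads: Iterable[str], reference: ReferenceSet) -> pd.Series:
    """Counts per entry under full-length exact identity."""
    by_seq: dict[str, str] = {}
    for e in reference.entries:
        by_seq.setdefault(e.sequence, e.id)
    tally: Counter = Counter()
    for seq in reads:
        entry_id = by_seq.get(seq)
        if entry_id is not None:
            tally[entry_id] += 1
    return pd.Series(tally, dtype=int).reindex(reference.ids(), fill_value=0)


def count_contained(reads: Iterable[str], reference: ReferenceSet, min_len: int = 0) -> pd.Series:
    """Counts per entry under exact sense containment with a length gate.

    Reads shorter than ``min_len`` are ignored; reads contained in more
    than one distinct entry are dropped as ambiguous.
    """
    distinct: Counter = Counter()
    for seq in reads:
        if len(seq) >= min_len:
            distinct[seq] += 1
    assignment: dict[str, str | None] = {}
    for seq in distinct:
        hits = [e.id for e in reference.entries if seq in e.sequence]
        assignment[seq] = hits[0] if len(hits) == 1 else None
    tally: Counter = Counter()
    for seq, n in distinct.items():
        eid = assignment[seq]
        if eid is not None:
            tally[eid] += n
    return pd.Series(tally, dtype=int).reindex(reference.ids(), fill_value=0)


def assemble_matrix(per_sample_counts: Mapping[str, Mapping[str, pd.Series]],
                    sample_class: pd.Series | None = None) -> CountMatrix:
    """Merge per-sample, per-RNA-type counts into one matrix.

    ``per_sample_counts[sample][rna_type]`` is a Series of counts per
    feature id.  Missing (feature, sample) pairs become 0.  A feature id
    appearing under two different RNA types is an error.
    """
    type_of: dict[str, str] = {}
    columns: dict[str, pd.Series] = {}
    for sample, by_type in per_sample_counts.items():
        parts = []
        for rna_type, series in by_type.items():
            for fid in series.index:
                prev = type_of.setdefault(fid, rna_type)
                if prev != rna_type:
                    raise ValueError(f"feature {fid!r} appears under types {prev!r} and {rna_type!r}")
            parts.append(series)
        columns[sample] = pd.concat(parts) if parts else pd.Series(dtype=int)
        if columns[sample].index.duplicated().any():
            raise ValueError(f"sample {sample!r}: duplicate feature IDs")
    counts = pd.DataFrame(columns).fillna(0).astype(int)
    rna_types = pd.Series({f: type_of[f] for f in counts.index}, name="rna_type")
    return CountMatrix(counts, rna_types, sample_class)


def rpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million: each column scaled to sum to 1e6."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero column total for sample(s): {', '.join(map(str, zero.index))}")
    return counts / totals * 1e6


def log2rpm(counts: pd.DataFrame) -> pd.DataFrame:
    return np.log2(rpm_normalize(counts) + 1.0)
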