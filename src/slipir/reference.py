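"""Reference sets and derived-reference construction.

The rsRNA/ysRNA reference is *derived from the data*: every distinct clean
read that occurs as an exact sense substring of a parent transcript (zero
mismatches) becomes a reference entry with a deterministic ordered ID
``{type}-{parent}-{start}-{length}``.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from slipir import io as sio


@dataclass(frozen=True)
class RefEntry:
    id: str
    rna_type: str
    sequence: str
    parent: Optional[str] = None
    parent_start: Optional[int] = None


class ReferenceSet:
    """Ordered collection of named, typed reference sequences."""

    def __init__(self, entries: Iterable[RefEntry]):
        self.entries: list[RefEntry] = list(entries)
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reference IDs")
        for e in self.entries:
            if not e.sequence:
                raise ValueError(f"entry {e.id!r}: empty sequence")
        self._by_id = {e.id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_id(self, entry_id: str) -> RefEntry:
        return self._by_id[entry_id]

    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def to_fasta(self, path) -> None:
        sio.write_fasta(((e.id, e.sequence) for e in self.entries), path)

    @classmethod
    def from_fasta(cls, path, rna_type: str) -> "ReferenceSet":
        return cls(RefEntry(id=name, rna_type=rna_type, sequence=seq) for name, seq in sio.read_fasta(path))


def build_derived_reference(reads: Iterable[str], parents: ReferenceSet, rna_type: str,
                            min_len: int = 15) -> ReferenceSet:
    """Unique read sequences that exactly match a parent, with ordered IDs.

    A fragment present in several parents (or at several positions) is
    assigned to the lexicographically first ``(parent, start)``.  Entries
    are ordered by ``(parent, start, length)``; reads matching no parent
    are silently excluded.
    """
    if len(parents) == 0:
        raise ValueError("parents must be non-empty")
    parent_list = sorted(parents.entries, key=lambda e: e.id)
    located: dict[str, tuple[str, int]] = {}
    for seq in reads:
        if len(seq) < min_len or seq in located:
            continue
        for p in parent_list:
            pos = p.sequence.find(seq)
            if pos != -1:
                located[seq] = (p.id, pos)
                break
    items = sorted(located.items(), key=lambda kv: (kv[1][0], kv[1][1], len(kv[0])))
    entries = [
        RefEntry(
            id=f"{rna_type}-{parent}-{start}-{len(seq)}",
            rna_type=rna_type,
            sequence=seq,
            parent=parent,
            parent_start=start,
        )
        for seq, (parent, start) in items
    ]
    return ReferenceSet(entries)


def coverage_profile(values_per_entry, reference: ReferenceSet, parents: ReferenceSet):
    """Per-position depth along each parent from per-entry abundances.

    ``values_per_entry`` maps entry id -> abundance (e.g. RPM);
    ``depth[parent][i]`` sums the abundance of every derived entry covering
    position ``i``.  Entries lacking parent coordinates are an error.
    """
    depth = {p.id: np.zeros(len(p.sequence)) for p in parents.entries}
    for entry_id, value in dict(values_per_entry).items():
        e = reference.by_id(entry_id)
        if e.parent is None or e.parent_start is None:
            raise ValueError(f"entry {entry_id!r} has no parent coordinates")
        depth[e.parent][e.parent_start : e.parent_start + len(e.sequence)] += value
    return depth
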