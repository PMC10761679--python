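"""Seeded synthetic-data generator for every pipeline stage.

Three generators, all deterministic given ``SimConfig.seed``:

* :func:`gen_parent_references` — random parent transcripts with the lengths
  of the human rRNA (28S/18S/5.8S/5S) and Y RNA (RNY1/3/4/5) parents.
* :func:`gen_fragment_reads` — paired-end reads with the splint-ligation
  library structure: R1 carries a sense parent fragment, a poly-A tail, an
  8-nt sample barcode and the sequencing adapter; R2 begins with the same
  barcode followed by poly-T.
* :func:`gen_count_matrix` — case/control (or multi-class) feature x sample
  count matrices with negative-binomial noise, library-size variation and
  planted log2 fold-change effects.

Fragment lengths follow a Gamma law in the shape/rate parameterisation
(alpha, beta); the defaults are the values fitted to plasma mRNA fragments
(alpha = 10.22, beta = 0.24, mean alpha/beta ~ 42.6 nt).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from slipir import io as sio

# Parent lengths mirror the human rRNA / Y RNA transcripts (nt).
DEFAULT_PARENT_LENGTHS: dict[str, int] = {
    "rRNA28S-like": 5070,
    "rRNA18S-like": 1869,
    "rRNA5.8S-like": 157,
    "rRNA5S-like": 121,
    "RNY1-like": 112,
    "RNY3-like": 102,
    "RNY4-like": 96,
    "RNY5-like": 83,
}

DEFAULT_FEATURES_PER_TYPE: dict[str, int] = {
    "mRNA": 200,
    "miRNA": 150,
    "tsRNA": 150,
    "rsRNA": 200,
    "ysRNA": 60,
    "snRNA": 60,
    "snoRNA": 60,
    "piRNA": 80,
    "lncRNA": 40,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Fragment lengths are Gamma(shape=``frag_gamma_shape``,
    rate=``frag_gamma_rate``); note the *rate* (not scale)
    parameterisation, so the mean length is shape/rate.
    """

    seed: int = 0
    n_samples_per_class: int = 50
    classes: tuple[str, ...] = ("control", "case")
    n_features_per_type: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FEATURES_PER_TYPE)
    )
    de_fraction: float = 0.05
    planted_log2fc: float = 1.5
    nb_dispersion: float = 0.2
    library_size_range: tuple[int, int] = (500_000, 2_000_000)
    frag_gamma_shape: float = 10.22
    frag_gamma_rate: float = 0.24
    barcode_length: int = 8
    adapter_seq: str = "AGATCGGAAGAGCACACGTCT"
    polyA_min: int = 4
    # read-level knobs (the assay leaves these free; see docs/methods.md)
    read_length: int = 150
    polyA_tail_range: tuple[int, int] = (10, 30)
    n_reads_per_sample: int = 2000
    low_quality_fraction: float = 0.0
    parent_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PARENT_LENGTHS)
    )
    n_common_features: int = 0  # planted in every case class (pan-cancer panel)

    def __post_init__(self):
        if len(self.classes) < 1:
            raise ValueError("at least one class required")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.frag_gamma_shape <= 0 or self.frag_gamma_rate <= 0:
            raise ValueError("Gamma shape and rate must be > 0")
        if self.barcode_length != 8:
            raise ValueError("barcode_length must be 8 (library design)")
        if any(n <= 0 for n in self.n_features_per_type.values()):
            raise ValueError("feature counts must be positive")
        if any(n <= 0 for n in self.parent_lengths.values()):
            raise ValueError("parent lengths must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid library_size_range")


@dataclass
class GroundTruth:
    """Generator-side truth used as the oracle for downstream stages."""

    sample_class: dict[str, str] = field(default_factory=dict)
    planted_features: dict[str, set[str]] = field(default_factory=dict)
    # read id -> (sample, derived reference id, insert sequence)
    read_origin: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    # true per-sample library size factors used by gen_count_matrix
    size_factors: "pd.Series | None" = None


BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def gen_parent_references(config: SimConfig):
    """Random parent transcripts, one per configured parent name.

    Returns a :class:`slipir.reference.ReferenceSet` of parents with
    deterministic sequences given ``config.seed``.
    """
    from slipir.reference import RefEntry, ReferenceSet

    rng = np.random.default_rng(config.seed)
    entries = []
    for name, length in config.parent_lengths.items():
        if length <= 0:
            raise ValueError(f"parent {name!r}: zero/negative length requested")
        rna_type = "rRNA" if name.lower().startswith("rrna") else "YRNA"
        entries.append(RefEntry(id=name, rna_type=rna_type, sequence=_random_seq(rng, length)))
    return ReferenceSet(entries)


def _draw_fragment(rng, parents, parent_ids, parent_lens, max_insert, cfg):
    """One sense fragment: parent chosen length-weighted, Gamma length."""
    weights = parent_lens / parent_lens.sum()
    pi = rng.choice(len(parent_ids), p=weights)
    plen = int(parent_lens[pi])
    length = int(round(rng.gamma(cfg.frag_gamma_shape, 1.0 / cfg.frag_gamma_rate)))
    length = max(15, min(length, plen, max_insert))
    start = int(rng.integers(0, plen - length + 1))
    pid = parent_ids[pi]
    return pid, start, length, parents.by_id(pid).sequence[start : start + length]


def gen_fragment_reads(parents, config: SimConfig, sample_barcodes: Mapping[str, str]):
    """Simulate paired reads for each sample in ``sample_barcodes``.

    R1 = insert + poly-A tail + barcode + adapter, padded with G to the read
    length (and truncated if the construct overruns it); R2 = barcode +
    poly-T. Inserts are capped so the full construct fits in one read,
    keeping every structural element present.

    Returns ``(r1_records, r2_records, truth)`` where records are
    ``(id, seq, qual)`` tuples ready for :func:`slipir.io.write_fastq`.
    """
    barcodes = list(sample_barcodes.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate sample barcodes")
    for bc in barcodes:
        if len(bc) != config.barcode_length:
            raise ValueError(f"barcode {bc!r} is not {config.barcode_length} nt")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    parent_ids = [e.id for e in parents.entries]
    parent_lens = np.array([len(e.sequence) for e in parents.entries], dtype=float)
    tail_lo, tail_hi = config.polyA_tail_range
    max_insert = config.read_length - tail_lo - config.barcode_length - 10

    truth = GroundTruth()
    r1_records, r2_records = [], []
    hi_q = "I" * config.read_length
    for sample, barcode in sample_barcodes.items():
        for j in range(config.n_reads_per_sample):
            pid, start, length, insert = _draw_fragment(
                rng, parents, parent_ids, parent_lens, max_insert, config
            )
            tail = "A" * int(rng.integers(tail_lo, tail_hi + 1))
            r1 = (insert + tail + barcode + config.adapter_seq)[: config.read_length]
            r1 = r1 + "G" * (config.read_length - len(r1))
            r2 = (barcode + "T" * config.read_length)[: config.read_length]
            if config.low_quality_fraction and rng.random() < config.low_quality_fraction:
                q1 = chr(10 + 33) * config.read_length  # mean Phred 10 < 20
            else:
                q1 = hi_q
            rid = f"{sample}:{j}"
            ref_id = f"{pid}:{start}:{length}"
            truth.read_origin[rid] = (sample, ref_id, insert)
            r1_records.append((rid, r1, q1))
            r2_records.append((rid, r2, hi_q))
    return r1_records, r2_records, truth


def write_read_pair(r1_records, r2_records, r1_path, r2_path) -> None:
    sio.write_fastq(r1_records, r1_path)
    sio.write_fastq(r2_records, r2_path)


def _feature_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    ids, types = [], []
    for rna_type, n in config.n_features_per_type.items():
        for i in range(n):
            ids.append(f"{rna_type}-{i:04d}")
            types.append(rna_type)
    return ids, types


def gen_count_matrix(config: SimConfig):
    """Case/control (or multi-class) NB count matrix with planted effects.

    The first entry of ``config.classes`` is the control class; each other
    class receives its own disjoint planted feature set, upregulated by
    ``planted_log2fc`` in samples of that class.  ``n_common_features``
    additional features are upregulated in *all* case classes (the shared
    pan-cancer signal).  Baseline means are log-normal across features;
    library sizes vary uniformly within ``library_size_range``.

    Returns ``(CountMatrix, GroundTruth)``.
    """
    from slipir.quantify import CountMatrix

    if len(config.classes) < 2:
        raise ValueError("need >= 2 classes for a count matrix")
    if config.n_samples_per_class < 3:
        raise ValueError("need >= 3 samples per class")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    ids, types = _feature_ids(config)
    n_feat = len(ids)
    samples, labels = [], []
    for cls in config.classes:
        for i in range(config.n_samples_per_class):
            samples.append(f"{cls}-{i:03d}")
            labels.append(cls)

    base = rng.lognormal(mean=np.log(60.0), sigma=1.2, size=n_feat)
    lo, hi = config.library_size_range
    lib = rng.uniform(lo, hi, size=len(samples))
    size_f = lib / lib.mean()

    case_classes = list(config.classes[1:])
    n_planted = int(round(config.de_fraction * n_feat))
    perm = rng.permutation(n_feat)
    truth = GroundTruth(
        sample_class=dict(zip(samples, labels)),
        size_factors=pd.Series(size_f, index=samples, name="size_factor"),
    )
    pos = 0
    common = [ids[k] for k in perm[:config.n_common_features]]
    pos = config.n_common_features
    for cls in case_classes:
        planted = [ids[k] for k in perm[pos : pos + n_planted]]
        pos += n_planted
        truth.planted_features[cls] = set(planted) | set(common)
    if common:
        truth.planted_features["__common__"] = set(common)

    id_index = {f: k for k, f in enumerate(ids)}
    lfc = np.zeros((n_feat, len(samples)))
    for s_idx, cls in enumerate(labels):
        if cls == config.classes[0]:
            continue
        for f in truth.planted_features.get(cls, ()):
            lfc[id_index[f], s_idx] = config.planted_log2fc

    mu = base[:, None] * size_f[None, :] * 2.0 ** lfc
    r = 1.0 / config.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    counts_df = pd.DataFrame(counts, index=ids, columns=samples)
    matrix = CountMatrix(
        counts_df,
        rna_types=pd.Series(types, index=ids, name="rna_type"),
        sample_class=pd.Series(labels, index=samples, name="class"),
    )
    return matrix, truth


def default_barcodes(n: int, seed: int = 0) -> dict[str, str]:
    """``n`` distinct 8-nt barcodes keyed by sample id S1..Sn."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    seen: set[str] = set()
    out: dict[str, str] = {}
    i = 1
    while len(out) < n:
        bc = _random_seq(rng, 8)
        if bc not in seen:
            seen.add(bc)
            out[f"S{i}"] = bc
            i += 1
    return out
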