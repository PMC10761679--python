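"""Per-sample quality control and cohort-level statistics.

Samples are excluded when any of four criteria trigger (strict
inequalities): clean-read ratio below 20%, fewer than 2 million clean
reads, rsRNA fraction above 30%, or combined lncRNA+mRNA fraction above
30%.  The module also provides transcriptome-wide Pearson reproducibility,
Gamma maximum-likelihood fragment-length fits with (non-excess) kurtosis,
and sense/antisense orientation tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from slipir.quantify import CountMatrix


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; defaults follow the published criteria.

    ``clean_reads_min`` (2e6 for real sequencing depth) scales down for
    desk-sized synthetic runs via the constructor.
    """

    clean_ratio_min_pct: float = 20.0
    clean_reads_min: int = 2_000_000
    rsrna_ratio_max_pct: float = 30.0
    lnc_mrna_ratio_max_pct: float = 30.0


def compute_qc(matrix: CountMatrix, preprocess_summary: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sample QC metrics table.

    Columns: total_reads, clean_reads, mappable_reads, per-type read sums
    (``<type>_reads``), percentage ratios of mappable reads
    (``<type>_pct``), and species-detected counts (``<type>_species``,
    RPM > 0).  When no preprocess summary is given (matrix-only runs),
    total and clean reads fall back to the column sums; "mappable" at desk
    scale means assigned by any counting workflow.
    """
    col_sums = matrix.counts.sum(axis=0)
    rows = []
    rpm = matrix.counts / col_sums.replace(0, np.nan) * 1e6
    for s in matrix.samples:
        row: dict = {"sample": s}
        if preprocess_summary is not None and s in preprocess_summary.index:
            row["total_reads"] = int(preprocess_summary.loc[s, "total_reads"])
            row["clean_reads"] = int(preprocess_summary.loc[s, "clean_reads"])
        else:
            row["total_reads"] = int(col_sums[s])
            row["clean_reads"] = int(col_sums[s])
        row["mappable_reads"] = int(col_sums[s])
        for rna_type in sorted(matrix.rna_types.unique()):
            mask = matrix.rna_types == rna_type
            type_sum = int(matrix.counts.loc[mask, s].sum())
            row[f"{rna_type}_reads"] = type_sum
            row[f"{rna_type}_pct"] = 100.0 * type_sum / col_sums[s] if col_sums[s] else 0.0
            row[f"{rna_type}_species"] = int((rpm.loc[mask, s] > 0).sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def apply_exclusion(report: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Apply the four exclusion criteria; returns the report with
    ``excluded`` and ``exclusion_reasons`` columns added.

    All comparisons are strict: a sample sitting exactly on a threshold is
    retained.
    """
    out = report.copy()
    excluded, reasons_col = [], []
    for s, row in report.iterrows():
        reasons = []
        clean_ratio = 100.0 * row["clean_reads"] / row["total_reads"] if row["total_reads"] else 0.0
        if clean_ratio < thresholds.clean_ratio_min_pct:
            reasons.append("clean_ratio")
        if row["clean_reads"] < thresholds.clean_reads_min:
            reasons.append("clean_reads")
        if row.get("rsRNA_pct", 0.0) > thresholds.rsrna_ratio_max_pct:
            reasons.append("rsrna_ratio")
        lnc_mrna = row.get("lncRNA_pct", 0.0) + row.get("mRNA_pct", 0.0)
        if lnc_mrna > thresholds.lnc_mrna_ratio_max_pct:
            reasons.append("lnc_mrna_ratio")
        excluded.append(bool(reasons))
        reasons_col.append(",".join(reasons))
    out["excluded"] = excluded
    out["exclusion_reasons"] = reasons_col
    return out


def transcriptome_correlation(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Transcriptome-wide Pearson r between two log2-RPM mean profiles,
    with the two-sided t-test p-value (n - 2 df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share the feature universe")
    if a.size < 3:
        raise ValueError("need at least 3 features")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class FragStats:
    gamma_shape: float  # alpha
    gamma_rate: float   # beta (mean = alpha/beta)
    kurtosis: float     # Pearson (non-excess) m4/m2^2
    n: int


def _gamma_mle_shape(logratio: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve log(a) - digamma(a) = logratio by Newton iteration."""
    if logratio <= 0:
        raise ValueError("degenerate sample (zero variance)")
    a = (3 - logratio + np.sqrt((logratio - 3) ** 2 + 24 * logratio)) / (12 * logratio)
    for _ in range(max_iter):
        f = np.log(a) - special.digamma(a) - logratio
        fp = 1.0 / a - special.polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2
        if abs(a_new - a) < tol * max(1.0, a):
            a = a_new
            break
        a = a_new
    return float(a)


def fragment_stats(lengths: Iterable[float]) -> FragStats:
    """Gamma MLE (shape alpha, rate beta) and non-excess kurtosis of a
    fragment-length sample.

    Raises on constant samples (the Gamma fit is degenerate).
    """
    x = np.asarray(list(lengths), dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 lengths for a Gamma fit")
    if (x <= 0).any():
        raise ValueError("lengths must be positive")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate fit: constant lengths")
    logratio = float(np.log(x.mean()) - np.mean(np.log(x)))
    shape = _gamma_mle_shape(logratio)
    rate = shape / x.mean()
    kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    return FragStats(gamma_shape=shape, gamma_rate=float(rate), kurtosis=kurt, n=int(x.size))


@dataclass(frozen=True)
class Transcript:
    """Annotated transcript fixture with exon structure on its own sequence."""

    id: str
    sequence: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open intervals

    def region_of(self, start: int, end: int) -> str:
        for lo, hi in self.exons:
            if start >= lo and end <= hi:
                return "exon"
        return "intron"


_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def orientation_tally(reads: Iterable[str], transcripts: Sequence[Transcript]) -> pd.DataFrame:
    """Sense/antisense read counts per region class (exon/intron).

    A read is sense when it occurs as a substring of a transcript, and
    antisense when its reverse complement does; unlocatable reads are
    ignored.
    """
    tally = {("exon", "sense"): 0, ("exon", "antisense"): 0,
             ("intron", "sense"): 0, ("intron", "antisense"): 0}
    for seq in reads:
        for orient, probe in (("sense", seq), ("antisense", reverse_complement(seq))):
            hit = False
            for t in transcripts:
                pos = t.sequence.find(probe)
                if pos != -1:
                    tally[(t.region_of(pos, pos + len(probe)), orient)] += 1
                    hit = True
                    break
            if hit:
                break
    df = pd.DataFrame(
        [{"region": r, "orientation": o, "reads": n} for (r, o), n in tally.items()]
    )
    return df.set_index(["region", "orientation"])
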