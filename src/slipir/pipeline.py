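"""End-to-end pipeline orchestration.

Two coupled arms, both seeded from one master seed via per-stage derived
seeds so a rerun reproduces every artifact bit-for-bit:

* read-level: simulate paired reads -> demultiplex + trim -> build the
  derived rsRNA reference -> exact-match counting -> QC report;
* cohort-level: simulate a case/control count matrix -> differential
  expression -> candidate filter -> LASSO stability selection ->
  repeated-partition classification.

Every stage writes plain-text artifacts (TSV/FASTA/FASTQ) into the output
directory and never mutates an upstream artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from slipir import io as sio
from slipir.classify import ModelConfig, repeat_harness
from slipir.diffexp import nb_wald_test
from slipir.preprocess import TrimSpec, demultiplex
from slipir.qc import QCThresholds, apply_exclusion, compute_qc
from slipir.quantify import assemble_matrix, count_exact
from slipir.reference import build_derived_reference
from slipir.select import SelectionConfig, lasso_select
from slipir.simulate import SimConfig, default_barcodes, gen_count_matrix, gen_fragment_reads, gen_parent_references, write_read_pair

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "slipir_run"
    seed: int = 0
    n_read_samples: int = 3
    n_reads_per_sample: int = 1500
    sim: SimConfig = field(default_factory=SimConfig)
    # clean-read floor scaled to synthetic library depth (2e6 at sequencing scale)
    qc_thresholds: QCThresholds = field(default_factory=lambda: QCThresholds(clean_reads_min=1000))
    selection: SelectionConfig = field(default_factory=lambda: SelectionConfig(n_repeats=20, frequency_floor=2, seed=0))
    model: ModelConfig = field(default_factory=lambda: ModelConfig(n_repeats=20, lr_cv=3, rf_trees=100))
    exclude_samples: tuple[str, ...] = ()
    subsample_reads_to: int | None = None  # optional fixed clean-read total


def _subsample(reads: list, target: int, seed: int) -> list:
    if target is None or len(reads) <= target:
        return reads
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=target, replace=False)
    return [reads[i] for i in sorted(idx)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict of in-memory artifacts.

    Raises RuntimeError naming the failing stage on any error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    stage = "setup"
    run_log: list[str] = []

    def note(msg):
        run_log.append(msg)
        log.info(msg)

    try:
        # ---- read-level arm ------------------------------------------------
        stage = "simulate_reads"
        sim = replace(config.sim, seed=config.seed, n_reads_per_sample=config.n_reads_per_sample)
        parents = gen_parent_references(sim)
        parents.to_fasta(out / "parents.fasta")
        barcodes = default_barcodes(config.n_read_samples, seed=config.seed)
        r1, r2, truth_reads = gen_fragment_reads(parents, sim, barcodes)
        write_read_pair(r1, r2, out / "reads_R1.fastq", out / "reads_R2.fastq")
        note(f"simulated {len(r1)} read pairs for {config.n_read_samples} samples (seed {config.seed})")

        stage = "preprocess"
        spec = TrimSpec(adapter_seq=sim.adapter_seq,
                        barcode_table={bc: s for s, bc in barcodes.items()},
                        polyA_min=sim.polyA_min)
        reads_by_sample, summary = demultiplex(out / "reads_R1.fastq", out / "reads_R2.fastq", spec, out_dir=out)
        note(f"demultiplexed: {summary.per_sample['clean_reads'].sum()} clean reads, "
             f"{summary.unassigned_reads} unassigned")

        stage = "reference"
        inserts = [seq for recs in reads_by_sample.values() for _, seq, _ in recs]
        derived = build_derived_reference(inserts, parents, "rsRNA")
        derived.to_fasta(out / "rsRNA_reference.fasta")
        note(f"derived reference: {len(derived)} unique fragments")

        stage = "quantify"
        per_sample = {}
        for s, recs in reads_by_sample.items():
            seqs = [seq for _, seq, _ in recs]
            seqs = _subsample(seqs, config.subsample_reads_to, config.seed + 11)
            per_sample[s] = {"rsRNA": count_exact(seqs, derived)}
        read_matrix = assemble_matrix(per_sample)
        read_matrix.to_tsv(out / "read_counts.tsv")

        stage = "qc_reads"
        qc_reads = apply_exclusion(compute_qc(read_matrix, summary.per_sample),
                                   config.qc_thresholds)
        sio.write_table(qc_reads, out / "qc_reads.tsv")

        # ---- cohort-level arm ---------------------------------------------
        stage = "simulate_cohort"
        cohort_sim = replace(config.sim, seed=config.seed + 1)
        matrix, truth_matrix = gen_count_matrix(cohort_sim)
        matrix.to_tsv(out / "cohort_counts.tsv")
        sio.write_table(matrix.sample_class.to_frame(), out / "cohort_design.tsv")

        stage = "qc_cohort"
        qc_cohort = apply_exclusion(compute_qc(matrix), config.qc_thresholds)
        drop = set(config.exclude_samples) | set(qc_cohort.index[qc_cohort["excluded"]])
        keep = [s for s in matrix.samples if s not in drop]
        if drop:
            note(f"excluding {len(drop)} samples: {sorted(drop)}")
        matrix = matrix.subset_samples(keep)
        sio.write_table(qc_cohort, out / "qc_cohort.tsv")
        matrix.to_tsv(out / "cohort_counts_retained.tsv")

        stage = "diffexp"
        case = cohort_sim.classes[1]
        control = cohort_sim.classes[0]
        de = nb_wald_test(matrix.counts, matrix.sample_class, case, control)
        sio.write_table(de.table, out / "de_table.tsv")
        note(de.summary())

        stage = "select"
        ranked = de.table.loc[de.candidates].sort_values(
            ["q", "log2FC"], ascending=[True, False]
        ).index.tolist()
        pool = ranked[:30] if len(ranked) >= 2 else de.table["q"].sort_values().index[:30].tolist()
        X = matrix.log2rpm().T[pool]
        sel_cfg = replace(config.selection, seed=config.seed + 7)
        selection = lasso_select(X, matrix.sample_class, sel_cfg)
        sel_df = pd.DataFrame({"frequency": selection.frequency,
                               "selected": selection.frequency.index.isin(selection.selected)})
        sio.write_table(sel_df, out / "selection.tsv")
        note(f"lasso selected {len(selection.selected)} of {len(pool)} candidates")

        stage = "classify"
        panel = selection.selected or pool[:5]
        model_cfg = replace(config.model, seed=config.seed + 13)
        report = repeat_harness(matrix.log2rpm().T, matrix.sample_class, panel,
                                "lr", case_label=case, config=model_cfg)
        sens, spec_ = report.sens_spec(matrix.sample_class, case)
        perf = pd.DataFrame({
            "iteration": np.arange(len(report.test_auc)),
            "train_auc": report.train_auc,
            "test_auc": report.test_auc,
        })
        sio.write_table(perf, out / "model_auc.tsv", index=False)
        sio.write_table(report.median_scores.to_frame(), out / "risk_scores.tsv")
        note(f"LR panel ({len(panel)} features): median test AUC "
             f"{float(np.median(report.test_auc)):.3f}, sens {sens:.3f}, spec {spec_:.3f}")

        artifacts.update(
            parents=parents, truth_reads=truth_reads, summary=summary,
            derived=derived, read_matrix=read_matrix, qc_reads=qc_reads,
            matrix=matrix, truth_matrix=truth_matrix, qc_cohort=qc_cohort,
            de=de, selection=selection, report=report,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "run_log.txt").write_text("\n".join(run_log) + "\n")
    return artifacts
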