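"""End-to-end orchestration: one call reproducing the full genome-level analysis.

``run_all`` executes composition metrics, ORF calling, genus/host/segment
statistics, and both similarity matrices in order, writing every module's
table plus a consolidated ``report.txt`` into the output directory.  Every
stage is logged with its parameters, and a failure aborts the run while
retaining partial outputs with a MANIFEST marking incompleteness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import composition, io, orfs, simulate, taxstats
from . import similarity as sim
from .records import HOST_CATEGORIES, SequenceRecord, TaxonomyAnnotation

__all__ = ["RunConfig", "PipelineError", "run_all", "validate_inputs"]

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "metrics.tsv",
    "orfs.gff3",
    "orf_counts.tsv",
    "genus_deviations.tsv",
    "host_comparisons.tsv",
    "segment_summary.tsv",
    "genus_architecture.tsv",
    "kmer_matrix.tsv",
    "protein_matrix.tsv",
    "report.txt",
)


@dataclass
class RunConfig:
    """Parameters of one pipeline run (inputs, thresholds, seed)."""

    fasta: str | None = None
    taxonomy: str | None = None
    synthetic: simulate.SyntheticConfig | None = None
    out_dir: str = "virotax_out"
    k: int = sim.DEFAULT_K
    tau: float = 0.20
    min_genus_members: int = 2
    min_host_n: int = 40
    min_orf_length: int = orfs.DEFAULT_MIN_ORF_NT
    start_codons: tuple[str, ...] = ("ATG",)
    min_fragment_aa: int = sim.DEFAULT_MIN_FRAGMENT_AA
    # all-pairs fragment alignment is the cost hotspot; keep the longest 20
    # fragments per genome by default
    max_fragments: int | None = 20
    n_permutations: int = 999
    seed: int = 0
    max_similarity_n: int = 500
    allow_large_similarity: bool = False


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_inputs(
    records: Sequence[SequenceRecord], annotations: Sequence[TaxonomyAnnotation]
) -> list[dict]:
    """Cross-reference and vocabulary checks; returns issues, raises nothing.

    Each issue is a dict with keys ``kind``, ``subject``, ``message``.
    """
    issues: list[dict] = []
    ann_by_acc: dict[str, TaxonomyAnnotation] = {}
    for ann in annotations:
        if ann.accession in ann_by_acc:
            issues.append(
                {"kind": "duplicate_accession", "subject": ann.accession,
                 "message": f"accession {ann.accession} appears more than once in the taxonomy table"}
            )
        ann_by_acc[ann.accession] = ann
        if ann.host_category not in HOST_CATEGORIES:
            issues.append(
                {"kind": "host_vocabulary", "subject": ann.accession,
                 "message": f"host {ann.host_category!r} outside vocabulary"}
            )
    rec_accs = set()
    for rec in records:
        if rec.accession in rec_accs:
            issues.append(
                {"kind": "duplicate_accession", "subject": rec.accession,
                 "message": f"accession {rec.accession} appears more than once in the FASTA"}
            )
        rec_accs.add(rec.accession)
        if rec.accession not in ann_by_acc:
            issues.append(
                {"kind": "missing_annotation", "subject": rec.accession,
                 "message": f"FASTA accession {rec.accession} absent from taxonomy table"}
            )
    for acc in ann_by_acc:
        if acc not in rec_accs:
            issues.append(
                {"kind": "missing_sequence", "subject": acc,
                 "message": f"taxonomy accession {acc} has no FASTA record"}
            )
    return issues


def _write_matrix(matrix: sim.SimilarityMatrix, path: Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.6f")


def run_all(config: RunConfig) -> Path:
    """Run the full analysis; returns the report directory.

    See module docstring for stage order and outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    report: list[str] = []
    stage = "load"
    try:
        if config.synthetic is not None:
            logger.info("stage load: generating synthetic cohort (seed=%d)", config.synthetic.seed)
            records, annotations, truth = simulate.generate(config.synthetic)
            io.write_fasta(records, out / "cohort.fasta")
            io.write_taxonomy_table(annotations, out / "cohort.tsv")
            truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
            written += ["cohort.fasta", "cohort.tsv", "ground_truth.tsv"]
        else:
            if not config.fasta or not config.taxonomy:
                raise ValueError("either synthetic config or fasta+taxonomy paths required")
            logger.info("stage load: reading %s / %s", config.fasta, config.taxonomy)
            records = io.read_fasta(config.fasta)
            annotations = io.read_taxonomy_table(config.taxonomy)
        assemblies = io.assemble_viruses(records, annotations)
        n_complete = sum(a.taxonomy.is_complete for a in assemblies)
        n_segmented = sum(a.is_segmented for a in assemblies)
        report.append(f"viruses: {len(assemblies)}")
        report.append(f"complete genomes: {n_complete}")
        report.append(f"segmented viruses: {n_segmented}")

        stage = "composition_metrics"
        logger.info("stage %s", stage)
        rows = composition.composition_table(assemblies)
        rows.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.6f")
        written.append("metrics.tsv")

        stage = "orf_caller"
        logger.info("stage %s: min_orf_length=%d", stage, config.min_orf_length)
        calls = [
            c
            for a in assemblies
            for segrec in a.segments
            for c in orfs.find_orfs(segrec, config.min_orf_length, config.start_codons)
        ]
        orfs.write_gff3(calls, out / "orfs.gff3")
        counts = orfs.orf_counts(assemblies, config.min_orf_length, config.start_codons)
        counts.to_csv(out / "orf_counts.tsv", sep="\t", index=False)
        written += ["orfs.gff3", "orf_counts.tsv"]
        corr = orfs.length_orf_correlation(counts)
        report.append(
            "orf-length correlation: "
            f"n={corr.n} pearson_r={corr.pearson_r:.4f} (p={corr.pearson_p:.3g}) "
            f"spearman_rho={corr.spearman_rho:.4f} (p={corr.spearman_p:.3g})"
        )

        stage = "taxonomy_stats"
        logger.info("stage %s: tau=%.3f min_genus_members=%d min_host_n=%d",
                    stage, config.tau, config.min_genus_members, config.min_host_n)
        deviations, skipped = taxstats.genus_deviations(assemblies, config.min_genus_members)
        deviations.to_csv(out / "genus_deviations.tsv", sep="\t", index=False, float_format="%.6f")
        written.append("genus_deviations.tsv")
        if len(deviations):
            frac, n_exceed = taxstats.fraction_within(deviations, config.tau)
            report.append(
                f"genus deviations: n={len(deviations)} (skipped genera: {len(skipped)}); "
                f"fraction |d| < {config.tau:.2f}: {frac:.4f} ({100 * frac:.2f}%); exceeding: {n_exceed}"
            )
        comp_rows = []
        for measure in ("length", "gc"):
            try:
                groups = taxstats.host_groups(rows, min_n=config.min_host_n, measure=measure)
            except ValueError as exc:
                logger.warning("host contrast (%s) skipped: %s", measure, exc)
                continue
            for c in taxstats.pairwise_wilcoxon(groups):
                comp_rows.append({"measure": measure, **c.__dict__})
        host_df = pd.DataFrame(
            comp_rows,
            columns=["measure", "group_a", "group_b", "n_a", "n_b",
                     "rank_sum_statistic", "p_value", "significance_code"],
        )
        host_df.to_csv(out / "host_comparisons.tsv", sep="\t", index=False, float_format="%.6g")
        written.append("host_comparisons.tsv")
        report.append(f"host contrasts computed: {len(host_df)}")
        for row in comp_rows:
            report.append(
                f"  [{row['measure']}] {row['group_a']} (n={row['n_a']}) vs "
                f"{row['group_b']} (n={row['n_b']}): p={row['p_value']:.3g} {row['significance_code']}"
            )

        summaries, seg_comp = taxstats.segment_class_summaries(assemblies)
        seg_df = pd.DataFrame(
            [
                {"class": lab, "n": s.n, "mean": s.mean, "median": s.median}
                for lab, s in summaries.items()
            ]
        )
        seg_df.to_csv(out / "segment_summary.tsv", sep="\t", index=False, float_format="%.2f")
        written.append("segment_summary.tsv")
        if seg_comp is not None:
            report.append(
                f"multiple-segments vs non-segmented lengths: p={seg_comp.p_value:.3g} "
                f"{seg_comp.significance_code}"
            )
        arch = taxstats.genus_segment_architecture(assemblies)
        arch.to_csv(out / "genus_architecture.tsv", sep="\t", index=False, float_format="%.2f")
        written.append("genus_architecture.tsv")

        stage = "similarity"
        if len(assemblies) > config.max_similarity_n and not config.allow_large_similarity:
            raise ValueError(
                f"{len(assemblies)} viruses exceeds the all-pairs similarity cap "
                f"({config.max_similarity_n}); set allow_large_similarity to override"
            )
        logger.info("stage %s: k=%d min_fragment_aa=%d", stage, config.k, config.min_fragment_aa)
        ann_map = {a.species: a.taxonomy for a in assemblies}
        kmer_m = sim.taxonomy_order(
            sim.similarity_matrix(assemblies, "nucleotide-kmer", k=config.k), ann_map
        )
        _write_matrix(kmer_m, out / "kmer_matrix.tsv")
        prot_m = sim.taxonomy_order(
            sim.similarity_matrix(
                assemblies, "protein-identity",
                min_fragment_aa=config.min_fragment_aa,
                max_fragments=config.max_fragments,
            ),
            ann_map,
        )
        _write_matrix(prot_m, out / "protein_matrix.tsv")
        written += ["kmer_matrix.tsv", "protein_matrix.tsv"]
        genus_of = {a.species: a.taxonomy.genus for a in assemblies}
        multi = {g for g in genus_of.values() if sum(v == g for v in genus_of.values()) >= 2}
        if len(multi) >= 2:
            for label, matrix in (("nucleotide", kmer_m), ("protein", prot_m)):
                contrast, p = sim.clustering_contrast(
                    matrix, genus_of, n_permutations=config.n_permutations, seed=config.seed
                )
                report.append(
                    f"clustering contrast ({label}, genus grouping): {contrast:.4f} (p={p:.3g})"
                )
        else:
            logger.warning("clustering contrast skipped: fewer than 2 multi-member genera")

        stage = "report"
        params = (
            f"parameters: k={config.k} tau={config.tau} min_genus_members={config.min_genus_members} "
            f"min_host_n={config.min_host_n} min_orf_length={config.min_orf_length} "
            f"min_fragment_aa={config.min_fragment_aa} seed={config.seed}"
        )
        (out / "report.txt").write_text(params + "\n" + "\n".join(report) + "\n")
        written.append("report.txt")
        (out / "MANIFEST").write_text("\n".join(["status: complete", *written]) + "\n")
        return out
    except PipelineError:
        raise
    except Exception as exc:
        (out / "MANIFEST").write_text(
            "\n".join([f"status: INCOMPLETE (stage {stage} failed: {exc})", *written]) + "\n"
        )
        raise PipelineError(stage, exc) from exc
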