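"""Orchestrate simulate -> map -> annotate -> metrics -> express as one
reproducible run, and score annotations against planted truth."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .annotator import annotate_locus, infer_jc_clusters
from .expression_call import calls_from_annotation
from .io_formats import (Feature, RunConfig, SequenceRecord, write_fasta,
                         write_gff3, write_intervals)
from .locus_metrics import ac_matrix, count_motif_windows, redundancy_summary
from .synthetic_locus import (LocusBlueprint, SyntheticTruth, assemble_locus,
                              extract_reference_set, simulate_reads)

logger = logging.getLogger("igloci")

SEGMENT_CLASSES = ("V_segment", "D_segment", "J_segment", "C_gene")


@dataclass
class ClassScore:
    tp: int = 0
    fn: int = 0
    fp: int = 0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0


@dataclass
class EvaluationReport:
    """Recall/precision per feature class (coordinate tolerance +-5 bp),
    functionality confusion matrix over matched features, and planted vs
    recovered cassette counts."""

    per_class: dict[str, ClassScore] = field(default_factory=dict)
    confusion: dict[str, dict[str, int]] = field(default_factory=dict)
    clusters_planted: int = 0
    clusters_recovered: int = 0
    matches: list[tuple[str, str]] = field(default_factory=list)

    @property
    def overall_recall(self) -> float:
        tp = sum(s.tp for s in self.per_class.values())
        fn = sum(s.fn for s in self.per_class.values())
        return tp / (tp + fn) if (tp + fn) else 1.0

    @property
    def overall_precision(self) -> float:
        tp = sum(s.tp for s in self.per_class.values())
        fp = sum(s.fp for s in self.per_class.values())
        return tp / (tp + fp) if (tp + fp) else 1.0

    def label_accuracy(self) -> float:
        total = sum(sum(row.values()) for row in self.confusion.values())
        good = sum(self.confusion.get(k, {}).get(k, 0)
                   for k in ("functional", "pseudogene"))
        return good / total if total else 1.0

    def to_dict(self) -> dict:
        return {
            "per_class": {k: asdict(v) | {"recall": v.recall,
                                          "precision": v.precision}
                          for k, v in self.per_class.items()},
            "confusion": self.confusion,
            "clusters_planted": self.clusters_planted,
            "clusters_recovered": self.clusters_recovered,
            "overall_recall": self.overall_recall,
            "overall_precision": self.overall_precision,
            "functionality_accuracy": self.label_accuracy(),
        }


def evaluate_against_truth(annotation: list[Feature],
                           truth: SyntheticTruth,
                           tolerance: int = 5,
                           classes: tuple[str, ...] = SEGMENT_CLASSES
                           ) -> EvaluationReport:
    """Greedy 1-to-1 matching of annotation to truth by overlap within each
    class; a feature whose boundaries deviate more than the tolerance is an
    FP+FN pair."""
    truth_feats = [f for f in truth.features if f.type in classes]
    ann_feats = [f for f in annotation if f.type in classes]
    truth_ids = {f.seq_id for f in truth_feats}
    ann_ids = {f.seq_id for f in ann_feats}
    if truth_ids and ann_ids and not truth_ids & ann_ids:
        raise ValueError(f"genome id mismatch: truth on {sorted(truth_ids)}, "
                         f"annotation on {sorted(ann_ids)}")
    report = EvaluationReport(
        per_class={c: ClassScore() for c in classes},
        clusters_planted=len(infer_jc_clusters(truth.features)),
        clusters_recovered=len(infer_jc_clusters(annotation)))

    for cls in classes:
        t_feats = [f for f in truth_feats if f.type == cls]
        a_feats = [f for f in ann_feats if f.type == cls]
        candidates = []
        for ti, t in enumerate(t_feats):
            for ai, a in enumerate(a_feats):
                if a.seq_id != t.seq_id or a.strand != t.strand:
                    continue
                if abs(a.start - t.start) > tolerance or \
                        abs(a.end - t.end) > tolerance:
                    continue
                overlap = min(a.end, t.end) - max(a.start, t.start) + 1
                candidates.append((-overlap, ti, ai))
        used_t: set[int] = set()
        used_a: set[int] = set()
        for _neg, ti, ai in sorted(candidates):
            if ti in used_t or ai in used_a:
                continue
            used_t.add(ti)
            used_a.add(ai)
            t, a = t_feats[ti], a_feats[ai]
            report.matches.append((t.attributes.get("ID", str(t.start)),
                                   a.attributes.get("ID", str(a.start))))
            t_label = t.attributes.get("functionality")
            a_label = a.attributes.get("functionality")
            if t_label and a_label:
                row = report.confusion.setdefault(t_label, {})
                row[a_label] = row.get(a_label, 0) + 1
        score = report.per_class[cls]
        score.tp = len(used_t)
        score.fn = len(t_feats) - len(used_t)
        score.fp = len(a_feats) - len(used_a)
    return report


def cassette_spans(features: list[Feature]) -> list[tuple[str, Feature, Feature]]:
    """(label, first-J, C) per inferred cassette, in cluster order."""
    out = []
    for idx, (js, c) in enumerate(infer_jc_clusters(features), start=1):
        first = min(js + [c], key=lambda f: f.start)
        last = max(js + [c], key=lambda f: f.end)
        out.append((f"cluster_{idx:02d}", first, last))
    return out


def extract_cassette_sequences(features: list[Feature],
                               genome: list[SequenceRecord]
                               ) -> list[tuple[str, str]]:
    seqs = {r.id: r.seq for r in genome}
    out = []
    for label, first, last in cassette_spans(features):
        out.append((label, seqs[first.seq_id][first.start0:last.end0]))
    return out


def run_pipeline(blueprint: LocusBlueprint, config: RunConfig,
                 out_dir: str | Path, divergence: float = 0.0) -> dict:
    """One end-to-end reproducible run; deterministic given the seeds.

    Writes genome, truth, reads, annotation, AC matrix, RGYW profile,
    expression table and the truth-evaluation report under ``out_dir`` and
    returns the evaluation plus summary numbers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config: %s", json.dumps(asdict(config), sort_keys=True))
        logger.info("blueprint: %s", json.dumps(asdict(blueprint),
                                                sort_keys=True))
        genome, truth = assemble_locus(blueprint)
        logger.info("simulate: %d records, %d features, %d bp",
                    len(genome), len(truth.features),
                    sum(len(r.seq) for r in genome))
        write_fasta(genome, out / "genome.fasta")
        write_gff3(truth.features, out / "truth.gff3")
        rng = np.random.default_rng(config.rng_seed + 1)
        reads = simulate_reads(truth, genome, rng)
        write_intervals(reads, out / "reads.bed")

        refs = extract_reference_set(truth, genome,
                                     np.random.default_rng(config.rng_seed + 2),
                                     divergence=divergence)
        logger.info("refs: %d unique (divergence %.3f)", len(refs), divergence)
        annotation = annotate_locus(genome, refs, config)
        write_gff3(annotation, out / "annotation.gff3")
        logger.info("annotate: %d features (score thresholds V/C=%d J=%d D=%d)",
                    len(annotation), config.score_threshold,
                    config.j_score_threshold, config.d_score_threshold)

        report = evaluate_against_truth(annotation, truth)
        (out / "evaluation.json").write_text(
            json.dumps(report.to_dict(), indent=2))

        summary: dict = {"evaluation": report.to_dict()}
        cassettes = extract_cassette_sequences(annotation, genome)
        if cassettes:
            mat = ac_matrix(cassettes, config)
            mat.to_dataframe().to_csv(out / "ac_matrix.tsv", sep="\t")
            summary["ac_min"] = float(mat.ac.min())
            offd = mat.off_diagonal()
            summary["ac_offdiag_mean"] = float(offd.mean()) if offd.size else None
            region_start = min(f.start0 for _, f, _l in cassette_spans(annotation))
            region_end = max(l.end0 for _, _f, l in cassette_spans(annotation))
            seqs = {r.id: r.seq for r in genome}
            region = seqs[truth.genome_id][region_start:region_end]
            profile = count_motif_windows(region, window=config.window_size)
            (out / "rgyw_profile.tsv").write_text(
                "window\tcount\n" + "\n".join(f"{i}\t{c}"
                                              for i, c in
                                              enumerate(profile.counts)) + "\n")
            summary["rgyw_windows"] = profile.counts
        j_aas = [f.attributes.get("j_aa", "") for f in annotation
                 if f.type == "J_segment"]
        j_aas = [a for a in j_aas if a]
        if j_aas:
            red = redundancy_summary(j_aas)
            summary["j_redundancy"] = {"n": red.n_sequences,
                                       "unique": red.n_unique,
                                       "singletons": red.n_singletons}
        calls = calls_from_annotation(annotation, reads,
                                      config.expression_read_threshold)
        with open(out / "expression.tsv", "w") as fh:
            fh.write("gene_id\tread_count\texpressed\n")
            for c in calls:
                fh.write(f"{c.gene_id}\t{c.read_count}\t"
                         f"{'true' if c.expressed else 'false'}\n")
        summary["n_expressed"] = sum(c.expressed for c in calls)
        summary["n_genes_called"] = len(calls)
        logger.info("evaluate: recall=%.4f precision=%.4f clusters=%d/%d",
                    report.overall_recall, report.overall_precision,
                    report.clusters_recovered, report.clusters_planted)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
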