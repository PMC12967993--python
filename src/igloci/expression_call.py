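"""Expression calls from read evidence: a gene is expressed when more than
``threshold`` reads (default 10, strict inequality) overlap its exons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Feature


@dataclass(frozen=True)
class ExpressionCall:
    gene_id: str
    read_count: int
    expressed: bool


def count_overlapping_reads(exons: list[tuple[int, int]],
                            reads: list[tuple[int, int]]) -> int:
    """Reads overlapping >=1 bp of >=1 exon; each read counted once per
    gene.  All intervals are 0-based half-open, so a read exactly abutting
    an exon end does not count."""
    if not exons or not reads:
        return 0
    rs = np.fromiter((r[0] for r in reads), dtype=np.int64, count=len(reads))
    re_ = np.fromiter((r[1] for r in reads), dtype=np.int64, count=len(reads))
    hit = np.zeros(len(reads), dtype=bool)
    for es, ee in exons:
        if not 0 <= es < ee:
            raise ValueError(f"degenerate exon {es}..{ee}")
        hit |= (rs < ee) & (re_ > es)
    return int(hit.sum())


def gene_exons(feature: Feature) -> list[tuple[int, int]]:
    """0-based half-open exon intervals of an annotated gene feature."""
    if "exons" in feature.attributes:
        out = []
        for span in feature.attributes["exons"].split(","):
            s, e = (int(x) for x in span.split("-"))
            out.append((s - 1, e))
        return out
    return [(feature.start0, feature.end0)]


def call_expression(genes: list[tuple[str, str, list[tuple[int, int]]]],
                    reads: list[tuple[str, int, int]],
                    threshold: int = 10) -> list[ExpressionCall]:
    """Per-gene calls; ``genes`` is (gene_id, seq_id, exons), ``reads`` is
    BED-style (seq_id, start0, end0).  Strictly more than ``threshold``
    overlapping reads makes a gene expressed (count 10 -> silent, 11 ->
    expressed under the default rule)."""
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for seq_id, s0, e0 in reads:
        by_seq.setdefault(seq_id, []).append((s0, e0))
    calls = []
    for gene_id, seq_id, exons in genes:
        n = count_overlapping_reads(exons, by_seq.get(seq_id, []))
        calls.append(ExpressionCall(gene_id, n, n > threshold))
    return calls


def calls_from_annotation(features: list[Feature],
                          reads: list[tuple[str, int, int]],
                          threshold: int = 10) -> list[ExpressionCall]:
    genes = [(f.attributes.get("ID", f"{f.type}@{f.start}"), f.seq_id,
              gene_exons(f))
             for f in features
             if f.type in ("V_segment", "D_segment", "J_segment", "C_gene")]
    return call_expression(genes, reads, threshold)
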