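"""Reciprocal-best-hit comparison of two assemblies' gene sets.

Genes lacking best-match reciprocity between assemblies flag putative
allelic variation, copy-number variation, or both; this module only counts,
the interpretation is the caller's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import RunConfig, SequenceRecord
from .segment_mapper import sw_full
from ._seq import revcomp


@dataclass
class RBHReport:
    pairs: list[tuple[str, str, int, int]]  # (gene_a, gene_b, score_ab, score_ba)
    unpaired_a: list[str]
    unpaired_b: list[str]
    ratio_a: float | None = None  # functional/pseudogene ratio per set
    ratio_b: float | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _score_matrix(set_a: list[SequenceRecord], set_b: list[SequenceRecord],
                  config: RunConfig) -> np.ndarray:
    """All-vs-all local alignment scores (best of both strands)."""
    scores = np.zeros((len(set_a), len(set_b)), dtype=np.int64)
    for i, a in enumerate(set_a):
        rc = revcomp(a.seq)
        for j, b in enumerate(set_b):
            scores[i, j] = max(sw_full(a.seq, b.seq, config),
                               sw_full(rc, b.seq, config))
    return scores


def _best_per_row(scores: np.ndarray, ids: list[str],
                  threshold: int) -> list[tuple[str, int] | None]:
    out: list[tuple[str, int] | None] = []
    order = sorted(range(len(ids)), key=lambda j: ids[j])
    for row in scores:
        best = None
        for j in order:  # lexicographic tie-break: first id at max score wins
            s = int(row[j])
            if s >= threshold and (best is None or s > best[1]):
                best = (ids[j], s)
        out.append(best)
    return out


def best_hits(set_a: list[SequenceRecord], set_b: list[SequenceRecord],
              config: RunConfig | None = None
              ) -> dict[str, tuple[str, int] | None]:
    """Per query in A, the best-scoring target in B (ties: lexicographic
    target id); queries with no hit above the score threshold map to None."""
    config = config or RunConfig()
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    scores = _score_matrix(set_a, set_b, config)
    bests = _best_per_row(scores, [b.id for b in set_b],
                          config.score_threshold)
    return {a.id: best for a, best in zip(set_a, bests)}


def functionality_ratio(labels: dict[str, str] | None) -> float | None:
    if not labels:
        return None
    n_f = sum(1 for v in labels.values() if v == "functional")
    n_p = sum(1 for v in labels.values() if v == "pseudogene")
    return n_f / n_p if n_p else float("inf")


def reciprocal_pairs(set_a: list[SequenceRecord],
                     set_b: list[SequenceRecord],
                     config: RunConfig | None = None,
                     labels_a: dict[str, str] | None = None,
                     labels_b: dict[str, str] | None = None) -> RBHReport:
    """(a, b) is a pair iff best(a) = b and best(b) = a; everything else is
    reported unpaired."""
    config = config or RunConfig()
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    scores = _score_matrix(set_a, set_b, config)
    ids_a = [a.id for a in set_a]
    ids_b = [b.id for b in set_b]
    best_ab = _best_per_row(scores, ids_b, config.score_threshold)
    best_ba = _best_per_row(scores.T, ids_a, config.score_threshold)
    best_ba_by_id = dict(zip(ids_b, best_ba))
    pairs: list[tuple[str, str, int, int]] = []
    paired_a: set[str] = set()
    paired_b: set[str] = set()
    for a_id, best in zip(ids_a, best_ab):
        if best is None:
            continue
        b_id, s_ab = best
        back = best_ba_by_id.get(b_id)
        if back is not None and back[0] == a_id:
            pairs.append((a_id, b_id, s_ab, back[1]))
            paired_a.add(a_id)
            paired_b.add(b_id)
    return RBHReport(
        pairs=sorted(pairs),
        unpaired_a=sorted(i for i in ids_a if i not in paired_a),
        unpaired_b=sorted(i for i in ids_b if i not in paired_b),
        ratio_a=functionality_ratio(labels_a),
        ratio_b=functionality_ratio(labels_b))
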