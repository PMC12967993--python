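"""Locus-scale statistics: RGYW switch-region profiling, J-C cassette
alignment-coverage matrices, and amino-acid redundancy summaries."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import IUPAC_SETS, encode_dna
from .io_formats import RunConfig
from .segment_mapper import seed_extend_hits
from .synthetic_locus import n_windows

RGYW = "RGYW"


@dataclass
class MotifWindowProfile:
    """Per-window counts of motif start positions over a region.

    A match is credited to the window containing its start even when it
    spans the boundary; overlapping occurrences all count; the given strand
    only is scanned (the reverse-strand mirror of RGYW, WRCY, is a distinct
    biological motif).
    """

    window_size: int
    counts: list[int]
    motif: str = RGYW

    @property
    def total(self) -> int:
        return int(sum(self.counts))


def motif_start_positions(seq: str, motif: str) -> np.ndarray:
    """All (overlapping) start positions of an IUPAC motif, forward strand.

    Ambiguous bases in the scanned sequence never match: only concrete
    A/C/G/T bases inside the motif's allowed set count.
    """
    motif = motif.upper()
    k = len(motif)
    if k == 0:
        raise ValueError("empty motif")
    for code in motif:
        if code not in IUPAC_SETS:
            raise ValueError(f"unknown IUPAC code {code!r}")
    L = len(seq)
    if L < k:
        return np.zeros(0, dtype=np.int64)
    enc = encode_dna(seq.upper())
    ok = np.ones(L - k + 1, dtype=bool)
    for j, code in enumerate(motif):
        allowed = np.zeros(5, dtype=bool)
        for base in IUPAC_SETS[code]:
            if base in "ACGT":
                allowed["ACGT".index(base)] = True
        ok &= allowed[enc[j:L - k + 1 + j]]
    return np.flatnonzero(ok)


def count_motif_windows(seq: str, motif: str = RGYW,
                        window: int = 2500) -> MotifWindowProfile:
    """Motif start counts in non-overlapping windows tiled from position 0."""
    if window < len(motif):
        raise ValueError("window smaller than the motif")
    if not seq:
        return MotifWindowProfile(window, [], motif)
    starts = motif_start_positions(seq, motif)
    nw = n_windows(len(seq), window)
    counts = np.bincount(starts // window, minlength=nw)
    return MotifWindowProfile(window, [int(c) for c in counts], motif)


def cluster_alignment_coverage(query: str, target: str,
                               config: RunConfig | None = None) -> float:
    """Alignment coverage (AC): percentage of query bases covered by at
    least one local alignment whose identity meets the threshold.

    Local alignments come from the mapper's seed-and-extend engine on both
    strands; blocks below the mapper's significance score are ignored;
    overlapping covered stretches count once.  AC is query-relative and
    therefore not symmetric.
    """
    config = config or RunConfig()
    if not query:
        raise ValueError("empty query cassette")
    if not target:
        raise ValueError("empty target cassette")
    hits = seed_extend_hits(query, target, config,
                            min_score=config.score_threshold)
    covered = np.zeros(len(query), dtype=bool)
    for h in hits:
        if h.identity < config.ac_identity_threshold:
            continue
        if h.strand == "+":
            covered[h.q_start:h.q_end] = True
        else:
            covered[len(query) - h.q_end:len(query) - h.q_start] = True
    return 100.0 * float(covered.sum()) / len(query)


@dataclass
class ClusterACMatrix:
    labels: list[str]
    ac: np.ndarray  # percentages in [0, 100], row = query cassette
    identity_threshold: float = 0.95

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.ac, index=self.labels, columns=self.labels)

    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(len(self.labels), dtype=bool)
        return self.ac[mask]


def ac_matrix(cassettes: list[tuple[str, str]],
              config: RunConfig | None = None) -> ClusterACMatrix:
    """Pairwise AC for all ordered (query, target) cassette pairs."""
    config = config or RunConfig()
    if not cassettes:
        raise ValueError("need at least one cassette")
    labels = [name for name, _ in cassettes]
    n = len(cassettes)
    ac = np.zeros((n, n), dtype=float)
    for i, (_, qseq) in enumerate(cassettes):
        for j, (_, tseq) in enumerate(cassettes):
            ac[i, j] = cluster_alignment_coverage(qseq, tseq, config)
    return ClusterACMatrix(labels, ac, config.ac_identity_threshold)


@dataclass
class RedundancySummary:
    n_sequences: int
    n_unique: int
    table: list[tuple[str, int]]  # descending count, then sequence
    n_singletons: int

    def fraction(self, seq: str) -> float:
        counts = dict(self.table)
        return counts.get(seq, 0) / self.n_sequences if self.n_sequences else 0.0


def redundancy_summary(aa_sequences: list[str]) -> RedundancySummary:
    """Exact-match grouping after upper-casing and whitespace trimming."""
    normalized = [s.strip().upper() for s in aa_sequences]
    counter = Counter(normalized)
    table = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    singles = sum(1 for _, c in counter.items() if c == 1)
    return RedundancySummary(len(normalized), len(counter), table, singles)
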