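"""Locate reference segments on a genome with a native seed-and-extend
banded Smith-Waterman aligner, plus a two-exon spliced model for V genes.

The mapper replaces the usual external homology-search stage with a fully
deterministic in-package engine: exact k-mer seeds on both strands, banded
affine-gap local extension, colinear chaining of leader + V-exon hits across
a GT..AG intron, and a collapse rule that reports each genomic locus once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import encode_dna, revcomp
from ._swcore import sw_band, sw_band_score
from .io_formats import RunConfig, SequenceRecord

_OPS = "=XID"


@dataclass(frozen=True)
class SeedMatch:
    """Exact k-mer match; for '-' seeds ``query_pos`` indexes the
    reverse-complemented query."""

    query_pos: int
    target_pos: int
    k: int
    strand: str


@dataclass
class AlignmentHit:
    query_id: str
    target_id: str
    strand: str
    score: int
    identity: float
    query_coverage: float
    cigar: list[tuple[str, int]]
    q_start: int  # 0-based half-open, aligned-orientation query coordinates
    q_end: int
    t_start: int  # 0-based half-open, forward-genome coordinates
    t_end: int


@dataclass
class ReferenceSegment:
    """A known segment sequence used as a mapping query."""

    id: str
    seq: str
    segment_class: str  # V | D | J | C
    chain: str = "heavy"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.segment_class not in ("V", "D", "J", "C"):
            raise ValueError(f"unknown segment class {self.segment_class!r}")


@dataclass
class Intron:
    start: int  # 0-based half-open, forward-genome coordinates
    end: int
    donor: str  # dinucleotides on the gene strand
    acceptor: str
    canonical: bool

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModelDraft:
    query_id: str
    target_id: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, genome-forward, 5'->3'
    introns: list[Intron] = field(default_factory=list)
    score: int = 0
    hits: list[AlignmentHit] = field(default_factory=list)
    long_intron: bool = False

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)


def _runs(ops: np.ndarray) -> list[tuple[str, int]]:
    cigar: list[tuple[str, int]] = []
    for op in ops:
        sym = _OPS[op]
        if cigar and cigar[-1][0] == sym:
            cigar[-1] = (sym, cigar[-1][1] + 1)
        else:
            cigar.append((sym, 1))
    return cigar


def score_from_cigar(cigar: list[tuple[str, int]], config: RunConfig) -> int:
    """Recompute a hit score from its operation list (invariant check)."""
    score = 0
    for sym, length in cigar:
        if sym == "=":
            score += config.match * length
        elif sym == "X":
            score += config.mismatch * length
        elif sym in ("I", "D"):
            score += config.gap_open + config.gap_extend * length
        else:
            raise ValueError(f"unknown cigar op {sym!r}")
    return score


def align_local(query: str, target: str, dlo: int, dhi: int,
                config: RunConfig):
    """Run the banded kernel; returns (score, qs, qe, ts, te, ops)."""
    q = encode_dna(query)
    t = encode_dna(target)
    dlo = max(dlo, -len(query))
    dhi = min(dhi, len(target))
    if dlo > dhi:
        raise ValueError("empty diagonal band")
    return sw_band(q, t, dlo, dhi, config.match, config.mismatch,
                   config.gap_open + config.gap_extend, config.gap_extend)


def sw_full(a: str, b: str, config: RunConfig | None = None) -> int:
    """Unconstrained local alignment score (band spans every diagonal)."""
    config = config or RunConfig()
    return int(sw_band_score(encode_dna(a), encode_dna(b), -len(a), len(b),
                             config.match, config.mismatch,
                             config.gap_open + config.gap_extend,
                             config.gap_extend))


class KmerIndex:
    """Hash of every ACGT k-mer position in a target sequence."""

    def __init__(self, target: str, k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.target = target
        index: dict[str, list[int]] = {}
        for i in range(len(target) - k + 1):
            kmer = target[i:i + k]
            if "A" <= min(kmer) and max(kmer) <= "T" and set(kmer) <= set("ACGT"):
                index.setdefault(kmer, []).append(i)
        self._index = index

    def lookup(self, kmer: str) -> list[int]:
        return self._index.get(kmer, [])


def find_seeds(query: str, target: str, k: int,
               index: KmerIndex | None = None) -> list[SeedMatch]:
    """All exact k-mer matches of the query on both target strands.

    '+' seeds satisfy query[qp:qp+k] == target[tp:tp+k]; '-' seeds satisfy
    revcomp(query)[qp:qp+k] == target[tp:tp+k].
    """
    if k > len(query):
        raise ValueError(f"seed length {k} exceeds query length {len(query)}")
    if index is None:
        index = KmerIndex(target, k)
    elif index.k != k:
        raise ValueError("index built with a different k")
    seeds: list[SeedMatch] = []
    for strand, qseq in (("+", query.upper()), ("-", revcomp(query.upper()))):
        for qp in range(len(qseq) - k + 1):
            for tp in index.lookup(qseq[qp:qp + k]):
                seeds.append(SeedMatch(qp, tp, k, strand))
    return seeds


def _hit_from_kernel(raw, query_len: int, window_start: int, strand: str,
                     query_id: str, target_id: str) -> AlignmentHit | None:
    score, qs, qe, ts, te, ops = raw
    if score <= 0 or len(ops) == 0:
        return None
    matches = int(np.count_nonzero(ops == 0))
    cigar = _runs(ops)
    return AlignmentHit(
        query_id=query_id, target_id=target_id, strand=strand,
        score=int(score), identity=matches / len(ops),
        query_coverage=(qe - qs) / query_len, cigar=cigar,
        q_start=int(qs), q_end=int(qe),
        t_start=window_start + int(ts), t_end=window_start + int(te))


def _extend_window(query: str, target: str, dmin: int, dmax: int,
                   qmin: int, qmax: int, band: int, strand: str,
                   config: RunConfig, query_id: str = "q",
                   target_id: str = "t") -> AlignmentHit | None:
    """Extend a diagonal cluster: align the query against a trimmed target
    window allowing diagonals [dmin-band, dmax+band]."""
    pad = band + 8
    wlo = max(0, dmin - pad)
    whi = min(len(target), dmax + len(query) + pad)
    if whi <= wlo:
        return None
    window = target[wlo:whi]
    raw = align_local(query, window, dmin - wlo - band, dmax - wlo + band,
                      config)
    return _hit_from_kernel(raw, len(query), wlo, strand, query_id, target_id)


def extend_banded_sw(query: str, target: str, seed: SeedMatch, band: int,
                     config: RunConfig | None = None,
                     query_id: str = "q", target_id: str = "t"
                     ) -> AlignmentHit | None:
    """Banded local extension of one seed.

    The alignment is constrained to diagonals within +-band of the seed
    diagonal; with band >= max(len(query), len(target)) this equals
    unconstrained Smith-Waterman.
    """
    config = config or RunConfig()
    qseq = query.upper() if seed.strand == "+" else revcomp(query.upper())
    diag = seed.target_pos - seed.query_pos
    if band >= max(len(query), len(target)):
        raw = align_local(qseq, target, -len(qseq), len(target), config)
        return _hit_from_kernel(raw, len(qseq), 0, seed.strand,
                                query_id, target_id)
    return _extend_window(qseq, target, diag, diag, seed.query_pos,
                          seed.query_pos, band, seed.strand, config,
                          query_id, target_id)


def _cluster_seeds(seeds: list[SeedMatch], band: int
                   ) -> list[tuple[int, int, int, int]]:
    """Group seeds into diagonal clusters -> (dmin, dmax, qmin, qmax)."""
    if not seeds:
        return []
    diags = sorted((s.target_pos - s.query_pos, s.query_pos) for s in seeds)
    clusters: list[tuple[int, int, int, int]] = []
    dmin, dmax = diags[0][0], diags[0][0]
    qmin = qmax = diags[0][1]
    for d, qp in diags[1:]:
        if d - dmax <= band:
            dmax = d
            qmin = min(qmin, qp)
            qmax = max(qmax, qp)
        else:
            clusters.append((dmin, dmax, qmin, qmax))
            dmin = dmax = d
            qmin = qmax = qp
    clusters.append((dmin, dmax, qmin, qmax))
    return clusters


def seed_extend_hits(query: str, target: str, config: RunConfig,
                     query_id: str = "q", target_id: str = "t",
                     index: KmerIndex | None = None,
                     min_score: int = 1) -> list[AlignmentHit]:
    """All seed-cluster local alignments of query vs target, both strands."""
    query = query.upper()
    if len(query) < config.seed_k:
        return []
    seeds = find_seeds(query, target, config.seed_k, index=index)
    hits: list[AlignmentHit] = []
    seen: set[tuple] = set()
    for strand in ("+", "-"):
        qseq = query if strand == "+" else revcomp(query)
        strand_seeds = [s for s in seeds if s.strand == strand]
        for dmin, dmax, qmin, qmax in _cluster_seeds(strand_seeds, config.band):
            hit = _extend_window(qseq, target, dmin, dmax, qmin, qmax,
                                 config.band, strand, config,
                                 query_id, target_id)
            if hit is None or hit.score < min_score:
                continue
            key = (strand, hit.t_start, hit.t_end, hit.q_start, hit.q_end)
            if key not in seen:
                seen.add(key)
                hits.append(hit)
    return hits


def _shift_to_splice(genome: str, pos: int, dinuc: str, max_shift: int
                     ) -> tuple[int, bool]:
    """Smallest |d| <= max_shift such that genome[pos+d : pos+d+2] == dinuc."""
    for d in sorted(range(-max_shift, max_shift + 1), key=lambda x: (abs(x), x)):
        if 0 <= pos + d and pos + d + 2 <= len(genome) \
                and genome[pos + d:pos + d + 2] == dinuc:
            return d, True
    return 0, False


def _tpos_at_query(hit: AlignmentHit, qj: int) -> int:
    """Target coordinate aligned at query position qj (within the hit)."""
    q, t = hit.q_start, hit.t_start
    for sym, ln in hit.cigar:
        if q == qj:
            return t  # stop before a target-gap run at the boundary
        if sym in "=X":
            if q + ln > qj:
                return t + (qj - q)
            q += ln
            t += ln
        elif sym == "I":
            if q + ln > qj:
                return t
            q += ln
        elif sym == "D":
            t += ln
    return t


# Local extension can creep a few score-positive chance columns past a true
# exon boundary; exon hits may therefore overlap on the query by more than
# the chaining gap allowance.  Junctions inside such overlaps are resolved by
# scanning for an exact GT..AG intron.
MAX_EXON_OVERLAP = 48


def _score_up_to(hit: AlignmentHit, qj: int, config: RunConfig) -> int:
    """Score of the hit's columns up to query position qj."""
    score = 0
    q = hit.q_start
    for sym, ln in hit.cigar:
        if sym in "=X":
            take = min(ln, max(0, qj - q))
            score += (config.match if sym == "=" else config.mismatch) * take
            q += ln
        elif sym == "I":
            take = min(ln, max(0, qj - q))
            if take:
                score += config.gap_open + config.gap_extend * take
            q += ln
        elif sym == "D" and q < qj:
            score += config.gap_open + config.gap_extend * ln
        if q >= qj:
            break
    return score


def _resolve_junction(a: AlignmentHit, b: AlignmentHit, genome: str,
                      config: RunConfig) -> tuple[int, int, bool] | None:
    """Choose the intron [t1, t2) between two colinear exon hits.

    Candidate junction points inside the hits' query overlap are screened
    for an exact GT..AG intron; among those, the junction keeping the
    highest combined alignment score wins (over-extended chance columns at
    exon boundaries score less than the true exon columns they displace).
    """
    overlap = a.q_end - b.q_start
    best: tuple[int, int, int] | None = None  # (-S, qj) -> t1, t2
    best_key = None
    if overlap >= 0:
        for qj in range(b.q_start, a.q_end + 1):
            t1 = _tpos_at_query(a, qj)
            t2 = _tpos_at_query(b, qj)
            if not config.min_intron <= t2 - t1 <= config.max_intron:
                continue
            if genome[t1:t1 + 2] == "GT" and genome[t2 - 2:t2] == "AG":
                s = _score_up_to(a, qj, config) \
                    + b.score - _score_up_to(b, qj, config)
                key = (-s, qj)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (t1, t2, qj)
        if best is not None:
            return best[0], best[1], True
        t1, t2 = a.t_end, _tpos_at_query(b, a.q_end)
    else:
        t1, t2 = a.t_end, b.t_start
    d1, ok1 = _shift_to_splice(genome, t1, "GT", config.max_query_gap)
    d2, ok2 = _shift_to_splice(genome, t2 - 2, "AG", config.max_query_gap)
    t1 += d1 if ok1 else 0
    t2 += d2 if ok2 else 0
    if not config.min_intron <= t2 - t1 <= config.max_intron:
        return None
    return t1, t2, ok1 and ok2


def chain_and_splice(hits: list[AlignmentHit], genome: str,
                     config: RunConfig | None = None) -> list[GeneModelDraft]:
    """Join colinear hit pairs of one query into two-exon gene models.

    Pairs separated by [min_intron, max_intron] bp of target and at most
    max_query_gap bp of query are joined; intron boundaries are shifted
    (donor and acceptor independently, <=max_query_gap bp) to the nearest
    GT..AG on the gene strand; introns longer than ``long_intron`` flag the
    model.  Unpaired hits become single-exon drafts.
    """
    config = config or RunConfig()
    if not hits:
        return []
    strands = {h.strand for h in hits}
    queries = {h.query_id for h in hits}
    targets = {h.target_id for h in hits}
    if len(strands) != 1 or len(queries) != 1 or len(targets) != 1:
        raise ValueError("chain_and_splice expects hits of one query on one "
                         "target and strand")
    strand = strands.pop()
    if strand == "-":
        # Work in the gene-strand frame: mirror target AND query coordinates
        # onto the reverse complement (queries were aligned reverse-
        # complemented, so both axes flip), chain as '+', then mirror back.
        L = len(genome)
        C = max(h.q_end for h in hits)
        mirrored = [replace(h, strand="+",
                            q_start=C - h.q_end, q_end=C - h.q_start,
                            t_start=L - h.t_end, t_end=L - h.t_start,
                            cigar=list(reversed(h.cigar))) for h in hits]
        drafts = chain_and_splice(mirrored, revcomp(genome), config)
        out = []
        for d in drafts:
            exons = [(L - e, L - s) for s, e in d.exons][:]
            introns = [Intron(L - i.end, L - i.start, i.donor, i.acceptor,
                              i.canonical) for i in d.introns]
            out.append(GeneModelDraft(d.query_id, d.target_id, "-", exons,
                                      introns, d.score, hits, d.long_intron))
        return out

    ordered = sorted(hits, key=lambda h: (h.q_start, h.t_start))
    candidates = []
    for a in ordered:
        for b in ordered:
            if b is a:
                continue
            qgap = b.q_start - a.q_end
            rough_tgap = (b.t_start + max(0, -qgap)) - a.t_end
            if -MAX_EXON_OVERLAP <= qgap <= config.max_query_gap and \
                    config.min_intron - MAX_EXON_OVERLAP <= rough_tgap \
                    <= config.max_intron and b.t_start > a.t_start:
                candidates.append((a, b, rough_tgap))
    drafts: list[GeneModelDraft] = []
    used: set[int] = set()
    # Strongest pairs first so noise micro-hits cannot steal a real exon;
    # ties (e.g. equal-scoring paralog chimeras) prefer the shortest intron.
    for a, b, _tgap in sorted(candidates,
                              key=lambda c: (-(c[0].score + c[1].score),
                                             c[2])):
        if id(a) in used or id(b) in used:
            continue
        junction = _resolve_junction(a, b, genome, config)
        if junction is None:
            continue
        i_start, i_end, canonical = junction
        if i_start <= a.t_start or i_end >= b.t_end:
            continue
        used.update((id(a), id(b)))
        intron = Intron(i_start, i_end, genome[i_start:i_start + 2],
                        genome[i_end - 2:i_end], canonical)
        exons = [(a.t_start, i_start), (i_end, b.t_end)]
        drafts.append(GeneModelDraft(
            a.query_id, a.target_id, "+", exons, [intron],
            a.score + b.score, [a, b],
            long_intron=len(intron) > config.long_intron))
    for h in ordered:
        if id(h) not in used:
            drafts.append(GeneModelDraft(h.query_id, h.target_id, "+",
                                         [(h.t_start, h.t_end)], [],
                                         h.score, [h]))
    return drafts


def _spans_overlap(a: GeneModelDraft, b: GeneModelDraft) -> bool:
    return (a.target_id == b.target_id and a.strand == b.strand
            and a.start < b.end and b.start < a.end)


def map_reference_set(refs: list[SequenceRecord | ReferenceSegment],
                      genome: list[SequenceRecord], config: RunConfig,
                      spliced: bool = True,
                      score_threshold: int | None = None
                      ) -> list[GeneModelDraft]:
    """Map every reference onto the genome and report each locus once.

    Per reference all drafts scoring >= threshold are kept; overlapping
    drafts on the same strand are then collapsed to the single best-scoring
    one (ties: lower start, then lexicographic query id).
    """
    if not refs:
        return []
    if not genome or all(len(g.seq) == 0 for g in genome):
        raise ValueError("empty genome")
    threshold = config.score_threshold if score_threshold is None \
        else score_threshold
    all_drafts: list[GeneModelDraft] = []
    for record in genome:
        if len(record.seq) < config.seed_k:
            continue
        index = KmerIndex(record.seq, config.seed_k)
        for ref in refs:
            if len(ref.seq) < config.seed_k:
                continue
            hits = seed_extend_hits(ref.seq, record.seq, config,
                                    query_id=ref.id, target_id=record.id,
                                    index=index)
            for strand in ("+", "-"):
                shits = [h for h in hits if h.strand == strand]
                if not shits:
                    continue
                if spliced:
                    drafts = chain_and_splice(shits, record.seq, config)
                else:
                    drafts = [GeneModelDraft(h.query_id, h.target_id, strand,
                                             [(h.t_start, h.t_end)], [],
                                             h.score, [h])
                              for h in shits]
                all_drafts.extend(d for d in drafts if d.score >= threshold)
    # Collapse overlapping drafts to one locus each.
    all_drafts.sort(key=lambda d: (-d.score, d.start, d.query_id))
    kept: list[GeneModelDraft] = []
    for draft in all_drafts:
        if not any(_spans_overlap(draft, k) for k in kept):
            kept.append(draft)
    kept.sort(key=lambda d: (d.target_id, d.start))
    return kept
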