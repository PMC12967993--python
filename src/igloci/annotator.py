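"""Classify mapped drafts: RSS detection, functionality calls, J motifs.

Functionality follows IMGT-style criteria: an in-frame ORF for both the
signal peptide and the V-domain exon, the invariant framework residues
Cys23, Trp41, Trp52 and Cys104 (located by alignment to the generator's
fixed-length V-domain template), absence of internal stops and frameshifts,
and a valid downstream RSS.  Every check runs; failures accumulate, so a
gene is functional iff no check fails.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

from ._seq import AA_ALPHABET, revcomp, translate
from .io_formats import Feature, RunConfig, SequenceRecord
from .segment_mapper import (GeneModelDraft, ReferenceSegment,
                             map_reference_set)
from .synthetic_locus import (CRITICAL_POSITIONS, RSS_HEPTAMER, RSS_NONAMER,
                              V_DOMAIN_AA)

V_CHECKS = ("orf_leader", "orf_vexon", "cys23", "trp41", "trp52", "cys104",
            "rss", "internal_stop", "frameshift")
SEGMENT_TYPES = {"V": "V_segment", "D": "D_segment", "J": "J_segment",
                 "C": "C_gene"}


@dataclass(frozen=True)
class RSSMatch:
    """Best heptamer/spacer/nonamer hit in the scanned window.

    ``offset`` is the heptamer start measured outward from the segment
    boundary (0 = immediately adjacent); genome coordinates of the whole
    element are in ``start0``/``end0``.
    """

    offset: int
    spacer: int
    heptamer_mismatches: int
    nonamer_mismatches: int
    strand: str
    start0: int
    end0: int

    @property
    def total_mismatches(self) -> int:
        return self.heptamer_mismatches + self.nonamer_mismatches


@dataclass(frozen=True)
class FunctionalityCall:
    status: str  # functional | pseudogene
    failed_checks: frozenset[str]

    def __post_init__(self) -> None:
        if (self.status == "functional") != (not self.failed_checks):
            raise ValueError("status must be functional iff no check failed")


@dataclass(frozen=True)
class JMotifCall:
    motif_class: str  # FGXG_canonical | GGG_triglycine | FSXXS | FGXXS | other
    preceding_residue: str | None


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_window(window: str, config: RunConfig) -> tuple | None:
    """Best (total_mm, offset, spacer, hept_mm, nona_mm) in an
    outward-facing window, or None.

    The heptamer must keep its CAC start invariant and have at most
    ``heptamer_max_mm`` mismatches to CACAGTG; the nonamer at a spacer of
    12 or 23 (+-tolerance) at most ``nonamer_max_mm`` to ACAAAAAC.  Ties are
    broken by smaller offset, then 23-family spacer before 12-family, then
    spacer closest to nominal.
    """
    h_len, n_len = len(RSS_HEPTAMER), len(RSS_NONAMER)
    spacers = []
    for nominal in (23, 12):
        for delta in range(-config.spacer_tolerance,
                           config.spacer_tolerance + 1):
            spacers.append((nominal + delta, nominal))
    best = None
    for off in range(0, len(window) - h_len + 1):
        hept = window[off:off + h_len]
        if hept[:3] != "CAC":
            continue
        hmm = _mismatches(hept, RSS_HEPTAMER)
        if hmm > config.heptamer_max_mm:
            continue
        for spacer, nominal in spacers:
            npos = off + h_len + spacer
            nona = window[npos:npos + n_len]
            if len(nona) < n_len:
                continue
            nmm = _mismatches(nona, RSS_NONAMER)
            if nmm > config.nonamer_max_mm:
                continue
            key = (hmm + nmm, off, 0 if nominal == 23 else 1,
                   abs(spacer - nominal), spacer)
            if best is None or key < best[0]:
                best = (key, off, spacer, hmm, nmm)
    if best is None:
        return None
    _key, off, spacer, hmm, nmm = best
    return (hmm + nmm, off, spacer, hmm, nmm)


def scan_rss(genome: str, anchor0: int, strand: str, side: str,
             config: RunConfig | None = None) -> RSSMatch | None:
    """Scan the 42-bp RSS window at a segment boundary.

    ``side`` is 'downstream' (3' of a V or D segment; ``anchor0`` is the
    segment's gene-strand end, 0-based half-open) or 'upstream' (5' of a J;
    ``anchor0`` is the segment's gene-strand start).  Windows truncated by
    the sequence end are scanned as-is.
    """
    config = config or RunConfig()
    w = config.rss_window
    if side not in ("downstream", "upstream"):
        raise ValueError(f"unknown side {side!r}")
    # Build the outward-facing window: position 0 adjacent to the boundary,
    # reading away from the segment in RSS orientation.
    if side == "downstream":
        if strand == "+":
            window = genome[anchor0:anchor0 + w]
        else:
            window = revcomp(genome[max(0, anchor0 - w):anchor0])
    else:
        if strand == "+":
            window = revcomp(genome[max(0, anchor0 - w):anchor0])
        else:
            window = genome[anchor0:anchor0 + w]
    hit = scan_window(window, config)
    if hit is None:
        return None
    _total, off, spacer, hmm, nmm = hit
    elem = len(RSS_HEPTAMER) + spacer + len(RSS_NONAMER)
    outward = (side == "downstream") == (strand == "+")
    if outward:
        start0 = anchor0 + off
        end0 = min(start0 + elem, len(genome))
    else:
        end0 = anchor0 - off
        start0 = max(0, end0 - elem)
    return RSSMatch(off, spacer, hmm, nmm, strand, start0, end0)


@lru_cache(maxsize=4)
def _template_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=-1, open_gap_score=-10,
                                    extend_gap_score=-1)
    return aligner


def locate_template_positions(aa_seq: str, template: str = V_DOMAIN_AA
                              ) -> dict[int, str | None]:
    """Map the template's critical positions onto ``aa_seq`` by global
    alignment; a position deleted in the query maps to None."""
    out: dict[int, str | None] = {p: None for p in CRITICAL_POSITIONS}
    if not aa_seq:
        return out
    alignment = _template_aligner().align(template, aa_seq)[0]
    for t_block, q_block in zip(*alignment.aligned):
        for pos in CRITICAL_POSITIONS:
            t_idx = pos - 1
            if t_block[0] <= t_idx < t_block[1]:
                out[pos] = aa_seq[q_block[0] + (t_idx - t_block[0])]
    return out


def classify_v_functionality(draft: GeneModelDraft, genome: str,
                             rss: RSSMatch | None,
                             config: RunConfig | None = None
                             ) -> FunctionalityCall:
    """Run every functionality check on a V gene model (no short-circuit)."""
    config = config or RunConfig()
    failed: set[str] = set()
    # draft.exons are already ordered 5'->3' on the gene strand
    exon_seqs = [genome[s:e] for s, e in draft.exons]
    if draft.strand == "-":
        exon_seqs = [revcomp(s) for s in exon_seqs]

    if len(exon_seqs) >= 2:
        leader, vexon = exon_seqs[0], exon_seqs[-1]
    else:
        leader, vexon = "", exon_seqs[0]

    if not leader or not leader.startswith("ATG") or len(leader) % 3 != 0 \
            or "*" in translate(leader):
        failed.add("orf_leader")
    if len(vexon) % 3 != 0:
        failed.add("frameshift")
    aa = translate(vexon)
    if not aa:
        failed.add("orf_vexon")
    if "*" in aa:
        failed.add("internal_stop")
        failed.add("orf_vexon")
    # Residues located by alignment to the template; a position the
    # alignment cannot map (exon truncated short of it) fails its check.
    residues = locate_template_positions(aa)
    for pos, want in CRITICAL_POSITIONS.items():
        name = f"{'cys' if want == 'C' else 'trp'}{pos}"
        if residues.get(pos) != want:
            failed.add(name)
    if rss is None:
        failed.add("rss")
    return FunctionalityCall("functional" if not failed else "pseudogene",
                             frozenset(failed))


def classify_j_motif(aa_seq: str) -> JMotifCall:
    """Classify a J amino-acid sequence by its glycine-bulge motif.

    Precedence: GGG tri-glycine, then canonical FGXG, then FGXXS, then
    FSXXS, else other.  The preceding residue is the one before the
    glycine run, or the F of the F-anchored motifs.
    """
    if len(aa_seq) < 4:
        raise ValueError("J amino-acid sequence shorter than any motif")
    bad = set(aa_seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"non-amino-acid characters {sorted(bad)}")
    idx = aa_seq.find("GGG")
    if idx >= 0:
        prev = aa_seq[idx - 1] if idx > 0 else None
        return JMotifCall("GGG_triglycine", prev)
    for i in range(len(aa_seq) - 3):
        if aa_seq[i] == "F" and aa_seq[i + 1] == "G" and aa_seq[i + 3] == "G":
            return JMotifCall("FGXG_canonical", "F")
    for i in range(len(aa_seq) - 4):
        if aa_seq[i] == "F" and aa_seq[i + 1] == "G" and aa_seq[i + 4] == "S":
            return JMotifCall("FGXXS", "F")
    for i in range(len(aa_seq) - 4):
        if aa_seq[i] == "F" and aa_seq[i + 1] == "S" and aa_seq[i + 4] == "S":
            return JMotifCall("FSXXS", "F")
    return JMotifCall("other", None)


def infer_jc_clusters(features: list[Feature]
                      ) -> list[tuple[list[Feature], Feature]]:
    """Group J segments with their downstream C gene into tandem cassettes.

    Walking each sequence in gene order, a maximal run of J segments
    followed by a C gene forms one cluster; a C without preceding J starts
    none.
    """
    clusters: list[tuple[list[Feature], Feature]] = []
    by_key: dict[tuple[str, str], list[Feature]] = {}
    for f in features:
        if f.type in ("J_segment", "C_gene"):
            by_key.setdefault((f.seq_id, f.strand), []).append(f)
    for (_, strand), feats in sorted(by_key.items()):
        feats.sort(key=lambda f: f.start, reverse=(strand == "-"))
        pending: list[Feature] = []
        for f in feats:
            if f.type == "J_segment":
                pending.append(f)
            else:
                if pending:
                    clusters.append((pending, f))
                pending = []
    return clusters


def _draft_end3(draft: GeneModelDraft) -> int:
    return draft.end if draft.strand == "+" else draft.start


def _draft_start5(draft: GeneModelDraft) -> int:
    return draft.start if draft.strand == "+" else draft.end


def _gene_seq(draft: GeneModelDraft, genome: str) -> str:
    exon_seqs = [genome[s:e] for s, e in draft.exons]  # gene 5'->3' order
    if draft.strand == "-":
        exon_seqs = [revcomp(s) for s in exon_seqs]
    return "".join(exon_seqs)


def annotate_locus(genome: list[SequenceRecord],
                   refs: list[ReferenceSegment],
                   config: RunConfig | None = None) -> list[Feature]:
    """Map references, scan RSS per draft, classify per segment class.

    Output is coordinate-sorted, deterministic, and carries the project's
    fixed attribute vocabulary (ID, segment_class, chain, functionality,
    rss_spacer, cluster_index).
    """
    config = config or RunConfig()
    if not refs:
        return []
    seqs = {r.id: r.seq for r in genome}
    features: list[Feature] = []
    thresholds = {"V": config.score_threshold, "C": config.score_threshold,
                  "J": config.j_score_threshold, "D": config.d_score_threshold}
    for cls in ("V", "D", "J", "C"):
        class_refs = [r for r in refs if r.segment_class == cls]
        if not class_refs:
            continue
        chain = class_refs[0].chain
        drafts = map_reference_set(class_refs, genome, config,
                                   spliced=(cls == "V"),
                                   score_threshold=thresholds[cls])
        for draft in drafts:
            target = seqs[draft.target_id]
            attrs = {"segment_class": cls, "chain": chain,
                     "source_ref": draft.query_id}
            rss = None
            if cls in ("V", "D"):
                rss = scan_rss(target, _draft_end3(draft), draft.strand,
                               "downstream", config)
            elif cls == "J":
                rss = scan_rss(target, _draft_start5(draft), draft.strand,
                               "upstream", config)
            gene_nt = _gene_seq(draft, target)
            failed: set[str] = set()
            if cls == "V":
                call = classify_v_functionality(draft, target, rss, config)
                failed = set(call.failed_checks)
            elif cls in ("J", "D"):
                if rss is None:
                    failed.add("rss")
                if cls == "J":
                    aa = translate(gene_nt)
                    if "*" in aa:
                        failed.add("internal_stop")
                    if len(aa) >= 4:
                        motif = classify_j_motif(aa)
                        attrs["j_motif"] = motif.motif_class
                        if motif.preceding_residue:
                            attrs["j_motif_preceding"] = motif.preceding_residue
                    attrs["j_aa"] = aa
            else:  # C genes: ORF/stop checks only
                if "*" in translate(gene_nt):
                    failed.add("internal_stop")
            attrs["functionality"] = "functional" if not failed \
                else "pseudogene"
            if failed:
                attrs["failed_checks"] = ",".join(sorted(failed))
            if rss is not None:
                attrs["rss_spacer"] = str(rss.spacer)
                attrs["rss_mismatches"] = str(rss.total_mismatches)
            if len(draft.exons) > 1:
                spans = sorted(draft.exons)
                attrs["exons"] = ",".join(f"{s + 1}-{e}" for s, e in spans)
                attrs["long_intron"] = "true" if draft.long_intron else "false"
            features.append(Feature.from_zero_based(
                draft.target_id, draft.start, draft.end, draft.strand,
                SEGMENT_TYPES[cls], attrs))
            if rss is not None and rss.end0 > rss.start0:
                features.append(Feature.from_zero_based(
                    draft.target_id, rss.start0, rss.end0, draft.strand,
                    "RSS", {"rss_spacer": str(rss.spacer),
                            "heptamer_mismatches": str(rss.heptamer_mismatches),
                            "nonamer_mismatches": str(rss.nonamer_mismatches),
                            "side": "downstream" if cls in ("V", "D")
                                    else "upstream"}))
    features.sort(key=lambda f: (f.seq_id, f.start, f.end, f.type))
    counters: dict[str, int] = {}
    for f in features:
        if f.type in SEGMENT_TYPES.values():
            n = counters.get(f.type, 0) + 1
            counters[f.type] = n
            f.attributes["ID"] = f"{f.type.split('_')[0]}_{n:03d}"
    for idx, (js, c) in enumerate(infer_jc_clusters(features), start=1):
        for f in js + [c]:
            f.attributes["cluster_index"] = str(idx)
    return features
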