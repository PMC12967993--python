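"""Synthetic immunoglobulin loci with planted, labelled features.

The generator emulates the architectures seen in tetrapod Ig loci: a cluster
of two-exon V genes (leader exon, GT..AG intron, V-domain exon, downstream
recombination signal sequence), optional D segments, tandem J-C cassettes
produced by duplicating a template cassette (recent-duplication redundancy),
RGYW-enriched switch regions upstream of constant genes, orphons on a
separate sequence record, and read pileups over the exons of expressed
genes.  Every planted feature is recorded in a :class:`SyntheticTruth` so
downstream stages can be scored exactly.

Pseudogenes are created by exactly one named corruption operator:

========  ==========================================================
cause     operator
========  ==========================================================
stop      one V-exon codon replaced by a stop codon
frameshift one base deleted inside the V exon
no_rss    downstream RSS window replaced by RSS-free random DNA
missing_residue one invariant residue (Cys23/Trp41/Trp52/Cys104) changed
========  ==========================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from ._seq import random_dna, revcomp, reverse_translate
from .io_formats import Feature, SequenceRecord

RGYW_MOTIF = "RGYW"
RSS_HEPTAMER = "CACAGTG"
RSS_NONAMER = "ACAAAAAC"  # printed vertebrate consensus element (8 bp)

# Fixed leader template: 18 codons, in-frame ATG start, no stops.
LEADER_AA = "MELGLSWVFLVAILEGVQ"

# Fixed 104-residue V-domain template.  Positions are counted on the
# gap-free translated exon (no CDR-length variation in this generator), so
# the invariant framework residues sit at exact template positions:
# Cys23, Trp41, Trp52, Cys104 (1-based).
V_DOMAIN_AA = ("QVQLVESGGG" "LVKPGGSLRL"      # 1-20
               "ASCKVSGFTF" "SDYYMSWVRQ"      # 21-40  (C at 23)
               "WAPGKGLEWV" "AWISYDGSNK"      # 41-60  (W at 41, W at 52)
               "YYADSVKGRF" "TISRDNSKNT"      # 61-80
               "LYLQMNSLRA" "EDTAVYYARD"      # 81-100
               "GLYC")                        # 101-104 (C at 104)
CRITICAL_POSITIONS = {23: "C", 41: "W", 52: "W", 104: "C"}  # 1-based
for _p, _aa in CRITICAL_POSITIONS.items():
    assert V_DOMAIN_AA[_p - 1] == _aa

PSEUDOGENE_CAUSES = ("stop", "frameshift", "no_rss", "missing_residue")

# Lambda-like J amino-acid pool, ordered so a template's first few J picks
# mix the dominant tri-glycine sequences with a canonical FGXG one.
LAMBDA_J_POOL = (
    "WMFGGGTQLNVL", "YVFGGGTQLSVL", "YVLGGGTQLNVY", "NVFGQGTKLTVL",
    "SMFGGGTKLTVL", "YTLGGGTQLTVL", "NVFGGGTRLTVL", "YAFGGGTKLELK",
    "WIFGGGTQLIVL", "SMFGGGSQLVVF", "NRIGGGTHLTVL", "QAFGGGTELQVL",
    "RSFGGGTKVEIK", "TMFGGGTKLDIK", "GHFGGGSKLIVL", "WNFGGGTQVLVL",
    "AMFGGGTELSVL", "YDIGGGTKLTVL", "KLFGSGTRLEIK", "SSFGAGTKLELK",
)
SIGMA_J_POOL = ("ADFGTESKLTVL", "ALFSGSSELTVL", "VTFSSGSKLNVQ", "AMFSTGSELVVK")

# Constant-gene exon template (no internal stops, frame 0).
C_EXON_AA = ("GQPKAAPSVTLFPPSSEELQANKATLVCLISDFYPGAVTVAWKADSSPVKAGVETTTPSK"
             "QSNNKYAASSYLSLTPEQWKSHRSYSC")

AA20 = "ACDEFGHIKLMNPQRSTVWY"

V_RSS_SPACER = {"heavy": 23, "lambda": 23, "sigma": 23}
J_RSS_SPACER = {"heavy": 23, "lambda": 12, "sigma": 12}


@dataclass
class LocusBlueprint:
    """Generative parameters of one synthetic locus.

    Defaults reproduce the study architecture: 87 V genes (64 functional,
    23 pseudogenes), all in the same transcriptional orientation, and 13
    tandem J-C cassettes of 5 J segments each with near-identical copies.
    """

    chain: str = "heavy"  # heavy | lambda | sigma (labels features)
    n_v_functional: int = 64
    n_v_pseudo: int = 23
    v_orientation_flip_fraction: float = 0.0
    n_d: int = 0
    n_jc_clusters: int = 13
    j_per_cluster: int = 5
    cassette_mutation_rate: float = 0.01
    rss_mutation_load: int = 0
    switch_regions: bool = True
    switch_enrichment: float = 8.0
    switch_length: int = 2500
    intergenic_length_mean: int = 800
    orphon_count: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_v_functional, self.n_v_pseudo, self.n_d,
                  self.n_jc_clusters, self.j_per_cluster, self.orphon_count,
                  self.rss_mutation_load, self.switch_length,
                  self.intergenic_length_mean)
        if any(c < 0 for c in counts):
            raise ValueError("blueprint counts must be >= 0")
        for rate in (self.v_orientation_flip_fraction,
                     self.cassette_mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("blueprint rates must lie in [0, 1]")
        if self.switch_enrichment < 1.0:
            raise ValueError("switch enrichment must be >= 1")
        if self.chain not in ("heavy", "lambda", "sigma"):
            raise ValueError(f"unknown chain {self.chain!r}")


@dataclass
class SyntheticTruth:
    """Planted feature list the recovery tests score against."""

    genome_id: str
    features: list[Feature]
    blueprint: LocusBlueprint

    def by_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.type == ftype]


def study_blueprint(seed: int = 0) -> LocusBlueprint:
    return LocusBlueprint(rng_seed=seed)


def sigma_blueprint(seed: int = 0) -> LocusBlueprint:
    return LocusBlueprint(chain="sigma", n_v_functional=6, n_v_pseudo=0,
                          n_jc_clusters=1, j_per_cluster=4,
                          switch_regions=False, orphon_count=0,
                          cassette_mutation_rate=0.0, rng_seed=seed)


def _mutate_aa(aa: str, rng: np.random.Generator, rate: float,
               protected: frozenset[int]) -> str:
    out = list(aa)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            choices = AA20.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _mutate_element(element: str, rng: np.random.Generator, n_mm: int,
                    protected: tuple[int, ...] = ()) -> tuple[str, int]:
    """Plant exactly n_mm substitutions in an RSS element."""
    free = [i for i in range(len(element)) if i not in protected]
    n_mm = min(n_mm, len(free))
    out = list(element)
    for i in rng.choice(len(free), size=n_mm, replace=False) if n_mm else []:
        pos = free[int(i)]
        alts = "ACGT".replace(out[pos], "")
        out[pos] = alts[rng.integers(3)]
    return "".join(out), n_mm


def make_rss(rng: np.random.Generator, spacer: int,
             mutation_load: int = 0) -> tuple[str, int, int]:
    """Heptamer + spacer + nonamer element; returns (seq, hept_mm, nona_mm)."""
    load_h = int(rng.integers(0, mutation_load + 1)) if mutation_load else 0
    load_n = int(rng.integers(0, mutation_load + 1)) if mutation_load else 0
    hept, hmm = _mutate_element(RSS_HEPTAMER, rng, min(load_h, 2),
                                protected=(0, 1, 2))  # CAC invariant
    nona, nmm = _mutate_element(RSS_NONAMER, rng, min(load_n, 3))
    return hept + random_dna(rng, spacer) + nona, hmm, nmm


def _window_has_heptamer(window: str) -> bool:
    for off in range(len(window) - len(RSS_HEPTAMER) + 1):
        cand = window[off:off + 7]
        if cand[:3] == "CAC" and \
                sum(a != b for a, b in zip(cand, RSS_HEPTAMER)) <= 2:
            return True
    return False


def rss_free_window(rng: np.random.Generator, length: int = 42) -> str:
    """Random DNA containing no heptamer within scanning tolerance."""
    while True:
        w = random_dna(rng, length)
        if not _window_has_heptamer(w):
            return w


def build_v_gene(rng: np.random.Generator, functional: bool,
                 cause: str = "none", chain: str = "heavy",
                 rss_mutation_load: int = 0, p_long_intron: float = 0.15
                 ) -> tuple[str, list[Feature]]:
    """One V gene unit: leader exon, intron, V exon, downstream RSS window.

    Returned features are unit-relative on a placeholder seq_id; the V
    segment spans leader start to V-exon end, with exon coordinates in the
    ``exons`` attribute.  ``cause`` must be 'none' iff functional.
    """
    if functional != (cause == "none"):
        raise ValueError("cause must be 'none' exactly when functional")
    if not functional and cause not in PSEUDOGENE_CAUSES:
        raise ValueError(f"unknown pseudogene cause {cause!r}")

    protected_leader = frozenset({0})
    protected_v = frozenset(p - 1 for p in CRITICAL_POSITIONS)
    leader_aa = _mutate_aa(LEADER_AA, rng, 0.10, protected_leader)
    v_aa = _mutate_aa(V_DOMAIN_AA, rng, 0.10, protected_v)
    if cause == "missing_residue":
        pos = int(rng.choice(sorted(CRITICAL_POSITIONS)))
        alts = AA20.replace(CRITICAL_POSITIONS[pos], "")
        v_aa = v_aa[:pos - 1] + alts[rng.integers(len(alts))] + v_aa[pos:]

    leader_nt = reverse_translate(leader_aa, rng)
    v_nt = reverse_translate(v_aa, rng)
    if cause == "stop":
        codon = int(rng.integers(30, 70))
        stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
        v_nt = v_nt[:codon * 3] + stop + v_nt[codon * 3 + 3:]
    elif cause == "frameshift":
        pos = int(rng.integers(50, 250))
        v_nt = v_nt[:pos] + v_nt[pos + 1:]

    long_intron = rng.random() < p_long_intron
    ilen = int(rng.integers(151, 401)) if long_intron \
        else int(rng.integers(80, 151))
    intron = "GT" + random_dna(rng, ilen - 4) + "AG"

    spacer = V_RSS_SPACER[chain]
    if cause == "no_rss":
        rss_seq, hmm, nmm = "", 0, 0
        tail = rss_free_window(rng, 42)
    else:
        rss_seq, hmm, nmm = make_rss(rng, spacer, rss_mutation_load)
        tail = ""

    seq = leader_nt + intron + v_nt + rss_seq + tail
    l_end = len(leader_nt)
    v_start = l_end + len(intron)
    v_end = v_start + len(v_nt)
    attrs = {
        "segment_class": "V",
        "chain": chain,
        "functionality": "functional" if functional else "pseudogene",
        "pseudogene_cause": cause,
        "exons": f"{1}-{l_end},{v_start + 1}-{v_end}",
        "long_intron": "true" if ilen > 150 else "false",
    }
    feats = [Feature.from_zero_based("_", 0, v_end, "+", "V_segment", attrs)]
    if rss_seq:
        feats.append(Feature.from_zero_based(
            "_", v_end, v_end + len(rss_seq), "+", "RSS",
            {"rss_spacer": str(spacer), "heptamer_mismatches": str(hmm),
             "nonamer_mismatches": str(nmm), "side": "downstream"}))
    return seq, feats


def build_d_segment(rng: np.random.Generator, chain: str = "heavy",
                    rss_mutation_load: int = 0
                    ) -> tuple[str, list[Feature]]:
    """Short D segment with a downstream 12-spacer RSS."""
    core = random_dna(rng, int(rng.integers(14, 22)))
    rss_seq, hmm, nmm = make_rss(rng, 12, rss_mutation_load)
    feats = [
        Feature.from_zero_based("_", 0, len(core), "+", "D_segment",
                                {"segment_class": "D", "chain": chain,
                                 "functionality": "functional",
                                 "pseudogene_cause": "none"}),
        Feature.from_zero_based("_", len(core), len(core) + len(rss_seq), "+",
                                "RSS", {"rss_spacer": "12",
                                        "heptamer_mismatches": str(hmm),
                                        "nonamer_mismatches": str(nmm),
                                        "side": "downstream"}),
    ]
    return core + rss_seq, feats


def build_switch_region(rng: np.random.Generator, length: int,
                        enrichment: float) -> str:
    """DNA with an RGYW start density of ~enrichment x the uniform
    background (1/32 per position).

    Random motifs are planted iteratively until the target count is reached
    (planting can destroy neighbouring matches, so a single batch would
    undershoot).  Densities near the motif packing limit cannot be reached
    by random placement: factors up to ~4 are matched closely, larger ones
    saturate around 5-6x background, which still dominates any background
    window by a wide margin.
    """
    if enrichment < 1.0:
        raise ValueError("enrichment must be >= 1")
    if length < 4:
        raise ValueError("switch region shorter than the RGYW motif")
    from .locus_metrics import motif_start_positions  # local: avoid cycle

    seq = list(random_dna(rng, length))
    target = int(round(enrichment * length / 32.0))
    if enrichment > 1.0:
        for _ in range(60):
            count = len(motif_start_positions("".join(seq), RGYW_MOTIF))
            deficit = target - count
            if deficit <= 0:
                break
            n_plant = min(deficit, max(1, length - 3))
            starts = rng.choice(length - 3, size=n_plant, replace=False)
            for s in starts:
                motif = ("AG"[rng.integers(2)] + "G" + "CT"[rng.integers(2)]
                         + "AT"[rng.integers(2)])
                seq[s:s + 4] = motif
    return "".join(seq)


def _j_pool(chain: str) -> tuple[str, ...]:
    return SIGMA_J_POOL if chain == "sigma" else LAMBDA_J_POOL


@dataclass
class _CassetteTemplate:
    seq: str
    features: list[Feature]          # cassette-relative
    protected: np.ndarray            # bool mask: never mutate (RSS elements)
    coding: list[tuple[int, int]]    # frame-0 exon intervals (stop-guarded)


def build_jc_template(rng: np.random.Generator, blueprint: LocusBlueprint
                      ) -> _CassetteTemplate:
    """One J..J-C cassette used as the duplication template."""
    if blueprint.j_per_cluster < 1:
        raise ValueError("j_per_cluster must be >= 1")
    chain = blueprint.chain
    pool = _j_pool(chain)
    parts: list[str] = []
    feats: list[Feature] = []
    coding: list[tuple[int, int]] = []
    protected_ranges: list[tuple[int, int]] = []
    cursor = 0

    def emit(seq: str) -> int:
        nonlocal cursor
        parts.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    spacer = J_RSS_SPACER[chain]
    for idx in range(blueprint.j_per_cluster):
        emit(random_dna(rng, 40))
        rss_fwd, hmm, nmm = make_rss(rng, spacer, blueprint.rss_mutation_load)
        # Upstream-of-J orientation: on the gene strand the element reads as
        # the reverse complement of heptamer+spacer+nonamer, pointing at J.
        rss_start = emit(revcomp(rss_fwd))
        elem = len(rss_fwd)
        protected_ranges.append((rss_start, rss_start + elem))
        feats.append(Feature.from_zero_based(
            "_", rss_start, rss_start + elem, "+", "RSS",
            {"rss_spacer": str(spacer), "heptamer_mismatches": str(hmm),
             "nonamer_mismatches": str(nmm), "side": "upstream"}))
        j_aa = pool[idx % len(pool)]
        j_nt = reverse_translate(j_aa, rng)
        j_start = emit(j_nt)
        coding.append((j_start, j_start + len(j_nt)))
        feats.append(Feature.from_zero_based(
            "_", j_start, j_start + len(j_nt), "+", "J_segment",
            {"segment_class": "J", "chain": chain,
             "functionality": "functional", "pseudogene_cause": "none",
             "j_aa": j_aa}))
        emit(random_dna(rng, 60))

    if blueprint.switch_regions:
        s_start = emit(build_switch_region(rng, blueprint.switch_length,
                                           blueprint.switch_enrichment))
        feats.append(Feature.from_zero_based(
            "_", s_start, s_start + blueprint.switch_length, "+",
            "switch_region", {"chain": chain}))
        emit(random_dna(rng, 80))
    c_nt = reverse_translate(C_EXON_AA, rng)
    c_start = emit(c_nt)
    coding.append((c_start, c_start + len(c_nt)))
    feats.append(Feature.from_zero_based(
        "_", c_start, c_start + len(c_nt), "+", "C_gene",
        {"segment_class": "C", "chain": chain, "functionality": "functional",
         "pseudogene_cause": "none"}))
    emit(random_dna(rng, 60))

    seq = "".join(parts)
    protected = np.zeros(len(seq), dtype=bool)
    for s, e in protected_ranges:
        protected[s:e] = True
    return _CassetteTemplate(seq, feats, protected, coding)


def _mutate_cassette(template: _CassetteTemplate, rng: np.random.Generator,
                     rate: float) -> str:
    """Substitution-only divergence; RSS elements are never touched and a
    substitution that would create an in-frame stop codon is skipped."""
    if rate == 0.0:
        return template.seq
    seq = list(template.seq)
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    frames = {}
    for s, e in template.coding:
        for p in range(s, e):
            frames[p] = (s, e)
    for p in hit:
        p = int(p)
        if template.protected[p]:
            continue
        alts = "ACGT".replace(seq[p], "")
        new = alts[rng.integers(3)]
        if p in frames:
            s, _e = frames[p]
            cstart = s + ((p - s) // 3) * 3
            codon = seq[cstart:cstart + 3]
            codon[(p - cstart)] = new
            if "".join(codon) in ("TAA", "TAG", "TGA"):
                continue
        seq[p] = new
    return "".join(seq)


def build_jc_cluster(rng: np.random.Generator, blueprint: LocusBlueprint,
                     template: _CassetteTemplate
                     ) -> tuple[str, list[Feature]]:
    """One cassette copy: template sequence mutated at the cassette rate,
    features cloned from the template (coordinates unchanged: substitutions
    only)."""
    seq = _mutate_cassette(template, rng, blueprint.cassette_mutation_rate)
    return seq, [_dc_replace(f, attributes=dict(f.attributes))
                 for f in template.features]


def _flip_unit(seq: str, feats: list[Feature]) -> tuple[str, list[Feature]]:
    L = len(seq)
    flipped = []
    for f in feats:
        attrs = dict(f.attributes)
        if "exons" in attrs:
            spans = []
            for span in attrs["exons"].split(","):
                s, e = (int(x) for x in span.split("-"))
                spans.append((L - e + 1, L - s + 1))
            attrs["exons"] = ",".join(f"{s}-{e}" for s, e in sorted(spans))
        flipped.append(Feature(f.seq_id, L - f.end + 1, L - f.start + 1,
                               "-" if f.strand == "+" else "+", f.type, attrs))
    return revcomp(seq), flipped


def _intergenic(rng: np.random.Generator, mean: int) -> str:
    lo = max(50, mean // 2)
    return random_dna(rng, int(rng.integers(lo, max(lo + 1, mean * 3 // 2))))


def assemble_locus(blueprint: LocusBlueprint
                   ) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Compose the full synthetic locus; deterministic for a fixed seed.

    Returns the genome (main record plus an orphon record when requested)
    and the planted truth.  Extracting any truth feature's span from the
    genome reproduces the generated sequence exactly.
    """
    rng = np.random.default_rng(blueprint.rng_seed)
    genome_id = "chrSim"
    parts: list[str] = []
    features: list[Feature] = []
    cursor = 0

    def append(seq: str, feats: list[Feature] | None = None,
               number: dict | None = None) -> None:
        nonlocal cursor
        parts.append(seq)
        for f in feats or []:
            placed = Feature(genome_id, f.start + cursor, f.end + cursor,
                             f.strand, f.type, dict(f.attributes))
            if "exons" in placed.attributes:
                spans = []
                for span in placed.attributes["exons"].split(","):
                    s, e = (int(x) for x in span.split("-"))
                    spans.append(f"{s + cursor}-{e + cursor}")
                placed.attributes["exons"] = ",".join(spans)
            features.append(placed)
        cursor += len(seq)

    # --- V cluster ---------------------------------------------------------
    plan = [(True, "none")] * blueprint.n_v_functional
    plan += [(False, PSEUDOGENE_CAUSES[i % len(PSEUDOGENE_CAUSES)])
             for i in range(blueprint.n_v_pseudo)]
    order = rng.permutation(len(plan))
    for idx in order:
        functional, cause = plan[int(idx)]
        append(_intergenic(rng, blueprint.intergenic_length_mean))
        seq, feats = build_v_gene(rng, functional, cause, blueprint.chain,
                                  blueprint.rss_mutation_load)
        if rng.random() < blueprint.v_orientation_flip_fraction:
            seq, feats = _flip_unit(seq, feats)
        append(seq, feats)

    # --- D segments --------------------------------------------------------
    for _ in range(blueprint.n_d):
        append(_intergenic(rng, max(200, blueprint.intergenic_length_mean // 2)))
        seq, feats = build_d_segment(rng, blueprint.chain,
                                     blueprint.rss_mutation_load)
        append(seq, feats)

    # plain spacer standing in for the tRNA cluster between sub-clusters
    if blueprint.n_jc_clusters:
        append(random_dna(rng, 3000))

    # --- tandem J-C cassettes ---------------------------------------------
    if blueprint.n_jc_clusters:
        template = build_jc_template(rng, blueprint)
        for ci in range(blueprint.n_jc_clusters):
            append(_intergenic(rng, blueprint.intergenic_length_mean))
            seq, feats = build_jc_cluster(rng, blueprint, template)
            for f in feats:
                f.attributes["cluster_index"] = str(ci + 1)
            append(seq, feats)
    append(_intergenic(rng, blueprint.intergenic_length_mean))

    records = [SequenceRecord(genome_id, "".join(parts))]

    # --- orphons on a separate record, RSS removed -------------------------
    if blueprint.orphon_count:
        oparts: list[str] = []
        ofeats: list[Feature] = []
        ocursor = 0
        for _ in range(blueprint.orphon_count):
            pad = _intergenic(rng, blueprint.intergenic_length_mean)
            seq, feats = build_v_gene(rng, False, "no_rss", blueprint.chain,
                                      blueprint.rss_mutation_load)
            oparts.append(pad)
            ocursor += len(pad)
            for f in feats:
                placed = Feature("chrSimOrphons", f.start + ocursor,
                                 f.end + ocursor, f.strand, f.type,
                                 dict(f.attributes))
                if "exons" in placed.attributes:
                    spans = []
                    for span in placed.attributes["exons"].split(","):
                        s, e = (int(x) for x in span.split("-"))
                        spans.append(f"{s + ocursor}-{e + ocursor}")
                    placed.attributes["exons"] = ",".join(spans)
                placed.attributes["orphon"] = "true"
                ofeats.append(placed)
            oparts.append(seq)
            ocursor += len(seq)
        oparts.append(_intergenic(rng, blueprint.intergenic_length_mean))
        records.append(SequenceRecord("chrSimOrphons", "".join(oparts)))
        features.extend(ofeats)

    # --- IDs, expression labels, ordering ----------------------------------
    features.sort(key=lambda f: (f.seq_id, f.start, f.end, f.type))
    counters: dict[str, int] = {}
    last_cluster = str(blueprint.n_jc_clusters)
    for f in features:
        if f.type in ("V_segment", "D_segment", "J_segment", "C_gene"):
            n = counters.get(f.type, 0) + 1
            counters[f.type] = n
            f.attributes["ID"] = f"{f.type.split('_')[0]}_{n:03d}"
            functional = f.attributes.get("functionality") == "functional"
            distal_c = (f.type == "C_gene"
                        and f.attributes.get("cluster_index") == last_cluster)
            f.attributes["expressed"] = \
                "true" if functional and not distal_c else "false"

    truth = SyntheticTruth(genome_id, features, blueprint)
    # truth/genome consistency is a hard generator invariant
    by_id = {r.id: r.seq for r in records}
    for f in features:
        assert f.end <= len(by_id[f.seq_id]), "feature outside genome"
    return records, truth


def feature_sequence(f: Feature, genome: list[SequenceRecord],
                     spliced: bool = True) -> str:
    """Gene-strand sequence of a feature (spliced over exons for V genes)."""
    seq = {r.id: r.seq for r in genome}[f.seq_id]
    if spliced and "exons" in f.attributes:
        parts = []
        for span in f.attributes["exons"].split(","):
            s, e = (int(x) for x in span.split("-"))
            parts.append(seq[s - 1:e])
        out = "".join(parts)
    else:
        out = seq[f.start0:f.end0]
    return revcomp(out) if f.strand == "-" else out


def simulate_reads(truth: SyntheticTruth, genome: list[SequenceRecord],
                   rng: np.random.Generator, read_length: int = 100
                   ) -> list[tuple[str, int, int]]:
    """Read intervals over exons: expressed genes get 15-60 reads, silent
    genes 0-3 (below the >10 expression rule either way)."""
    lengths = {r.id: len(r.seq) for r in genome}
    reads: list[tuple[str, int, int]] = []
    for f in truth.features:
        if f.type not in ("V_segment", "D_segment", "J_segment", "C_gene"):
            continue
        n = int(rng.integers(15, 61)) if f.attributes.get("expressed") == "true" \
            else int(rng.integers(0, 4))
        exons = []
        if "exons" in f.attributes:
            for span in f.attributes["exons"].split(","):
                s, e = (int(x) for x in span.split("-"))
                exons.append((s - 1, e))
        else:
            exons.append((f.start0, f.end0))
        for _ in range(n):
            es, ee = exons[int(rng.integers(len(exons)))]
            start = int(rng.integers(max(0, es - read_length + 1), ee))
            end = min(start + read_length, lengths[f.seq_id])
            if end > start:
                reads.append((f.seq_id, start, end))
    reads.sort()
    return reads


def divergent_copy(seq: str, rng: np.random.Generator,
                   divergence: float) -> str:
    """Substitution-only copy at the given per-base divergence."""
    if divergence == 0.0:
        return seq
    out = list(seq)
    for p in np.flatnonzero(rng.random(len(out)) < divergence):
        p = int(p)
        alts = "ACGT".replace(out[p], "") if out[p] in "ACGT" else "ACGT"
        out[p] = alts[rng.integers(len(alts))]
    return "".join(out)


def extract_reference_set(truth: SyntheticTruth,
                          genome: list[SequenceRecord],
                          rng: np.random.Generator | None = None,
                          divergence: float = 0.0):
    """Build the mapping reference set from the planted segments.

    V references are spliced cDNAs (leader + V exon); D/J/C references are
    the plain segment sequences.  Optional per-base divergence emulates
    mapping a related individual's references.  Identical sequences are
    deduplicated (first id wins).
    """
    from .segment_mapper import ReferenceSegment

    rng = rng or np.random.default_rng(0)
    refs: list[ReferenceSegment] = []
    seen: dict[tuple[str, str], str] = {}
    for f in truth.features:
        if f.type not in ("V_segment", "D_segment", "J_segment", "C_gene"):
            continue
        cls = f.attributes["segment_class"]
        seq = feature_sequence(f, genome, spliced=True)
        seq = divergent_copy(seq, rng, divergence)
        key = (cls, seq)
        if key in seen:
            continue
        seen[key] = f.attributes["ID"]
        refs.append(ReferenceSegment(f.attributes["ID"], seq, cls,
                                     f.attributes.get("chain", "heavy")))
    return refs


def expected_pairwise_identity(rate: float) -> float:
    """Expected identity of two independent copies mutated at ``rate``
    (substitution to a uniformly chosen different base)."""
    p_diff = 2 * rate * (1 - rate) + rate * rate * (2.0 / 3.0)
    return 1.0 - p_diff


def background_rgyw_rate() -> float:
    """Per-position RGYW start probability in uniform random DNA."""
    return (2 / 4) * (1 / 4) * (2 / 4) * (2 / 4)


def n_windows(length: int, window: int) -> int:
    return math.ceil(length / window)
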