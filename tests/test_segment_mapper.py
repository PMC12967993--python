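import pytest
from Bio import Align

from conftest import point_mutate, random_dna
from igloci._seq import revcomp
from igloci.io_formats import SequenceRecord
from igloci.segment_mapper import (SeedMatch, chain_and_splice,
                                   extend_banded_sw, find_seeds,
                                   map_reference_set, score_from_cigar,
                                   seed_extend_hits, sw_full)
from igloci.synthetic_locus import build_v_gene


def reference_aligner() -> Align.PairwiseAligner:
    """Independent exhaustive-DP oracle under the mapper's scoring scheme
    (gap of length L costs 5 + 2L)."""
    return Align.PairwiseAligner(mode="local", match_score=2,
                                 mismatch_score=-3, open_gap_score=-7,
                                 extend_gap_score=-2)


def brute_force_seeds(query, target, k):
    seeds = set()
    for strand, q in (("+", query), ("-", revcomp(query))):
        for i in range(len(q) - k + 1):
            for j in range(len(target) - k + 1):
                if q[i:i + k] == target[j:j + k]:
                    seeds.add((i, j, strand))
    return seeds


class TestFindSeeds:
    def test_identity_forward_seed(self):
        s = "ACGTACGTACGT"
        plus = [x for x in find_seeds(s, s, 12) if x.strand == "+"]
        assert plus == [SeedMatch(0, 0, 12, "+")]

    def test_reverse_complement_strand(self):
        t = "AACCGGTTACGTAAGG"
        q = revcomp(t)
        minus = [x for x in find_seeds(q, t, len(t)) if x.strand == "-"]
        assert minus == [SeedMatch(0, 0, len(t), "-")]

    def test_matches_brute_force_enumeration(self, rng):
        target = random_dna(rng, 1000)
        query = target[300:400]
        got = {(s.query_pos, s.target_pos, s.strand)
               for s in find_seeds(query, target, 11)}
        assert got == brute_force_seeds(query, target, 11)

    def test_k_longer_than_query_rejected(self):
        with pytest.raises(ValueError):
            find_seeds("ACGT", "ACGTACGT", 11)


class TestExtension:
    def test_identical_fifty_mers_score_100(self, rng, config):
        q = random_dna(rng, 50)
        hit = extend_banded_sw(q, q, SeedMatch(0, 0, 11, "+"), band=64,
                               config=config)
        assert hit.score == 100
        assert hit.identity == 1.0
        assert hit.query_coverage == 1.0

    def test_single_mismatch_scores_95(self, rng, config):
        q = random_dna(rng, 50)
        t = q[:25] + ("A" if q[25] != "A" else "C") + q[26:]
        hit = extend_banded_sw(q, t, SeedMatch(0, 0, 11, "+"), band=64,
                               config=config)
        assert hit.score == 95  # 49 matches x2, one mismatch -3
        assert hit.identity == pytest.approx(49 / 50)

    def test_score_consistent_with_cigar(self, rng, config):
        t = random_dna(rng, 600)
        q = point_mutate(t[100:300], rng, 0.05)
        for seed in find_seeds(q, t, 11)[:5]:
            hit = extend_banded_sw(q, t, seed, band=32, config=config)
            assert hit.score == score_from_cigar(hit.cigar, config)

    def test_unrelated_sequences_stay_below_threshold(self, rng, config):
        scores = [sw_full(random_dna(rng, 80), random_dna(rng, 80), config)
                  for _ in range(30)]
        assert max(scores) < config.score_threshold

    def test_wide_band_equals_unconstrained_smith_waterman(self, rng, config):
        aligner = reference_aligner()
        for _ in range(40):
            n1, n2 = rng.integers(20, 200, size=2)
            a = random_dna(rng, int(n1))
            b = point_mutate(a, rng, 0.1)[:int(n2)] + random_dna(rng, 30)
            assert sw_full(a, b, config) == aligner.score(a, b)

    def test_ambiguous_bases_never_match(self, config):
        assert sw_full("NNNNNNNNNN", "NNNNNNNNNN", config) == 0


class TestChainAndSplice:
    def test_planted_two_exon_gene_recovers_intron(self, rng, config):
        seq, feats = build_v_gene(rng, functional=True)
        genome = random_dna(rng, 300) + seq + random_dna(rng, 300)
        vf = feats[0]
        exons = [tuple(map(int, s.split("-")))
                 for s in vf.attributes["exons"].split(",")]
        cdna = "".join(genome[300 + s - 1:300 + e] for s, e in exons)
        hits = seed_extend_hits(cdna, genome, config)
        drafts = chain_and_splice([h for h in hits if h.strand == "+"],
                                  genome, config)
        two_exon = [d for d in drafts if len(d.exons) == 2]
        assert len(two_exon) == 1
        d = two_exon[0]
        assert d.exons == [(300 + s - 1, 300 + e) for s, e in exons]
        assert d.introns[0].donor == "GT" and d.introns[0].acceptor == "AG"
        assert d.introns[0].canonical

    def test_single_hit_gives_single_exon_draft(self, rng, config):
        t = random_dna(rng, 500)
        q = t[100:200]
        hits = [h for h in seed_extend_hits(q, t, config) if h.strand == "+"]
        drafts = chain_and_splice(hits, t, config)
        assert all(len(d.exons) == 1 and not d.introns for d in drafts)

    def test_long_intron_flagged(self, rng, config):
        leader = random_dna(rng, 60)
        exon = random_dna(rng, 200)
        intron = "GT" + random_dna(rng, 196) + "AG"  # 200 bp > 150
        genome = random_dna(rng, 100) + leader + intron + exon \
            + random_dna(rng, 100)
        cdna = leader + exon
        hits = [h for h in seed_extend_hits(cdna, genome, config)
                if h.strand == "+"]
        drafts = [d for d in chain_and_splice(hits, genome, config)
                  if len(d.exons) == 2]
        assert drafts and drafts[0].long_intron


class TestMapReferenceSet:
    def test_planted_recovery_exact(self, small_locus, config):
        _, genome, truth = small_locus
        from igloci.synthetic_locus import extract_reference_set
        refs = [r for r in extract_reference_set(truth, genome)
                if r.segment_class == "V"]
        drafts = map_reference_set(refs, genome, config)
        truth_v = [f for f in truth.features if f.type == "V_segment"]
        assert len(drafts) == len(truth_v)
        spans = {(d.target_id, d.start, d.end) for d in drafts}
        assert spans == {(f.seq_id, f.start0, f.end0) for f in truth_v}

    def test_near_identical_paralogs_collapse_to_one_locus(self, rng, config):
        gene = random_dna(rng, 200)
        genome = [SequenceRecord("g", random_dna(rng, 200) + gene
                                 + random_dna(rng, 200))]
        refs = [SequenceRecord("ref_b", point_mutate(gene, rng, 0.02)),
                SequenceRecord("ref_a", gene)]
        drafts = map_reference_set(refs, genome, config, spliced=False)
        assert len(drafts) == 1
        assert drafts[0].query_id == "ref_a"  # exact copy outscores mutant

    def test_absent_reference_maps_nowhere(self, rng, config):
        genome = [SequenceRecord("g", random_dna(rng, 2000))]
        refs = [SequenceRecord("r", random_dna(rng, 300))]
        assert map_reference_set(refs, genome, config, spliced=False) == []

    def test_empty_genome_rejected(self, rng, config):
        refs = [SequenceRecord("r", random_dna(rng, 100))]
        with pytest.raises(ValueError):
            map_reference_set(refs, [], config)

    def test_strand_involution(self, rng, config):
        gene = random_dna(rng, 250)
        fwd = random_dna(rng, 150) + gene + random_dna(rng, 150)
        genome_f = [SequenceRecord("g", fwd)]
        genome_r = [SequenceRecord("g", revcomp(fwd))]
        refs = [SequenceRecord("r", gene)]
        df = map_reference_set(refs, genome_f, config, spliced=False)
        dr = map_reference_set(refs, genome_r, config, spliced=False)
        assert len(df) == len(dr) == 1
        L = len(fwd)
        assert df[0].strand != dr[0].strand
        assert (df[0].start, df[0].end) == (L - dr[0].end, L - dr[0].start)
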