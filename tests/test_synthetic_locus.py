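import numpy as np
import pytest

from igloci._seq import hamming, translate
from igloci.locus_metrics import motif_start_positions
from igloci.synthetic_locus import (CRITICAL_POSITIONS, LocusBlueprint,
                                    assemble_locus, background_rgyw_rate,
                                    build_jc_cluster, build_jc_template,
                                    build_switch_region, build_v_gene,
                                    expected_pairwise_identity,
                                    feature_sequence, rss_free_window)


def v_exon_translation(seq, feats):
    vf = feats[0]
    spans = [tuple(map(int, s.split("-")))
             for s in vf.attributes["exons"].split(",")]
    s, e = spans[-1]
    return translate(seq[s - 1:e])


class TestBuildVGene:
    def test_functional_gene_has_all_invariant_residues(self, rng):
        seq, feats = build_v_gene(rng, functional=True)
        aa = v_exon_translation(seq, feats)
        for pos, want in CRITICAL_POSITIONS.items():
            assert aa[pos - 1] == want
        assert "*" not in aa

    def test_stop_corruption_plants_internal_stop_only(self, rng):
        seq, feats = build_v_gene(rng, functional=False, cause="stop")
        aa = v_exon_translation(seq, feats)
        assert "*" in aa
        # conserved residues otherwise intact
        for pos, want in CRITICAL_POSITIONS.items():
            if aa[pos - 1] != "*":
                assert aa[pos - 1] == want

    def test_frameshift_removes_one_base(self, rng):
        seq_f, feats_f = build_v_gene(np.random.default_rng(1), True)
        seq_p, feats_p = build_v_gene(np.random.default_rng(2), False,
                                      cause="frameshift")
        span = feats_p[0].attributes["exons"].split(",")[-1]
        s, e = map(int, span.split("-"))
        assert (e - s + 1) % 3 == 2  # 312 - 1 deleted base

    def test_no_rss_window_lacks_tolerated_heptamer(self, rng):
        from igloci.annotator import scan_window
        from igloci.io_formats import RunConfig
        seq, feats = build_v_gene(rng, functional=False, cause="no_rss")
        vf = feats[0]
        window = seq[vf.end0:vf.end0 + 42]
        assert scan_window(window, RunConfig()) is None

    def test_cause_functional_consistency_enforced(self, rng):
        with pytest.raises(ValueError):
            build_v_gene(rng, functional=True, cause="stop")
        with pytest.raises(ValueError):
            build_v_gene(rng, functional=False, cause="none")
        with pytest.raises(ValueError):
            build_v_gene(rng, functional=False, cause="weird")


class TestJcCassettes:
    def test_zero_mutation_duplicates_are_byte_identical(self):
        rng = np.random.default_rng(0)
        bp = LocusBlueprint(cassette_mutation_rate=0.0, n_jc_clusters=13,
                            j_per_cluster=5)
        template = build_jc_template(rng, bp)
        copies = [build_jc_cluster(rng, bp, template)[0] for _ in range(13)]
        assert len(set(copies)) == 1

    def test_mutated_copies_match_expected_identity(self):
        rng = np.random.default_rng(1)
        bp = LocusBlueprint(cassette_mutation_rate=0.02, switch_regions=False,
                            j_per_cluster=5)
        template = build_jc_template(rng, bp)
        a, _ = build_jc_cluster(rng, bp, template)
        b, _ = build_jc_cluster(rng, bp, template)
        identity = 1 - hamming(a, b) / len(a)
        assert identity == pytest.approx(expected_pairwise_identity(0.02),
                                         abs=0.015)

    def test_j_count_is_clusters_times_j_per_cluster(self):
        bp = LocusBlueprint(n_v_functional=0, n_v_pseudo=0, orphon_count=0,
                            n_jc_clusters=13, j_per_cluster=5, rng_seed=0)
        _, truth = assemble_locus(bp)
        assert len(truth.by_type("J_segment")) == 65


class TestSwitchRegion:
    def test_enrichment_one_matches_uniform_background(self):
        rng = np.random.default_rng(0)
        n = len(motif_start_positions(build_switch_region(rng, 50000, 1.0),
                                      "RGYW"))
        expect = 50000 * background_rgyw_rate()
        assert abs(n - expect) < 4 * np.sqrt(expect)

    def test_moderate_enrichment_calibrated(self):
        rng = np.random.default_rng(0)
        n = len(motif_start_positions(build_switch_region(rng, 50000, 3.0),
                                      "RGYW"))
        assert n == pytest.approx(3.0 * 50000 / 32, rel=0.02)

    def test_enriched_window_exceeds_background_99th_percentile(self):
        rng = np.random.default_rng(7)
        background = [len(motif_start_positions(
            "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2500)]), "RGYW"))
            for _ in range(1000)]
        p99 = np.quantile(background, 0.99)
        enriched = len(motif_start_positions(
            build_switch_region(rng, 2500, 8.0), "RGYW"))
        assert enriched > p99

    def test_shorter_than_motif_rejected(self):
        with pytest.raises(ValueError):
            build_switch_region(np.random.default_rng(0), 3, 2.0)


class TestAssembleLocus:
    def test_truth_counts_match_blueprint(self, small_locus):
        bp, _, truth = small_locus
        v = truth.by_type("V_segment")
        assert len(v) == bp.n_v_functional + bp.n_v_pseudo + bp.orphon_count
        functional = [f for f in v
                      if f.attributes["functionality"] == "functional"]
        assert len(functional) == bp.n_v_functional
        assert len(truth.by_type("J_segment")) == \
            bp.n_jc_clusters * bp.j_per_cluster
        assert len(truth.by_type("C_gene")) == bp.n_jc_clusters

    def test_same_orientation_when_flip_fraction_zero(self, small_locus):
        _, _, truth = small_locus
        assert all(f.strand == "+" for f in truth.by_type("V_segment"))

    def test_determinism_identical_genome_bytes(self):
        bp = LocusBlueprint(n_v_functional=3, n_v_pseudo=1, n_jc_clusters=2,
                            j_per_cluster=2, rng_seed=11)
        g1, t1 = assemble_locus(bp)
        g2, t2 = assemble_locus(bp)
        assert [r.seq for r in g1] == [r.seq for r in g2]
        assert t1.features == t2.features

    def test_truth_coordinates_extract_planted_sequences(self, small_locus):
        _, genome, truth = small_locus
        seqs = {r.id: r.seq for r in genome}
        for f in truth.features:
            assert f.end <= len(seqs[f.seq_id])
            sub = seqs[f.seq_id][f.start0:f.end0]
            assert len(sub) == len(f)
            if f.type == "RSS" and f.strand == "+" \
                    and f.attributes["side"] == "downstream" \
                    and f.attributes["heptamer_mismatches"] == "0":
                assert sub.startswith("CAC")

    def test_orphons_on_separate_record_without_rss(self, small_locus):
        _, genome, truth = small_locus
        orphons = [f for f in truth.by_type("V_segment")
                   if f.attributes.get("orphon") == "true"]
        assert orphons
        assert all(f.seq_id == "chrSimOrphons" for f in orphons)
        assert all(f.attributes["pseudogene_cause"] == "no_rss"
                   for f in orphons)

    def test_blueprint_invariants_enforced(self):
        with pytest.raises(ValueError):
            LocusBlueprint(n_v_functional=-1)
        with pytest.raises(ValueError):
            LocusBlueprint(cassette_mutation_rate=1.5)
        with pytest.raises(ValueError):
            LocusBlueprint(switch_enrichment=0.5)


class TestReferencesAndHelpers:
    def test_spliced_reference_is_leader_plus_exon(self, small_locus):
        _, genome, truth = small_locus
        f = truth.by_type("V_segment")[0]
        cdna = feature_sequence(f, genome, spliced=True)
        spans = [tuple(map(int, s.split("-")))
                 for s in f.attributes["exons"].split(",")]
        assert len(cdna) == sum(e - s + 1 for s, e in spans)
        assert cdna.startswith("ATG")

    def test_rss_free_window_scans_clean(self, rng):
        from igloci.annotator import scan_window
        from igloci.io_formats import RunConfig
        for _ in range(20):
            assert scan_window(rss_free_window(rng), RunConfig()) is None
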