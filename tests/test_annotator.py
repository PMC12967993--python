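import numpy as np
import pytest

from conftest import random_dna
from igloci._seq import revcomp
from igloci.annotator import (annotate_locus, classify_j_motif,
                              classify_v_functionality, infer_jc_clusters,
                              scan_rss, scan_window)
from igloci.io_formats import Feature
from igloci.synthetic_locus import (RSS_HEPTAMER, RSS_NONAMER,
                                    extract_reference_set)

HEPT = RSS_HEPTAMER
NONA = RSS_NONAMER


def brute_force_scan(window, config):
    """Independent enumeration of every (offset, spacer) combination with
    the contract's tie-break: fewest total mismatches, then smaller offset,
    then 23-family spacer before 12-family, then spacer closest to nominal."""
    best = None
    for off in range(len(window) - 7 + 1):
        hept = window[off:off + 7]
        if not hept.startswith("CAC"):
            continue
        hmm = sum(a != b for a, b in zip(hept, HEPT))
        if hmm > config.heptamer_max_mm:
            continue
        for nominal in (12, 23):
            for spacer in range(nominal - config.spacer_tolerance,
                                nominal + config.spacer_tolerance + 1):
                nona = window[off + 7 + spacer:off + 7 + spacer + 8]
                if len(nona) < 8:
                    continue
                nmm = sum(a != b for a, b in zip(nona, NONA))
                if nmm > config.nonamer_max_mm:
                    continue
                key = (hmm + nmm, off, 0 if nominal == 23 else 1,
                       abs(spacer - nominal), spacer)
                if best is None or key < best[0]:
                    best = (key, (hmm + nmm, off, spacer, hmm, nmm))
    return None if best is None else best[1]


class TestScanRss:
    def test_planted_consensus_found_exactly(self, rng, config):
        window = HEPT + random_dna(rng, 23) + NONA + random_dna(rng, 4)
        got = scan_window(window, config)
        assert got == (0, 0, 23, 0, 0)

    def test_window_without_cac_yields_none(self, config):
        assert scan_window("T" * 42, config) is None

    def test_one_heptamer_mismatch_counted(self, rng, config):
        window = "CACTGTG" + random_dna(rng, 12) + NONA + random_dna(rng, 15)
        got = scan_window(window, config)
        assert got is not None
        total, off, spacer, hmm, nmm = got
        assert (off, spacer, hmm) == (0, 12, 1)

    def test_matches_brute_force_on_random_windows(self, rng, config):
        for _ in range(300):
            w = random_dna(rng, 42)
            assert scan_window(w, config) == brute_force_scan(w, config)

    def test_truncated_window_scanned(self, rng, config):
        genome = random_dna(rng, 10) + HEPT + random_dna(rng, 12) + NONA
        got = scan_rss(genome, 10, "+", "downstream", config)
        assert got is not None and got.spacer == 12

    def test_strand_and_side_geometry(self, rng, config):
        rss = HEPT + random_dna(rng, 23) + NONA
        pad = "TTTTTTTTTT"
        # V downstream on '+': RSS right after anchor
        g = pad + rss + pad
        hit = scan_rss(g, 10, "+", "downstream", config)
        assert (hit.start0, hit.end0) == (10, 10 + len(rss))
        # J upstream on '+': reverse-complemented element right before anchor
        g = pad + revcomp(rss) + pad
        hit = scan_rss(g, 10 + len(rss), "+", "upstream", config)
        assert (hit.start0, hit.end0) == (10, 10 + len(rss))
        # V downstream on '-': element before anchor, mirrored
        g = pad + revcomp(rss) + pad
        hit = scan_rss(g, 10 + len(rss), "-", "downstream", config)
        assert (hit.start0, hit.end0) == (10, 10 + len(rss))


class TestFunctionality:
    def _classified(self, truth, ann):
        out = []
        tmap = {(f.seq_id, f.start, f.end): f
                for f in truth.features if f.type == "V_segment"}
        for a in ann:
            if a.type != "V_segment":
                continue
            t = tmap.get((a.seq_id, a.start, a.end))
            if t is not None:
                out.append((t, a))
        return out

    def test_planted_causes_detected(self, small_locus, config):
        _, genome, truth = small_locus
        refs = extract_reference_set(truth, genome)
        ann = annotate_locus(genome, refs, config)
        cause_to_check = {"stop": "internal_stop", "frameshift": "frameshift",
                          "no_rss": "rss"}
        pairs = self._classified(truth, ann)
        assert pairs
        for t, a in pairs:
            cause = t.attributes["pseudogene_cause"]
            assert a.attributes["functionality"] == \
                t.attributes["functionality"]
            if cause == "none":
                assert "failed_checks" not in a.attributes
            else:
                failed = set(a.attributes["failed_checks"].split(","))
                if cause in cause_to_check:
                    assert cause_to_check[cause] in failed
                else:  # missing_residue
                    assert failed & {"cys23", "trp41", "trp52", "cys104"}

    def test_corruption_is_monotone(self, rng, config):
        """Breaking an additional check never flips pseudogene->functional."""
        from igloci.segment_mapper import GeneModelDraft
        from igloci.synthetic_locus import build_v_gene
        seq, feats = build_v_gene(rng, functional=True)
        spans = [tuple(map(int, s.split("-")))
                 for s in feats[0].attributes["exons"].split(",")]
        exons = [(s - 1, e) for s, e in spans]
        draft = GeneModelDraft("q", "t", "+", exons)
        rss_hit = object()  # any non-None stands for a valid RSS

        base = classify_v_functionality(draft, seq, rss_hit, config)
        assert base.status == "functional"
        # corrupt the leader start codon on top of an absent RSS
        broken = "TTG" + seq[3:]
        call1 = classify_v_functionality(draft, broken, None, config)
        assert call1.status == "pseudogene"
        assert {"orf_leader", "rss"} <= call1.failed_checks
        call2 = classify_v_functionality(draft, broken, rss_hit, config)
        assert call2.failed_checks <= call1.failed_checks


class TestJMotif:
    @pytest.mark.parametrize("aa,motif,prev", [
        ("WMFGGGTQLNVL", "GGG_triglycine", "F"),
        ("YVFGGGTQLSVL", "GGG_triglycine", "F"),
        ("YVLGGGTQLNVY", "GGG_triglycine", "L"),
        ("FGQGTKL", "FGXG_canonical", "F"),
        ("ADFGTESKLTVL", "FGXXS", "F"),
        ("ALFSGSSELTVL", "FSXXS", "F"),
        ("AAAAKLM", "other", None),
    ])
    def test_printed_and_constructed_motifs(self, aa, motif, prev):
        call = classify_j_motif(aa)
        assert call.motif_class == motif
        assert call.preceding_residue == prev

    def test_triglycine_takes_precedence_over_canonical(self):
        # FGGG matches both patterns; the tri-glycine reading wins
        assert classify_j_motif("YVFGGGTKL").motif_class == "GGG_triglycine"

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            classify_j_motif("FG1")
        with pytest.raises(ValueError):
            classify_j_motif("AB#XYZ")


class TestAnnotateLocus:
    def test_empty_reference_set_gives_empty_annotation(self, small_locus,
                                                        config):
        _, genome, _ = small_locus
        assert annotate_locus(genome, [], config) == []

    def test_functional_pseudogene_ratio_recovered(self, small_locus, config):
        bp, genome, truth = small_locus
        refs = extract_reference_set(truth, genome)
        ann = annotate_locus(genome, refs, config)
        v = [f for f in ann if f.type == "V_segment"]
        n_f = sum(f.attributes["functionality"] == "functional" for f in v)
        n_p = len(v) - n_f
        assert (n_f, n_p) == (bp.n_v_functional,
                              bp.n_v_pseudo + bp.orphon_count)

    def test_cluster_inference_counts_tandem_cassettes(self):
        def feat(start, ftype, strand="+"):
            return Feature("c", start, start + 10, strand, ftype)
        feats = [feat(1, "J_segment"), feat(20, "J_segment"),
                 feat(40, "C_gene"), feat(60, "J_segment"),
                 feat(80, "C_gene"), feat(100, "C_gene")]
        clusters = infer_jc_clusters(feats)
        assert [len(js) for js, _ in clusters] == [2, 1]
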