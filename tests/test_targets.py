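"""CDS position, NMD 50-nt rule, exon symmetry, splice classes, ESE/annotation
/SNP overlap."""

import numpy as np
import pytest

from conftest import build_transcript, guide_cutting_at, random_dna
from guidesmith.genome import AnnotationInterval, Polymorphism
from guidesmith.guides import Guide, extract_guides
from guidesmith.targets import (annotate_target, annotation_overlap,
                                cut_cds_offset, ese_overlap, exon_symmetry,
                                is_internal_exon, nmd_frames, pct_cds,
                                snp_overlap, splice_site_class)


def _cds_only_transcript(n_codons=100, exon_splits=(90, 210), strand="+"):
    """CDS-spanning transcript built from neutral CCC codons + TAA stop."""
    cds = "CCC" * (n_codons - 1) + "TAA"
    bounds = [0, *exon_splits, len(cds)]
    exons = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
    introns = ["GT" + "T" * 30 + "AG"] * (len(exons) - 1)
    return build_transcript(exons, introns, (0, len(cds)), strand)


class TestPctCds:
    def test_cut_at_cds_start_is_zero(self):
        genome, tx = _cds_only_transcript()
        assert pct_cds(guide_cutting_at(tx, 0), tx) == 0.0

    def test_cut_near_end_is_flagged_region(self):
        genome, tx = _cds_only_transcript()
        assert pct_cds(guide_cutting_at(tx, 294), tx) == pytest.approx(0.98)

    def test_cut_midway(self):
        genome, tx = _cds_only_transcript()
        assert pct_cds(guide_cutting_at(tx, 150), tx) == pytest.approx(0.50)

    def test_intronic_cut_has_no_value(self):
        genome, tx = _cds_only_transcript()
        g = guide_cutting_at(tx, 0)
        intronic = Guide(g.guide_id, g.contig_id, "+", g.protospacer, g.pam,
                         g.protospacer_start, tx.exons[0][1] + 5, g.context30)
        assert pct_cds(intronic, tx) is None

    def test_strictly_increasing_along_cds(self, fixture_data):
        genome = fixture_data.genome
        tx = fixture_data.transcripts[0]
        vals = []
        for g in extract_guides(genome):
            v = pct_cds(g, tx)
            if v is not None:
                vals.append((cut_cds_offset(g, tx), v))
        vals.sort()
        assert len(vals) > 5
        assert all(b[1] > a[1] for a, b in zip(vals, vals[1:]) if b[0] > a[0])


def _planted_stop_transcript(exon_lens, stops, cds_len, strand="+"):
    """Transcript of neutral C's with TAA stops planted at given spliced
    offsets; CDS ends with its own TAA."""
    total = sum(exon_lens)
    seq = ["C"] * total
    seq[cds_len - 3:cds_len] = "TAA"
    for q in stops:
        seq[q:q + 3] = "TAA"
    tx_seq = "".join(seq)
    bounds = np.cumsum([0, *exon_lens])
    exons = [tx_seq[a:b] for a, b in zip(bounds, bounds[1:])]
    introns = ["GTCCCCCCAG"] * (len(exons) - 1)
    return build_transcript(exons, introns, (0, cds_len), strand)


class TestNmdFrames:
    def test_both_shifted_frames_stop_far_upstream(self):
        # 5 exons, last junction at 360; +1-frame stop at 8, +2 at 13
        genome, tx = _planted_stop_transcript(
            [90, 90, 90, 90, 120], stops=[8, 13], cds_len=60)
        g = guide_cutting_at(tx, 6)
        assert nmd_frames(g, tx, genome) == 2

    def test_cut_in_last_exon_never_induces_nmd(self):
        genome, tx = _planted_stop_transcript(
            [90, 90, 90, 90, 120], stops=[8, 13], cds_len=420)
        # breakpoint inside the last exon and inside the CDS
        g = guide_cutting_at(tx, 390)
        assert nmd_frames(g, tx, genome) == 0

    def test_one_frame_stops_too_close_to_last_junction(self):
        # last junction at 240; +1 stop at 230 (10 nt upstream, too close),
        # +2 stop at 40 (200 nt upstream, induces NMD)
        genome, tx = _planted_stop_transcript(
            [80, 80, 80, 100], stops=[230, 40], cds_len=60)
        g = guide_cutting_at(tx, 6)
        assert nmd_frames(g, tx, genome) == 1

    def test_minus_strand_mirror(self):
        genome, tx = _planted_stop_transcript(
            [90, 90, 90, 90, 120], stops=[8, 13], cds_len=60, strand="-")
        g = guide_cutting_at(tx, 6)
        assert nmd_frames(g, tx, genome) == 2

    def test_single_exon_transcript_scores_zero(self):
        genome, tx = _planted_stop_transcript([300], stops=[8, 13], cds_len=60)
        assert nmd_frames(guide_cutting_at(tx, 6), tx, genome) == 0

    def test_last_exon_rule_holds_across_fixture(self, fixture_data):
        genome = fixture_data.genome
        for tx in fixture_data.transcripts:
            last = tx.exons_transcription_order()[-1]
            for g in extract_guides(genome):
                b = g.cut_position
                pos = b if tx.strand == "+" else b - 1
                if last[0] <= pos < last[1] and cut_cds_offset(g, tx) is not None:
                    assert nmd_frames(g, tx, genome) == 0


class TestExonSymmetry:
    def test_symmetric_internal_exon(self):
        genome, tx = _cds_only_transcript(exon_splits=(90, 189))   # middle 99 nt
        assert exon_symmetry(tx, tx.exons_transcription_order()[1]) is False

    def test_asymmetric_internal_exon(self):
        genome, tx = _cds_only_transcript(exon_splits=(90, 190))   # middle 100 nt
        assert exon_symmetry(tx, tx.exons_transcription_order()[1]) is True

    def test_terminal_exons_not_applicable(self):
        genome, tx = _cds_only_transcript()
        order = tx.exons_transcription_order()
        assert exon_symmetry(tx, order[0]) is None
        assert exon_symmetry(tx, order[-1]) is None

    def test_internal_exon_flag(self):
        genome, tx = _cds_only_transcript()
        assert is_internal_exon(tx, guide_cutting_at(tx, 150)) is True
        assert is_internal_exon(tx, guide_cutting_at(tx, 10)) is False


class TestSpliceSiteClass:
    @staticmethod
    def _guide_with_cut(tx, b):
        return Guide("synthetic", tx.contig_id, "+", "A" * 20, "AGG",
                     b - 17, b, "A" * 30)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_donor_edge_and_offsets(self, strand):
        genome, tx = _cds_only_transcript(strand=strand)
        first = tx.exons_transcription_order()[0]
        # breakpoint at the donor edge of the first exon
        b = first[1] if strand == "+" else first[0]
        assert splice_site_class(self._guide_with_cut(tx, b), tx) == "sd+0"

    def test_donor_two_nt_into_intron(self):
        genome, tx = _cds_only_transcript()
        e = tx.exons_transcription_order()[0][1]
        g = guide_cutting_at(tx, 0)
        shifted = Guide(g.guide_id, g.contig_id, "+", g.protospacer, g.pam,
                        g.protospacer_start, e + 2, g.context30)
        assert splice_site_class(shifted, tx) == "sd+2"

    def test_acceptor_edge_and_intron_offset(self):
        genome, tx = _cds_only_transcript()
        s = tx.exons_transcription_order()[1][0]
        assert splice_site_class(self._guide_with_cut(tx, s), tx) == "sa+0"
        assert splice_site_class(self._guide_with_cut(tx, s - 1), tx) == "sa+1"

    def test_mid_exon_is_none(self):
        genome, tx = _cds_only_transcript()
        assert splice_site_class(guide_cutting_at(tx, 45), tx) == "none"


class TestEseOverlap:
    def test_motif_planted_across_cut(self):
        genome, tx = _cds_only_transcript()
        contig = genome[tx.contig_id]
        g = guide_cutting_at(tx, 45)
        b = g.cut_position
        motif = contig[b - 3:b + 3]
        assert ese_overlap(g, tx, genome, [motif]) is True

    def test_motif_away_from_cut_requires_overlap(self):
        genome, tx = _cds_only_transcript()
        contig = genome[tx.contig_id]
        g = guide_cutting_at(tx, 45)
        far = contig[g.cut_position + 30:g.cut_position + 36]
        got = ese_overlap(g, tx, genome, [far])
        # CCC-homopolymer background may repeat the motif across the cut;
        # use a unique marker instead for the negative case
        genome2, tx2 = _cds_only_transcript()
        assert ese_overlap(g, tx, genome, ["TTTTTT"]) is False
        assert ese_overlap(g, tx, genome, []) is False

    def test_exon_presence_mode(self):
        genome, tx = _cds_only_transcript()
        contig = genome[tx.contig_id]
        g = guide_cutting_at(tx, 45)
        far = contig[g.cut_position + 20:g.cut_position + 26]
        assert ese_overlap(g, tx, genome, [far],
                           require_cut_overlap=False) is True


class TestAnnotationOverlap:
    def _guide_at_residue(self, tx, residue):
        return guide_cutting_at(tx, (residue - 1) * 3 + 1)

    def test_domain_containment(self):
        genome, tx = _cds_only_transcript()
        dom = AnnotationInterval(kind="CDD_domain", gene_id=tx.gene_id,
                                 aa_start=10, aa_end=100)
        g50 = self._guide_at_residue(tx, 50)
        assert annotation_overlap(g50, tx, [dom])["in_domain"] is True
        g5 = self._guide_at_residue(tx, 5)
        assert annotation_overlap(g5, tx, [dom])["in_domain"] is False

    def test_point_site_at_cut_residue(self):
        genome, tx = _cds_only_transcript()
        site = AnnotationInterval(kind="CDD_site", gene_id=tx.gene_id,
                                  aa_start=50, aa_end=50)
        g = self._guide_at_residue(tx, 50)
        assert annotation_overlap(g, tx, [site])["in_cdd_site"] is True

    def test_uniprot_kinds_reported(self):
        genome, tx = _cds_only_transcript()
        helix = AnnotationInterval(kind="Uniprot_helix", gene_id=tx.gene_id,
                                   aa_start=40, aa_end=60)
        g = self._guide_at_residue(tx, 50)
        assert annotation_overlap(g, tx, [helix])["uniprot_2ary"] == "helix"

    def test_matches_brute_force_interval_scan(self):
        rng = np.random.default_rng(55)
        genome, tx = _cds_only_transcript()
        prot_len = tx.cds_length // 3 - 1
        for _ in range(300):
            a = int(rng.integers(1, prot_len))
            b = int(rng.integers(a, prot_len + 1))
            residue = int(rng.integers(1, prot_len + 1))
            iv = AnnotationInterval(kind="CDD_domain", gene_id=tx.gene_id,
                                    aa_start=a, aa_end=b)
            g = self._guide_at_residue(tx, residue)
            assert annotation_overlap(g, tx, [iv])["in_domain"] == (a <= residue <= b)


class TestSnpOverlap:
    def _guide(self):
        return Guide("c:100:+", "c", "+", "A" * 20, "AGG", 100, 117, "A" * 30)

    def test_pam_snp_above_threshold(self):
        g = self._guide()
        snp = Polymorphism("c", 122, "A", "G", 0.12)   # inside the PAM
        assert snp_overlap(g, [snp]) is True

    def test_low_vaf_ignored(self):
        g = self._guide()
        snp = Polymorphism("c", 110, "A", "G", 0.05)
        assert snp_overlap(g, [snp]) is False

    def test_deletion_footprint_straddles_edge(self):
        g = self._guide()
        deletion = Polymorphism("c", 98, "AAAA", "A", 0.30)   # 98..102 overlaps 100
        assert snp_overlap(g, [deletion]) is True

    def test_adjacent_but_not_overlapping(self):
        g = self._guide()
        snp = Polymorphism("c", 123, "A", "G", 0.50)   # first base past the PAM
        assert snp_overlap(g, [snp]) is False


class TestAnnotateTarget:
    def test_full_record_for_cds_cut(self, fixture_data):
        genome = fixture_data.genome
        tx = fixture_data.transcripts[0]
        for g in extract_guides(genome):
            t = annotate_target(g, tx, genome,
                                intervals=fixture_data.annotations,
                                polymorphisms=fixture_data.polymorphisms,
                                ese_motifs=fixture_data.ese_motifs)
            if t is None:
                continue
            assert 0.0 <= t.pct_cds <= 1.0
            assert t.aa_position == cut_cds_offset(g, tx) // 3 + 1
            assert t.strand_relative in ("same", "opposite")
            break
        else:
            pytest.fail("no CDS-cutting guide found")

    def test_non_cds_cut_returns_none(self):
        genome, tx = _cds_only_transcript()
        g = guide_cutting_at(tx, 0)
        intergenic = Guide(g.guide_id, g.contig_id, "+", g.protospacer, g.pam,
                           5, 4, g.context30)
        assert annotate_target(intergenic, tx, genome) is None
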