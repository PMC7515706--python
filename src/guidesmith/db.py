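"""Assembly of the per-guide feature database.

Runs extraction, intrinsic annotation, specificity, target features and
conservation lookup over a genome and emits one row per CDS-cutting guide —
the unit every downstream step (tiering, picking, training) consumes.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import conservation as cons
from . import guides as gd
from . import intrinsic as intr
from . import specificity as spec
from . import targets as tg
from .design import GuideFeatureRecord

logger = logging.getLogger(__name__)


def principal_transcripts(transcripts) -> dict[str, object]:
    """One principal transcript per gene (first principal, else first)."""
    by_gene: dict[str, object] = {}
    for tx in transcripts:
        cur = by_gene.get(tx.gene_id)
        if cur is None or (tx.is_principal and not cur.is_principal):
            by_gene[tx.gene_id] = tx
    return by_gene


def build_feature_database(genome, transcripts, scorer,
                           annotations=(), polymorphisms=(), ese_motifs=(),
                           conservation_tracks: dict[str, cons.ConservationTrack] | None = None,
                           construct_context: intr.ConstructContext = intr.ConstructContext(),
                           proteome_specificity: bool = False,
                           max_mm: int = 4, max_hits: int = 5000,
                           ) -> tuple[list[GuideFeatureRecord], pd.DataFrame]:
    """Annotate every CDS-cutting guide against its gene's principal isoform.

    Returns the design-facing records plus a tidy DataFrame carrying every
    feature (including those annotated but not used as tier criteria),
    suitable for the training analysis.
    """
    conservation_tracks = conservation_tracks or {}
    all_guides = gd.extract_guides(genome)
    genome_index = spec.OfftargetIndex(genome)
    proteome_index = None
    if proteome_specificity:
        proteome_index = spec.OfftargetIndex(spec.cds_search_space(transcripts, genome))
    by_gene = principal_transcripts(transcripts)

    records: list[GuideFeatureRecord] = []
    rows = []
    for guide in all_guides:
        target = None
        transcript = None
        for tx in by_gene.values():
            if tx.contig_id != guide.contig_id:
                continue
            t = tg.annotate_target(guide, tx, genome, annotations,
                                   polymorphisms, ese_motifs)
            if t is not None:
                target, transcript = t, tx
                break
        if target is None:
            continue   # UTR/intron/intergenic cuts carry no target features
        intrinsics = intr.annotate_intrinsic(guide, scorer, construct_context)
        sp_record, hits = spec.specificity_record(
            guide, genome_index, proteome_index, max_mm, max_hits)
        on_target = spec.find_on_target(guide, hits)
        close = sum(1 for h in hits
                    if h.m <= 1 and (on_target is None or h != on_target))
        conservation_score = None
        track = conservation_tracks.get(target.gene_id)
        if track is not None and 1 <= target.aa_position <= len(track):
            conservation_score = track.scores[target.aa_position - 1]
        records.append(GuideFeatureRecord(
            guide_id=guide.guide_id, gene_id=target.gene_id,
            contig_id=guide.contig_id, strand=guide.strand,
            cut_position=guide.cut_position,
            efficacy=intrinsics.efficacy,
            specificity=sp_record.specificity,
            conservation=conservation_score,
            pct_cds=target.pct_cds,
            in_domain=target.in_domain,
            poly_a=intrinsics.poly_a, poly_c=intrinsics.poly_c,
            poly_g=intrinsics.poly_g, poly_t=intrinsics.poly_t,
            has_esp3i=intrinsics.has_esp3i,
            snp_overlap=target.snp_overlap,
            close_offtargets=close,
            exceeded_max_hits=sp_record.exceeded_max_hits,
        ))
        rows.append({
            "guide_id": guide.guide_id, "gene_id": target.gene_id,
            "transcript_id": target.transcript_id,
            "contig_id": guide.contig_id, "strand": guide.strand,
            "cut_position": guide.cut_position,
            "protospacer": guide.protospacer, "pam": guide.pam,
            "efficacy": intrinsics.efficacy,
            "specificity": sp_record.specificity,
            "proteome_specificity": sp_record.proteome_specificity,
            "exceeded_max_hits": sp_record.exceeded_max_hits,
            "mm0": sp_record.mm_counts[0], "mm1": sp_record.mm_counts[1],
            "mm2": sp_record.mm_counts[2], "mm3": sp_record.mm_counts[3],
            "mm4": sp_record.mm_counts[4],
            "close_offtargets": close,
            "conservation": conservation_score,
            "tm": intrinsics.tm_celsius,
            "poly_a": intrinsics.poly_a, "poly_c": intrinsics.poly_c,
            "poly_g": intrinsics.poly_g, "poly_t": intrinsics.poly_t,
            "esp3i": intrinsics.has_esp3i,
            "pct_cds": target.pct_cds, "cds_gt95": target.pct_cds > 0.95,
            "aa_position": target.aa_position,
            "nmd_frames": target.nmd_frames,
            "internal_exon": target.internal_exon,
            "exon_asymmetric": bool(target.exon_asymmetric),
            "splice_class": target.splice_class,
            "ese": target.ese_overlap,
            "domain": target.in_domain, "cdd_site": target.in_cdd_site,
            "pfam": target.in_pfam,
            "uniprot_helix": target.uniprot_2ary == "helix",
            "uniprot_beta": target.uniprot_2ary == "beta",
            "uniprot_turn": target.uniprot_2ary == "turn",
            "uniprot_ccr": target.uniprot_2ary == "ccr",
            "snp": target.snp_overlap,
            "strand_relative": target.strand_relative,
            "in_cds": True,
            "poly_a_ge5": intrinsics.poly_a >= 5,
            "poly_c_ge5": intrinsics.poly_c >= 5,
            "poly_g_ge5": intrinsics.poly_g >= 5,
            "poly_t_ge3": intrinsics.poly_t >= 3,
        })
    return records, pd.DataFrame(rows)
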