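"""Features of what a guide cuts: CDS position, NMD competence, exon
symmetry, splice-site proximity, ESE overlap, domain/site/secondary-structure
overlap, and polymorphism overlap.

Guides whose cut falls outside the CDS (UTR, intron, intergenic) receive no
target features and are excluded from tiered design.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import STOP_CODONS, AnnotationInterval, Polymorphism, TranscriptModel

NMD_DISTANCE_NT = 55   # conservative end of the published 50-55 nt range

UNIPROT_KINDS = {
    "Uniprot_helix": "helix",
    "Uniprot_beta": "beta",
    "Uniprot_turn": "turn",
    "Uniprot_CCR": "ccr",
}


@dataclass(frozen=True)
class TargetFeatures:
    gene_id: str
    transcript_id: str
    pct_cds: float
    aa_position: int                 # 1-based residue under the cut
    nmd_frames: int                  # of the 2 frameshift frames, how many induce NMD
    internal_exon: bool
    exon_asymmetric: bool | None     # None when not an internal exon
    splice_class: str                # sd+0..sd+2, sa+0..sa+2 or none
    ese_overlap: bool
    in_domain: bool
    in_cdd_site: bool
    in_pfam: bool
    uniprot_2ary: str                # helix, beta, turn, ccr or none
    snp_overlap: bool
    strand_relative: str             # same or opposite

    def __post_init__(self):
        if not 0.0 <= self.pct_cds <= 1.0:
            raise ValueError("pct_cds outside [0, 1]")
        if self.nmd_frames not in (0, 1, 2):
            raise ValueError("nmd_frames must be 0, 1 or 2")


def cut_cds_offset(guide, transcript: TranscriptModel) -> int | None:
    """0-based spliced-CDS offset of the cut breakpoint: the number of CDS
    nucleotides 5' (in transcript orientation) of the cut.

    None when the breakpoint does not fall strictly inside the CDS.
    """
    b = guide.cut_position
    # base immediately 3' of the breakpoint in transcript orientation
    pos = b if transcript.strand == "+" else b - 1
    return transcript.genome_to_cds(pos)


def pct_cds(guide, transcript: TranscriptModel) -> float | None:
    """Fractional position of the cut within the spliced CDS."""
    off = cut_cds_offset(guide, transcript)
    if off is None:
        return None
    return off / transcript.cds_length


def aa_position(guide, transcript: TranscriptModel) -> int | None:
    off = cut_cds_offset(guide, transcript)
    if off is None:
        return None
    return off // 3 + 1


def _cut_transcript_offset(guide, transcript: TranscriptModel) -> int | None:
    b = guide.cut_position
    pos = b if transcript.strand == "+" else b - 1
    return transcript.genome_to_transcript(pos)


def nmd_frames(guide, transcript: TranscriptModel, genome,
               distance_nt: int = NMD_DISTANCE_NT) -> int | None:
    """How many of the two frameshift frames yield an NMD-inducing stop.

    Frameshift model: a net +1 or +2 nt insertion at the cut.  Downstream of
    the cut the reading frame of the mature mRNA shifts; the first in-frame
    stop codon is found by scanning complete shifted codons 3' of the cut.
    The frame induces NMD iff that stop starts more than ``distance_nt``
    upstream of the last exon-exon junction (the 50-nt rule).  Single-exon
    transcripts can never satisfy the rule and score 0.
    """
    t_cut = _cut_transcript_offset(guide, transcript)
    if t_cut is None or cut_cds_offset(guide, transcript) is None:
        return None
    junctions = transcript.junction_transcript_positions()
    if not junctions:
        return 0
    last_junction = junctions[-1]
    mrna = transcript.spliced_sequence(genome)
    c0 = transcript.cds_start_transcript()
    count = 0
    for ins in (1, 2):
        # after inserting `ins` nt at t_cut, a downstream base originally at
        # transcript position q starts a codon iff (q - c0 + ins) % 3 == 0
        q = t_cut + ((-(t_cut - c0 + ins)) % 3)
        stop_at = None
        while q + 3 <= len(mrna):
            if mrna[q:q + 3] in STOP_CODONS:
                stop_at = q
                break
            q += 3
        if stop_at is not None and last_junction - stop_at > distance_nt:
            count += 1
    return count


def exon_symmetry(transcript: TranscriptModel, exon: tuple[int, int]) -> bool | None:
    """True when removing the (internal) exon frameshifts downstream exons:
    its exonic CDS length is not a multiple of 3.  None for first/last exons
    (the feature is defined for internal exons only)."""
    order = transcript.exons_transcription_order()
    if exon == order[0] or exon == order[-1]:
        return None
    es, ee = exon
    cds_nt = sum(max(0, min(ee, ce) - max(es, cs)) for cs, ce in transcript.cds)
    return cds_nt % 3 != 0


def _containing_exon(transcript: TranscriptModel, guide) -> tuple[int, int] | None:
    b = guide.cut_position
    pos = b if transcript.strand == "+" else b - 1
    for s, e in transcript.exons:
        if s <= pos < e:
            return (s, e)
    return None


def is_internal_exon(transcript: TranscriptModel, guide) -> bool | None:
    exon = _containing_exon(transcript, guide)
    if exon is None:
        return None
    order = transcript.exons_transcription_order()
    return exon != order[0] and exon != order[-1]


def splice_site_class(guide, transcript: TranscriptModel) -> str:
    """Position of the cut relative to the nearest exon edge: sd (splice
    donor, downstream intron) or sa (splice acceptor, upstream intron),
    with offsets +0 (exon edge), +1 and +2 (into the splice site); "none"
    beyond 2 nt.

    Offsets are measured between the cut breakpoint and the exon boundary
    in the intron direction.  Terminal transcript ends have no splice site
    and report "none".
    """
    b = guide.cut_position
    order = transcript.exons_transcription_order()
    best = "none"
    for k, (s, e) in enumerate(order):
        if transcript.strand == "+":
            donor_edge, acceptor_edge = e, s
            donor_off, acceptor_off = b - donor_edge, acceptor_edge - b
        else:
            donor_edge, acceptor_edge = s, e
            donor_off, acceptor_off = donor_edge - b, b - acceptor_edge
        if k < len(order) - 1 and 0 <= donor_off <= 2:
            return f"sd+{donor_off}"
        if k > 0 and 0 <= acceptor_off <= 2:
            best = f"sa+{acceptor_off}"
    return best


def ese_overlap(guide, transcript: TranscriptModel, genome,
                motifs, require_cut_overlap: bool = True) -> bool:
    """True iff an exonic-splicing-enhancer motif occurrence in the cut exon
    overlaps the cut (default) — the cut then abrogates the motif — or, in
    exon-presence mode, merely occurs anywhere in that exon.

    Motifs are exact DNA strings matched in transcript orientation.
    """
    if not motifs:
        return False
    exon = _containing_exon(transcript, guide)
    if exon is None:
        return False
    s, e = exon
    seq = genome[transcript.contig_id][s:e]
    if transcript.strand == "-":
        from .genome import revcomp
        seq = revcomp(seq)
    b = guide.cut_position
    # breakpoint offset within the exon, transcript orientation
    cut_off = (b - s) if transcript.strand == "+" else (e - b)
    for motif in motifs:
        start = seq.find(motif)
        while start != -1:
            if not require_cut_overlap:
                return True
            if start < cut_off < start + len(motif):   # cut splits the motif
                return True
            start = seq.find(motif, start + 1)
    return False


def annotation_overlap(guide, transcript: TranscriptModel,
                       intervals: list[AnnotationInterval],
                       ) -> dict[str, object]:
    """Per-kind overlap of the cut with domain/site/structure annotations.

    Protein-space intervals are tested against the residue index under the
    cut; genome-space intervals against the cut breakpoint.
    """
    aa = aa_position(guide, transcript)
    b = guide.cut_position
    out = {"in_domain": False, "in_cdd_site": False, "in_pfam": False,
           "uniprot_2ary": "none"}
    for iv in intervals:
        if iv.is_protein_space:
            if iv.gene_id != transcript.gene_id or aa is None:
                continue
            hit = iv.aa_start <= aa <= iv.aa_end
        else:
            if iv.contig_id != transcript.contig_id:
                continue
            # the cut intersects the interval when either base flanking the
            # breakpoint lies inside it
            hit = iv.start <= b - 1 < iv.end or iv.start <= b < iv.end
        if not hit:
            continue
        if iv.kind == "CDD_domain":
            out["in_domain"] = True
        elif iv.kind == "CDD_site":
            out["in_cdd_site"] = True
        elif iv.kind == "Pfam_domain":
            out["in_pfam"] = True
        elif iv.kind in UNIPROT_KINDS:
            out["uniprot_2ary"] = UNIPROT_KINDS[iv.kind]
    return out


def snp_overlap(guide, polymorphisms: list[Polymorphism],
                vaf_min: float = 0.10) -> bool:
    """True iff a variant at or above ``vaf_min`` allele frequency overlaps
    the 23-nt protospacer+PAM footprint (indels by reference footprint)."""
    lo, hi = guide.target_interval
    for p in polymorphisms:
        if p.contig_id != guide.contig_id or p.vaf < vaf_min:
            continue
        ps, pe = p.interval
        if ps < hi and pe > lo:
            return True
    return False


def annotate_target(guide, transcript: TranscriptModel, genome,
                    intervals: list[AnnotationInterval] = (),
                    polymorphisms: list[Polymorphism] = (),
                    ese_motifs=(), vaf_min: float = 0.10,
                    nmd_distance_nt: int = NMD_DISTANCE_NT,
                    ese_require_cut_overlap: bool = True,
                    ) -> TargetFeatures | None:
    """All target features for one guide, or None when the cut is not in
    the transcript's CDS."""
    off = cut_cds_offset(guide, transcript)
    if off is None:
        return None
    exon = _containing_exon(transcript, guide)
    internal = is_internal_exon(transcript, guide)
    ann = annotation_overlap(guide, transcript, list(intervals))
    return TargetFeatures(
        gene_id=transcript.gene_id,
        transcript_id=transcript.transcript_id,
        pct_cds=off / transcript.cds_length,
        aa_position=off // 3 + 1,
        nmd_frames=nmd_frames(guide, transcript, genome, nmd_distance_nt),
        internal_exon=bool(internal),
        exon_asymmetric=exon_symmetry(transcript, exon) if exon else None,
        splice_class=splice_site_class(guide, transcript),
        ese_overlap=ese_overlap(guide, transcript, genome, list(ese_motifs),
                                ese_require_cut_overlap),
        in_domain=ann["in_domain"],
        in_cdd_site=ann["in_cdd_site"],
        in_pfam=ann["in_pfam"],
        uniprot_2ary=ann["uniprot_2ary"],
        snp_overlap=snp_overlap(guide, list(polymorphisms), vaf_min),
        strand_relative="same" if guide.strand == transcript.strand else "opposite",
    )
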