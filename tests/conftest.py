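"""Shared fixtures and transcript-construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from guidesmith.genome import TranscriptModel, revcomp
from guidesmith.guides import Guide
from guidesmith.synth import FixtureSpec, make_fixture

BASES = "ACGT"


@pytest.fixture(scope="session")
def fixture_data():
    """One deterministic synthetic dataset shared across the session."""
    return make_fixture(FixtureSpec(seed=42))


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def build_transcript(exon_seqs, intron_seqs, cds_span, strand="+",
                     contig="chrX", gene_id="GX", pad=30, rng=None):
    """Assemble a genome + TranscriptModel from explicit transcript pieces.

    ``exon_seqs`` are in transcription order; ``cds_span`` is a (start, end)
    half-open range in spliced-transcript coordinates.  The gene is placed
    ``pad`` nt into the contig; for minus-strand transcripts the genomic
    sequence is the reverse complement of the assembled plus-orientation
    gene and all intervals are mirrored.
    """
    if rng is None:
        rng = np.random.default_rng(7)
    assert len(intron_seqs) == len(exon_seqs) - 1
    parts, rel_exons, off = [], [], 0
    for k, ex in enumerate(exon_seqs):
        parts.append(ex)
        rel_exons.append((off, off + len(ex)))
        off += len(ex)
        if k < len(intron_seqs):
            parts.append(intron_seqs[k])
            off += len(intron_seqs[k])
    gene_plus = "".join(parts)
    c0, c1 = cds_span
    rel_cds, t = [], 0
    for (es, ee), ex in zip(rel_exons, exon_seqs):
        lo, hi = max(c0, t), min(c1, t + len(ex))
        if lo < hi:
            rel_cds.append((es + (lo - t), es + (hi - t)))
        t += len(ex)
    L = len(gene_plus)
    if strand == "-":
        gene_seq = revcomp(gene_plus)
        rel_exons = [(L - e, L - s) for s, e in rel_exons]
        rel_cds = [(L - e, L - s) for s, e in rel_cds]
    else:
        gene_seq = gene_plus
    genome = {contig: random_dna(rng, pad) + gene_seq + random_dna(rng, pad)}
    tx = TranscriptModel(
        gene_id=gene_id, transcript_id=f"{gene_id}.t1", contig_id=contig,
        strand=strand,
        exons=[(pad + s, pad + e) for s, e in rel_exons],
        cds=[(pad + s, pad + e) for s, e in rel_cds])
    return genome, tx


def transcript_base_to_genomic(tx: TranscriptModel, t: int) -> int:
    """Genomic coordinate of spliced-transcript base ``t``."""
    off = 0
    order = tx.exons if tx.strand == "+" else tx.exons[::-1]
    for s, e in order:
        n = e - s
        if t < off + n:
            return s + (t - off) if tx.strand == "+" else e - 1 - (t - off)
        off += n
    raise IndexError(t)


def guide_cutting_at(tx: TranscriptModel, t_breakpoint: int,
                     guide_strand: str = "+") -> Guide:
    """A synthetic Guide whose cut breakpoint precedes spliced-transcript
    base ``t_breakpoint``; sequence fields are placeholders."""
    p = transcript_base_to_genomic(tx, t_breakpoint)
    b = p if tx.strand == "+" else p + 1
    start = b - 17 if guide_strand == "+" else b - 3
    return Guide(guide_id=f"synthetic:{b}:{guide_strand}", contig_id=tx.contig_id,
                 strand=guide_strand, protospacer="A" * 20, pam="AGG",
                 protospacer_start=start, cut_position=b, context30="A" * 30)
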