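"""Deletion-based per-residue protein conservation.

The score for residue i is the negated alignment-delta of deleting that
residue: for every ortholog, align the wild-type protein and the deletion
variant to it with a semi-global affine-gap aligner and take the score
difference; deltas are averaged within sequence clusters, cluster means are
averaged, and the sign is flipped so that larger positive values mean higher
conservation.  Regions whose length is invariant across orthologs score
high — even in-frame indels there are likely to disrupt function — while
length-variable regions score near zero.

Substitution mode (averaging all 20 amino-acid replacements) and 2- or 3-
residue deletion windows are provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0

CONSERVED_SCORE_THRESHOLD = 7.0


def blosum62():
    return substitution_matrices.load("BLOSUM62")


def identity_matrix(match: float = 5.0, mismatch: float = -2.0):
    """Flat identity substitution matrix (+5 identical / -2 different)."""
    alphabet = AMINO_ACIDS + "BZX*"
    n = len(alphabet)
    data = np.full((n, n), mismatch)
    np.fill_diagonal(data, match)
    return substitution_matrices.Array(alphabet=alphabet, dims=2, data=data)


def _aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = matrix
    # affine cost: a gap of length L costs gap_open + L * gap_extend
    a.open_gap_score = -(gap_open + gap_extend)
    a.extend_gap_score = -gap_extend
    # semi-global: end gaps are free
    a.end_insertion_score = 0.0
    a.end_deletion_score = 0.0
    return a


def semiglobal_align_score(query: str, subject: str, matrix=None,
                           gap_open: float = DEFAULT_GAP_OPEN,
                           gap_extend: float = DEFAULT_GAP_EXTEND) -> float:
    """Optimal semi-global (free end gaps) affine-gap alignment score."""
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    if matrix is None:
        matrix = blosum62()
    return float(_aligner(matrix, gap_open, gap_extend).score(query, subject))


@dataclass
class OrthologSet:
    """Supporting sequences for one gene, partitioned into clusters.

    By default every sequence is its own cluster; ``cluster_by_identity``
    reproduces a greedy >=75 %-identity clustering scheme.
    """
    gene_id: str
    sequences: list[tuple[str, str]]          # (source_id, protein)
    clusters: list[list[int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequences:
            raise ValueError(f"{self.gene_id}: ortholog set is empty")
        for sid, seq in self.sequences:
            if not seq:
                raise ValueError(f"{self.gene_id}/{sid}: empty protein")
            bad = set(seq) - set(AMINO_ACIDS + "X")
            if bad:
                raise ValueError(f"{self.gene_id}/{sid}: invalid residues {bad}")
        if not self.clusters:
            self.clusters = [[i] for i in range(len(self.sequences))]
        covered = sorted(i for c in self.clusters for i in c)
        if covered != list(range(len(self.sequences))):
            raise ValueError("clusters must cover all sequences exactly once")

    @classmethod
    def from_fasta(cls, gene_id: str, path) -> "OrthologSet":
        seqs = [(rec.id, str(rec.seq).upper())
                for rec in SeqIO.parse(str(path), "fasta")]
        return cls(gene_id, seqs)

    def cluster_by_identity(self, threshold: float = 0.75) -> None:
        """Greedy clustering: each sequence joins the first cluster whose
        representative shares >= threshold identity (ungapped, over the
        shorter length), else founds a new cluster."""
        reps: list[int] = []
        clusters: list[list[int]] = []
        for i, (_, seq) in enumerate(self.sequences):
            placed = False
            for ci, r in enumerate(reps):
                ref = self.sequences[r][1]
                n = min(len(seq), len(ref))
                ident = sum(a == b for a, b in zip(seq, ref)) / n
                if ident >= threshold:
                    clusters[ci].append(i)
                    placed = True
                    break
            if not placed:
                reps.append(i)
                clusters.append([i])
        self.clusters = clusters


@dataclass(frozen=True)
class ConservationTrack:
    """Per-residue conservation scores for one protein (higher = more
    conserved)."""
    gene_id: str
    scores: tuple[float, ...]
    deletion_width: int = 1

    def __len__(self) -> int:
        return len(self.scores)


def delta_score(protein: str, variant_protein: str, ortholog_set: OrthologSet,
                matrix=None, gap_open: float = DEFAULT_GAP_OPEN,
                gap_extend: float = DEFAULT_GAP_EXTEND) -> float:
    """Mean alignment-score change caused by a variant.

    For each supporting sequence: score(variant, subject) − score(wild type,
    subject).  Deltas are averaged within each cluster, then cluster means
    are averaged.  Negative deltas indicate deleterious variants.
    """
    if not ortholog_set.sequences:
        raise ValueError("ortholog set is empty")
    if matrix is None:
        matrix = blosum62()
    aligner = _aligner(matrix, gap_open, gap_extend)
    if variant_protein == protein:
        return 0.0
    deltas = [float(aligner.score(variant_protein, subj)) -
              float(aligner.score(protein, subj))
              for _, subj in ortholog_set.sequences]
    cluster_means = [float(np.mean([deltas[i] for i in cluster]))
                     for cluster in ortholog_set.clusters]
    return float(np.mean(cluster_means))


def aadelcons_track(protein: str, ortholog_set: OrthologSet,
                    deletion_width: int = 1, matrix=None,
                    gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND) -> ConservationTrack:
    """Per-residue deletion-conservation track.

    For width 1, scores[i] = -delta of deleting residue i.  For wider
    windows each window's negated delta is attributed to every residue in
    the window, and residues covered by several windows take the mean.
    """
    if not 1 <= deletion_width <= 3:
        raise ValueError("deletion_width must be 1, 2 or 3")
    L = len(protein)
    if L <= deletion_width:
        raise ValueError("protein shorter than the deletion window")
    totals = np.zeros(L)
    counts = np.zeros(L)
    for i in range(L - deletion_width + 1):
        variant = protein[:i] + protein[i + deletion_width:]
        d = delta_score(protein, variant, ortholog_set, matrix,
                        gap_open, gap_extend)
        totals[i:i + deletion_width] += -d
        counts[i:i + deletion_width] += 1
    scores = totals / counts
    return ConservationTrack(ortholog_set.gene_id, tuple(float(s) for s in scores),
                             deletion_width)


def conserved_flag(track: ConservationTrack, aa_position: int,
                   threshold: float = CONSERVED_SCORE_THRESHOLD) -> bool:
    """True iff the residue under the cut scores strictly above the
    conservation cutoff (``aa_position`` is 1-based)."""
    if not 1 <= aa_position <= len(track):
        raise IndexError(f"aa_position {aa_position} outside 1..{len(track)}")
    return track.scores[aa_position - 1] > threshold


def substitution_mode_score(protein: str, position: int,
                            ortholog_set: OrthologSet, matrix=None,
                            gap_open: float = DEFAULT_GAP_OPEN,
                            gap_extend: float = DEFAULT_GAP_EXTEND) -> float:
    """Mean negated delta over all 20 amino-acid substitutions at a 1-based
    position (the self-substitution contributes 0)."""
    if not 1 <= position <= len(protein):
        raise IndexError(f"position {position} outside 1..{len(protein)}")
    i = position - 1
    total = 0.0
    for aa in AMINO_ACIDS:
        if aa == protein[i]:
            continue
        variant = protein[:i] + aa + protein[i + 1:]
        total += -delta_score(protein, variant, ortholog_set, matrix,
                              gap_open, gap_extend)
    return total / len(AMINO_ACIDS)


def track_to_tsv(track: ConservationTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\taa_index\tscore\n")
        for i, s in enumerate(track.scores, 1):
            fh.write(f"{track.gene_id}\t{i}\t{s:.4f}\n")


def track_to_bed(track: ConservationTrack, transcript, path) -> None:
    """Anchor a per-protein track onto the genome as BED (one record per
    residue's codon footprint)."""
    with open(path, "w") as fh:
        for i, s in enumerate(track.scores):
            gpos = sorted(transcript.cds_to_genome(off)
                          for off in range(i * 3, i * 3 + 3))
            fh.write("\t".join(map(str, [
                transcript.contig_id, gpos[0], gpos[-1] + 1,
                f"{track.gene_id}:aa{i + 1}", f"{s:.4f}", transcript.strand])) + "\n")
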