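"""Enumeration of SpCas9 NGG guides and their cut sites.

Only NGG PAMs are considered: SpCas9's affinity for NGG dwarfs all other
PAM sequences.  Each guide is anchored to the blunt-cut breakpoint 3 bp
5' of the PAM (between protospacer positions 17 and 18), the consensus
SpCas9 cut position.  The breakpoint is represented as the genomic
coordinate of the first base 3' of the cut on the reference strand, which
makes it identical for the two strands of the same physical bond.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import revcomp

PROTOSPACER_LEN = 20
PAM_LEN = 3
CUT_OFFSET = 17  # breakpoint after this many protospacer bases (guide orientation)


@dataclass(frozen=True)
class Guide:
    """One NGG guide: 20-nt protospacer + PAM anchored on a contig."""
    guide_id: str
    contig_id: str
    strand: str                 # "+" or "-"
    protospacer: str            # 20 nt, guide orientation
    pam: str                    # 3 nt, guide orientation, N-G-G
    protospacer_start: int      # genomic 0-based start of the 20-mer interval
    cut_position: int           # genomic breakpoint (first base 3' of the cut)
    context30: str              # 4 nt up + protospacer + PAM + 3 nt down, guide orientation

    @property
    def protospacer_end(self) -> int:
        return self.protospacer_start + PROTOSPACER_LEN

    @property
    def target_interval(self) -> tuple[int, int]:
        """Genomic footprint of the 23-nt protospacer+PAM."""
        if self.strand == "+":
            return self.protospacer_start, self.protospacer_end + PAM_LEN
        return self.protospacer_start - PAM_LEN, self.protospacer_end


def cut_site(contig_start: int, strand: str) -> int:
    """Genomic cut breakpoint for a protospacer starting at ``contig_start``."""
    if strand == "+":
        return contig_start + CUT_OFFSET
    return contig_start + (PROTOSPACER_LEN - CUT_OFFSET)


def _guide_id(contig: str, start: int, strand: str) -> str:
    return f"{contig}:{start}:{strand}"


def extract_guides(genome: dict[str, str]) -> list[Guide]:
    """Enumerate every NGG guide on both strands of every contig.

    Guides with N anywhere in the protospacer+PAM, or whose 30-nt efficacy
    context would be clipped by a contig edge, are discarded (the context
    is required by 30-mer efficacy scorers).  Output is ordered by
    (contig, protospacer start, strand).
    """
    out: list[Guide] = []
    for contig in sorted(genome):
        seq = genome[contig]
        L = len(seq)
        per_contig: list[Guide] = []
        # + strand: protospacer [i, i+20), PAM [i+20, i+23) with GG at i+21
        for i in range(0, L - 22):
            if seq[i + 21] != "G" or seq[i + 22] != "G":
                continue
            if i < 4 or i + 26 > L:
                continue
            context = seq[i - 4:i + 26]
            if "N" in seq[i:i + 23]:
                continue
            per_contig.append(Guide(
                guide_id=_guide_id(contig, i, "+"), contig_id=contig, strand="+",
                protospacer=seq[i:i + 20], pam=seq[i + 20:i + 23],
                protospacer_start=i, cut_position=cut_site(i, "+"),
                context30=context))
        # - strand: CC at [i, i+2) is the PAM GG on the minus strand;
        # PAM genomic [i, i+3), protospacer genomic [i+3, i+23)
        for i in range(0, L - 22):
            if seq[i] != "C" or seq[i + 1] != "C":
                continue
            if i < 3 or i + 27 > L:
                continue
            if "N" in seq[i:i + 23]:
                continue
            start = i + 3
            per_contig.append(Guide(
                guide_id=_guide_id(contig, start, "-"), contig_id=contig, strand="-",
                protospacer=revcomp(seq[start:start + 20]),
                pam=revcomp(seq[i:i + 3]),
                protospacer_start=start, cut_position=cut_site(start, "-"),
                context30=revcomp(seq[i - 3:i + 27])))
        per_contig.sort(key=lambda g: (g.protospacer_start, g.strand))
        out.extend(per_contig)
    return out


def guides_to_tsv(guides: list[Guide], path) -> None:
    cols = ["guide_id", "contig", "start", "end", "strand",
            "protospacer", "pam", "cut_position", "context30"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for g in guides:
            fh.write("\t".join(map(str, [
                g.guide_id, g.contig_id, g.protospacer_start, g.protospacer_end,
                g.strand, g.protospacer, g.pam, g.cut_position, g.context30])) + "\n")


def guides_to_bed(guides: list[Guide], path) -> None:
    """BED6 of protospacer intervals."""
    with open(path, "w") as fh:
        for g in guides:
            fh.write("\t".join(map(str, [
                g.contig_id, g.protospacer_start, g.protospacer_end,
                g.guide_id, 0, g.strand])) + "\n")
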