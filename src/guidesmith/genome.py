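"""Genome, gene-model, variant and annotation data model.

Conventions
-----------
All internal genomic intervals are 0-based half-open.  GTF is read and
written as 1-based inclusive per the format standard; the conversion is
isolated to the I/O functions here.  Ambiguity bases other than N are
normalised to N on input; guides overlapping N are discarded downstream,
since Cas9 targeting of ambiguous sequence is undefined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")

STOP_CODONS = {"TAA", "TAG", "TGA"}


class FormatError(ValueError):
    """Raised for malformed input files."""


def _normalize(seq: str) -> str:
    s = seq.upper()
    if set(s) <= _VALID:
        return s
    cleaned = "".join(c if c in _VALID else "N" for c in s)
    logger.warning("non-ACGTN symbols mapped to N (%d replaced)",
                   sum(a != b for a, b in zip(s, cleaned)))
    return cleaned


def read_genome(fasta_path) -> dict[str, str]:
    """Load a FASTA file into a {contig_id: sequence} map.

    Lowercase is uppercased and any non-ACGTN symbol becomes N (with a
    logged warning).  Duplicate contig ids are a format error.
    """
    genome: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
    except Exception as exc:  # Bio raises assorted ValueErrors
        raise FormatError(f"malformed FASTA {fasta_path}: {exc}") from exc
    if not records:
        # distinguish empty file from non-FASTA junk
        with open(fasta_path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.strip() and not line.startswith(">"):
                    raise FormatError(
                        f"malformed FASTA {fasta_path}: line {lineno} outside a record")
    for rec in records:
        if rec.id in genome:
            raise FormatError(f"duplicate contig id {rec.id!r} in {fasta_path}")
        genome[rec.id] = _normalize(str(rec.seq))
    return genome


def write_genome(genome: dict[str, str], fasta_path, width: int = 70) -> None:
    with open(fasta_path, "w") as fh:
        for cid, seq in genome.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    """Translate a CDS, stripping one trailing stop if present."""
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


@dataclass(frozen=True)
class Polymorphism:
    """A variant with its reference footprint and allele frequency."""
    contig_id: str
    position: int          # 0-based start of the reference footprint
    ref: str
    alt: str
    vaf: float

    def __post_init__(self):
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open reference footprint."""
        return self.position, self.position + len(self.ref)


@dataclass(frozen=True)
class AnnotationInterval:
    """A protein- or genome-space annotation (domain, site, 2° structure, ESE).

    Protein-space coordinates are 1-based inclusive residue indices tied to
    a gene; genome-space coordinates are 0-based half-open on a contig.
    """
    kind: str              # e.g. CDD_domain, CDD_site, Pfam_domain, Uniprot_helix, ...
    label: str = ""
    gene_id: str | None = None
    aa_start: int | None = None     # 1-based inclusive
    aa_end: int | None = None
    contig_id: str | None = None
    start: int | None = None        # 0-based half-open
    end: int | None = None

    def __post_init__(self):
        if self.gene_id is not None:
            if self.aa_start is None or self.aa_end is None or self.aa_start > self.aa_end:
                raise ValueError("protein-space interval requires aa_start <= aa_end")
        elif self.contig_id is None:
            raise ValueError("interval must be protein-space or genome-space")

    @property
    def is_protein_space(self) -> bool:
        return self.gene_id is not None


@dataclass
class TranscriptModel:
    """A protein-coding transcript: exon and CDS intervals on a contig.

    ``exons`` and ``cds`` are stored in ascending genomic order; iteration
    in transcription order is strand-aware via the helper methods.
    """
    gene_id: str
    transcript_id: str
    contig_id: str
    strand: str                      # "+" or "-"
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    is_principal: bool = True
    _cds_map: dict[int, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)

    # -- sequence assembly -------------------------------------------------

    def _splice(self, intervals, genome) -> str:
        seq = "".join(genome[self.contig_id][s:e] for s, e in intervals)
        return revcomp(seq) if self.strand == "-" else seq

    def spliced_sequence(self, genome) -> str:
        """Mature mRNA sequence (all exons, transcription orientation)."""
        return self._splice(self.exons, genome)

    def cds_sequence(self, genome) -> str:
        return self._splice(self.cds, genome)

    def protein(self, genome) -> str:
        return translate(self.cds_sequence(genome))

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def exons_transcription_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    # -- coordinate maps ---------------------------------------------------

    def genome_to_cds(self, position: int) -> int | None:
        """0-based offset into the spliced CDS, or None outside the CDS.

        Minus-strand transcripts count from the genomic 3' end.
        """
        offset = 0
        if self.strand == "+":
            for s, e in self.cds:
                if s <= position < e:
                    return offset + (position - s)
                offset += e - s
        else:
            for s, e in reversed(self.cds):
                if s <= position < e:
                    return offset + (e - 1 - position)
                offset += e - s
        return None

    def cds_to_genome(self, offset: int) -> int:
        """Inverse of :meth:`genome_to_cds`."""
        if not 0 <= offset < self.cds_length:
            raise IndexError(f"CDS offset {offset} outside [0, {self.cds_length})")
        remaining = offset
        intervals = self.cds if self.strand == "+" else self.cds[::-1]
        for s, e in intervals:
            n = e - s
            if remaining < n:
                return s + remaining if self.strand == "+" else e - 1 - remaining
            remaining -= n
        raise AssertionError("unreachable")

    def genome_to_transcript(self, position: int) -> int | None:
        """0-based offset into the spliced mature mRNA, or None (intronic)."""
        offset = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= position < e:
                    return offset + (position - s)
                offset += e - s
        else:
            for s, e in reversed(self.exons):
                if s <= position < e:
                    return offset + (e - 1 - position)
                offset += e - s
        return None

    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def junction_transcript_positions(self) -> list[int]:
        """Transcript offsets of exon-exon junctions (boundary before the
        first base of each non-first exon, in transcription order)."""
        out, off = [], 0
        for s, e in self.exons_transcription_order()[:-1]:
            off += e - s
            out.append(off)
        return out

    def cds_start_transcript(self) -> int:
        """Transcript offset of the first CDS base."""
        first = self.cds[0] if self.strand == "+" else self.cds[-1]
        pos = first[0] if self.strand == "+" else first[1] - 1
        t = self.genome_to_transcript(pos)
        assert t is not None
        return t

    # -- validation --------------------------------------------------------

    def validate(self, genome) -> None:
        """Raise ValueError when an invariant fails."""
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if self.contig_id not in genome:
            raise ValueError(f"{self.transcript_id}: unknown contig {self.contig_id}")
        for a, b in zip(self.exons, self.exons[1:]):
            if a[1] > b[0]:
                raise ValueError(f"{self.transcript_id}: overlapping exons {a} {b}")
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValueError(f"{self.transcript_id}: CDS {s}-{e} outside exons")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length {self.cds_length} not a multiple of 3")
        prot = str(Seq(self.cds_sequence(genome)).translate())
        if "*" in prot[:-1]:
            raise ValueError(f"{self.transcript_id}: internal stop codon in CDS")


def read_transcripts(gtf_path, genome, reject_log: list | None = None) -> list[TranscriptModel]:
    """Parse exon/CDS features from a GTF into validated TranscriptModels.

    Transcripts violating any CDS invariant (frame, internal stops, CDS
    outside exons) are rejected with a logged reason, not fatally.
    The ``tag "principal"`` attribute marks principal isoforms.
    """
    import gffutils

    db = gffutils.create_db(str(gtf_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            disable_infer_genes=True, disable_infer_transcripts=True)
    by_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx_id = feat.attributes["transcript_id"][0]
        rec = by_tx.setdefault(tx_id, {
            "gene_id": feat.attributes["gene_id"][0],
            "contig": feat.seqid, "strand": feat.strand,
            "exons": [], "cds": [], "principal": False,
        })
        iv = (feat.start - 1, feat.end)          # GTF 1-based inclusive -> half-open
        rec["exons" if feat.featuretype == "exon" else "cds"].append(iv)
        tags = feat.attributes.get("tag", [])
        if "principal" in tags:
            rec["principal"] = True

    out: list[TranscriptModel] = []
    for tx_id, rec in by_tx.items():
        model = TranscriptModel(
            gene_id=rec["gene_id"], transcript_id=tx_id,
            contig_id=rec["contig"], strand=rec["strand"],
            exons=rec["exons"], cds=rec["cds"], is_principal=rec["principal"],
        )
        try:
            model.validate(genome)
        except ValueError as exc:
            logger.warning("rejected transcript %s: %s", tx_id, exc)
            if reject_log is not None:
                reject_log.append((tx_id, str(exc)))
            continue
        out.append(model)
    return out


def write_transcripts(transcripts: list[TranscriptModel], gtf_path) -> None:
    """Write transcripts back to GTF (1-based inclusive)."""
    with open(gtf_path, "w") as fh:
        for tx in transcripts:
            tag = ' tag "principal";' if tx.is_principal else ""
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";{tag}'
            for kind, ivs in (("exon", tx.exons), ("CDS", tx.cds)):
                for s, e in ivs:
                    fh.write("\t".join([
                        tx.contig_id, "guidesmith", kind, str(s + 1), str(e),
                        ".", tx.strand, ".", attrs]) + "\n")


def read_polymorphisms(vcf_path, genome: dict[str, str] | None = None,
                       ) -> list[Polymorphism]:
    """Read variants from a VCF; VAF comes from the AF INFO field.

    Multi-allelic records yield one Polymorphism per alt allele.  When a
    genome is supplied, the REF allele is checked against it.
    """
    from cyvcf2 import VCF

    out: list[Polymorphism] = []
    for var in VCF(str(vcf_path)):
        af = var.INFO.get("AF")
        if af is None:
            raise FormatError(f"record at {var.CHROM}:{var.POS} lacks AF INFO field")
        afs = af if isinstance(af, tuple) else (af,)
        pos0 = var.POS - 1
        if genome is not None:
            ref_obs = genome.get(var.CHROM, "")[pos0:pos0 + len(var.REF)]
            if ref_obs != var.REF.upper():
                raise FormatError(
                    f"REF mismatch at {var.CHROM}:{var.POS}: VCF {var.REF}, genome {ref_obs}")
        for alt, vaf in zip(var.ALT, afs):
            out.append(Polymorphism(var.CHROM, pos0, var.REF.upper(), alt.upper(), float(vaf)))
    return out


def read_protein_annotations(tsv_path) -> list[AnnotationInterval]:
    """TSV dialect: gene_id, aa_start, aa_end, kind, label (tab-separated)."""
    out = []
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{tsv_path}: line {lineno}: expected >=4 columns")
            gene_id, aa_start, aa_end, kind = parts[:4]
            label = parts[4] if len(parts) > 4 else ""
            out.append(AnnotationInterval(kind=kind, label=label, gene_id=gene_id,
                                          aa_start=int(aa_start), aa_end=int(aa_end)))
    return out


def read_bed_annotations(bed_path, kind: str | None = None) -> list[AnnotationInterval]:
    """BED6 genome-space annotations; the name column is the label.

    When ``kind`` is None the BED name column doubles as the kind.
    """
    out = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{bed_path}: line {lineno}: expected >=3 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            out.append(AnnotationInterval(kind=kind or label, label=label,
                                          contig_id=contig, start=start, end=end))
    return out
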