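"""Deterministic synthetic fixtures: a toy genome with multi-exon genes,
ortholog protein sets with a conserved length-invariant core, planted
off-target copies, guide-overlapping variants, domain/site annotations,
an efficacy table, and simulated guide-activity training tables.

Everything derives from a single integer seed — the same seed produces
byte-identical files.  The fixtures stand in for reference genomes and
curated databases so every pipeline stage is testable without downloads;
they emulate gene structure faithfully but not realistic genome-scale
composition (see the package methods note).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from . import genome as gn
from .conservation import AMINO_ACIDS, OrthologSet

_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS.setdefault(aa, []).append(codon)
STOPS = sorted(gn.STOP_CODONS)

BASES = "ACGT"


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``conserved_core`` is the residue range (0-based half-open fraction of
    the protein) shared verbatim by all orthologs; outside it ortholog
    tails diverge by substitutions and indels, so the deletion-conservation
    signal is planted by construction.
    """
    seed: int = 0
    n_genes: int = 4
    exons_per_gene: int = 4
    protein_length: int = 60
    conserved_core: tuple[float, float] = (0.3, 0.7)
    n_orthologs: int = 8
    tail_substitution_rate: float = 0.5
    tail_indel_rate: float = 0.15
    utr5_length: int = 30
    utr3_length: int = 90
    intron_length: int = 70
    intergenic_length: int = 300
    n_planted_offtargets: int = 3
    n_snps: int = 4
    contig_id: str = "chrT"


@dataclass
class PlantedOfftarget:
    protospacer: str
    origin_position: int          # genomic start of the perfect site
    origin_strand: str
    copy_position: int
    copy_strand: str
    mismatches: int
    mismatch_positions: list[int]


@dataclass
class FixtureGene:
    gene_id: str
    transcript_id: str
    strand: str
    protein: str
    core_aa_range: tuple[int, int]      # 1-based inclusive residue range


@dataclass
class Fixture:
    spec: FixtureSpec
    genome: dict[str, str]
    transcripts: list
    genes: list[FixtureGene]
    ortholog_sets: dict[str, OrthologSet]
    polymorphisms: list
    annotations: list
    ese_motifs: list[str]
    efficacy: dict[str, float]
    planted_offtargets: list[PlantedOfftarget]


def _random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _back_translate(rng, protein: str) -> str:
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein)


def _random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _intron(rng, length: int) -> str:
    body = _random_dna(rng, length - 4)
    return "GT" + body + "AG"


def _mutate_tail(rng, tail: str, sub_rate: float, indel_rate: float) -> str:
    out = []
    for aa in tail:
        r = rng.random()
        if r < indel_rate / 2:
            continue                      # deletion
        if r < indel_rate:
            out.append(aa)
            out.append(AMINO_ACIDS[rng.integers(20)])   # insertion
            continue
        if rng.random() < sub_rate:
            out.append(AMINO_ACIDS[rng.integers(20)])
        else:
            out.append(aa)
    return "".join(out)


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build the in-memory fixture; :func:`write_fixture` serialises it."""
    rng = np.random.default_rng(spec.seed)
    genes: list[FixtureGene] = []
    transcripts = []
    ortholog_sets: dict[str, OrthologSet] = {}
    annotations = []
    contig_parts: list[str] = []
    pos = 0
    gene_intervals = []

    for gi in range(spec.n_genes):
        gene_id = f"G{gi + 1:03d}"
        tx_id = f"{gene_id}.t1"
        strand = "+" if gi % 2 == 0 else "-"
        protein = _random_protein(rng, spec.protein_length)
        cds = _back_translate(rng, protein) + STOPS[rng.integers(len(STOPS))]
        utr5 = _random_dna(rng, spec.utr5_length)
        utr3 = _random_dna(rng, spec.utr3_length)
        tx_seq = utr5 + cds + utr3

        # split the mature transcript into exons at interior points
        n_ex = spec.exons_per_gene
        interior = sorted(rng.choice(
            np.arange(20, len(tx_seq) - 20), size=n_ex - 1, replace=False))
        bounds = [0, *map(int, interior), len(tx_seq)]
        exon_seqs = [tx_seq[a:b] for a, b in zip(bounds, bounds[1:])]
        introns = [_intron(rng, spec.intron_length) for _ in range(n_ex - 1)]

        # assemble the gene in transcript (plus) orientation, then mirror
        parts, rel_exons, off = [], [], 0
        for k, ex in enumerate(exon_seqs):
            parts.append(ex)
            rel_exons.append((off, off + len(ex)))
            off += len(ex)
            if k < len(introns):
                parts.append(introns[k])
                off += len(introns[k])
        gene_plus = "".join(parts)
        cds_tx_range = (spec.utr5_length, spec.utr5_length + len(cds))
        rel_cds = []
        t = 0
        for (es, ee), ex in zip(rel_exons, exon_seqs):
            lo = max(cds_tx_range[0], t)
            hi = min(cds_tx_range[1], t + len(ex))
            if lo < hi:
                rel_cds.append((es + (lo - t), es + (hi - t)))
            t += len(ex)
        L = len(gene_plus)
        if strand == "-":
            gene_seq = gn.revcomp(gene_plus)
            rel_exons = [(L - e, L - s) for s, e in rel_exons]
            rel_cds = [(L - e, L - s) for s, e in rel_cds]
        else:
            gene_seq = gene_plus

        spacer = _random_dna(rng, spec.intergenic_length)
        contig_parts.extend([spacer, gene_seq])
        gene_start = pos + len(spacer)
        pos = gene_start + len(gene_seq)
        if gene_intervals and gene_start < gene_intervals[-1][1]:
            raise FixtureError("overlapping genes in fixture layout")
        gene_intervals.append((gene_start, pos))

        transcripts.append(gn.TranscriptModel(
            gene_id=gene_id, transcript_id=tx_id, contig_id=spec.contig_id,
            strand=strand,
            exons=[(gene_start + s, gene_start + e) for s, e in rel_exons],
            cds=[(gene_start + s, gene_start + e) for s, e in rel_cds],
            is_principal=True))

        # conserved core shared verbatim across orthologs; divergent tails
        c0 = int(spec.conserved_core[0] * spec.protein_length)
        c1 = int(spec.conserved_core[1] * spec.protein_length)
        core = protein[c0:c1]
        orthologs = []
        for oi in range(spec.n_orthologs):
            head = _mutate_tail(rng, protein[:c0], spec.tail_substitution_rate,
                                spec.tail_indel_rate)
            tail = _mutate_tail(rng, protein[c1:], spec.tail_substitution_rate,
                                spec.tail_indel_rate)
            orthologs.append((f"{gene_id}_orth{oi + 1}", head + core + tail))
        ortholog_sets[gene_id] = OrthologSet(gene_id, orthologs)
        genes.append(FixtureGene(gene_id, tx_id, strand, protein, (c0 + 1, c1)))

        annotations.append(gn.AnnotationInterval(
            kind="CDD_domain", label=f"{gene_id}_core",
            gene_id=gene_id, aa_start=c0 + 1, aa_end=c1))
        annotations.append(gn.AnnotationInterval(
            kind="CDD_site", label=f"{gene_id}_site",
            gene_id=gene_id, aa_start=(c0 + c1) // 2, aa_end=(c0 + c1) // 2))
        annotations.append(gn.AnnotationInterval(
            kind="Uniprot_helix", label=f"{gene_id}_helix",
            gene_id=gene_id, aa_start=max(1, c0 - 5), aa_end=c0 + 5))

    contig_parts.append(_random_dna(rng, spec.intergenic_length))
    contig = "".join(contig_parts)

    # plant off-target copies of intergenic guides in a terminal spacer
    planted: list[PlantedOfftarget] = []
    tail_parts: list[str] = []
    cursor = len(contig)
    for k in range(spec.n_planted_offtargets):
        proto = _random_dna(rng, 20)
        n_mm = int(rng.integers(0, 3))
        mm_pos = sorted(int(p) + 1 for p in
                        rng.choice(20, size=n_mm, replace=False))
        mutated = list(proto)
        for p in mm_pos:
            choices = [b for b in BASES if b != mutated[p - 1]]
            mutated[p - 1] = choices[rng.integers(3)]
        origin = cursor
        for piece in (proto + "TGG", "ACGTA"):
            tail_parts.append(piece)
            cursor += len(piece)
        copy_pos = cursor
        for piece in ("".join(mutated) + "TGG", "ACGTA"):
            tail_parts.append(piece)
            cursor += len(piece)
        planted.append(PlantedOfftarget(
            protospacer=proto, origin_position=origin, origin_strand="+",
            copy_position=copy_pos, copy_strand="+",
            mismatches=n_mm, mismatch_positions=mm_pos))
    contig += "".join(tail_parts) + _random_dna(rng, 20)

    genome = {spec.contig_id: contig}
    for tx in transcripts:
        tx.validate(genome)

    # variants straddling the 10 % VAF cutoff, planted on guide targets
    polymorphisms = []
    cds_positions = [p for tx in transcripts for s, e in tx.cds for p in (s, e - 1)]
    vafs = [0.05, 0.12, 0.30, 0.08, 0.15, 0.02]
    for k in range(spec.n_snps):
        p = int(cds_positions[(k * 3) % len(cds_positions)]) + k
        ref = contig[p]
        alt = BASES[(BASES.index(ref) + 1) % 4]
        polymorphisms.append(gn.Polymorphism(spec.contig_id, p, ref, alt,
                                             vafs[k % len(vafs)]))

    # synthetic stand-in ESE motif list (the real curated enhancer set is
    # an input file in production use)
    ese_motifs = ["".join(rng.choice(list(BASES), size=6)) for _ in range(8)]

    from .guides import extract_guides
    efficacy = {g.guide_id: round(float(rng.uniform(0.05, 0.95)), 4)
                for g in extract_guides(genome)}

    return Fixture(spec=spec, genome=genome, transcripts=transcripts,
                   genes=genes, ortholog_sets=ortholog_sets,
                   polymorphisms=polymorphisms, annotations=annotations,
                   ese_motifs=ese_motifs, efficacy=efficacy,
                   planted_offtargets=planted)


def write_fixture(fixture: Fixture, out_dir) -> dict:
    """Serialise a fixture to FASTA/GTF/VCF/TSV files plus a ground-truth
    manifest (JSON) sufficient to assert every planted fact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gn.write_genome(fixture.genome, out / "genome.fa")
    gn.write_transcripts(fixture.transcripts, out / "genes.gtf")

    with open(out / "variants.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        for cid, seq in fixture.genome.items():
            fh.write(f"##contig=<ID={cid},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for p in fixture.polymorphisms:
            fh.write(f"{p.contig_id}\t{p.position + 1}\t.\t{p.ref}\t{p.alt}"
                     f"\t.\t.\tAF={p.vaf}\n")

    with open(out / "annotations.tsv", "w") as fh:
        for a in fixture.annotations:
            fh.write(f"{a.gene_id}\t{a.aa_start}\t{a.aa_end}\t{a.kind}\t{a.label}\n")

    orth_dir = out / "orthologs"
    orth_dir.mkdir(exist_ok=True)
    for gene_id, oset in fixture.ortholog_sets.items():
        with open(orth_dir / f"{gene_id}.fa", "w") as fh:
            for sid, seq in oset.sequences:
                fh.write(f">{sid}\n{seq}\n")

    with open(out / "ese_motifs_synthetic.txt", "w") as fh:
        fh.write("\n".join(fixture.ese_motifs) + "\n")

    with open(out / "efficacy.tsv", "w") as fh:
        fh.write("guide_id\tefficacy\n")
        for gid in sorted(fixture.efficacy):
            fh.write(f"{gid}\t{fixture.efficacy[gid]}\n")

    manifest = {
        "seed": fixture.spec.seed,
        "contig_id": fixture.spec.contig_id,
        "genes": [asdict(g) for g in fixture.genes],
        "planted_offtargets": [asdict(p) for p in fixture.planted_offtargets],
        "snps": [{"position": p.position, "ref": p.ref, "alt": p.alt,
                  "vaf": p.vaf} for p in fixture.polymorphisms],
        "ese_motifs": fixture.ese_motifs,
        "files": ["genome.fa", "genes.gtf", "variants.vcf", "annotations.tsv",
                  "ese_motifs_synthetic.txt", "efficacy.tsv"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def simulate_training_table(feature_db: pd.DataFrame, effect_model: dict[str, float],
                            n: int, seed: int, n_experiments: int = 3,
                            noise_sd: float = 1.0) -> pd.DataFrame:
    """Simulated guide-activity table drawn from a linear model.

    Guides are resampled with replacement from the feature database; z is
    the configured linear combination of their (numeric-coerced) features
    plus Gaussian noise, and an experiment label imposes the
    (experiment x gene) group structure.
    """
    rng = np.random.default_rng(seed)
    rows = feature_db.sample(n=n, replace=True, random_state=int(rng.integers(2**31)))
    rows = rows.reset_index(drop=True)
    z = np.zeros(n)
    for feat, beta in effect_model.items():
        z += beta * pd.to_numeric(rows[feat]).to_numpy(dtype=float)
    z += rng.normal(0.0, noise_sd, size=n)
    rows["z"] = z
    rows["lfc"] = z
    rows["experiment_id"] = [f"exp{rng.integers(n_experiments) + 1}" for _ in range(n)]
    return rows
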