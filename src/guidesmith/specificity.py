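"""Off-target enumeration and Hsu-style specificity scoring.

Candidate off-targets are NGG-anchored 20-mers within Hamming distance 4 of
the protospacer (no bulges), found with a k-mer seed index: the protospacer
is split into five non-overlapping 4-mers, so by pigeonhole any site with at
most four mismatches matches at least one seed exactly at its slot.  Each
per-site mismatch pattern is scored with the position-weighted single-site
formula and aggregated into one score in [0, 1]; the same code path serves
genome-wide and protein-coding-sequence-restricted search spaces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .genome import revcomp

PROTOSPACER_LEN = 20
SEED_LEN = 4
N_SEEDS = PROTOSPACER_LEN // SEED_LEN

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def load_position_weights() -> list[float]:
    """The shipped 20-entry per-position mismatch weight vector (index 0 =
    PAM-distal).  Any other vector may be injected wherever weights are
    accepted."""
    text = resources.files("guidesmith.data").joinpath(
        "hsu_position_weights.json").read_text()
    return list(json.loads(text)["weights"])


@dataclass(frozen=True)
class OfftargetHit:
    """One NGG-anchored alignment of a protospacer, with its mismatches."""
    contig_id: str
    strand: str
    position: int               # genomic 0-based start of the 20-mer site
    mismatch_positions: tuple[int, ...]   # 1..20, 1 = PAM-distal

    @property
    def m(self) -> int:
        return len(self.mismatch_positions)


@dataclass(frozen=True)
class SpecificityRecord:
    specificity: float
    proteome_specificity: float | None
    exceeded_max_hits: bool
    mm_counts: tuple[int, int, int, int, int]   # alignments with 0..4 mismatches

    def __post_init__(self):
        if not 0.0 <= self.specificity <= 1.0:
            raise ValueError("specificity outside [0, 1]")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


class OfftargetIndex:
    """Seed index over every NGG site in a search space.

    The search space is a {name: sequence} map — a genome, or concatenated
    protein-coding sequences for the proteome-restricted score.
    """

    def __init__(self, search_space: dict[str, str]):
        mers, metas = [], []
        for name in sorted(search_space):
            seq = search_space[name]
            L = len(seq)
            # + strand sites: 20-mer [i, i+20), NGG at [i+20, i+23)
            for i in range(0, L - 22):
                if seq[i + 21] == "G" and seq[i + 22] == "G":
                    mer = seq[i:i + 20]
                    if "N" not in mer:
                        mers.append(mer)
                        metas.append((name, "+", i))
            # - strand sites: CC at [i, i+2), 20-mer genomic [i+3, i+23)
            for i in range(0, L - 22):
                if seq[i] == "C" and seq[i + 1] == "C":
                    mer = revcomp(seq[i + 3:i + 23])
                    if "N" not in mer:
                        mers.append(mer)
                        metas.append((name, "-", i + 3))
        self.metas = metas
        if mers:
            self.site_matrix = np.vstack([_encode(m) for m in mers])
        else:
            self.site_matrix = np.empty((0, PROTOSPACER_LEN), dtype=np.uint8)
        self._seed_index: dict[tuple[int, str], list[int]] = {}
        for idx, mer in enumerate(mers):
            for slot in range(N_SEEDS):
                seed = mer[slot * SEED_LEN:(slot + 1) * SEED_LEN]
                self._seed_index.setdefault((slot, seed), []).append(idx)

    def query(self, protospacer: str, max_mm: int = 4,
              max_hits: int = 5000) -> tuple[list[OfftargetHit], bool]:
        """All sites within ``max_mm`` mismatches, and whether enumeration
        was truncated at ``max_hits``.

        Hits are ordered by (contig, position, strand); truncation keeps the
        first ``max_hits`` in that order and sets the flag.
        """
        if len(protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        cand: set[int] = set()
        for slot in range(N_SEEDS):
            seed = protospacer[slot * SEED_LEN:(slot + 1) * SEED_LEN]
            cand.update(self._seed_index.get((slot, seed), ()))
        if not cand:
            return [], False
        idx = np.fromiter(cand, dtype=np.int64)
        query = _encode(protospacer)
        mism = self.site_matrix[idx] != query          # (n_cand, 20)
        counts = mism.sum(axis=1)
        keep = counts <= max_mm
        hits = []
        for site_i, row in zip(idx[keep], mism[keep]):
            name, strand, pos = self.metas[site_i]
            positions = tuple(int(p) + 1 for p in np.flatnonzero(row))
            hits.append(OfftargetHit(name, strand, pos, positions))
        hits.sort(key=lambda h: (h.contig_id, h.position, h.strand))
        truncated = len(hits) > max_hits
        return hits[:max_hits], truncated


def hsu_single_offtarget_score(mismatch_positions, weights=None) -> float:
    """Likelihood-of-cleavage score for one off-target site in [0, 1].

    Product over mismatched positions p of (1 - W[p]), times a mean-pairwise
    -distance factor 1 / (((19 - dbar)/19) * 4 + 1), times 1/m^2.  A perfect
    match scores 1.0 by convention, and for m < 2 the distance factor is 1
    (the dbar -> 19 limit of the formula).
    """
    if weights is None:
        weights = load_position_weights()
    positions = sorted(mismatch_positions)
    if any(not 1 <= p <= PROTOSPACER_LEN for p in positions):
        raise ValueError(f"mismatch positions outside 1..20: {positions}")
    if len(set(positions)) != len(positions):
        raise ValueError(f"duplicate mismatch positions: {positions}")
    m = len(positions)
    if m == 0:
        return 1.0
    score = 1.0
    for p in positions:
        score *= 1.0 - weights[p - 1]
    if m >= 2:
        pairs = [(b - a) for i, a in enumerate(positions) for b in positions[i + 1:]]
        dbar = sum(pairs) / len(pairs)
        score *= 1.0 / (((19.0 - dbar) / 19.0) * 4.0 + 1.0)
        score *= 1.0 / (m * m)
    return score


def aggregate_specificity(hits, on_target: OfftargetHit | None,
                          weights=None) -> float:
    """Aggregate per-site scores into one guide specificity in [0, 1]:
    100 / (100 + sum_i 100 * s_i) over off-target sites.

    ``on_target`` (the hit at the guide's own locus) is excluded from the
    sum; additional perfect-match sites count as maximally dangerous
    (s = 1).  With no off-targets the score is exactly 1.0.
    """
    if weights is None:
        weights = load_position_weights()
    total = 0.0
    for h in hits:
        if on_target is not None and h == on_target:
            continue
        total += hsu_single_offtarget_score(h.mismatch_positions, weights)
    return 100.0 / (100.0 + 100.0 * total)


def find_on_target(guide, hits) -> OfftargetHit | None:
    """The hit at the guide's own coordinates; None if absent (e.g. a
    CDS-restricted search space that does not contain the locus)."""
    for h in hits:
        if (h.contig_id == guide.contig_id and h.strand == guide.strand
                and h.position == guide.protospacer_start and h.m == 0):
            return h
    return None


def specificity_record(guide, genome_index: OfftargetIndex,
                       proteome_index: OfftargetIndex | None = None,
                       max_mm: int = 4, max_hits: int = 5000,
                       weights=None) -> tuple[SpecificityRecord, list[OfftargetHit]]:
    """Enumerate off-targets and aggregate both specificity flavours."""
    hits, truncated = genome_index.query(guide.protospacer, max_mm, max_hits)
    on_target = find_on_target(guide, hits)
    spec = aggregate_specificity(hits, on_target, weights)
    mm = [0] * 5
    for h in hits:
        mm[h.m] += 1
    prot_spec = None
    if proteome_index is not None:
        p_hits, _ = proteome_index.query(guide.protospacer, max_mm, max_hits)
        p_on = find_on_target(guide, p_hits)
        prot_spec = aggregate_specificity(p_hits, p_on, weights)
    record = SpecificityRecord(
        specificity=spec, proteome_specificity=prot_spec,
        exceeded_max_hits=truncated, mm_counts=tuple(mm))
    return record, hits


def passes_specificity_filter(record: SpecificityRecord, hits,
                              on_target: OfftargetHit | None,
                              min_specificity: float = 0.50,
                              close_offtarget_mm: int = 1) -> bool:
    """Hard training/design filter: specificity strictly above the cutoff
    AND no non-self site with <= ``close_offtarget_mm`` mismatches."""
    if record.specificity <= min_specificity:
        return False
    for h in hits:
        if on_target is not None and h == on_target:
            continue
        if h.m <= close_offtarget_mm:
            return False
    return True


def cds_search_space(transcripts, genome) -> dict[str, str]:
    """Protein-coding search space: each transcript's spliced CDS as its own
    named sequence, used identically to a genome by :class:`OfftargetIndex`."""
    return {tx.transcript_id: tx.cds_sequence(genome) for tx in transcripts}


def brute_force_offtargets(protospacer: str, search_space: dict[str, str],
                           max_mm: int = 4) -> list[OfftargetHit]:
    """Reference full-scan enumeration (O(L) per contig).  Slow; intended
    for validation on small search spaces."""
    hits = []
    for name in sorted(search_space):
        seq = search_space[name]
        L = len(seq)
        for i in range(0, L - 22):
            if seq[i + 21] == "G" and seq[i + 22] == "G" and "N" not in seq[i:i + 20]:
                mism = tuple(p + 1 for p in range(20) if seq[i + p] != protospacer[p])
                if len(mism) <= max_mm:
                    hits.append(OfftargetHit(name, "+", i, mism))
        for i in range(0, L - 22):
            if seq[i] == "C" and seq[i + 1] == "C":
                site = revcomp(seq[i + 3:i + 23])
                if "N" in site:
                    continue
                mism = tuple(p + 1 for p in range(20) if site[p] != protospacer[p])
                if len(mism) <= max_mm:
                    hits.append(OfftargetHit(name, "-", i + 3, mism))
    hits.sort(key=lambda h: (h.contig_id, h.position, h.strand))
    return hits
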