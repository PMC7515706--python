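"""Tiered guide selection: binary feature cutoffs, tier assignment with
iterative constraint relaxation (specificity first), tier/efficacy sorting,
spaced picking of N guides per gene, and the binomial coverage calculator.

Specificity is the highest-priority constraint: tiers 1-6 all require fully
specific guides, tiers 7.1-7.6 repeat the same relaxation ladder for guides
with borderline specificity, and tier 8 collects non-specific guides so that
every gene can be targeted.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from importlib import resources

from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GuideFeatureRecord:
    """One row of the guide feature database: everything tier assignment
    and picking need about one guide."""
    guide_id: str
    gene_id: str
    contig_id: str
    strand: str
    cut_position: int
    efficacy: float
    specificity: float
    conservation: float | None       # per-residue score under the cut, if known
    pct_cds: float
    in_domain: bool
    poly_a: int
    poly_c: int
    poly_g: int
    poly_t: int
    has_esp3i: bool
    snp_overlap: bool
    close_offtargets: int            # non-self genome hits with <= 1 mismatch
    exceeded_max_hits: bool = False


@dataclass(frozen=True)
class DesignCriteria:
    """Binary cutoffs used for tier assignment and picking."""
    efficacy_min: float = 0.40           # strict >
    conservation_min: float = 7.0        # strict >
    pct_cds_max: float = 0.95            # strict <
    max_poly_a: int = 4                  # AAAAA forbidden
    max_poly_c: int = 4
    max_poly_g: int = 4
    max_poly_t: int = 2                  # TTT forbidden (Pol III termination)
    esp3i_forbidden: bool = True
    snp_forbidden: bool = True
    specificity_full: float = 0.50       # strict >
    specificity_relaxed: float = 0.25    # strict >
    close_offtarget_mm: int = 1
    picks_per_gene: int = 6
    min_spacing_nt: int = 3


FEATURE_NAMES = ("domain", "conserved", "efficacy_ok", "cds_ok",
                 "construct_ok", "snp_ok", "specific_full", "specific_relaxed")


def binarize_features(record: GuideFeatureRecord,
                      criteria: DesignCriteria = DesignCriteria()) -> dict[str, bool]:
    """Apply the binary cutoffs to one feature record."""
    construct_ok = (record.poly_a <= criteria.max_poly_a
                    and record.poly_c <= criteria.max_poly_c
                    and record.poly_g <= criteria.max_poly_g
                    and record.poly_t <= criteria.max_poly_t
                    and not (criteria.esp3i_forbidden and record.has_esp3i))
    specific_full = (record.specificity > criteria.specificity_full
                     and record.close_offtargets == 0
                     and not record.exceeded_max_hits)
    specific_relaxed = (record.specificity > criteria.specificity_relaxed
                        and not record.exceeded_max_hits)
    return {
        "domain": record.in_domain,
        "conserved": (record.conservation is not None
                      and record.conservation > criteria.conservation_min),
        "efficacy_ok": record.efficacy > criteria.efficacy_min,
        "cds_ok": record.pct_cds < criteria.pct_cds_max,
        "construct_ok": construct_ok,
        "snp_ok": not (criteria.snp_forbidden and record.snp_overlap),
        "specific_full": specific_full,
        "specific_relaxed": specific_relaxed,
    }


@dataclass
class TierTable:
    """Ordered tier ladder; data, not code — load any ladder from JSON."""
    full_specificity_tiers: list[tuple[str, frozenset]]
    relaxed_specificity_tiers: list[tuple[str, frozenset]]
    fallback_tier: str = "8"

    @classmethod
    def default(cls) -> "TierTable":
        text = resources.files("guidesmith.data").joinpath(
            "tier_table.json").read_text()
        return cls.from_dict(json.loads(text))

    @classmethod
    def from_dict(cls, d: dict) -> "TierTable":
        def parse(rows):
            return [(r["label"], frozenset(r["requires"])) for r in rows]
        return cls(parse(d["full_specificity_tiers"]),
                   parse(d["relaxed_specificity_tiers"]),
                   d.get("fallback_tier", "8"))

    @classmethod
    def from_json(cls, path) -> "TierTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def tier_order(self) -> list[str]:
        return ([label for label, _ in self.full_specificity_tiers]
                + [label for label, _ in self.relaxed_specificity_tiers]
                + [self.fallback_tier])


def assign_tier(mask: dict[str, bool],
                tier_table: TierTable | None = None) -> str:
    """Lowest tier whose requirements the mask satisfies.

    Tiers 1-6 additionally require full specificity, 7.1-7.6 relaxed
    specificity; everything else is the fallback (non-specific) tier.
    """
    if tier_table is None:
        tier_table = TierTable.default()
    if mask["specific_full"]:
        for label, req in tier_table.full_specificity_tiers:
            if all(mask[f] for f in req):
                return label
    if mask["specific_relaxed"]:
        for label, req in tier_table.relaxed_specificity_tiers:
            if all(mask[f] for f in req):
                return label
    return tier_table.fallback_tier


@dataclass(frozen=True)
class LibraryPick:
    gene_id: str
    guide_id: str
    tier: str
    rank_in_tier: int          # 1-based, by efficacy descending within tier
    pick_index: int            # 1-based pick order within the gene


def _sort_key(tier_rank: dict[str, int]):
    def key(item):
        record, tier = item
        return (tier_rank[tier], -record.efficacy, record.cut_position)
    return key


def pick_guides(gene_records: list[GuideFeatureRecord],
                criteria: DesignCriteria = DesignCriteria(),
                tier_table: TierTable | None = None,
                exhaustive_limit: int = 20) -> list[LibraryPick]:
    """Pick up to ``picks_per_gene`` guides for one gene.

    Guides are sorted by (tier, efficacy desc).  All top-tier guides are
    auto-included with the spacing constraint waived among them (truncated
    by efficacy if they alone exceed the quota).  Remaining slots are filled
    to maximise the number of picks and then their summed rank, subject to
    cut sites being >= ``min_spacing_nt`` apart from every prior pick
    (including the waived ones): exhaustive subset search when the candidate
    pool is small, else greedy with local-swap improvement.  Ties break
    toward the lower genomic coordinate.
    """
    if tier_table is None:
        tier_table = TierTable.default()
    if not gene_records:
        logger.warning("gene with zero guides")
        return []
    tier_rank = {t: i for i, t in enumerate(tier_table.tier_order())}
    tiered = [(r, assign_tier(binarize_features(r, criteria), tier_table))
              for r in gene_records]
    tiered.sort(key=_sort_key(tier_rank))
    quota = criteria.picks_per_gene
    spacing = criteria.min_spacing_nt

    top_label = tier_table.full_specificity_tiers[0][0]
    waived = [(r, t) for r, t in tiered if t == top_label][:quota]
    rest = [(r, t) for r, t in tiered if t != top_label]
    slots = quota - len(waived)

    chosen = list(waived)
    if slots > 0 and rest:
        ranks = {r.guide_id: i for i, (r, _) in enumerate(tiered)}
        waived_cuts = [r.cut_position for r, _ in waived]

        def compatible(subset) -> bool:
            cuts = [r.cut_position for r, _ in subset]
            for c in cuts:
                if any(abs(c - w) < spacing for w in waived_cuts):
                    return False
            cuts.sort()
            return all(b - a >= spacing for a, b in zip(cuts, cuts[1:]))

        # exhaustive subset search over the best-ranked candidates; greedy
        # top-up from the remainder only if spacing conflicts in the pool
        # leave the quota unfilled
        pool = rest[:exhaustive_limit]
        best = None
        for size in range(min(slots, len(pool)), 0, -1):
            for combo in itertools.combinations(pool, size):
                if not compatible(combo):
                    continue
                score = (sum(ranks[r.guide_id] for r, _ in combo),
                         tuple(sorted(r.cut_position for r, _ in combo)))
                if best is None or score < best[0]:
                    best = (score, combo)
            if best is not None:
                break
        picked = sorted(best[1], key=_sort_key(tier_rank)) if best else []
        for r, t in rest[exhaustive_limit:]:
            if len(picked) >= slots:
                break
            cuts = (waived_cuts + [p.cut_position for p, _ in picked])
            if all(abs(r.cut_position - c) >= spacing for c in cuts):
                picked.append((r, t))
        chosen.extend(picked)

    # rank within tier by efficacy over the gene's full candidate list
    per_tier_rank: dict[str, int] = {}
    rank_of: dict[str, int] = {}
    for r, t in tiered:
        per_tier_rank[t] = per_tier_rank.get(t, 0) + 1
        rank_of[r.guide_id] = per_tier_rank[t]
    return [LibraryPick(gene_id=r.gene_id, guide_id=r.guide_id, tier=t,
                        rank_in_tier=rank_of[r.guide_id], pick_index=i + 1)
            for i, (r, t) in enumerate(chosen)]


def design_library(records: list[GuideFeatureRecord],
                   criteria: DesignCriteria = DesignCriteria(),
                   tier_table: TierTable | None = None) -> list[LibraryPick]:
    """Run picking gene by gene over a whole feature database."""
    by_gene: dict[str, list[GuideFeatureRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    picks = []
    for gene in sorted(by_gene):
        picks.extend(pick_guides(by_gene[gene], criteria, tier_table))
    return picks


def genes_with_at_least_k_effective(n: int, k: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p): the chance a gene receives at
    least k effective guides when each of its n guides is independently
    effective with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p outside [0, 1]")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def biallelic_frameshift_rate(frameshift_rate: float = 2.0 / 3.0,
                              ploidy: int = 2) -> float:
    """Probability that every allele carries a frameshift, given the
    per-allele frameshift rate (the expected indel frameshift rate of 2/3
    squares to 4/9 for a diploid locus)."""
    if not 0.0 <= frameshift_rate <= 1.0:
        raise ValueError("frameshift_rate outside [0, 1]")
    return frameshift_rate ** ploidy


def library_to_tsv(picks: list[LibraryPick],
                   records: dict[str, GuideFeatureRecord], path,
                   criteria: DesignCriteria = DesignCriteria(),
                   tier_table: TierTable | None = None) -> None:
    cols = ["gene_id", "pick_index", "guide_id", "tier", "rank_in_tier",
            "efficacy", "specificity", "conservation", "pct_cds",
            *FEATURE_NAMES]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in picks:
            r = records[p.guide_id]
            mask = binarize_features(r, criteria)
            fh.write("\t".join(map(str, [
                p.gene_id, p.pick_index, p.guide_id, p.tier, p.rank_in_tier,
                f"{r.efficacy:.4f}", f"{r.specificity:.4f}",
                "" if r.conservation is None else f"{r.conservation:.4f}",
                f"{r.pct_cds:.4f}",
                *[int(mask[f]) for f in FEATURE_NAMES]])) + "\n")
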