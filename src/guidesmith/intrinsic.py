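"""Guide-intrinsic features: homopolymers, Esp3I sites, melting temperature,
and the pluggable cleavage-efficacy contract.

Homopolymer runs and restriction-site hits are evaluated on the synthesized
construct (vector flank + protospacer + scaffold flank) so that runs spanning
the guide/flank junction are caught, but only runs and sites that overlap the
protospacer itself count: the scaffold carries its own fixed TTT runs and the
intentional cloning sites, which are properties of the vector, not the guide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

from .genome import revcomp

ESP3I_SITE = "CGTCTC"

# junction sequences flanking the protospacer in a typical U6 / optimized
# scaffold expression construct; overridable per library configuration
DEFAULT_UPSTREAM_FLANK = "CACCG"
DEFAULT_DOWNSTREAM_FLANK = "GTTTAAGAGCTATGCTG"


@dataclass(frozen=True)
class ConstructContext:
    """Fixed vector sequence 5' and scaffold sequence 3' of the protospacer."""
    upstream_flank: str = DEFAULT_UPSTREAM_FLANK
    downstream_flank: str = DEFAULT_DOWNSTREAM_FLANK

    def construct(self, protospacer: str) -> str:
        return self.upstream_flank + protospacer + self.downstream_flank

    def protospacer_span(self, protospacer: str) -> tuple[int, int]:
        s = len(self.upstream_flank)
        return s, s + len(protospacer)


EMPTY_CONTEXT = ConstructContext("", "")


@dataclass(frozen=True)
class IntrinsicFeatures:
    poly_a: int
    poly_c: int
    poly_g: int
    poly_t: int
    has_esp3i: bool
    tm_celsius: float
    efficacy: float

    def __post_init__(self):
        if not 0.0 <= self.efficacy <= 1.0:
            raise ValueError(f"efficacy {self.efficacy} outside [0, 1]")


def max_homopolymer_runs(protospacer: str,
                         context: ConstructContext = ConstructContext(),
                         ) -> tuple[int, int, int, int]:
    """Maximum homopolymer run per base (A, C, G, T) over the construct.

    A run counts only if it overlaps the protospacer; runs confined to the
    flanks are ignored.  Runs may span the guide/flank junctions.
    """
    seq = context.construct(protospacer)
    lo, hi = context.protospacer_span(protospacer)
    best = {"A": 0, "C": 0, "G": 0, "T": 0}
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        base = seq[i]
        if base in best and i < hi and j > lo:   # run overlaps protospacer
            best[base] = max(best[base], j - i)
        i = j
    return best["A"], best["C"], best["G"], best["T"]


def has_esp3i_site(protospacer: str,
                   context: ConstructContext = ConstructContext(),
                   both_strands: bool = True) -> bool:
    """True iff an Esp3I recognition site overlapping the protospacer occurs
    in the construct.

    Cloned DNA is double stranded, so by default both CGTCTC and its reverse
    complement GAGACG are scanned; ``both_strands=False`` restricts to the
    literal CGTCTC motif.
    """
    seq = context.construct(protospacer)
    lo, hi = context.protospacer_span(protospacer)
    motifs = [ESP3I_SITE] + ([revcomp(ESP3I_SITE)] if both_strands else [])
    for motif in motifs:
        start = seq.find(motif)
        while start != -1:
            if start < hi and start + len(motif) > lo:
                return True
            start = seq.find(motif, start + 1)
    return False


@dataclass(frozen=True)
class TmConditions:
    """Hybridization conditions for the nearest-neighbor Tm model.

    total_strand_conc_nm is the total oligo concentration C_T in nM; with
    equimolar strands the association constant uses C_T/4.  Absolute Tm
    shifts with these conditions; rank order across guides does not.
    """
    total_strand_conc_nm: float = 250.0   # 0.25 uM
    na_mm: float = 50.0


def melting_temperature(protospacer: str,
                        conditions: TmConditions = TmConditions()) -> float:
    """Nearest-neighbor duplex melting temperature in degrees Celsius.

    Uses the unified Allawi & SantaLucia 1997 dH/dS parameters with
    initiation terms and the SantaLucia 1998 entropic salt correction:
    Tm = dH / (dS + R ln(C_T/4)) - 273.15.
    """
    if not protospacer or set(protospacer) - set("ACGT"):
        raise ValueError(f"protospacer must be non-empty ACGT, got {protospacer!r}")
    half = conditions.total_strand_conc_nm / 2.0
    return float(_mt.Tm_NN(protospacer, nn_table=_mt.DNA_NN3,
                           dnac1=half, dnac2=half,
                           Na=conditions.na_mm, saltcorr=5))


# ---------------------------------------------------------------------------
# cleavage efficacy: pluggable scorers


class MissingEfficacyError(KeyError):
    """Raised when the score table lacks requested guide ids."""

    def __init__(self, guide_ids):
        self.guide_ids = list(guide_ids)
        super().__init__(f"no efficacy score for guide ids: {self.guide_ids}")


class TableEfficacyScorer:
    """Looks up precomputed scores (e.g. from an external gradient-boosted
    model) in a TSV of (guide_id, efficacy)."""

    def __init__(self, table: dict[str, float], default: float | None = None):
        bad = {k: v for k, v in table.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"efficacy values outside [0, 1]: {bad}")
        self.table = dict(table)
        self.default = default

    @classmethod
    def from_tsv(cls, path, default: float | None = None) -> "TableEfficacyScorer":
        table = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("guide_id\t"):
                    continue
                gid, val = line.split("\t")[:2]
                table[gid] = float(val)
        return cls(table, default=default)

    def score(self, guide_id: str, context30: str) -> float:
        if guide_id in self.table:
            return self.table[guide_id]
        if self.default is not None:
            return self.default
        raise MissingEfficacyError([guide_id])

    def score_many(self, guides) -> dict[str, float]:
        missing = [g.guide_id for g in guides
                   if g.guide_id not in self.table and self.default is None]
        if missing:
            raise MissingEfficacyError(missing)
        return {g.guide_id: self.score(g.guide_id, g.context30) for g in guides}


# fixed position weights of the surrogate: PAM-proximal positions matter most,
# loosely mimicking the seed-region emphasis of trained efficacy models
_SURROGATE_BASE_SCORE = {"A": 0.1, "C": 0.5, "G": 0.9, "T": -0.3, "N": 0.0}


class SurrogateEfficacyScorer:
    """Deterministic position-weight function of the 30-mer context.

    Test-fixture scorer only: it produces stable, sequence-dependent values
    in [0, 1] but has no experimental basis and must not be used to design
    real libraries.  Production scores come from :class:`TableEfficacyScorer`
    fed by an external trained model.
    """

    def score(self, guide_id: str, context30: str) -> float:
        if len(context30) != 30:
            raise ValueError(f"context must be 30 nt, got {len(context30)}")
        total = 0.0
        for i, base in enumerate(context30):
            # triangular weight peaking at the PAM-proximal protospacer end
            w = 1.0 - abs(i - 20) / 20.0
            total += w * _SURROGATE_BASE_SCORE.get(base, 0.0)
        # map the bounded sum smoothly into (0, 1)
        import math
        return 1.0 / (1.0 + math.exp(-0.6 * (total - 4.0)))

    def score_many(self, guides) -> dict[str, float]:
        return {g.guide_id: self.score(g.guide_id, g.context30) for g in guides}


def efficacy_score(guide_id: str, context30: str, scorer) -> float:
    """Score cleavage efficacy through a pluggable scorer; result in [0, 1]."""
    value = scorer.score(guide_id, context30)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"scorer returned {value} outside [0, 1]")
    return value


def annotate_intrinsic(guide, scorer,
                       context: ConstructContext = ConstructContext(),
                       tm_conditions: TmConditions = TmConditions(),
                       esp3i_both_strands: bool = True) -> IntrinsicFeatures:
    a, c, g, t = max_homopolymer_runs(guide.protospacer, context)
    return IntrinsicFeatures(
        poly_a=a, poly_c=c, poly_g=g, poly_t=t,
        has_esp3i=has_esp3i_site(guide.protospacer, context, esp3i_both_strands),
        tm_celsius=melting_temperature(guide.protospacer, tm_conditions),
        efficacy=efficacy_score(guide.guide_id, guide.context30, scorer),
    )
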