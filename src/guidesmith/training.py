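"""Feature-selection machinery for guide-activity training data.

Guide dropout (log2 fold change) is z-scored within each (experiment, gene)
group so that activities are comparable across screens and genes of
different essentiality; records are filtered to specific, CDS-targeting
guides; an ordinary-least-squares model of z on the guide features is fit
and decomposed into per-feature relative importances by averaging each
predictor group's incremental R^2 over orderings (the LMG decomposition);
and binary features are triaged by median-z difference versus prevalence.
Screen dropout metrics (negative-control-normalised RPM, LFC, intra-gene
CV, hit calls) round out the screen-analysis surface.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

DEFAULT_FORMULA = (
    "z ~ efficacy + specificity + conservation + tm + C(pam) + C(nmd_frames)"
    " + esp3i + cds_gt95 + ese + exon_asymmetric + internal_exon"
    " + uniprot_beta + uniprot_ccr + uniprot_helix + uniprot_turn"
    " + poly_a_ge5 + poly_c_ge5 + poly_g_ge5 + poly_t_ge3"
    " + domain + snp + cdd_site + C(strand_relative)"
)


def zscore_by_group(records: pd.DataFrame, value_col: str = "lfc",
                    group_cols=("experiment_id", "gene_id"),
                    out_col: str = "z") -> pd.DataFrame:
    """z = (lfc - group mean) / group sd within each (experiment, gene).

    Sample sd (n-1 denominator).  Groups of size 1 or with zero sd are
    dropped with a log entry.  Enrichment-readout experiments are expected
    to arrive pre-negated (dropout-signed LFCs).
    """
    df = records.copy()
    groups = df.groupby(list(group_cols))[value_col]
    mean = groups.transform("mean")
    sd = groups.transform("std")      # ddof=1
    n = groups.transform("size")
    bad = (n < 2) | (sd == 0) | sd.isna()
    if bad.any():
        logger.info("dropping %d records in degenerate groups (size<2 or sd=0)",
                    int(bad.sum()))
    df[out_col] = (df[value_col] - mean) / sd
    return df.loc[~bad].copy()


def apply_training_filters(records: pd.DataFrame,
                           min_specificity: float = 0.50) -> pd.DataFrame:
    """Keep specific, CDS-targeting guides.

    Requires columns ``specificity``, ``close_offtargets`` (non-self genome
    hits with <= 1 mismatch) and ``in_cds``.  Stage counts are logged.
    """
    n0 = len(records)
    df = records.loc[records["in_cds"].astype(bool)]
    n1 = len(df)
    df = df.loc[(df["specificity"] > min_specificity)
                & (df["close_offtargets"] == 0)]
    logger.info("training filters: %d -> %d (CDS) -> %d (specific)", n0, n1, len(df))
    return df.copy()


@dataclass
class ImportanceResult:
    """Relative importance of each predictor group as its share of model
    R^2; shares are non-negative and sum to the total R^2."""
    shares: dict[str, float]
    coefficients: pd.Series
    r_squared: float


def _group_design_columns(records: pd.DataFrame, formula: str):
    """Build the design matrix and map each formula term to its columns."""
    import patsy

    y, X = patsy.dmatrices(formula, records, return_type="dataframe")
    term_slices = X.design_info.term_name_slices
    groups = {name: list(range(sl.start, sl.stop))
              for name, sl in term_slices.items() if name != "Intercept"}
    return np.asarray(y).ravel(), np.asarray(X), groups


def _r2_cache_factory(y: np.ndarray, X: np.ndarray, groups: dict[str, list[int]]):
    """R^2 of the OLS fit on the intercept plus any subset of groups."""
    names = list(groups)
    tss = float(((y - y.mean()) ** 2).sum())
    cache: dict[frozenset, float] = {}

    def r2(subset: frozenset) -> float:
        if subset in cache:
            return cache[subset]
        cols = [0] + [c for name in names if name in subset for c in groups[name]]
        beta, *_ = np.linalg.lstsq(X[:, cols], y, rcond=None)
        rss = float(((y - X[:, cols] @ beta) ** 2).sum())
        val = 1.0 - rss / tss
        cache[subset] = val
        return val

    return names, r2


def lmg_importance(y: np.ndarray, X: np.ndarray, groups: dict[str, list[int]],
                   exact_limit: int = 15, n_orders: int = 10000,
                   seed: int = 0) -> dict[str, float]:
    """Average incremental R^2 of each predictor group over orderings.

    Exact enumeration over subsets when the group count is at most
    ``exact_limit`` (each group's LMG share is a weighted sum of
    R^2(S+g) - R^2(S) over subsets S); Monte-Carlo over random orderings
    otherwise, with a fixed seed.
    """
    names, r2 = _r2_cache_factory(y, X, groups)
    p = len(names)
    shares = {name: 0.0 for name in names}
    if p <= exact_limit:
        fact = math.factorial
        denom = fact(p)
        for name in names:
            others = [n for n in names if n != name]
            for k in range(p):
                weight = fact(k) * fact(p - k - 1) / denom
                for combo in itertools.combinations(others, k):
                    s = frozenset(combo)
                    shares[name] += weight * (r2(s | {name}) - r2(s))
    else:
        rng = np.random.default_rng(seed)
        order = np.array(names, dtype=object)
        for _ in range(n_orders):
            rng.shuffle(order)
            seen: set = set()
            prev = r2(frozenset())
            for name in order:
                seen.add(name)
                cur = r2(frozenset(seen))
                shares[name] += cur - prev
                prev = cur
        shares = {k: v / n_orders for k, v in shares.items()}
    return shares


def fit_feature_model(records: pd.DataFrame, formula: str = DEFAULT_FORMULA,
                      exact_limit: int = 15, n_orders: int = 10000,
                      seed: int = 0) -> ImportanceResult:
    """OLS fit of z on the guide features plus LMG importance decomposition.

    Perfectly collinear (aliased) columns are dropped with a warning, as is
    any constant predictor group.
    """
    y, X, groups = _group_design_columns(records, formula)
    # drop groups whose columns are constant (aliased / degenerate)
    dropped = [name for name, cols in groups.items()
               if all(np.ptp(X[:, c]) == 0 for c in cols)]
    for name in dropped:
        logger.warning("dropping constant/aliased predictor group %s", name)
        del groups[name]
    ols = smf.ols(formula, data=records).fit()
    shares = lmg_importance(y, X, groups, exact_limit, n_orders, seed)
    return ImportanceResult(shares=shares, coefficients=ols.params,
                            r_squared=float(ols.rsquared))


def median_diff_vs_prevalence(records: pd.DataFrame, binary_features,
                              universe: pd.DataFrame | None = None,
                              z_col: str = "z") -> pd.DataFrame:
    """Per binary feature: median(z | present) - median(z | absent), and the
    fraction of guides in the reference universe possessing the feature.

    ``universe`` defaults to the training records but should be the full
    guide database when available — prevalence is a property of the genome,
    not of the training set.  Features present in all or none of the
    records get a missing (NaN) median difference.
    """
    if universe is None:
        universe = records
    rows = []
    for feat in binary_features:
        present = records[feat].astype(bool)
        if present.all() or (~present).all():
            diff = float("nan")
        else:
            diff = float(records.loc[present, z_col].median()
                         - records.loc[~present, z_col].median())
        rows.append({"feature": feat, "median_diff": diff,
                     "prevalence": float(universe[feat].astype(bool).mean())})
    return pd.DataFrame(rows).set_index("feature")


@dataclass
class ScreenMetrics:
    rpm: pd.DataFrame              # normalised RPM, guide x sample
    guide_lfc: pd.Series
    gene_lfc: pd.Series
    gene_cv: pd.Series             # sd / |mean| of guide LFCs per gene
    hits: pd.Series                # gene LFC < hit threshold


def screen_dropout_metrics(counts: pd.DataFrame, design: pd.DataFrame,
                           gene_map: pd.Series, negative_control_genes,
                           pseudocount_rpm: float = 0.5,
                           hit_lfc: float = -1.0) -> ScreenMetrics:
    """Counts -> negative-control-normalised RPM -> LFCs -> gene metrics.

    ``counts``: guide_id x sample read counts.  ``design``: indexed by
    sample with a ``role`` column of {reference, endpoint}.  ``gene_map``:
    guide_id -> gene_id.  RPMs are scaled per sample so the summed RPM of
    guides targeting negative-control genes is identical across samples
    (set to the cross-sample mean), removing composition shifts caused by
    real dropout.  Guide LFC = log2((RPM_end + c) / (RPM_ref + c)) with
    replicate RPMs averaged within each role; a gene is a hit when its mean
    guide LFC is below ``hit_lfc`` (more than 2-fold mean dropout).
    """
    neg_guides = gene_map[gene_map.isin(set(negative_control_genes))].index
    if len(neg_guides) == 0:
        raise ValueError("no guides target negative-control genes")
    rpm = counts / counts.sum(axis=0) * 1e6
    neg_mass = rpm.loc[rpm.index.intersection(neg_guides)].sum(axis=0)
    if (neg_mass == 0).any():
        raise ValueError("zero negative-control mass in some sample")
    rpm = rpm * (neg_mass.mean() / neg_mass)
    ref_samples = design.index[design["role"] == "reference"]
    end_samples = design.index[design["role"] == "endpoint"]
    if len(ref_samples) == 0 or len(end_samples) == 0:
        raise ValueError("design must contain reference and endpoint samples")
    ref = rpm[ref_samples].mean(axis=1)
    end = rpm[end_samples].mean(axis=1)
    guide_lfc = np.log2((end + pseudocount_rpm) / (ref + pseudocount_rpm))
    gene_lfc = guide_lfc.groupby(gene_map).mean()
    gene_sd = guide_lfc.groupby(gene_map).std()
    gene_cv = gene_sd / gene_lfc.abs()
    hits = gene_lfc < hit_lfc
    return ScreenMetrics(rpm=rpm, guide_lfc=guide_lfc, gene_lfc=gene_lfc,
                         gene_cv=gene_cv, hits=hits)
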