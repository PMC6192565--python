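"""Consensus-score generation: scaling, imputation, and the five fusion schemes.

Pipeline order (the executable sequence):

1. raw scores -> dissimilarities ``X`` (similarity-polarity methods are negated;
   any strictly decreasing transform is equivalent after autoscaling);
2. per-method logistic-sigmoid scaling ``S = 1 - 1/(1 + exp(-(X - mu)/sigma))``
   with ``mu``/``sigma`` the mean / population SD of that method's
   dissimilarities, yielding similarities in (0, 1);
3. mirroring to the full ordered-pair matrix;
4. per-method "local average fill" imputation of missing pairs;
5. consensus schemes M1-M5 and their per-pair median.

Schemes: M1 generalized mean (q = 1: plain average); M2 coverage-weighted;
M3 coverage x expert-prior weighted; M4 divergence-weighted (each method
weighted by the mean RMS distance of its scores from the other methods');
M5 user- or regression-learned weights.  For every pair, the weights of the
m available methods are renormalized to sum to one before averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .score_model import (
    CONSENSUS_COLUMNS,
    DomainRecord,
    ScalingParams,
    ScoreTable,
    mirror_symmetric,
)
from .psc_engine import PSCMethodSpec

logger = logging.getLogger(__name__)

SCHEMES = ("m2", "m3", "m4", "m5")


@dataclass
class ConsensusWeights:
    """Global per-method weights for one scheme (renormalized per pair later)."""

    scheme: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be >= 0")
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError("at least one weight must be > 0")


@dataclass
class DivergenceStats:
    """Pairwise method divergences (RMS distance of score vectors) and row means."""

    methods: list[str]
    rmsd: np.ndarray  # M x M, symmetric, zero diagonal
    r: np.ndarray  # per-method mean divergence


@dataclass
class ConsensusResult:
    """Wide per-pair tables for the three evaluation views.

    ``imputed`` is fully filled; ``original`` keeps missing scaled scores
    as NaN; ``common`` is the subset of pairs scored by every method.
    All three carry per-method scaled-score columns plus m1..m5 and median.
    """

    methods: list[str]
    domains: list[str]
    imputed: pd.DataFrame
    original: pd.DataFrame
    common: pd.DataFrame
    scaling: dict[str, ScalingParams]
    weights: dict[str, ConsensusWeights]
    coverage: dict[str, float]


def to_dissimilarity(raw: float, polarity: str) -> float:
    """Map a raw score to dissimilarity orientation (higher = more different)."""
    if polarity == "dissimilarity":
        return raw
    if polarity == "similarity":
        return -raw
    raise ValueError(f"unknown polarity {polarity!r}")


def fit_scaling_params(dissimilarities: Sequence[float], method: str = "") -> ScalingParams:
    """Mean and population SD over the non-missing dissimilarities of one method."""
    x = np.asarray(dissimilarities, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError(f"method {method!r} has no scores")
    return ScalingParams(method, float(x.mean()), float(x.std(ddof=0)))


def logistic_scale(x: np.ndarray | float, params: ScalingParams) -> np.ndarray | float:
    """Autoscaled logistic sigmoid: S = 1 - 1/(1 + exp(-(X - mu)/sigma)).

    Strictly decreasing in X, so high dissimilarity maps to low similarity;
    S is in (0, 1).  The degenerate sigma = 0 (constant scores) maps
    everything to the midpoint 0.5.
    """
    x = np.asarray(x, dtype=float)
    if params.sigma == 0:
        out = np.where(np.isnan(x), np.nan, 0.5)
    else:
        out = expit(-(x - params.mu) / params.sigma)
    return float(out) if out.ndim == 0 else out


def impute_local_average(table: ScoreTable, method: str) -> ScoreTable:
    """Local-average fill of missing scaled scores for one method.

    For each ordered pair (d_i, d_j) with a missing score: merge the set of
    scores whose first domain is d_i with the set whose second domain is
    d_j and impute the mean of that union (each record contributes once);
    if both sets are empty, fall back to the method's global mean.  Source
    values are always the pre-imputation ones, so the fill is independent
    of pair order.  The table must already be mirrored and scaled.
    """
    out = table.copy()
    df = out.df
    mask_m = df["method"] == method
    sub = df.loc[mask_m]
    if "scaled" not in df.columns:
        raise ValueError("table must be scaled before imputation")
    present = sub.dropna(subset=["scaled"])
    if present.empty:
        raise ValueError(f"method {method!r} has no scores; cannot impute")
    global_mean = float(present["scaled"].mean())

    g1 = present.groupby("domain1")["scaled"].agg(["sum", "count"])
    g2 = present.groupby("domain2")["scaled"].agg(["sum", "count"])

    missing_idx = sub.index[sub["scaled"].isna()]
    if len(missing_idx) == 0:
        return out
    d1 = df.loc[missing_idx, "domain1"]
    d2 = df.loc[missing_idx, "domain2"]
    s1 = g1["sum"].reindex(d1).fillna(0.0).to_numpy()
    n1 = g1["count"].reindex(d1).fillna(0).to_numpy()
    s2 = g2["sum"].reindex(d2).fillna(0.0).to_numpy()
    n2 = g2["count"].reindex(d2).fillna(0).to_numpy()
    n = n1 + n2
    values = np.where(n > 0, (s1 + s2) / np.where(n > 0, n, 1), global_mean)
    df.loc[missing_idx, "scaled"] = values
    df.loc[missing_idx, "imputed"] = True
    return out


def m1_generalized_mean(scores: Sequence[float], q: float = 1.0) -> float:
    """Generalized mean ((1/m) sum S_i^q)^(1/q) of the available scores."""
    s = np.asarray([v for v in scores if not np.isnan(v)], dtype=float)
    if s.size == 0:
        raise ValueError("no scores available")
    if q == 0:
        raise ValueError("q must be nonzero")
    if q == 1.0:
        return float(s.mean())
    return float(np.mean(s ** q) ** (1.0 / q))


def m2_coverage_weights(table: ScoreTable) -> ConsensusWeights:
    """Weight each method by its coverage s_i / P (pre-imputation)."""
    return ConsensusWeights("m2", dict(table.coverage()))


def m3_expert_weights(table: ScoreTable, specs: Sequence[PSCMethodSpec]) -> ConsensusWeights:
    """Coverage weights multiplied by per-method expert priors."""
    experts = {s.name: s.expert_weight for s in specs}
    cov = table.coverage()
    return ConsensusWeights(
        "m3", {m: cov[m] * experts.get(m, 1.0) for m in table.methods}
    )


def divergence_stats(scaled_wide: pd.DataFrame, methods: Sequence[str]) -> DivergenceStats:
    """Pairwise RMS divergences between method score vectors.

    ``scaled_wide`` holds one column per method over the ordered pairs,
    NaN where a method is missing (pre-imputation); each pairwise RMSD
    is computed over the pairs both methods cover.
    """
    m = len(methods)
    rmsd = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            a = scaled_wide[methods[i]].to_numpy(dtype=float)
            b = scaled_wide[methods[j]].to_numpy(dtype=float)
            both = ~np.isnan(a) & ~np.isnan(b)
            if not both.any():
                raise ValueError(
                    f"methods {methods[i]!r} and {methods[j]!r} share no scored pairs"
                )
            rmsd[i, j] = rmsd[j, i] = float(np.sqrt(np.mean((a[both] - b[both]) ** 2)))
    r = rmsd.sum(axis=1) / m
    return DivergenceStats(list(methods), rmsd, r)


def m4_divergence_weights(scaled_wide: pd.DataFrame, methods: Sequence[str]) -> ConsensusWeights:
    """Weight each method by its mean divergence from the others, w_i = r_i / max r.

    Degenerate case (all methods identical, every r_i = 0) falls back to
    equal weights.
    """
    if len(methods) < 2:
        return ConsensusWeights("m4", {m: 1.0 for m in methods})
    stats = divergence_stats(scaled_wide, methods)
    rmax = stats.r.max()
    # tolerance: near-identical methods give divergences that are pure float
    # noise; weights as ratios of noise would be meaningless
    if rmax <= 1e-12:
        return ConsensusWeights("m4", {m: 1.0 for m in methods})
    return ConsensusWeights(
        "m4", {m: float(ri / rmax) for m, ri in zip(methods, stats.r)}
    )


def m5_user_weights(
    methods: Sequence[str],
    weights: Mapping[str, float] | None = None,
    learn: Mapping | None = None,
) -> ConsensusWeights:
    """User-supplied relative weights, or weights learned by logistic regression.

    ``learn`` keys: ``scaled_wide`` (complete per-method score columns),
    ``labels`` (domain -> ClassificationLabel), ``pairs`` (ordered list of
    (domain1, domain2) matching scaled_wide rows), ``level`` (default 1),
    ``train_fraction`` (default 0.10), ``seed``.  The binary target is
    same-vs-different classification at the chosen level; learned weights
    are the normalized absolute coefficients.
    """
    if (weights is None) == (learn is None):
        raise ValueError("supply exactly one of explicit weights or a learn config")
    if weights is not None:
        if any(w < 0 for w in weights.values()):
            raise ValueError("explicit weights must be >= 0")
        return ConsensusWeights("m5", {m: float(weights.get(m, 0.0)) for m in methods})

    from sklearn.linear_model import LogisticRegression

    scaled_wide: pd.DataFrame = learn["scaled_wide"]
    labels = learn["labels"]
    pairs = learn["pairs"]
    level = int(learn.get("level", 1))
    train_fraction = float(learn.get("train_fraction", 0.10))
    seed = int(learn.get("seed", 0))
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must be in (0, 1]")

    y = np.array(
        [labels[d1].matches(labels[d2], level) for d1, d2 in pairs], dtype=int
    )
    X = scaled_wide[list(methods)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    k = max(2, int(round(train_fraction * n))) if train_fraction < 1 else n
    idx = rng.choice(n, size=k, replace=False) if k < n else np.arange(n)
    if len(np.unique(y[idx])) < 2:
        raise ValueError("training sample contains a single class; cannot learn weights")
    clf = LogisticRegression(max_iter=1000)
    clf.fit(X[idx], y[idx])
    coef = np.abs(clf.coef_.ravel())
    if coef.sum() == 0:
        coef = np.ones_like(coef)
    coef = coef / coef.sum()
    return ConsensusWeights("m5", {m: float(c) for m, c in zip(methods, coef)})


def weighted_consensus(
    scores: Mapping[str, float], weights: ConsensusWeights
) -> float:
    """Weighted average of the available scores, weights renormalized per pair."""
    avail = {m: s for m, s in scores.items() if not np.isnan(s)}
    if not avail:
        raise ValueError("no scores available")
    w = np.array([weights.weights.get(m, 0.0) for m in avail])
    if w.sum() == 0:
        raise ValueError("all available methods have zero weight")
    w = w / w.sum()
    s = np.array(list(avail.values()))
    return float((w * s).sum())


def median_mcpsc(m_scores: Sequence[float]) -> float:
    """Median (3rd order statistic) of the five consensus scores."""
    s = np.asarray(m_scores, dtype=float)
    if s.size != 5 or np.isnan(s).any():
        raise ValueError("median consensus needs all five scheme scores")
    return float(np.median(s))


def _weighted_matrix(
    S: np.ndarray, avail: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Row-wise weighted average of S over available entries, renormalized.

    ``S``: n_pairs x M scores (NaN allowed outside availability);
    ``avail``: boolean mask of the same shape; ``w``: global weights (M,).
    Rows with no available method (or zero total weight) yield NaN.
    """
    wa = np.where(avail, w[None, :], 0.0)
    tot = wa.sum(axis=1)
    ok = tot > 0
    out = np.full(S.shape[0], np.nan)
    Sz = np.where(avail, S, 0.0)
    out[ok] = (wa[ok] * Sz[ok]).sum(axis=1) / tot[ok]
    return out


def _consensus_columns(
    wide: pd.DataFrame,
    methods: Sequence[str],
    avail: np.ndarray,
    all_weights: dict[str, ConsensusWeights],
    q: float,
) -> pd.DataFrame:
    S = wide[list(methods)].to_numpy(dtype=float)
    out = wide.copy()
    # M1: generalized mean over available scores
    Sq = np.where(avail, S, np.nan)
    m = avail.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        if q == 1.0:
            m1 = np.nansum(Sq, axis=1) / np.where(m > 0, m, np.nan)
        else:
            m1 = (np.nansum(Sq ** q, axis=1) / np.where(m > 0, m, np.nan)) ** (1.0 / q)
    m1 = np.where(m > 0, m1, np.nan)
    out["m1"] = m1
    for scheme in SCHEMES:
        w = np.array([all_weights[scheme].weights.get(mm, 0.0) for mm in methods])
        out[scheme] = _weighted_matrix(S, avail, w)
    cons = out[["m1", "m2", "m3", "m4", "m5"]].to_numpy(dtype=float)
    med = np.full(len(out), np.nan)
    full = ~np.isnan(cons).any(axis=1)
    med[full] = np.median(cons[full], axis=1)
    out["median"] = med
    return out


def run_consensus(
    table: ScoreTable,
    specs: Sequence[PSCMethodSpec],
    q: float = 1.0,
    m5_weights: Mapping[str, float] | None = None,
    m5_learn: Mapping | None = None,
    labels: Mapping | None = None,
) -> ConsensusResult:
    """Full consensus pipeline on a raw score table.

    Executes dissimilarity conversion, per-method autoscaled sigmoid
    scaling, mirroring, local-average imputation and the M1-M5 + median
    schemes, and assembles the three evaluation views (original with
    missing values, common subset, fully imputed).  ``m5_weights`` gives
    explicit M5 weights; ``m5_learn`` a learning config (needs ``labels``);
    with neither, M5 defaults to equal weights.
    """
    spec_map = {s.name: s for s in specs}
    unknown = [m for m in table.methods if m not in spec_map]
    if unknown:
        raise ValueError(f"no method spec for {unknown}")
    methods = list(table.methods)

    work = table.copy()
    df = work.df
    df["raw"] = df["raw"].astype(float)
    pol = df["method"].map(lambda m: spec_map[m].polarity)
    df["dissimilarity"] = np.where(pol == "similarity", -df["raw"], df["raw"])

    scaling: dict[str, ScalingParams] = {}
    df["scaled"] = np.nan
    for m in methods:
        mask = (df["method"] == m) & df["dissimilarity"].notna()
        if not mask.any():
            raise ValueError(f"method {m!r} has no scores")
        params = fit_scaling_params(df.loc[mask, "dissimilarity"], m)
        scaling[m] = params
        df.loc[mask, "scaled"] = logistic_scale(df.loc[mask, "dissimilarity"].to_numpy(), params)
    df["imputed"] = False

    mirrored = mirror_symmetric(ScoreTable(df, methods, work.domains))

    # full ordered-pair universe, one row per pair
    domains = list(mirrored.domains)
    pairs = [(a, b) for a in domains for b in domains if a != b]
    universe = pd.DataFrame(pairs, columns=["domain1", "domain2"])
    full_long_parts = []
    for m in methods:
        sub = mirrored.df.loc[mirrored.df["method"] == m]
        merged = universe.merge(sub, on=["domain1", "domain2"], how="left")
        merged["method"] = m
        merged["imputed"] = merged["imputed"].eq(True)
        full_long_parts.append(merged)
    full_long = pd.concat(full_long_parts, ignore_index=True)
    full_table = ScoreTable(full_long, methods, domains)

    coverage = full_table.coverage()

    pre_wide = full_long.pivot(index=["domain1", "domain2"], columns="method", values="scaled")
    pre_wide = pre_wide.reindex(columns=methods).reset_index()
    avail_pre = ~pre_wide[methods].isna().to_numpy()

    imputed_table = full_table
    for m in methods:
        imputed_table = impute_local_average(imputed_table, m)
    post = imputed_table.df
    post_wide = post.pivot(index=["domain1", "domain2"], columns="method", values="scaled")
    post_wide = post_wide.reindex(columns=methods).reset_index()
    imp_flags = post.pivot(index=["domain1", "domain2"], columns="method", values="imputed")
    imp_flags = imp_flags.reindex(columns=methods).reset_index()

    # global weights (coverage / divergence computed pre-imputation)
    all_weights: dict[str, ConsensusWeights] = {}
    all_weights["m2"] = m2_coverage_weights(full_table)
    all_weights["m3"] = m3_expert_weights(full_table, specs)
    all_weights["m4"] = m4_divergence_weights(pre_wide, methods)
    if m5_weights is not None:
        all_weights["m5"] = m5_user_weights(methods, weights=m5_weights)
    elif m5_learn is not None:
        if labels is None:
            raise ValueError("m5_learn requires domain labels")
        learn = dict(m5_learn)
        learn.setdefault("scaled_wide", post_wide)
        learn.setdefault("labels", labels)
        learn.setdefault("pairs", list(zip(post_wide["domain1"], post_wide["domain2"])))
        all_weights["m5"] = m5_user_weights(methods, learn=learn)
    else:
        all_weights["m5"] = ConsensusWeights("m5", {m: 1.0 for m in methods})

    avail_all = np.ones_like(avail_pre, dtype=bool)
    imputed_view = _consensus_columns(post_wide, methods, avail_all, all_weights, q)
    original_view = _consensus_columns(pre_wide, methods, avail_pre, all_weights, q)
    common_mask = avail_pre.all(axis=1)
    common_view = original_view.loc[common_mask].reset_index(drop=True)

    for m in methods:
        imputed_view[f"{m}_imputed"] = imp_flags[m].astype(bool).to_numpy()
        original_view[f"{m}_imputed"] = False
    common_view = common_view.copy()
    for m in methods:
        common_view[f"{m}_imputed"] = False

    return ConsensusResult(
        methods=methods,
        domains=domains,
        imputed=imputed_view,
        original=original_view,
        common=common_view,
        scaling=scaling,
        weights=all_weights,
        coverage=coverage,
    )
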