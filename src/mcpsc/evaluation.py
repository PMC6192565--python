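"""Ground-truth-driven benchmarking of PSC and consensus scores.

Two benchmarks, both label-driven at a chosen level of the 4-level
hierarchy (1 = class, 2 = fold, 3 = superfamily, 4 = family):

* ROC/AUC over domain pairs: positives are pairs whose domains share the
  first k label components; the similarity threshold sweeps the observed
  unique score values from high to low ("greater than threshold" strict).
* Leave-one-out nearest-neighbor auto-classification: every domain is a
  query, its nearest non-self neighbor (distance 1 - S) donates a label,
  and the fraction of correct level-k predictions is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .score_model import ClassificationLabel, DomainRecord
from .structure_viz import DistanceMatrix, build_distance_matrix


@dataclass
class ROCResult:
    method: str
    level: int
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class ClassificationReport:
    method: str
    level: int
    dataset_view: str
    fraction_correct: float
    predictions: pd.DataFrame  # columns: domain, predicted_neighbor, correct


def level_match(label_a: ClassificationLabel, label_b: ClassificationLabel, level: int) -> bool:
    """True iff the first ``level`` components of the two labels agree."""
    return label_a.matches(label_b, level)


def roc_points(
    similarities: Sequence[float],
    positives: Sequence[bool],
    method: str = "",
    level: int = 0,
) -> ROCResult:
    """ROC curve from a threshold sweep over the observed similarity values.

    A pair is predicted similar when its score is strictly greater than the
    threshold; thresholds run from above the maximum (nothing predicted)
    down to below the minimum (everything predicted), so the curve runs
    from (0, 0) to (1, 1).  AUC by the trapezoidal rule.
    """
    s = np.asarray(similarities, dtype=float)
    y = np.asarray(positives, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("similarities and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: need at least one positive and one negative pair")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # group ties: cumulative TP/FP after each distinct-value block = strict '>' counts
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    cum_tp = np.cumsum(y_sorted)[distinct]
    cum_fp = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(method, level, fpr, tpr, auc)


def roc_for_pairs(
    pair_scores: pd.DataFrame,
    column: str,
    labels: Mapping[str, ClassificationLabel],
    level: int,
    method_name: str | None = None,
) -> ROCResult:
    """ROC over the unordered pairs of a wide per-pair table.

    Rows with a missing score in ``column`` are excluded (they carry no
    prediction); the duplicate orientation of each pair is dropped.
    """
    df = pair_scores.loc[pair_scores["domain1"] < pair_scores["domain2"]]
    df = df.dropna(subset=[column])
    pos = [
        level_match(labels[a], labels[b], level)
        for a, b in zip(df["domain1"], df["domain2"])
    ]
    return roc_points(
        df[column].to_numpy(dtype=float), pos, method_name or column, level
    )


def nn_classify_loo(
    dmat: DistanceMatrix,
    labels: Mapping[str, ClassificationLabel],
    level: int,
    method: str = "",
    dataset_view: str = "",
) -> ClassificationReport:
    """Leave-one-out nearest-neighbor classification at one hierarchy level.

    Every domain is a query; the non-self domain at minimal distance donates
    its label; ties resolve to the lexicographically smallest neighbor ID
    (domain order in the matrix is sorted, so argmin implements this).
    """
    ids = dmat.domains
    if len(ids) < 2:
        raise ValueError("need at least 2 domains")
    if list(ids) != sorted(ids):
        raise ValueError("distance matrix domains must be sorted for deterministic ties")
    D = dmat.D.copy()
    np.fill_diagonal(D, np.inf)
    nn_idx = np.argmin(D, axis=1)  # first minimal index = lexicographic tie-break
    rows = []
    n_correct = 0
    for i, qid in enumerate(ids):
        neigh = ids[nn_idx[i]]
        correct = level_match(labels[qid], labels[neigh], level)
        n_correct += correct
        rows.append({"domain": qid, "predicted_neighbor": neigh, "correct": correct})
    return ClassificationReport(
        method=method,
        level=level,
        dataset_view=dataset_view,
        fraction_correct=n_correct / len(ids),
        predictions=pd.DataFrame(rows),
    )


def evaluate_all(
    views: Mapping[str, pd.DataFrame],
    records: Sequence[DomainRecord],
    score_columns: Sequence[str],
    roc_level: int = 3,
    nn_levels: Sequence[int] = (1, 2, 3, 4),
) -> dict[str, pd.DataFrame]:
    """NN fractions (levels 1-4) and ROC AUCs for every score column and view.

    ``views`` maps view name (original / common / imputed) to a wide
    per-pair table.  In views with missing scores the pairwise distance
    falls back to 1 (maximum dissimilarity) for NN; missing pairs are
    excluded from ROC.  Returns ``{"nn": ..., "auc": ...}`` tidy tables.
    """
    labels = {r.domain_id: r.label for r in records}
    all_domains = sorted(labels)
    nn_rows = []
    auc_rows = []
    for view_name, wide in views.items():
        for col in score_columns:
            dmat = build_distance_matrix(wide, col, domains=all_domains)
            for level in nn_levels:
                rep = nn_classify_loo(dmat, labels, level, method=col, dataset_view=view_name)
                nn_rows.append(
                    {
                        "view": view_name,
                        "method": col,
                        "level": level,
                        "fraction_correct": rep.fraction_correct,
                    }
                )
            try:
                roc = roc_for_pairs(wide, col, labels, roc_level, method_name=col)
                auc_rows.append(
                    {"view": view_name, "method": col, "level": roc_level, "auc": roc.auc}
                )
            except ValueError:
                # single-class labels or no scored pairs at this level
                auc_rows.append(
                    {"view": view_name, "method": col, "level": roc_level, "auc": np.nan}
                )
    return {"nn": pd.DataFrame(nn_rows), "auc": pd.DataFrame(auc_rows)}
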