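"""Leave-one-out cross-validation and ranking metrics.

Each drug is held out in turn: its known indications are removed, every
disease is scored for it by guilt-by-association against the remaining drugs'
associations, and the removed indications are treated as positives among all
other diseases as negatives.  Because the scoring rule already excludes the
self term, the held-out drug's own associations never influence its scores.
Similarity matrices derive from feature profiles, not from associations, so
they are not recomputed per fold.

Per-drug AUC is the Mann-Whitney rank statistic (ties count 1/2); per-drug
AUPR is non-interpolated average precision with positives placed after
equal-scoring negatives, so a constant predictor is not rewarded.  Reported
summaries are macro-averages over the evaluated drugs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fusion import FusionParams, cross_diffuse
from .profiles import SimilarityMatrix, ValidationError
from .scoring import AssociationMatrix, score_all

__all__ = [
    "EvaluationResult",
    "GridResult",
    "roc_auc",
    "pr_aupr",
    "precision_recall_at_k",
    "loocv",
    "paired_t_test",
    "parameter_grid",
    "TOP_K_DEFAULTS",
    "GRID_DEFAULTS",
]

TOP_K_DEFAULTS = (5, 10, 15, 20)
GRID_DEFAULTS = (1, 5, 10, 20, 30)


@dataclass(frozen=True)
class EvaluationResult:
    """Per-drug LOOCV metrics and their top-k summaries."""

    per_drug_auc: np.ndarray = field(repr=False)
    per_drug_aupr: np.ndarray = field(repr=False)
    precision_at_k: dict
    recall_at_k: dict
    evaluated_drug_ids: tuple
    skipped_drug_ids: tuple = ()
    params: FusionParams | None = None
    sim_label: str = "sim"

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_drug_auc))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.per_drug_aupr))

    def summary_frame(self) -> pd.DataFrame:
        rows = {"mean_auc": self.mean_auc, "mean_aupr": self.mean_aupr}
        for k in sorted(self.precision_at_k):
            rows[f"precision@{k}"] = self.precision_at_k[k]
        for k in sorted(self.recall_at_k):
            rows[f"recall@{k}"] = self.recall_at_k[k]
        return pd.DataFrame({self.sim_label: rows})

    def per_drug_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"drug_id": list(self.evaluated_drug_ids),
             "auc": self.per_drug_auc, "aupr": self.per_drug_aupr}
        )


def roc_auc(scores_pos, scores_neg) -> float:
    """Probability that a random positive outranks a random negative.

    Equals the area under the ROC curve traced by sweeping the decision
    threshold; tied scores count 1/2.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("roc_auc needs nonempty positive and negative scores")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def pr_aupr(scores_pos, scores_neg) -> float:
    """Non-interpolated average precision.

    Positives are placed *after* negatives of equal score, so ties never
    inflate the result.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0:
        raise ValidationError("pr_aupr needs at least one positive score")
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.lexsort((labels, -scores))  # desc score; ties: negatives first
    sorted_labels = labels[order]
    hits = np.cumsum(sorted_labels)
    ranks = np.arange(1, scores.size + 1)
    prec_at_pos = (hits / ranks)[sorted_labels == 1]
    return float(prec_at_pos.mean())


def precision_recall_at_k(positive_ranks_per_drug, k: int):
    """Mean precision@k and recall@k over drugs.

    ``positive_ranks_per_drug`` holds, per evaluated drug, the 1-based ranks
    of its held-out indications in that drug's full candidate ordering.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    precisions, recalls = [], []
    for ranks in positive_ranks_per_drug:
        ranks = np.asarray(ranks)
        hits = int((ranks <= k).sum())
        precisions.append(hits / k)
        recalls.append(hits / ranks.size)
    return float(np.mean(precisions)), float(np.mean(recalls))


def _positive_ranks(row_scores: np.ndarray, pos_mask: np.ndarray,
                    lex_rank: np.ndarray) -> np.ndarray:
    """1-based ranks of positives under descending score, ties by disease id."""
    order = np.lexsort((lex_rank, -row_scores))
    rank_of = np.empty(order.size, dtype=int)
    rank_of[order] = np.arange(1, order.size + 1)
    return rank_of[pos_mask]


def loocv(sim: SimilarityMatrix, assoc: AssociationMatrix,
          top_k=TOP_K_DEFAULTS, params: FusionParams | None = None) -> EvaluationResult:
    """Leave-one-out cross-validation of a similarity matrix.

    Drugs without any known association cannot be evaluated and are skipped
    with a warning.
    """
    if sim.drug_ids != assoc.drug_ids:
        raise ValidationError("similarity and association drug ids differ")
    a = assoc.values
    n_pos_per_drug = a.sum(axis=1)
    skipped = tuple(d for d, npos in zip(assoc.drug_ids, n_pos_per_drug) if npos == 0)
    if skipped:
        warnings.warn(
            f"skipping {len(skipped)} drug(s) with no known association",
            stacklevel=2,
        )
    # The self term is excluded by the scoring rule, so zeroing drug i's
    # association row cannot change drug i's own scores: one score_all pass
    # yields every fold's held-out scores.
    scores = score_all(sim, assoc).values
    ids = np.array(assoc.disease_ids, dtype=object)
    lex_rank = np.argsort(np.argsort(ids))

    aucs, auprs, pos_ranks, eval_ids = [], [], [], []
    for i, drug in enumerate(assoc.drug_ids):
        pos_mask = a[i] == 1
        if not pos_mask.any():
            continue
        if pos_mask.all():
            # no negatives to rank against; degenerate drug is skipped too
            continue
        row = scores[i]
        aucs.append(roc_auc(row[pos_mask], row[~pos_mask]))
        auprs.append(pr_aupr(row[pos_mask], row[~pos_mask]))
        pos_ranks.append(_positive_ranks(row, pos_mask, lex_rank))
        eval_ids.append(drug)

    if not eval_ids:
        raise ValidationError("no evaluable drug (all have 0 or all associations)")
    prec, rec = {}, {}
    for k in top_k:
        prec[k], rec[k] = precision_recall_at_k(pos_ranks, k)
    return EvaluationResult(
        per_drug_auc=np.array(aucs),
        per_drug_aupr=np.array(auprs),
        precision_at_k=prec,
        recall_at_k=rec,
        evaluated_drug_ids=tuple(eval_ids),
        skipped_drug_ids=skipped,
        params=params,
        sim_label=sim.label,
    )


def paired_t_test(metric_a, metric_b):
    """One-sided paired t-test of mean(a - b) > 0.

    Returns ``(t_statistic, p_value)``.  Zero-variance differences are handled
    by convention: p = 0.5 if the mean difference is 0, p = 0 if positive,
    p = 1 if negative.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired vectors must have equal length")
    if a.size < 2:
        raise ValidationError("paired t-test needs n >= 2")
    d = a - b
    if np.ptp(d) == 0:  # all differences identical -> zero variance
        mean = d.mean()
        if mean == 0:
            return 0.0, 0.5
        return (np.inf, 0.0) if mean > 0 else (-np.inf, 1.0)
    res = stats.ttest_rel(a, b, alternative="greater")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GridResult:
    """k x t parameter sweep: full table plus the argmax cells."""

    table: pd.DataFrame
    best_by_auc: tuple
    best_by_aupr: tuple


def parameter_grid(views, assoc: AssociationMatrix,
                   k_values=GRID_DEFAULTS, t_values=GRID_DEFAULTS,
                   renormalize: bool = True) -> GridResult:
    """Run fuse + LOOCV for every (k, t) pair and tabulate mean AUC / AUPR."""
    rows = []
    for k in k_values:
        for t in t_values:
            params = FusionParams(k=int(k), t=int(t))
            fused = cross_diffuse(views, params, renormalize=renormalize)
            res = loocv(fused, assoc, params=params)
            rows.append({"k": int(k), "t": int(t),
                         "mean_auc": res.mean_auc, "mean_aupr": res.mean_aupr})
    table = pd.DataFrame(rows)
    ia = int(table["mean_auc"].idxmax())
    ip = int(table["mean_aupr"].idxmax())
    return GridResult(
        table=table,
        best_by_auc=(int(table.loc[ia, "k"]), int(table.loc[ia, "t"])),
        best_by_aupr=(int(table.loc[ip, "k"]), int(table.loc[ip, "t"])),
    )
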