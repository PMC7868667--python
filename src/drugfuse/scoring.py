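"""Guilt-by-association drug-disease scoring.

If a drug treats a disease, drugs similar to it are candidates for the same
indication.  The inference score for a drug-disease pair (r_i, d_j) is the
similarity-weighted fraction of the other drugs known to treat d_j::

    score(r_i, d_j) = sum_{l != i} Sim(r_i, r_l) * a_lj
                      / sum_{l != i} Sim(r_i, r_l)

where a_lj is 1 when drug l is associated with disease j.  The self term is
excluded from both sums; a drug with no similarity to any other drug scores 0
for every disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import SimilarityMatrix, ValidationError, _check_unique, _sep_for

__all__ = [
    "AssociationMatrix",
    "ScoreMatrix",
    "read_association_matrix",
    "gba_score",
    "score_all",
    "rank_candidates",
]


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary drugs x diseases association matrix."""

    drug_ids: tuple
    disease_ids: tuple
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))
        vals = np.asarray(self.values)
        shape = (len(self.drug_ids), len(self.disease_ids))
        if vals.shape != shape:
            raise ValidationError(f"association shape {vals.shape} is not {shape}")
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.disease_ids, "disease")
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary association {vals[i, j]!r} at drug "
                f"{self.drug_ids[i]!r}, disease {self.disease_ids[j]!r}"
            )
        object.__setattr__(self, "values", vals.astype(np.uint8))

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.drug_ids),
                            columns=list(self.disease_ids))


@dataclass(frozen=True)
class ScoreMatrix:
    """Drugs x diseases inference scores, each in [0, 1]."""

    drug_ids: tuple
    disease_ids: tuple
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))
        vals = np.asarray(self.values, dtype=float)
        shape = (len(self.drug_ids), len(self.disease_ids))
        if vals.shape != shape:
            raise ValidationError(f"score shape {vals.shape} is not {shape}")
        if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
            raise ValidationError("scores must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(vals, 0.0, 1.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.drug_ids),
                            columns=list(self.disease_ids))


def read_association_matrix(path) -> AssociationMatrix:
    """Read a drugs x diseases 0/1 table (header = disease ids, first column =
    drug ids; delimiter inferred from the extension)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    try:
        vals = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric entry ({exc})") from None
    return AssociationMatrix(tuple(df.index.astype(str)),
                             tuple(df.columns.astype(str)), vals)


def _check_scoring_inputs(sim: SimilarityMatrix, assoc: AssociationMatrix) -> None:
    if sim.drug_ids != assoc.drug_ids:
        raise ValidationError("similarity and association drug ids differ")


def gba_score(sim: SimilarityMatrix, assoc: AssociationMatrix,
              drug_index: int, disease_index: int) -> float:
    """Inference score for one drug-disease pair (self term excluded)."""
    _check_scoring_inputs(sim, assoc)
    w = np.asarray(sim.values[drug_index], dtype=float).copy()
    w[drug_index] = 0.0
    denom = w.sum()
    if denom == 0:
        return 0.0
    return float(w @ assoc.values[:, disease_index] / denom)


def score_all(sim: SimilarityMatrix, assoc: AssociationMatrix) -> ScoreMatrix:
    """Score every drug-disease pair, including already-known pairs.

    Vectorized form of :func:`gba_score`: with the similarity diagonal zeroed,
    the numerator is ``S0 @ A`` and the denominator the row sums of ``S0``.
    """
    _check_scoring_inputs(sim, assoc)
    s0 = np.asarray(sim.values, dtype=float).copy()
    np.fill_diagonal(s0, 0.0)
    denom = s0.sum(axis=1)
    num = s0 @ assoc.values.astype(float)
    safe = np.where(denom > 0, denom, 1.0)
    scores = np.where(denom[:, None] > 0, num / safe[:, None], 0.0)
    return ScoreMatrix(sim.drug_ids, assoc.disease_ids, scores)


def rank_candidates(scores: ScoreMatrix, drug_index: int,
                    exclude_known: AssociationMatrix | None = None):
    """Diseases for one drug sorted by descending score (ties by disease id).

    With ``exclude_known`` given, diseases already associated with the drug
    are dropped (novel-prediction mode); without it all diseases are ranked
    (cross-validation mode).
    """
    row = scores.values[drug_index]
    ids = np.array(scores.disease_ids, dtype=object)
    keep = np.ones(len(ids), dtype=bool)
    if exclude_known is not None:
        if exclude_known.disease_ids != scores.disease_ids:
            raise ValidationError("score and association disease ids differ")
        keep = exclude_known.values[drug_index] == 0
    lex = np.argsort(np.argsort(ids[keep]))
    order = np.lexsort((lex, -row[keep]))
    kept_ids = ids[keep]
    kept_scores = row[keep]
    return [(str(kept_ids[i]), float(kept_scores[i])) for i in order]
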