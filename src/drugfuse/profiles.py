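"""Binary drug feature profiles and per-view Jaccard similarity.

A *view* (feature space) is one source of drug characterization -- chemical
substructure fingerprints, protein-target profiles, or side-effect profiles --
encoded as a drugs x features matrix of 0/1 indicators.  Drug-drug similarity
within a view is the Jaccard score: the size of the intersection of the two
drugs' feature sets over the size of their union.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinaryProfileMatrix",
    "SimilarityMatrix",
    "ValidationError",
    "read_profile_matrix",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "jaccard_similarity",
    "align_drug_sets",
]

SPACE_LABELS = ("chemical", "genomic", "pharmacological", "other")


class ValidationError(ValueError):
    """Raised when an input matrix violates its contract."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class BinaryProfileMatrix:
    """Drugs x binary features for one feature space.

    Parameters
    ----------
    drug_ids, feature_ids
        Ordered, duplicate-free identifier sequences.
    values
        ``(n_drugs, n_features)`` array with entries in {0, 1}.
    space_label
        One of ``chemical``, ``genomic``, ``pharmacological``, ``other``.
    """

    drug_ids: tuple
    feature_ids: tuple
    values: np.ndarray = field(repr=False)
    space_label: str = "other"

    def __post_init__(self):
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        vals = np.asarray(self.values)
        if vals.ndim != 2 or vals.shape != (len(self.drug_ids), len(self.feature_ids)):
            raise ValidationError(
                f"profile shape {vals.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.feature_ids)} features"
            )
        if len(self.drug_ids) < 2:
            raise ValidationError("need at least 2 drugs")
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.feature_ids, "feature")
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary entry {vals[i, j]!r} at drug {self.drug_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if self.space_label not in SPACE_LABELS:
            raise ValidationError(
                f"space_label must be one of {SPACE_LABELS}, got {self.space_label!r}"
            )
        object.__setattr__(self, "values", vals.astype(np.uint8))

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.drug_ids),
                            columns=list(self.feature_ids))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric n x n drug-drug similarity with entries in [0, 1]."""

    drug_ids: tuple
    values: np.ndarray = field(repr=False)
    label: str = "sim"

    def __post_init__(self):
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        vals = np.asarray(self.values, dtype=float)
        n = len(self.drug_ids)
        if vals.shape != (n, n):
            raise ValidationError(f"similarity shape {vals.shape} is not ({n}, {n})")
        _check_unique(self.drug_ids, "drug")
        if not np.allclose(vals, vals.T, atol=1e-12, rtol=0.0):
            raise ValidationError("similarity matrix is not symmetric")
        if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
            raise ValidationError("similarity entries must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(vals, 0.0, 1.0))

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.drug_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)


def _sep_for(path) -> str:
    # .tsv -> tab, .csv -> comma; anything else defaults to tab
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_id_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_profile_matrix(path, space_label: str = "other") -> BinaryProfileMatrix:
    """Read a drugs x features 0/1 table from delimited text.

    The header row holds feature ids and the first column drug ids; the
    delimiter is inferred from the extension (``.csv`` comma, otherwise tab).
    Row and column order are preserved as found in the file.
    """
    df = _read_id_table(path)
    try:
        vals = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric entry ({exc})") from None
    bad = ~np.isin(vals, (0.0, 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: non-binary entry {df.iat[i, j]!r} at drug "
            f"{df.index[i]!r}, feature {df.columns[j]!r}"
        )
    return BinaryProfileMatrix(tuple(df.index), tuple(df.columns),
                               vals.astype(np.uint8), space_label)


def read_similarity_matrix(path, label: str = "sim") -> SimilarityMatrix:
    """Read a square drug-drug similarity TSV/CSV (ids as header and first column)."""
    df = _read_id_table(path)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column drug ids differ")
    return SimilarityMatrix(tuple(df.index), df.to_numpy(dtype=float), label)


def write_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    """Write a similarity matrix as delimited text with full-precision floats."""
    sim.to_frame().to_csv(path, sep=_sep_for(path), float_format=None)


def jaccard_similarity(profiles: BinaryProfileMatrix) -> SimilarityMatrix:
    """Pairwise Jaccard similarity between drug feature sets.

    Entry (i, j) is |F_i & F_j| / |F_i | F_j| where F_i is the set of features
    with value 1 for drug i.  Two all-zero profiles score 0 off-diagonal (no
    shared evidence is not similarity); the diagonal is forced to 1.
    """
    x = profiles.values.astype(np.float64)
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(sim, 1.0)
    sim = (sim + sim.T) / 2.0  # remove float round-off asymmetry
    label = {"chemical": "chemSim", "genomic": "genoSim",
             "pharmacological": "pharSim"}.get(profiles.space_label,
                                               f"{profiles.space_label}Sim")
    return SimilarityMatrix(profiles.drug_ids, sim, label)


def align_drug_sets(matrices, associations=None):
    """Restrict profile matrices (and optionally an association matrix) to the
    drugs they all share, in canonical lexicographic id order.

    Returns ``(aligned_matrices, aligned_associations)``;
    ``aligned_associations`` is None when no association matrix was given.
    """
    if not matrices:
        raise ValidationError("need at least one profile matrix")
    common = set(matrices[0].drug_ids)
    for m in matrices[1:]:
        common &= set(m.drug_ids)
    if associations is not None:
        common &= set(associations.drug_ids)
    if len(common) < 2:
        raise ValidationError(
            f"drug id intersection across inputs has {len(common)} drugs; need >= 2"
        )
    order = sorted(common)
    out = []
    for m in matrices:
        pos = {d: i for i, d in enumerate(m.drug_ids)}
        idx = [pos[d] for d in order]
        out.append(BinaryProfileMatrix(tuple(order), m.feature_ids,
                                       m.values[idx], m.space_label))
    assoc_out = None
    if associations is not None:
        pos = {d: i for i, d in enumerate(associations.drug_ids)}
        idx = [pos[d] for d in order]
        assoc_out = type(associations)(tuple(order), associations.disease_ids,
                                       associations.values[idx])
    return out, assoc_out
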