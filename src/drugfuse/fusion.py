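"""Cross-diffusion fusion of multiple drug-drug similarity views.

Each view's similarity matrix W is turned into two row-stochastic kernels:

* a *full kernel* P carrying half its row mass on the diagonal,
  ``P(i,j) = W(i,j) / (2 * sum_{k != i} W(i,k))`` off-diagonal and ``1/2`` on it;
* a *local affinity* S restricted to each drug's k nearest neighbours,
  ``S(i,j) = W(i,j) / sum_{l in N_i} W(i,l)`` for ``j in N_i`` and 0 elsewhere.

The views then exchange information iteratively: each view's status matrix is
propagated through its own neighbourhood graph while reading the other views'
status, ``P^(v) <- S^(v) @ mean_{u != v}(P^(u)) @ S^(v).T``, run for t steps
with all views updated simultaneously from the previous step.  The fused
similarity is the average of the final status matrices.

By default each status matrix is re-passed through the full-kernel transform
after every update.  The raw update does not keep the diagonal dominant, while
a drug should stay more similar to itself than to any other drug throughout
the iterations; re-normalization enforces that invariant and keeps every
status matrix row-stochastic.  It can be disabled with ``renormalize=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import SimilarityMatrix, ValidationError

__all__ = [
    "FullKernel",
    "LocalAffinity",
    "FusionParams",
    "normalize_full_kernel",
    "knn_local_affinity",
    "cross_diffuse",
    "average_fusion_baseline",
]


@dataclass(frozen=True)
class FusionParams:
    """Neighbour count k and iteration count t (defaults 5 and 5)."""

    k: int = 5
    t: int = 5

    def __post_init__(self):
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if self.t < 0:
            raise ValidationError(f"t must be >= 0, got {self.t}")


@dataclass(frozen=True)
class FullKernel:
    """Row-stochastic full kernel P; diagonal 1/2 except isolated-drug rows."""

    values: np.ndarray = field(repr=False)
    drug_ids: tuple = ()


@dataclass(frozen=True)
class LocalAffinity:
    """Row-stochastic KNN affinity S; row i is supported on its k neighbours."""

    values: np.ndarray = field(repr=False)
    drug_ids: tuple = ()
    k: int = 0


def _full_kernel_values(w: np.ndarray) -> np.ndarray:
    """Full-kernel transform: off-diagonal row-normalized to mass 1/2,
    diagonal 1/2.  Rows with zero off-diagonal mass become identity rows."""
    w = np.asarray(w, dtype=float)
    off_sums = w.sum(axis=1) - np.diag(w)
    safe = np.where(off_sums > 0, off_sums, 1.0)
    p = w / (2.0 * safe[:, None])
    np.fill_diagonal(p, 0.5)
    dead = off_sums <= 0
    if dead.any():
        p[dead] = 0.0
        p[dead, np.flatnonzero(dead)] = 1.0
    return p


def normalize_full_kernel(w: SimilarityMatrix) -> FullKernel:
    """Normalize a similarity matrix into the full kernel P.

    The input's diagonal is ignored by the row sums; every row of P sums to 1.
    """
    return FullKernel(_full_kernel_values(w.values), w.drug_ids)


def _knn_values(w: np.ndarray, k: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if not 1 <= k <= n - 1:
        raise ValidationError(f"k must be in [1, {n - 1}], got {k}")
    masked = w.copy()
    np.fill_diagonal(masked, -np.inf)  # self is never a neighbour
    # stable argsort on the negated row: ties at the k-th rank go to the lower index
    order = np.argsort(-masked, axis=1, kind="stable")[:, :k]
    s = np.zeros_like(w)
    for i in range(n):
        nb = order[i]
        d = w[i, nb].sum()
        if d > 0:
            s[i, nb] = w[i, nb] / d
        else:
            s[i, nb] = 1.0 / k  # zero-similarity neighbourhood: uniform fallback
    return s


def knn_local_affinity(w: SimilarityMatrix, k: int) -> LocalAffinity:
    """Sparse local affinity S over each drug's k most similar other drugs."""
    return LocalAffinity(_knn_values(w.values, k), w.drug_ids, k)


def _check_aligned(views) -> tuple:
    if len(views) < 2:
        raise ValidationError(f"need >= 2 views, got {len(views)}")
    ids = views[0].drug_ids
    for i, v in enumerate(views[1:], start=2):
        if v.drug_ids != ids:
            raise ValidationError(
                f"view {i} ({v.label!r}) drug ids differ from view 1 ({views[0].label!r})"
            )
    return ids


def cross_diffuse(views, params: FusionParams = FusionParams(),
                  renormalize: bool = True,
                  return_history: bool = False):
    """Fuse m >= 2 similarity views by cross-diffusion.

    Parameters
    ----------
    views
        Aligned :class:`SimilarityMatrix` instances (same drug ids, same order).
    params
        Neighbour count k and iteration count t.
    renormalize
        Re-apply the full-kernel transform after each update (default).
    return_history
        Also return the list of per-iteration status matrices
        ``[[P^(v)_0, ...], [P^(v)_1, ...], ...]`` for diagnostics.

    Returns
    -------
    SimilarityMatrix labelled ``IntegratedSim``: the mean of the final status
    matrices, symmetrized as ``(M + M.T) / 2`` and rescaled to [0, 1] by its
    maximum entry.  With ``return_history=True`` a ``(sim, history)`` pair.
    """
    ids = _check_aligned(views)
    m = len(views)
    ps = [_full_kernel_values(v.values) for v in views]
    ss = [_knn_values(v.values, params.k) for v in views]
    history = [[p.copy() for p in ps]]
    for _ in range(params.t):
        new = []
        for v in range(m):
            others = sum(ps[u] for u in range(m) if u != v) / (m - 1)
            upd = ss[v] @ others @ ss[v].T
            if renormalize:
                upd = _full_kernel_values(upd)
            new.append(upd)
        ps = new
        history.append([p.copy() for p in ps])
    fused = sum(ps) / m
    fused = (fused + fused.T) / 2.0
    peak = fused.max()
    if peak > 0:
        fused = fused / peak
    sim = SimilarityMatrix(ids, fused, "IntegratedSim")
    if return_history:
        return sim, history
    return sim


def average_fusion_baseline(views) -> SimilarityMatrix:
    """Naive fusion comparator: the element-wise mean of the input views."""
    ids = _check_aligned(views)
    mean = sum(np.asarray(v.values, dtype=float) for v in views) / len(views)
    return SimilarityMatrix(ids, mean, "AverageSim")
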