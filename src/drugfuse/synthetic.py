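"""Synthetic multi-view drug profiles with planted cluster structure.

The generator emulates the shape of real multi-source drug data: three sparse
binary feature spaces (chemical substructures, protein targets, side-effects)
over a shared set of drugs, plus a sparse binary drug-disease association
matrix.  Drugs belong to latent clusters; each cluster owns a block of
characteristic feature bits per view, and diseases attach preferentially to
one cluster's drugs, so drugs that share a cluster share both features and
indications -- the regime in which guilt-by-association works.

Noise is *complementary across views*: each view scrambles a different subset
of drugs, so information lost in one feature space survives in the others.
This is the setting where fusing the views should beat any single view.

The random stream is consumed in a fixed documented order (profiles view by
view in chemical/genomic/pharmacological order -- cluster bits, background
bits, corruption -- then associations), so a config plus seed pins every bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import BinaryProfileMatrix, ValidationError
from .scoring import AssociationMatrix

__all__ = ["SyntheticConfig", "generate", "VIEW_ORDER"]

VIEW_ORDER = ("chemical", "genomic", "pharmacological")


def _default_features():
    # real-data dimensionalities: 881 substructures, 775 targets, 1385 side-effects
    return {"chemical": 881, "genomic": 775, "pharmacological": 1385}


def _default_flips():
    return {"chemical": 0.35, "genomic": 0.35, "pharmacological": 0.35}


def _default_corrupt():
    return {"chemical": 1 / 3, "genomic": 1 / 3, "pharmacological": 1 / 3}


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-cluster generator.

    Defaults: 120 drugs in 6 clusters over 60 diseases; per-view feature
    counts match the real dimensionalities; in each view a disjoint third of
    the drugs has every profile bit flipped with probability 0.35
    (complementary noise); same-cluster drug-disease pairs associate with
    probability 0.3 against a 0.005 background.
    """

    n_drugs: int = 120
    n_diseases: int = 60
    n_clusters: int = 6
    features_per_view: dict = field(default_factory=_default_features)
    bits_per_cluster: int = 40
    background_density: float = 0.02
    flip_prob_per_view: dict = field(default_factory=_default_flips)
    corrupted_drug_fraction_per_view: dict = field(default_factory=_default_corrupt)
    assoc_within_cluster_prob: float = 0.3
    assoc_background_prob: float = 0.005
    seed: int = 1

    def validate(self) -> None:
        if self.n_drugs < 2 or self.n_diseases < 1 or self.n_clusters < 1:
            raise ValidationError("counts must be positive (n_drugs >= 2)")
        if self.n_clusters > self.n_drugs:
            raise ValidationError("n_clusters cannot exceed n_drugs")
        if self.bits_per_cluster < 1:
            raise ValidationError("bits_per_cluster must be positive")
        for view in VIEW_ORDER:
            if view not in self.features_per_view:
                raise ValidationError(f"missing feature count for view {view!r}")
            if self.features_per_view[view] < self.n_clusters * self.bits_per_cluster:
                raise ValidationError(
                    f"view {view!r} needs >= n_clusters * bits_per_cluster features"
                )
        probs = (
            [self.background_density, self.assoc_within_cluster_prob,
             self.assoc_background_prob]
            + [self.flip_prob_per_view[v] for v in VIEW_ORDER]
            + [self.corrupted_drug_fraction_per_view[v] for v in VIEW_ORDER]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")


def _drug_ids(n):
    width = len(str(n - 1))
    return tuple(f"drug{str(i).zfill(width)}" for i in range(n))


def _disease_ids(n):
    width = len(str(n - 1))
    return tuple(f"disease{str(i).zfill(width)}" for i in range(n))


def generate(config: SyntheticConfig):
    """Generate three profile matrices, an association matrix and cluster labels.

    Returns ``(profiles, associations, labels)`` where ``profiles`` is a dict
    keyed by view name and ``labels`` maps each drug (by position) to its
    cluster index.  Fully deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, c = config.n_drugs, config.n_clusters
    labels = np.arange(n) % c  # round-robin assignment
    drug_ids = _drug_ids(n)

    # disjoint-where-possible corrupted drug sets, carved from one permutation
    perm = rng.permutation(n)
    corrupt_sets = {}
    cursor = 0
    for view in VIEW_ORDER:
        n_corrupt = int(round(config.corrupted_drug_fraction_per_view[view] * n))
        if cursor + n_corrupt <= n:
            chosen = perm[cursor:cursor + n_corrupt]
            cursor += n_corrupt
        else:  # fractions exceed 1 overall; wrap around
            chosen = np.concatenate([perm[cursor:], perm[: cursor + n_corrupt - n]])
            cursor = (cursor + n_corrupt) % n
        mask = np.zeros(n, dtype=bool)
        mask[chosen] = True
        corrupt_sets[view] = mask

    profiles = {}
    for view in VIEW_ORDER:
        f = config.features_per_view[view]
        vals = (rng.random((n, f)) < config.background_density)
        for cl in range(c):
            lo = cl * config.bits_per_cluster
            vals[labels == cl, lo:lo + config.bits_per_cluster] = True
        flips = (rng.random((n, f)) < config.flip_prob_per_view[view])
        flips[~corrupt_sets[view]] = False
        vals = vals ^ flips
        profiles[view] = BinaryProfileMatrix(
            drug_ids,
            tuple(f"{view[:4]}_f{j}" for j in range(f)),
            vals.astype(np.uint8),
            view,
        )

    disease_cluster = np.arange(config.n_diseases) % c  # each disease owns a cluster
    same = labels[:, None] == disease_cluster[None, :]
    p = np.where(same, config.assoc_within_cluster_prob, config.assoc_background_prob)
    assoc_vals = (rng.random((n, config.n_diseases)) < p).astype(np.uint8)
    assoc = AssociationMatrix(drug_ids, _disease_ids(config.n_diseases), assoc_vals)
    return profiles, assoc, labels
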