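# Methods

## Model

Drugs are described in m binary feature spaces ("views"). Within a view,
similarity between drugs i and j is the Jaccard score of their feature sets.
The fusion step treats each view's n × n similarity matrix W as a weighted
graph over the drugs and builds two row-stochastic operators from it:

- **Full kernel** P: off-diagonal entries are row-normalized to total mass
  1/2, the diagonal is fixed at 1/2, so every row sums to 1 and the input's
  own diagonal never enters the normalization. P is each view's "status"
  matrix carrying its current estimate of drug–drug similarity.
- **Local affinity** S: row i is supported on the k other drugs most similar
  to i and row-normalized. S is kept fixed across iterations; it encodes each
  view's trusted local neighbourhood, through which information from the
  other views is propagated.

One cross-diffusion step replaces each view's status with its neighbourhood-
filtered average of the *other* views' statuses,
P⁽ᵛ⁾ ← S⁽ᵛ⁾ · mean_{u≠v}(P⁽ᵘ⁾) · (S⁽ᵛ⁾)ᵀ, all views updated simultaneously
from the previous step (Jacobi-style, since both update formulas read
step-t matrices). With exactly two views this reduces to the familiar
two-matrix recursion; the m-view form averages the complementary statuses.
After t steps the integrated similarity is the mean of the final statuses,
symmetrized as (M + Mᵀ)/2 and rescaled by its maximum entry so it satisfies
the same contract as the input similarities (symmetric, in [0, 1]).

### Post-update re-normalization

After every update each status matrix is re-passed through the full-kernel
transform. The raw product S·P·Sᵀ is neither row-stochastic nor
diagonally dominant, but a sound drug similarity should keep each drug more
similar to itself than to any other drug throughout the iterations; the
re-normalization enforces exactly that (diagonal 1/2 ≥ every off-diagonal
entry, whose row mass of 1/2 is split over ≥ 1 entries) and stabilizes the
diffusion. Because it changes numerical output, it is exposed as a switch
(`renormalize=True` in the library, `--no-renormalize` on the CLI).

### Scoring and evaluation

Guilt-by-association: score(r_i, d_j) is the similarity-weighted fraction of
the *other* drugs associated with disease j. The self term is excluded from
numerator and denominator, which makes the score scale-invariant in the
similarity and — crucially for evaluation — makes drug i's own association
row irrelevant to its own scores, so a single scoring pass yields every
leave-one-out fold's held-out scores without re-computation.

Per-drug metrics over the held-out indications (positives) versus all other
diseases (negatives):

- **AUC**: Mann–Whitney rank statistic, ties counted ½ (equivalent to the
  threshold-sweep ROC area in the all-thresholds limit).
- **AUPR**: non-interpolated average precision with positives ranked *after*
  negatives of equal score, so a constant predictor scores the prevalence
  rather than being inflated by optimistic tie placement.
- **precision@k / recall@k** for k ∈ {5, 10, 15, 20}, using a deterministic
  candidate ordering (descending score, ties by lexicographic disease id).

Summaries are macro-averages over evaluated drugs; drugs without any known
association are skipped with a warning. Paired one-sided t-tests (alternative
"greater", n−1 degrees of freedom) compare the fused measurement's per-drug
metric vector with each single view's; when all paired differences are
identical the p-value is 0.5 / 0 / 1 by convention for zero / positive /
negative mean difference.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| k | neighbours per drug in S | 5 | grid optimum by AUC and AUPR; small k keeps propagation local |
| t | diffusion iterations | 5 | grid optimum; more iterations over-smooth |
| renormalize | re-apply full-kernel transform per step | on | preserves row-stochasticity and self-similarity dominance |
| grid | k, t sweep values | {1, 5, 10, 20, 30}² | standard sweep reported by the grid runner |

## Numerical choices and degenerate inputs

- A drug with zero similarity to all others gets an identity row in P
  (nothing to diffuse) and, in S, a uniform row over its k lowest-index
  pseudo-neighbours — both keep the operators row-stochastic without NaNs.
  Its guilt-by-association scores are 0 (denominator rule), ranking it last.
- Two all-zero feature profiles have Jaccard similarity 0, not NaN: absence
  of shared evidence is not evidence of similarity. Diagonals are forced to 1.
- KNN ties at the k-th rank break toward the lower drug index (after
  canonical lexicographic ordering of drug ids), making runs deterministic.
  The price is that fusion is permutation-equivariant only on tie-free
  similarities; with ties, re-ordering the drugs can change which tied
  neighbour is kept.
- Row-stochasticity is asserted to 1e-10; oracle agreement in tests to 1e-12.

## Synthetic data

The generator plants c drug clusters (round-robin assignment); each cluster
owns a disjoint block of characteristic bits per view on top of sparse
background bits, and each disease is attached to one cluster, with
associations drawn at a high within-cluster and low background probability.
Noise is *complementary*: each view flips the bits of a different third of
the drugs (carved from one permutation, disjoint when fractions allow), so a
drug scrambled in one view remains well-placed in the other two — the regime
in which fusing views should beat any single view, which is what the
qualitative benchmark asserts over ten replicate seeds.

Default conditions: 120 drugs, 60 diseases, 6 clusters; 881/775/1385 features
per view (matching the dimensionalities of public substructure / target /
side-effect data); 40 cluster bits; background density 0.02; flip probability
0.35 on a corrupted third per view; association probability 0.3 within
cluster and 0.005 background (≈3–4 indications per drug — sparse, as real
indication data is). The generator consumes a single RNG stream in a fixed
documented order, so a config plus seed pins every bit.

What the synthetic regime does **not** emulate: real chemistry (bits are
abstract, not fragment semantics), heterogeneous cluster sizes, drugs acting
in several mechanistic families at once, or disease–disease structure.
Passing the benchmark shows the pipeline exploits planted complementary
structure; it does not certify effect sizes on real pharmacological data.
Problem sizes in the test suite are scaled to the structure being checked:
oracle comparisons run at n ≤ 12, protocol-level checks at 120 drugs, and one
readiness check at the full 548-drug / 719-disease shape.

## Limitations

- Fixed iteration count t; no convergence detection or early stopping.
- The scoring rule cannot say anything about a disease no remaining drug is
  associated with (score 0) or about a drug with no similarity support.
- Rescaling the fused matrix by its maximum affects reported similarity
  values but not rankings or scores (the score is scale-invariant).
- The evaluation assumes the association matrix is complete ground truth;
  unknown-but-true associations are counted as negatives.
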