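# drugfuse

Computational drug repositioning by multi-view similarity fusion.

Approved drugs are characterized in several independent feature spaces —
chemical substructure fingerprints, protein-target profiles, and side-effect
profiles — each a sparse binary drugs × features matrix. Each space captures
a different, complementary facet of drug behaviour. `drugfuse` computes
drug–drug similarities per space, fuses them into one integrated similarity
network by iterative cross-diffusion, and uses the fused network to rank
candidate diseases for every drug under the guilt-by-association principle:
drugs similar to a drug that treats a disease are candidates for the same
indication.

## Method

For each feature space the drug–drug similarity is the Jaccard score
W(i,j) = |F_i ∩ F_j| / |F_i ∪ F_j| over the drugs' feature sets. Each view's
similarity matrix W is normalized into two row-stochastic kernels:

- a **full kernel** P with P(i,j) = W(i,j) / (2 Σ_{k≠i} W(i,k)) for j ≠ i and
  P(i,i) = 1/2, so half of each row's mass stays on the drug itself;
- a **local affinity** S supported on each drug's k nearest neighbours N_i,
  S(i,j) = W(i,j) / Σ_{l∈N_i} W(i,l) for j ∈ N_i and 0 otherwise.

The m views then exchange information for t iterations, all views updating
simultaneously from the previous step:

    P⁽ᵛ⁾ ← S⁽ᵛ⁾ · mean_{u≠v}(P⁽ᵘ⁾) · (S⁽ᵛ⁾)ᵀ

after which each P⁽ᵛ⁾ is re-passed through the full-kernel transform, keeping
every status matrix row-stochastic and every drug more similar to itself than
to any other drug throughout the iterations. The integrated similarity is the
mean of the final status matrices, symmetrized and rescaled to [0, 1].
Defaults are k = 5 and t = 5.

A candidate pair (drug r_i, disease d_j) is scored by

    score(r_i, d_j) = Σ_{l≠i} Sim(r_i, r_l) · a_lj / Σ_{l≠i} Sim(r_i, r_l)

where a_lj = 1 when drug l is known to treat disease j. Evaluation is
leave-one-out cross-validation: each drug's known indications are withheld
and recovered by ranking all diseases, measured by per-drug AUC (Mann–Whitney,
ties ½), AUPR (average precision), and precision/recall in the top
k ∈ {5, 10, 15, 20}, macro-averaged over drugs; one-sided paired t-tests
compare measurements drug-by-drug.

A synthetic data module generates multi-view binary profiles with planted
drug clusters and *complementary* per-view noise (each view scrambles a
different subset of drugs), the regime in which fusing views genuinely helps.

## Worked example

```
drugfuse simulate --n-drugs 120 --n-diseases 60 --n-clusters 6 --seed 1 --out data/
drugfuse evaluate --view data/chemical.tsv --view data/genomic.tsv \
    --view data/pharmacological.tsv --assoc data/assoc.tsv --per-view --out report/
```

`report/summary.tsv` then contains (seed 1):

```
              IntegratedSim  chemSim  genoSim  pharSim  AverageSim
mean_auc             0.9012   0.7778   0.7982   0.7505      0.8950
mean_aupr            0.3938   0.2927   0.3041   0.3157      0.3711
precision@5          0.2828   0.1448   0.2224   0.2259      0.2534
```

The fused similarity recovers withheld indications better than any single
feature space (mean AUC 0.90 against 0.75–0.80) and better than naive view
averaging — the complementary information in the three spaces is what the
cross-diffusion exploits. `report/t_tests.tsv` holds the paired t-tests of
that advantage, and `drugfuse evaluate --grid` sweeps the k × t parameter
grid ({1, 5, 10, 20, 30}²).

To fuse your own data, supply TSV/CSV profile matrices (header row = feature
ids, first column = drug ids, body 0/1) and an equally shaped drug–disease
association table; drugs are aligned across files by id intersection:

```
drugfuse fuse --view chem.tsv --view geno.tsv --view phar.tsv --k 5 --t 5 --out integrated.tsv
drugfuse score --sim integrated.tsv --assoc assoc.tsv --top 20 --out predictions.tsv
```

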