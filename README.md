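# sosa — sparse optimal scoring with adjustment

Embedded gene selection for expression data confounded by unwanted
heterogeneity.  Gene expression matrices collected across technical
replicates, laboratories or platform batches carry known group structure,
and usually additional *unknown* latent factors.  Both distort any attempt
to rank genes by their association with the factor actually of interest —
the grouping itself (unsupervised; e.g. which genes differentiate spike-in
array groups) or an outcome (supervised; e.g. which genes separate tumour
types).  `sosa` is for analysts who want a single ranking of genes that is
resilient to both kinds of nuisance variation, with model-based selection
rather than per-gene testing.

## The method

Samples-by-genes data X (n × p) are modelled additively,

    X = Y γ + G η + F φ + ε        (supervised; drop Y γ for unsupervised)

with group indicators G, outcome Y, K latent factors F and i.i.d. Gaussian
noise ε.  **Stage 1** removes unwanted heterogeneity: the residual
projector R_N = I − N(NᵀN)⁻Nᵀ of the known design N strips known effects,
SVD of R_N X yields surrogate factors h_k, each refined into a full factor
estimate F_k from its most-associated genes, and the adjusted matrix
X_a = X − U α̂ is formed from a joint least-squares fit on [M | U]
(U = F or [G | F]; M is the interest design).  **Stage 2** solves the
row-sparse optimal-scoring problem

    min_{B,Θ} (1/n)‖X_a B − M Θ‖²_F + λ Σ_j ‖b_j‖₂   s.t.  Θᵀ MᵀM Θ = I

by alternating an exact orthogonal-Procrustes Θ-update (SVD of
(MᵀM)^{-1/2}MᵀX_a B) with iteratively reweighted-l2 ridge steps for B, and
ranks genes by the row norms ‖b_j‖₂.  λ is chosen by cross-validation on
the held-out objective.  See `docs/methods.md` for assumptions, defaults
and numerical details.

## Worked example

Simulate a spike-in-shaped benchmark (59 arrays in 14 replicate groups, 16
planted signal genes among 2,000, six confounded latent factors), adjust,
fit and evaluate:

```python
import numpy as np
import sosa

X, design, truth = sosa.spike_in_scenario(seed=1)
adjusted, surrogates, known = sosa.adjust_heterogeneity(X, design, K=6)
fit = sosa.fit_sosa(adjusted.X_a, adjusted.M, lam=0.3)
ranking = sosa.rank_variables(fit.B, gene_ids=X.gene_ids)
print(f"converged={fit.converged} after {fit.n_iter} iterations; "
      f"objective {fit.objective_trace[0]:.4f} -> {fit.objective_trace[-1]:.4f}")
print(f"active genes (row norm > 1e-6): {int(np.sum(ranking.scores > 1e-6))}")

controls = sosa.ControlSets(
    true_genes={X.gene_ids[j] for j in truth.signal_gene_indices},
    false_genes=set(X.gene_ids)
    - {X.gene_ids[j] for j in truth.signal_gene_indices},
)
tp, _ = sosa.hits_at_n(ranking, controls, 16)
print(f"top-16 hits: {tp}/16, AUC = {sosa.roc_auc(ranking, controls).auc:.4f}")
```

Output:

```
converged=True after 34 iterations; objective 0.9208 -> 0.1935
active genes (row norm > 1e-6): 16
top-16 hits: 16/16, AUC = 1.0000
```

At this sparsity level the fit keeps exactly 16 nonzero coefficient rows —
and they are precisely the 16 planted genes, so the ranking recovers the
ground truth and the ROC area against the 1,984 null genes is 1.

The same pipeline is available from the shell:

```sh
sosa simulate --scenario spike-in --seed 1 --out data/
sosa run-all --expression data/expression.tsv --annotation data/annotation.tsv \
     --K 6 --lam 0.3 --seed 1 --out results/
sosa cv --expression data/expression.tsv --annotation data/annotation.tsv \
     --K 6 --scheme group --seed 1 --out results/cv/
```

Expression files are delimited text, genes-as-rows by default; annotations
are TSV with `sample_id`, `group` and optional `outcome` columns; control
gene lists are plain text, one id per line.

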