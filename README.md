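# preadapt

Single-cell analysis toolkit for detecting **rare pre-adapted tumour cells**
— treatment-naive cells whose transcriptome already resembles that of
drug-exposed cells — and for characterising the multi-step adaptation of
ER-positive breast cancer cells to endocrine therapy. It packages, as a
tested and reusable pipeline, the computational procedures such a study
needs:

- **Expression-derived copy-number inference**: per-cell log-normalised
  expression averaged over genome-ordered sliding windows (100 genes, step
  10), regressed by OLS against a reference pseudo-bulk; the residuals are
  the copy-number proxy, clustered with Ward linkage to separate genetic
  clones.
- **Gene-regulatory-network inference by partial information decomposition
  (PID)**: per condition, every gene pair is scored by its proportional
  unique contribution, `u(X,Y) = Σ_Z [Uniq_Y(X|{Y,Z}) + Uniq_X(Y|{X,Z})] /
  I(X;Y)`, with Williams–Beer redundancy
  `I_min = Σ_t p(t) min_S I_spec(t;S)`, calibrated through each gene's
  empirical CDF (the PIDC scheme), keeping the top 2,000 edges.
- **Network overlap analysis**: two condition networks superimposed with
  edges labelled by provenance, communities from recursive label
  propagation (≥ 10 nodes), and per-community cross-condition similarity
  (Jaccard index over internal edges) tested against a degree-preserving
  configuration-model null (1,000 rewired pairs, empirical
  `p = (r+1)/(n+1)`, BH-corrected).
- **Dual-strategy rare-cell detection**: an NMF embedding threshold
  (leading factor ≥ 0.75 after min-max scaling, k chosen by masked-entry
  imputation) and a random-forest misclassification procedure (10%/90%
  train/test split, marker-gene features, naive cells with
  P(treated) > 0.5 flagged; out-of-bag error as the expected baseline).
- **Signature statistics**: per-cell sum scores and rank-AUC
  (recovery-curve) scores capped at the top 5% of ranks, hypergeometric
  overlap tests, co-regulation tests against size-matched random gene sets,
  and CTC (circulating tumour cell) enrichment statistics with
  permutation-estimated FDR (Wilcoxon rank-sum over per-capture DEG
  fractions or max-normalised cluster scores; 1,000 label permutations).
- **A synthetic-data module** that generates every input with planted
  ground truth — negative-binomial counts with logistic dropout, planted
  CNA blocks, a rare signature-shifted subpopulation, a bimodal surface
  marker, dependency-network expression and CTC-like capture/control pairs
  — so the whole pipeline is testable without any download.

See `docs/methods.md` for the models, conventions and their assumptions.

## Worked example: recovering planted pre-adapted cells

Simulate a treatment-naive and a starved population (2,000 genes, 2,000
cells each) where 1% of naive cells mimic the starved expression signature,
then find them with the classifier strategy:

```python
from preadapt.simulate import SimConfig, simulate_counts
from preadapt.preprocess import lognormalize
from preadapt.pa import pa_by_classifier

cfg = SimConfig(seed=7, n_cells_per_population=2000, rare_fraction=0.01)
counts, truth = simulate_counts(cfg)
norm = lognormalize(counts)
pop = truth.cells["population"].to_numpy()

call, model = pa_by_classifier(
    norm.subset_cells(pop == "naive"),
    norm.subset_cells(pop == "starved"),
    seed=1,
)
```

Output:

```
features used          : 104 marker genes
out-of-bag error       : 0.0050
flagged pre-adapted    : 25 of 1800 naive test cells
planted rare recovered : 19/19 (precision 0.76, recall 1.00)
```

All 19 planted pre-adapted cells in the test split are flagged (recall
1.00). The six false positives amount to 0.33% of the tested naive cells —
within the forest's own 0.5% out-of-bag error, which is exactly the
baseline the misclassification procedure reports for judging such calls.
At 5,000 cells per condition both precision and recall exceed 0.9.

The same scenario end to end — QC, CNA residuals, per-condition PIDC
networks, overlap communities, both PA strategies, signature scores, and a
reproducibility manifest — runs from the command line:

```bash
preadapt run --seed 11 --out run1
```

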