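# mindrank

Two-stage prioritization of non-coding variants and candidate genes for
mental disorders (schizophrenia, ASD, ADHD, MDD and related conditions) from
whole-genome sequencing data.

Most disease-associated variation in psychiatric genetics is non-coding, and
no single functional score separates causal regulatory variants from benign
ones well. `mindrank` is for researchers who have a list of variants from a
personal genome or a case/control study and want a ranked shortlist of
variants and genes worth following up. It integrates the standard
annotation resources — pre-computed functional predictor scores, population
allele frequency, brain eQTL evidence and brain enhancer/promoter ChIP-seq
peaks — with a trained scoring model, then propagates variant evidence to
genes.

## The model

**Stage 1 — variant scoring (ncDeepBrain).** Each variant *v* is described
by an 11-component feature vector

    F(v) = (EIGEN, CADD, DANN, GWAVA, FATHMM, GNOMAD,
            eQTL, H3K4me3, H3K4me1, H3K27me3, H3K27Ac)

The five predictor scores and the GNOMAD frequency are looked up in
pre-computed tables; absent entries are imputed jointly by Bayesian PCA. The
remaining features are defined by rule for every variant: per histone mark,
an indicator that equals 1 iff the variant lies inside a ChIP-seq peak of
that mark, and the brain-eQTL feature

    f(v) = 1 − q  (clamped to [0.5, 1])  if v has a significant brain eQTL
    f(v) = 0.5                           otherwise

A feed-forward network with four hidden layers (ReLU, dropout) and a sigmoid
output unit ŷ = σ(WᵀX + b) = 1/(1 + e^−(WᵀX+b)) is trained on labelled
variants by SGD with momentum, minimizing the summed negative log
likelihood L(y, ŷ) = −y log ŷ − (1−y) log(1−ŷ). Training sets are
rebalanced beforehand by smoothed-bootstrap resampling (ROSE-style, with the
asymptotically optimal per-class kernel bandwidths). A logistic-regression
baseline (ncLGBrain) trained by the same optimizer serves as the comparison
model, and performance is measured by stratified 10-fold cross-validated
ROC/AUC.

**Stage 2 — gene scoring.** Scored variants are linked to every gene whose
body lies within 100 kb; per gene, linked variant scores are reduced to one
scalar (default: maximum). That value joins six gene-level predictors into

    F(g) = (variant score, RVIS, GTEx, haploinsufficiency, Phenolyzer, CNV, DNM)

with per-source fill rules for genes absent from a table: RVIS → 0,
CNV → 0.5 (q-values inverted to 1 − q), GTEx / haploinsufficiency /
Phenolyzer → the training-set missing rate of that feature (EMR), and the
de-novo-mutation burden is the per-gene count min–max normalized over the
gene universe. The same network architecture produces the final gene
prioritization score.

Because the real annotation resources are large external downloads, the
package ships a first-class synthetic-data generator that emulates all of
them on a toy genome with a planted, configurable class signal, and reports
the construction's exact Bayes AUC as an upper bound for any trained model.

## Worked example

```python
import numpy as np
from mindrank import (SimulationConfig, simulate_stage1, assemble_variant_features,
                      LabeledDataset, cross_validate, PipelineSpec, compare_single_scores)

cfg = SimulationConfig(seed=42)
data = simulate_stage1(cfg)
print(f"simulated {len(data.variants)} variants "
      f"({data.labels.sum()} disease-associated), Bayes AUC {data.bayes_auc:.3f}")

features = assemble_variant_features(
    data.variants, data.score_tables, data.eqtl_table, data.mark_tracks)
print(f"feature matrix: {features.shape[0]} x {features.shape[1]}, "
      f"{100 * features.mask.mean():.1f}% cells missing")

dataset = LabeledDataset(features, data.labels)
cv = cross_validate(dataset, PipelineSpec(), k=10, seed=42)
print(f"deep scorer 10-fold CV AUC: {cv.mean_auc:.3f} +/- {cv.std_auc:.3f}")

table = compare_single_scores(dataset, {"ncDeepBrain": cv.pooled_scores})
print(table.sort_values("auc", ascending=False).head(4).to_string(index=False))
```

Output:

```
simulated 3000 variants (600 disease-associated), Bayes AUC 0.900
feature matrix: 3000 x 11, 5.0% cells missing
deep scorer 10-fold CV AUC: 0.881 +/- 0.036
      score      auc  flipped  constant
ncDeepBrain 0.878302    False     False
      GWAVA 0.661713    False     False
       CADD 0.649810    False     False
    H3K4me3 0.642500    False     False
```

The generator planted a signal whose optimal classifier reaches AUC 0.900;
the integrated scorer recovers 0.881 in leakage-free cross-validation, while
the best single input feature reaches only 0.662 — integration is what buys
the separation, since no individual feature carries the whole signal.

The same pipeline is available from the shell:

```bash
mindrank simulate --out fixtures --seed 7           # writes inputs + config.yaml
mindrank train-variant --config fixtures/config.yaml --out run/variant
mindrank score-variant --config fixtures/config.yaml \
    --model run/variant/variant_model.json --out run/scored
mindrank train-gene --config fixtures/config.yaml \
    --variant-scores run/scored/ranked_variants.tsv --out run/gene
mindrank rank-genes --config fixtures/config.yaml \
    --variant-scores run/scored/ranked_variants.tsv \
    --model run/gene/gene_model.json --out run/ranked
mindrank evaluate --config fixtures/config.yaml \
    --model run/variant/variant_model.json --out run/eval
```

Real data drop into the same config file: variant lists in VCF, BED or
ANNOVAR avinput format, annotation sources as TSV tables and BED peak files
(see `docs/methods.md` for the exact dialects).

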