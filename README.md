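# rair-axis

Transcriptional signature scoring and multimodal drug-response modelling for
radioiodine-refractory (RAIR) and anaplastic (ATC) thyroid cancer states.

Radioiodine-refractory papillary thyroid carcinoma and anaplastic thyroid
carcinoma sit at the difficult end of the thyroid cancer spectrum. A useful
way to study them jointly is to derive gene modules from case/control
expression cohorts, collapse the up-module into a single-sample signature
score, transfer that score to cell-line panels, and ask which drug classes
are preferentially potent in signature-high models. `rair-axis` implements
that analysis chain as a tested, reusable library with a synthetic-data layer
that plants known structure at every stage, so each statistical step can be
verified against ground truth without downloading any cohort.

The pipeline stages, in order:

1. **Differential expression** — per-gene two-group fits on log2-scale
   expression with empirical-Bayes variance shrinkage. The moderated
   statistic is `t_g = lfc_g / sqrt(s2_post_g (1/n1 + 1/n2))` with
   `s2_post = (d0 s0^2 + d s_g^2) / (d0 + d)`, where the prior `(d0, s0^2)`
   is moment-matched on the log residual variances. Modules are the genes
   passing `p < 1e-2` and `|log2FC| > 0.5` (strict), unioned across
   replicate cohorts with an optional recurrence filter.
2. **Enrichment** — preranked weighted Kolmogorov–Smirnov enrichment scores
   with a gene-set resampling null (NES, permutation p, BH), plus two
   single-sample pathway scorers: mean member z-score and a rank-based
   ssGSEA-style score.
3. **Signature scoring and stratification** — per-sample mean z-score over
   the up-module; tumour cohorts split into tertiles (extremes absorb
   remainders, so n=572 gives 191/190/191), cell panels dichotomised at the
   median score.
4. **Differential drug sensitivity** — per-drug
   `deltaAUC = mean AUC(high) − mean AUC(low)` with a two-sided Wilcoxon
   rank-sum test (exact by enumeration for combined n ≤ 12 without ties);
   keyword-based targeted-class annotation; class-level means with 95%
   t-intervals.
5. **Multimodal ridge regression** — AUC of a (cell, drug) pair modelled
   from 16 expression principal components, the signature score, and one-hot
   drug identity; `min_b ||y − Xb||^2 + lambda ||b||^2` with an unpenalised
   intercept, 5-fold cross-validation with per-fold standardisation, scored
   by RMSE, Pearson r and R² = 1 − SSE/SST on out-of-fold predictions.
6. **Sensitivity network** — module → pathway → drug-class → cell-model
   graph, with edges gated by enrichment q-values and class-level deltaAUC
   confidence intervals.

## Worked example

```python
import numpy as np
from rair_axis import (CohortSpec, generate_cohort, moderated_t, call_de,
                       zscore_genes, score_signature, tertile_stratify)

spec = CohortSpec(n_genes=2000, n_per_group=(20, 20),
                  planted_up=frozenset(range(50)),
                  planted_down=frozenset(range(50, 100)),
                  effect_size=2.0, noise_sd=0.3, seed=1)
cohort, truth = generate_cohort(spec)

de = moderated_t(cohort)
up, down = call_de(de, p_thresh=1e-2, lfc_thresh=0.5)
print(f"DE calls: {len(up)} up, {len(down)} down (prior df d0={de.d0:.1f})")

scores = score_signature(zscore_genes(cohort), up, name="RAIR_up")
strata = tertile_stratify(scores)
print("stratum sizes:", strata.sizes())
print(scores.scores.groupby(strata.assignments).mean().round(3))
```

prints

```
DE calls: 50 up, 50 down (prior df d0=4899.6)
stratum sizes: {'low': 14, 'high': 14, 'mid': 12}
stratum
high    0.965
low    -0.967
mid     0.002
Name: RAIR_up, dtype: float64
```

The 100 planted genes (50 up, 50 down) are recovered exactly at the stated
thresholds with no false calls among the 1900 null genes; the signature
score then orders the 40 tumours so that the tertile means step up from
−0.97 through 0.00 to +0.97 — the case samples concentrate in the high
stratum because the planted up-module is what the score averages.

The same chain runs end to end from the shell:

```sh
rair-axis run-all --seed 1 --out run/
```

which writes every stage's tables (expression, DE results, modules as GMT,
enrichment, scores, strata, per-drug deltaAUC, class summaries, model
metrics, network node/edge TSVs) plus a manifest with content hashes. On
the default synthetic screen the class summary recovers the planted
class-level differential sensitivities (RAF/BRAF the most negative), the
multimodal model beats the drug-only baseline (r 0.960 vs 0.948), and the
network retains exactly the planted sensitive classes.

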