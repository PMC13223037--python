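# Methods

This note documents the statistical procedures, the synthetic-data model the
package is verified against, the numerical conventions, and the design
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Expression conventions

All expression analysis happens on the log scale: RNA-seq style inputs as
`log2(x+1)` (`log2_tpm1`), external cohorts optionally as `ln(x+1)`
(`log1p`). Count matrices are only consumed by the adaptive low-expression
filter, which keeps a gene when its counts-per-million reach an adaptive
threshold in at least `k` samples, `k` being the smallest group size. The
threshold is `min_count / (median library size / 10^6)` with `min_count=10`,
rounded to two significant figures. This re-implements the cited filtering
tool's documented default logic rather than calling it; exact edge-case
parity with that tool is not a goal.

Gene-wise z-scores use the sample standard deviation (denominator n−1).
Zero-variance genes become all-zero rows and are *flagged, not dropped*, so
module gene lists keep stable membership while scorers skip the degenerate
members. Feature standardisation in the modelling module deliberately uses
the population convention (denominator N) instead — the two contexts are
kept explicit because the modelling step reuses its μ/σ on held-out rows.
Z-scores are computed once over all samples; stratification happens
afterwards on the resulting scores.

## Moderated differential expression

Per gene, an ordinary two-group fit yields the log2 fold change (case minus
control) and the pooled residual variance `s_g^2` on `d = n1 + n2 − 2`
degrees of freedom. The empirical-Bayes prior is a scaled inverse-chi-square
`(d0, s0^2)` fitted by moment matching on
`e_g = log s_g^2 − digamma(d/2) + log(d/2)`: the excess of `var(e)` over
`trigamma(d/2)` identifies `d0` through trigamma inversion (bisection,
tolerance 1e−8), and `mean(e)` identifies `s0^2`. Posterior variances
`s2_post = (d0 s0^2 + d s_g^2)/(d0 + d)` give the moderated t with `d0 + d`
degrees of freedom. Two limits are exercised by tests: maximally dispersed
variances drive `d0 → 0` and the statistic reduces to the ordinary pooled t;
under-dispersed variances drive `d0 → ∞` (capped at 1e8) and all genes share
`s0^2`. All-constant genes are flagged with `t=0, p=1`. No precision
weights are applied: the synthetic inputs are homoskedastic on the log
scale, and this is a documented simplification of the pipeline.

Module membership uses *nominal* p (`p < 1e-2`) with `|log2FC| > 0.5`, both
strict; BH-adjusted p values are reported alongside for reference. Modules
from replicate cohorts are combined by union (`min_support=1`, maximally
sensitive); the `min_support` knob exposes recurrence filtering for
down-weighting cohort-private genes. The Benjamini–Hochberg step-up is
implemented directly (six lines) so that tests can require exact agreement
with an enumeration oracle without floating-point association differences.

## Enrichment

The preranked enrichment score is the classic weighted KS running statistic:
genes sorted by decreasing score (ties broken by gene ID), in-set genes
increment by `|score|^p` normalised over in-set genes (p=1 by default;
all-zero in-set scores fall back to equal weights), out-of-set genes
decrement by `1/(N−|S|)`; the ES is the signed maximum deviation. The null
resamples random same-size gene sets on the fixed ranking — set resampling,
not phenotype permutation, because the pipeline consumes preranked
statistics. `NES = ES / mean(|null ES| of the same sign)` and
`p = (1 + #{same-sign nulls at least as extreme})/(1 + #same-sign)`; if no
null shares the sign, p is floored at `1/(1+n_perm)` and flagged. The
vectorised null evaluates candidate extrema only at hit positions, which is
exact because the running sum is piecewise linear between hits.

Sample-level pathway activity comes in two flavours: the mean member
z-score (transparent, used for the primary cohort/panel correlation
analyses) and an ssGSEA-style rank score (weighted in-set ECDF minus uniform
out-of-set ECDF, rank weights `rank^alpha` with alpha=0.25, no cross-sample
rescaling by default, ties broken by gene ID). Both scorers are provided
because transfer analyses may use either backend; choosing between them is
configuration, not inference.

Correlation transfer profiles report the Pearson r of the signature against
each pathway score in a primary context and a transfer context, with
`delta_r = r_transfer − r_primary` and BH adjustment per context.
Zero-variance vectors yield NaN and are excluded from the adjustment.

## Signature scores and stratification

A signature score is the arithmetic mean of z-scores over the module genes
present and non-degenerate; gene order and absent genes are irrelevant.
Tertile stratification sorts ascending (ties by sample ID) and assigns the
bottom and top `ceil(n/3)` samples to low/high with the remainder mid — the
extremes absorb remainders. This convention is normative here because it is
the one that yields 191/190/191 at n=572. Median dichotomisation sends
scores strictly above the median to high and everything else (including
exact-median scores) to low — conservative toward calling models
signature-high. Signed AUC is the rank-based two-sample statistic
`U/(n1·n2)` with midrank ties, oriented so values above 0.5 mean the case
class scores higher; it is invariant under strictly monotone transforms.
Signature benchmarking scores every competing gene set with the identical
mean-z scorer so differences reflect gene content only.

## Differential drug sensitivity

`deltaAUC(drug) = mean AUC over signature-high cells − mean over low cells`;
negative values mean preferential potency in high models (lower
area-under-viability-curve = stronger inhibition). The Wilcoxon rank-sum
test is exact (full enumeration, via the exact distribution) when the
combined sample is ≤ 12 without ties — feasible for small cell panels — and
otherwise uses the normal approximation with tie and continuity
corrections. Per-drug p values are reported nominally; BH is available as
an option. Class summaries are unweighted means of member deltaAUCs with a
95% t-interval on `n_drugs − 1` degrees of freedom; singleton classes carry
an undefined, flagged interval. The t-interval is a documented choice — the
interval construction for class bars is otherwise unconstrained.

Targeted-class annotation matches canonical kinase/receptor keywords
case-insensitively on word boundaries over the mechanism+target text, with
priority order RAF/BRAF > VEGFR/KDR > FGFR > RET > mTOR > other kinases when
several families match; numbered receptor names (VEGFR2, FGFR1, …) are
spelled out because word-boundary matching will not find a prefix inside
them. No match gives "Other/unspecified".

## Multimodal model

Pair features concatenate cell-level and drug-level blocks. Cell features
are the leading 16 principal components of the log-scale panel
(gene-centred, cells as observations; capped at n_cells − 1) plus the
signature score; drug features are one-hot indicators over the vocabulary of
the *full* response table. PCA is fitted once on the full panel before
cross-validation: the cell representation is unsupervised and shared across
pairs, mirroring how panel-wide expression embeddings are constructed in
practice. This is a known, deliberate leakage channel at the cell-feature
level; per-fold standardisation of all columns (training-fold μ/σ applied
to the test fold) guards the supervised path.

Ridge coefficients solve `(X'X + λI)β = X'y` on centred data with the
intercept unpenalised; λ is fixed at 1.0 by default (exposed in
configuration). Five-fold cross-validation shuffles pairs once under a seed
(default 42), concatenates out-of-fold predictions, and reports RMSE,
Pearson r, and two R² flavours: `1 − SSE/SST` (normative — it decomposes, so
the ΔR² signature benchmark is well defined) and squared Pearson (reported
alongside). `delta_r2` requires identical fold assignments so the
comparison isolates the feature contribution.

## Sensitivity network

Nodes are typed (module, pathway, drug_class, cell_model) and edges only run
module→pathway→class→cell. Defaults: pathways enter at BH q < 0.05 with
weight |NES|; classes enter when their mean deltaAUC is below the threshold
with a defined confidence interval excluding zero, with weight
|mean deltaAUC|; class→cell edges connect to signature-high cells only,
weighted by the cell's AUC deficit relative to the panel mean for that class
(positive = more sensitive than average) — the deficit-from-panel-mean
convention is this package's definition. When model predictions are
supplied, the same deficit is recomputed from predicted AUCs and stored on
the edge. The "Other/unspecified" class is excluded from the network's
class layer: the graph is about targeted classes. The pipeline's default
class threshold is −0.05 AUC — a practical effect-size floor under which a
class shift is not considered actionable — so weak shifts (on the order of
−0.03) are summarised in the class table but do not become network nodes.
Edge counts are monotone non-increasing as any threshold tightens, and
construction is a pure function of its input tables.

## Synthetic-data model

The generators define the conditions under which every stage is verified.

* **Cohorts** — gene-wise baselines uniform on [4, 10] log2 units, i.i.d.
  Gaussian noise (default sd 0.5; the pipeline's discovery cohort uses
  sd 0.3 with effect size 2.0 and 20 samples per group, the calibration at
  which planted-module recovery is asserted), planted up/down genes shifted
  by ±effect_size in the case group. Replicate cohorts share a planted core
  plus cohort-private genes, emulating several independent case/control
  studies on different platforms.
* **Cell panels** — same background; each cell's planted-up genes are
  shifted by `engagement_i × effect_size` with engagement in [0, 1]
  (evenly spaced by default), so the signature score rank-orders cells by
  construction.
* **Screens** — `AUC = potency(drug) + offset(cell) +
  interaction(class) × engagement(cell) + noise`, clipped to [0, 1.2]
  (a PRISM-like dynamic range). The default screen is a scaled-down
  thyroid panel: 18 cells × 150 drugs with class sizes RAF/BRAF 12,
  VEGFR/KDR 15, FGFR 6, RET 5, mTOR 18 and the remainder unspecified, and
  planted class interactions −0.193 / −0.096 / −0.029 — the class-mean
  differential sensitivities reported for the real screen — so the
  deltaAUC stage has realistic targets to recover. Measurement noise and
  per-cell offsets default to sd 0.05. With binary (0/1) engagement the
  planted interaction *is* the recoverable class-mean deltaAUC; with
  continuous engagement it is attenuated by the high/low engagement gap —
  the recovery analyses therefore use binary engagement, and per-cell
  offsets are set small (0 or 0.02) there because an offset shared by all
  drugs shifts every deltaAUC jointly and is not part of the planted
  effect being recovered.
* **Counts** — a negative-binomial generator (gamma–Poisson, dispersion
  0.1) exists solely to exercise the count filter; downstream stages
  consume log-scale data directly, bypassing a count model.
* **Gene-set collections** — Hallmark-like synthetic collections with a few
  sets drawing 60% of members from the planted module (positive controls)
  and the rest uniform random (negative controls).

One config-level integer seed fans out to per-generator child seeds by fixed
offsets, so stages are reproducible in isolation without coupling.

What the generators do *not* emulate: batch and platform effects, count
overdispersion structure beyond the filter exercise, gene–gene correlation,
mutation/copy-number features, dose–response curve shape (AUC is generated
directly), and any microenvironment signal. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under clean planted structure, not robustness to those real-data artefacts.

## Numerical choices and degenerate inputs

* Ranking ties (enrichment, ssGSEA, stratification) break deterministically
  by gene/sample ID.
* The ES extremum tie (max deviation equal in both signs) resolves to the
  positive side.
* Trigamma inversion: bisection on (0, ∞), relative tolerance 1e−8; prior
  df capped at 1e8.
* Zero-variance columns in standardisation are left at zero and flagged;
  zero-variance genes in z-scoring are flagged and excluded by scorers.
* All-tied Wilcoxon inputs return p = 1 directly.
* Degenerate gene sets (empty, disjoint from the ranking, or covering it
  entirely) raise immediately rather than returning sentinel scores.

## Problem sizes

The verification suite runs at deliberately modest sizes: 2000-gene
cohorts, 18-cell panels, 40–150-drug screens, 1000-permutation nulls, and
100-seed repetition for recovery claims. These sizes were chosen so the
planted effects sit well inside detectable ranges while the whole suite
remains quick to run; the statistical machinery itself is size-agnostic.

## Known limitations

* The moderated-t implementation targets the two-group design only; no
  covariates, paired designs, or precision weights.
* Permutation enrichment resamples gene sets, so correlated gene sets share
  a null that ignores inter-gene correlation.
* The ridge model is linear with a fixed penalty; no hyperparameter search,
  fingerprint features, or nonlinear interactions.
* Class annotation is keyword-based and inherits the vocabulary's blind
  spots; annotation text absent from the keyword families lands in
  "Other/unspecified".
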