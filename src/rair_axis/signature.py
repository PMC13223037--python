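"""Single-sample signature scoring, stratification and benchmarking.

A signature score is the arithmetic mean of gene-wise z-scores over a
module's member genes, per sample — a transparent aggregate that emphasises
coherent up-regulation of the module.  Tumour cohorts are stratified into
score tertiles (low/mid/high); cell panels are dichotomised at the median
score (low/high).  Signed AUC measures how well a score discriminates a
binary phenotype, oriented so values above 0.5 mean the case class scores
higher.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .diffexpr import GeneModule
from .preprocess import ExpressionMatrix

logger = logging.getLogger("rair_axis")


@dataclass
class SignatureScores:
    """Per-sample module score (mean of member z-scores)."""

    scores: pd.Series            # sample_id -> score
    module_name: str
    n_genes_used: int


@dataclass
class StratumAssignment:
    """Sample -> stratum labels, monotone in the underlying score."""

    assignments: pd.Series       # sample_id -> stratum label
    boundaries: dict[str, float]
    scheme: str                  # "tertile" or "median"

    def samples(self, stratum: str) -> list[str]:
        return list(self.assignments.index[self.assignments == stratum])

    def sizes(self) -> dict[str, int]:
        return self.assignments.value_counts().to_dict()


def score_signature(m: ExpressionMatrix, module: GeneModule | Iterable[str],
                    name: str | None = None) -> SignatureScores:
    """Mean z-score over the module genes present and non-degenerate.

    Gene order within the module is irrelevant and absent genes are ignored
    (with a warning), so the same module can be applied unchanged across
    cohorts profiled on different platforms.
    """
    if m.scale != "zscore":
        raise ValueError(f"score_signature requires z-scored data, got {m.scale!r}")
    if isinstance(module, GeneModule):
        genes = module.genes
        name = name or module.name
    else:
        genes = frozenset(module)
        name = name or "signature"
    usable = sorted((genes & set(m.gene_ids)) - set(m.zero_variance))
    dropped = len(genes) - len(usable)
    if dropped:
        logger.warning("score_signature[%s]: %d of %d genes absent or degenerate",
                       name, dropped, len(genes))
    if not usable:
        raise ValueError(f"no usable module genes present for {name!r}")
    scores = m.values.loc[usable].mean(axis=0)
    return SignatureScores(scores=scores.rename(name), module_name=name,
                           n_genes_used=len(usable))


def tertile_stratify(scores: pd.Series | SignatureScores) -> StratumAssignment:
    """Partition samples into score tertiles: low / mid / high.

    Sorted ascending (ties broken by sample ID), the bottom ``ceil(n/3)``
    samples are low and the top ``ceil(n/3)`` are high, with the remainder
    mid — the extreme strata absorb remainders, so e.g. n=572 splits
    191/190/191.
    """
    s = scores.scores if isinstance(scores, SignatureScores) else scores
    n = len(s)
    if n < 3:
        raise ValueError("tertile stratification needs >= 3 samples")
    order = s.rename("score").rename_axis("sample").reset_index() \
             .sort_values(["score", "sample"])
    k = math.ceil(n / 3)
    labels = np.array(["mid"] * n, dtype=object)
    labels[:k] = "low"
    labels[n - k:] = "high"
    assign = pd.Series(labels, index=order["sample"].to_numpy(), name="stratum")
    ordered_scores = order["score"].to_numpy()
    boundaries = {"low_upper": float(ordered_scores[k - 1]),
                  "high_lower": float(ordered_scores[n - k])}
    return StratumAssignment(assignments=assign.loc[s.index], boundaries=boundaries,
                             scheme="tertile")


def median_split(scores: pd.Series | SignatureScores) -> StratumAssignment:
    """Dichotomise at the median score: above -> high, at or below -> low.

    Assigning exact-median scores to the low stratum is the documented
    convention (conservative toward calling models signature-high); for even
    n with distinct scores this yields equal halves.
    """
    s = scores.scores if isinstance(scores, SignatureScores) else scores
    if len(s) < 2:
        raise ValueError("median split needs >= 2 samples")
    med = float(s.median())
    if (s == s.iloc[0]).all():
        raise ValueError("all scores identical: no median split exists")
    labels = np.where(s.to_numpy(dtype=float) > med, "high", "low")
    assign = pd.Series(labels, index=s.index, name="stratum")
    return StratumAssignment(assignments=assign, boundaries={"median": med},
                             scheme="median")


def signed_auc(scores: pd.Series, labels: pd.Series, case_label) -> float:
    """Rank-based two-sample AUC, ties counted half; equals U/(n1*n2).

    Values above 0.5 mean the ``case_label`` class tends to score higher; the
    statistic is invariant under any strictly monotone transform of the
    scores.
    """
    common = scores.index.intersection(labels.index)
    s = scores.loc[common].to_numpy(dtype=float)
    is_case = (labels.loc[common] == case_label).to_numpy()
    n1 = int(is_case.sum())
    n0 = int((~is_case).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both label classes must be present")
    ranks = rankdata(s)                      # midranks handle ties
    u = ranks[is_case].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class BenchmarkRecord:
    """How one signature performs across discrimination and transfer tasks."""

    signature_name: str
    signed_auc: float
    delta_r2: float | None = None                  # CV R^2 gain over a baseline
    class_shifts: dict[str, float] | None = None   # class -> delta-AUC shift


def benchmark_signatures(m: ExpressionMatrix, modules: dict[str, Iterable[str]],
                         labels: pd.Series, case_label) -> pd.DataFrame:
    """Score competing signatures with the identical mean-z scorer and report
    each one's signed AUC for the case/control contrast.

    Using one scorer for all signatures means differences reflect gene
    content only.
    """
    rows = []
    for name, genes in modules.items():
        sc = score_signature(m, genes, name=name)
        rows.append({"signature": name,
                     "signed_auc": signed_auc(sc.scores, labels, case_label),
                     "n_genes_used": sc.n_genes_used})
    return pd.DataFrame(rows).set_index("signature")
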