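"""Two-group moderated differential expression and module derivation.

Per gene, an ordinary two-group linear model is fitted on log-scale
expression and the residual variances are shrunk toward a pooled prior by
empirical Bayes: the prior degrees of freedom ``d0`` and prior variance
``s0^2`` are estimated by moment matching on the log residual variances
(digamma/trigamma inversion by bisection), the posterior variance is

    s2_post = (d0 * s0^2 + d * s2) / (d0 + d),      d = n1 + n2 - 2,

and the moderated t statistic is ``log2fc / sqrt(s2_post * (1/n1 + 1/n2))``
with ``d0 + d`` degrees of freedom.  As variances disperse maximally,
``d0 -> 0`` and the moderated t reduces to the ordinary pooled t; as group
sizes grow the shrinkage vanishes.

Differentially expressed genes are called at strict nominal thresholds
(default p < 1e-2 and |log2FC| > 0.5), and up/down modules across replicate
cohorts are formed as a support-filtered union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from .preprocess import ExpressionMatrix, LOG_SCALES

logger = logging.getLogger("rair_axis")

#: Cap on prior degrees of freedom; beyond this shrinkage is effectively total.
_D0_MAX = 1e8


@dataclass
class DEResult:
    """Per-gene moderated DE table plus the shared shrinkage hyperparameters."""

    table: pd.DataFrame        # gene_id index; log2fc, t_mod, p, p_adj, s2, s2_post, flagged
    d0: float                  # prior degrees of freedom (>= 0)
    s0_sq: float               # prior variance
    n_per_group: tuple[int, int]
    contrast: str = "case-control"


def _trigamma_inv(y: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection.

    trigamma is strictly decreasing on (0, inf) with range (0, inf).
    """
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    lo, hi = 1e-12, 1.0
    while special.polygamma(1, hi) > y:
        hi *= 2.0
        if hi > 1e12:
            return hi
    while special.polygamma(1, lo) < y:
        lo /= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, lo):
            break
    return 0.5 * (lo + hi)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to residual variances.

    Works on ``e = log(s2) - digamma(df/2) + log(df/2)`` whose mean and excess
    variance over ``trigamma(df/2)`` identify ``(d0, s0^2)``.  Returns
    ``d0 = inf`` (capped) when the variances are underdispersed relative to
    chi-square sampling noise, and ``d0 = 0`` when the inversion diverges.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return 0.0, float(s2.mean()) if s2.size else 1.0
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    excess = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        # variances more concentrated than sampling noise alone: total shrinkage
        return _D0_MAX, float(np.exp(e_mean))
    x = _trigamma_inv(excess)       # x = d0 / 2
    d0 = 2.0 * x
    if d0 >= _D0_MAX:
        return _D0_MAX, float(np.exp(e_mean))
    s0_sq = float(np.exp(e_mean + special.digamma(x) - np.log(x)))
    return d0, s0_sq


def moderated_t(m: ExpressionMatrix, group_order: tuple[str, str] | None = None
                ) -> DEResult:
    """Empirical-Bayes moderated two-group DE on a log-scale matrix.

    The contrast is group2 minus group1 (case minus control); by default the
    groups are taken in order of first appearance in the sample labels, or
    pass ``group_order=(control, case)`` explicitly.
    """
    if m.scale not in LOG_SCALES:
        raise ValueError(f"moderated_t requires log-scale data, got {m.scale!r}")
    groups = m.group_columns()
    if group_order is None:
        labels = list(groups)
    else:
        labels = list(group_order)
    if len(labels) != 2 or any(g not in groups for g in labels):
        raise ValueError(f"need exactly two groups from {list(groups)}")
    g1, g2 = labels
    x1 = m.values[groups[g1]].to_numpy(dtype=float)
    x2 = m.values[groups[g2]].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need >= 2 samples, got {n1}/{n2}")
    df = n1 + n2 - 2
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    lfc = m2 - m1
    rss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = rss / df
    flagged = s2 == 0.0

    d0, s0_sq = estimate_prior(s2, df)
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, lfc / se, 0.0)
    df_total = min(d0 + df, _D0_MAX)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    # all-constant genes carry no evidence
    t_mod[flagged] = 0.0
    p[flagged] = 1.0
    table = pd.DataFrame({
        "log2fc": lfc, "t_mod": t_mod, "p": p,
        "p_adj": bh_adjust(p), "s2": s2, "s2_post": s2_post,
        "flagged": flagged,
    }, index=m.gene_ids)
    logger.info("moderated_t: %d genes, d0=%.3g, s0^2=%.3g (%s vs %s)",
                m.n_genes, d0, s0_sq, g2, g1)
    return DEResult(table=table, d0=d0, s0_sq=s0_sq, n_per_group=(n1, n2),
                    contrast=f"{g2}-{g1}")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_de(result: DEResult | pd.DataFrame, p_thresh: float = 1e-2,
            lfc_thresh: float = 0.5) -> tuple[frozenset[str], frozenset[str]]:
    """Strict-threshold DE calls: returns (up, down) gene-ID sets.

    Nominal p is thresholded (adjusted p is reported alongside for
    reference); inequalities are strict, so a gene sitting exactly on a
    threshold is excluded.
    """
    if p_thresh <= 0 or lfc_thresh <= 0:
        raise ValueError("thresholds must be positive")
    table = result.table if isinstance(result, DEResult) else result
    sig = table["p"] < p_thresh
    up = frozenset(table.index[sig & (table["log2fc"] > lfc_thresh)])
    down = frozenset(table.index[sig & (table["log2fc"] < -lfc_thresh)])
    return up, down


@dataclass
class GeneModule:
    """Named, directed gene list with per-gene cohort provenance."""

    name: str
    direction: str                       # "up" or "down"
    genes: frozenset[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if not self.genes:
            raise ValueError(f"module {self.name!r} is empty")

    def support(self, gene: str) -> int:
        return len(self.provenance.get(gene, []))


def union_modules(per_cohort: Mapping[str, frozenset[str] | set[str]],
                  name: str, direction: str, min_support: int = 1) -> GeneModule:
    """Union of per-cohort DE sets, optionally requiring recurrent support.

    ``min_support=1`` (default) is the plain union — maximally sensitive to
    genes altered in at least one cohort; higher values drop genes seen in
    fewer than ``min_support`` cohorts, suppressing cohort-private noise.
    """
    if not per_cohort:
        raise ValueError("need at least one cohort")
    provenance: dict[str, list[str]] = {}
    for cohort, genes in per_cohort.items():
        for g in genes:
            provenance.setdefault(g, []).append(cohort)
    kept = frozenset(g for g, cohorts in provenance.items()
                     if len(cohorts) >= min_support)
    if not kept:
        raise ValueError(f"module {name!r} empty at min_support={min_support}")
    return GeneModule(name=name, direction=direction, genes=kept,
                      provenance={g: provenance[g] for g in kept})


def write_de_tsv(result: DEResult, path) -> None:
    cols = ["log2fc", "t_mod", "p", "p_adj"]
    result.table[cols].to_csv(path, sep="\t", index_label="gene_id")
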