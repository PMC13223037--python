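"""Per-drug differential sensitivity (delta-AUC) and class-level summaries.

The screen's AUC is the area under the dose-response viability curve; lower
AUC means stronger growth inhibition.  For each drug, delta-AUC is the mean
AUC across signature-high cell lines minus the mean across signature-low
lines — negative values mean preferential potency in the high group — with a
two-sided Wilcoxon rank-sum test on the two AUC samples (exact enumeration
when the combined n is small and tie-free, normal approximation with tie and
continuity corrections otherwise).

Drugs are annotated as targeted-like by case-insensitive word-boundary
keyword matching over their mechanism/target text, with a fixed priority
order deciding the class when several keyword families match.  Class-level
summaries average member-drug delta-AUCs with a t-distribution 95%
confidence interval.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .signature import StratumAssignment

logger = logging.getLogger("rair_axis")

#: Combined sample size at or below which the Wilcoxon test is exact
#: (feasible for small cell-line panels).
EXACT_WILCOXON_MAX_N = 12

#: Keyword families in priority order: the first matching family wins.
#: Numbered receptor variants are spelled out because word-boundary matching
#: will not find "VEGFR" inside "VEGFR2".
DEFAULT_CLASS_KEYWORDS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("RAF/BRAF", ("BRAF", "RAF", "ARAF", "RAF1", "CRAF")),
    ("VEGFR/KDR", ("VEGFR", "VEGFR1", "VEGFR2", "VEGFR3", "KDR", "VEGF",
                   "FLT1", "FLT4")),
    ("FGFR", ("FGFR", "FGFR1", "FGFR2", "FGFR3", "FGFR4")),
    ("RET", ("RET",)),
    ("mTOR", ("MTOR",)),
    ("Other kinase", ("EGFR", "MET", "PI3K", "PIK3CA", "AKT", "SRC", "ABL",
                      "PDGFR", "PDGFRA", "PDGFRB", "KIT", "ALK", "JAK",
                      "JAK1", "JAK2", "CDK")),
)

UNSPECIFIED_CLASS = "Other/unspecified"


def annotate_targeted(annotations: pd.DataFrame,
                      keywords=DEFAULT_CLASS_KEYWORDS) -> pd.DataFrame:
    """Flag targeted-like drugs and assign a mechanism class.

    ``annotations`` needs columns ``drug_id``, ``moa`` and ``target`` (free
    text, may be empty/NaN).  Matching is case-insensitive on word
    boundaries over the concatenated text; no match gives class
    ``Other/unspecified`` and ``targeted_like=False``.
    """
    patterns = [(cls, re.compile(r"\b(?:" + "|".join(map(re.escape, kws)) + r")\b",
                                 re.IGNORECASE))
                for cls, kws in keywords]
    out = annotations.copy()
    classes, targeted = [], []
    for _, row in annotations.iterrows():
        text = " ".join(str(row.get(c, "")) for c in ("moa", "target")
                        if pd.notna(row.get(c, "")))
        hit = next((cls for cls, pat in patterns if pat.search(text)), None)
        classes.append(hit or UNSPECIFIED_CLASS)
        targeted.append(hit is not None)
    out["drug_class"] = classes
    out["targeted_like"] = targeted
    return out


def _wilcoxon_p(high: np.ndarray, low: np.ndarray) -> float:
    """Two-sided rank-sum p: exact for small tie-free samples, else normal
    approximation with tie and continuity corrections."""
    combined = np.concatenate([high, low])
    if np.all(combined == combined[0]):
        return 1.0
    tie_free = len(np.unique(combined)) == len(combined)
    if len(combined) <= EXACT_WILCOXON_MAX_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(high, low, alternative="two-sided",
                             method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


@dataclass
class DeltaAUCRecord:
    """Differential sensitivity of one drug between strata."""

    drug_id: str
    mean_high: float
    mean_low: float
    delta_auc: float
    p_wilcoxon: float
    n_high: int
    n_low: int


def delta_auc(table: pd.DataFrame, assignment: StratumAssignment,
              adjust: bool = False) -> pd.DataFrame:
    """Per-drug delta-AUC (mean high minus mean low) with Wilcoxon p.

    ``table`` is long-format with columns ``cell_id, drug_id, auc``.  Drugs
    lacking measurements in either stratum are excluded with a warning.  No
    multiple-testing adjustment is applied by default (nominal per-drug p);
    set ``adjust=True`` to append BH-adjusted values.
    """
    required = {"cell_id", "drug_id", "auc"}
    if not required <= set(table.columns):
        raise ValueError(f"response table needs columns {sorted(required)}")
    if table.duplicated(["cell_id", "drug_id"]).any():
        raise ValueError("duplicate (cell, drug) pairs in response table")
    high = set(assignment.samples("high"))
    low = set(assignment.samples("low"))
    if not high or not low:
        raise ValueError("assignment must contain both high and low strata")
    rows = []
    skipped = []
    for drug, sub in table.groupby("drug_id", sort=True):
        a_high = sub.loc[sub["cell_id"].isin(high), "auc"].to_numpy(dtype=float)
        a_low = sub.loc[sub["cell_id"].isin(low), "auc"].to_numpy(dtype=float)
        if a_high.size == 0 or a_low.size == 0:
            skipped.append(drug)
            continue
        mh, ml = float(a_high.mean()), float(a_low.mean())
        rows.append({"drug_id": drug, "mean_high": mh, "mean_low": ml,
                     "delta_auc": mh - ml,
                     "p_wilcoxon": _wilcoxon_p(a_high, a_low),
                     "n_high": a_high.size, "n_low": a_low.size})
    if skipped:
        logger.warning("delta_auc: %d drug(s) lacked both strata, skipped: %s",
                       len(skipped), skipped[:5])
    if not rows:
        raise ValueError("no drug had measurements in both strata")
    df = pd.DataFrame(rows).set_index("drug_id")
    if adjust:
        df["p_adj"] = bh_adjust(df["p_wilcoxon"].to_numpy())
    return df


@dataclass
class ClassSummary:
    """Mean delta-AUC of a drug class with a 95% t-interval."""

    drug_class: str
    mean_delta: float
    ci_low: float
    ci_high: float
    n_drugs: int
    ci_defined: bool


def class_summary(records: pd.DataFrame, classes: pd.Series,
                  conf: float = 0.95) -> pd.DataFrame:
    """Aggregate per-drug delta-AUCs to class level.

    ``classes`` maps drug_id -> class label.  The summary is the unweighted
    mean of member delta-AUCs with a ``conf`` t-interval (n_drugs - 1 df);
    singleton classes get an undefined interval (NaN, flagged).
    """
    joined = records.join(classes.rename("drug_class"), how="inner")
    if joined.empty:
        raise ValueError("no overlap between records and class labels")
    rows = []
    for cls, sub in joined.groupby("drug_class", sort=True):
        d = sub["delta_auc"].to_numpy(dtype=float)
        n = d.size
        mean = float(d.mean())
        if n >= 2:
            half = stats.t.ppf(0.5 + conf / 2.0, n - 1) * d.std(ddof=1) / np.sqrt(n)
            lo, hi, defined = mean - half, mean + half, True
        else:
            lo = hi = np.nan
            defined = False
        rows.append({"drug_class": cls, "mean_delta": mean, "ci_low": lo,
                     "ci_high": hi, "n_drugs": n, "ci_defined": defined})
    return pd.DataFrame(rows).set_index("drug_class")


def read_response_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"cell_id", "drug_id", "auc"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_response_csv(table: pd.DataFrame, path) -> None:
    table[["cell_id", "drug_id", "auc"]].to_csv(path, index=False)
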