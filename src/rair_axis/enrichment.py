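"""Preranked gene-set enrichment, single-sample pathway scores, correlations.

The enrichment score (ES) is the classic weighted Kolmogorov-Smirnov running
statistic on a ranked gene list: walking down the ranking, in-set genes
increment the running sum proportionally to ``|score|^p`` (normalised over
in-set genes) and out-of-set genes decrement it by ``1/(N - |S|)``; the ES is
the signed maximum deviation from zero.  Significance uses a gene-set
resampling null (random same-size sets on the fixed ranking), with the
normalised ES defined as the ES divided by the mean |null ES| of matching
sign.

Sample-level pathway activity comes in two flavours: the transparent mean of
member-gene z-scores, and a rank-based single-sample score (ssGSEA-style
weighted ECDF difference, exponent alpha).

Correlation profiling relates a signature score to each pathway score in a
primary context (tumour cohort) and a transfer context (cell panel), with
``delta_r = r_transfer - r_primary`` summarising how well each association
survives the transfer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .preprocess import ExpressionMatrix, LOG_SCALES

logger = logging.getLogger("rair_axis")


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. Hallmark-style pathways)."""

    sets: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path, source: str | None = None) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, genes...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets=sets, source=source or str(path))


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


# --------------------------------------------------------------------------
# Preranked ES
# --------------------------------------------------------------------------

def _order_ranking(ranked: pd.Series) -> pd.Series:
    """Descending by score, ties broken by gene ID (deterministic)."""
    if ranked.index.duplicated().any():
        raise ValueError("ranking contains duplicate gene IDs")
    df = ranked.rename("score").rename_axis("gene").reset_index()
    df = df.sort_values(["score", "gene"], ascending=[False, True])
    return pd.Series(df["score"].to_numpy(), index=df["gene"].to_numpy())


def preranked_es(ranked: pd.Series, gene_set, weight_exponent: float = 1.0
                 ) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score; returns (es, full running sum)."""
    ordered = _order_ranking(ranked)
    in_set = ordered.index.isin(set(gene_set))
    n = len(ordered)
    k = int(in_set.sum())
    if k == 0:
        raise ValueError("gene set is disjoint from the ranking")
    if k == n:
        raise ValueError("gene set covers the entire ranking")
    w = np.abs(ordered.to_numpy(dtype=float)) ** weight_exponent
    w_hit = np.where(in_set, w, 0.0)
    total = w_hit.sum()
    if total == 0:                       # all in-set scores zero: equal weights
        w_hit = in_set.astype(float)
        total = float(k)
    step = w_hit / total - (~in_set) / (n - k)
    running = np.cumsum(step)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _es_from_positions(pos: np.ndarray, weights_sorted: np.ndarray, n: int
                       ) -> np.ndarray:
    """Vectorised ES for many same-size sets given 0-based hit positions.

    ``pos`` is (n_perm, k), sorted along axis 1; ``weights_sorted`` are the
    |score|^p weights of the full ordered ranking.  Candidate extrema occur
    only immediately after each hit (running maximum) and immediately before
    each hit (running minimum), which this exploits.
    """
    n_perm, k = pos.shape
    d = 1.0 / (n - k)
    w = weights_sorted[pos]
    total = w.sum(axis=1, keepdims=True)
    zero = total[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        total[zero] = k
    cumw = np.cumsum(w, axis=1) / total
    i = np.arange(k)
    misses_before = pos - i                      # misses preceding hit i
    after = cumw - misses_before * d
    before = np.concatenate(
        [np.zeros((n_perm, 1)), cumw[:, :-1]], axis=1) - misses_before * d
    cand_max = after.max(axis=1)
    cand_min = before.min(axis=1)
    return np.where(cand_max > -cand_min, cand_max, cand_min)


@dataclass
class EnrichmentResult:
    """Permutation-based enrichment summary for one gene set."""

    set_name: str
    es: float
    nes: float
    p: float
    n_perm: int
    flagged: bool = False      # no same-sign nulls: p floored at 1/(1+n_perm)
    p_adj: float | None = None


def permutation_nes(ranked: pd.Series, gene_set, n_perm: int = 1000,
                    seed: int = 0, weight_exponent: float = 1.0,
                    set_name: str = "") -> EnrichmentResult:
    """ES with gene-set resampling null, NES and permutation p.

    The null resamples random gene sets of the same size from the ranking;
    ``nes = es / mean(|null es| of the same sign)`` and
    ``p = (1 + #{same-sign nulls at least as extreme}) / (1 + #same-sign)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ordered = _order_ranking(ranked)
    n = len(ordered)
    present = [g for g in gene_set if g in set(ordered.index)]
    k = len(present)
    if k == 0:
        raise ValueError("gene set is disjoint from the ranking")
    es, _ = preranked_es(ranked, present, weight_exponent)
    weights = np.abs(ordered.to_numpy(dtype=float)) ** weight_exponent
    rng = np.random.default_rng(seed)
    # k distinct positions per permutation
    keys = rng.random((n_perm, n))
    pos = np.sort(np.argpartition(keys, k - 1, axis=1)[:, :k], axis=1)
    null_es = _es_from_positions(pos, weights, n)
    same_sign = null_es > 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    flagged = n_same == 0
    if flagged:
        nes = np.nan
        p = 1.0 / (1.0 + n_perm)
    else:
        nes = float(es / np.abs(null_es[same_sign]).mean())
        extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
        p = (1.0 + extreme) / (1.0 + n_same)
    return EnrichmentResult(set_name=set_name, es=es, nes=nes, p=p,
                            n_perm=n_perm, flagged=flagged)


def enrich_collection(ranked: pd.Series, collection: GeneSetCollection,
                      n_perm: int = 1000, seed: int = 0,
                      weight_exponent: float = 1.0, min_size: int = 2
                      ) -> pd.DataFrame:
    """Permutation enrichment of every set, BH-adjusted across sets."""
    rng = np.random.default_rng(seed)
    rows = []
    genes = set(ranked.index)
    for name, gene_set in collection:
        present = genes & gene_set
        if len(present) < min_size or len(present) >= len(genes):
            logger.warning("enrich_collection: skipping %r (%d usable genes)",
                           name, len(present))
            continue
        res = permutation_nes(ranked, present, n_perm=n_perm,
                              seed=int(rng.integers(0, 2**31 - 1)),
                              weight_exponent=weight_exponent, set_name=name)
        rows.append({"set_name": name, "es": res.es, "nes": res.nes,
                     "p": res.p, "flagged": res.flagged})
    if not rows:
        raise ValueError("no gene set overlapped the ranking")
    df = pd.DataFrame(rows).set_index("set_name")
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


# --------------------------------------------------------------------------
# Sample-level pathway scores
# --------------------------------------------------------------------------

def meanz_pathway_scores(m: ExpressionMatrix, collection: GeneSetCollection,
                         on_missing: str = "error") -> pd.DataFrame:
    """Per-sample mean z-score over each set's member genes.

    Requires a z-scored matrix; genes flagged zero-variance are excluded,
    absent genes are dropped with a warning.  ``on_missing`` controls what
    happens when a set has no usable genes: ``"error"`` raises, ``"skip"``
    drops the set.
    """
    if m.scale != "zscore":
        raise ValueError(f"meanz_pathway_scores requires z-scored data, got {m.scale!r}")
    usable = set(m.gene_ids) - set(m.zero_variance)
    cols = {}
    for name, genes in collection:
        members = sorted(genes & usable)
        missing = len(genes) - len(members)
        if missing:
            logger.warning("meanz_pathway_scores: %r missing/degenerate %d of %d genes",
                           name, missing, len(genes))
        if not members:
            if on_missing == "skip":
                continue
            raise ValueError(f"no usable member genes for set {name!r}")
        cols[name] = m.values.loc[members].mean(axis=0)
    return pd.DataFrame(cols, index=m.sample_ids)


def ssgsea_scores(m: ExpressionMatrix, collection: GeneSetCollection,
                  alpha: float = 0.25, rescale: bool = False) -> pd.DataFrame:
    """Rank-based single-sample scores (weighted ECDF difference, exponent alpha).

    Per sample, genes are ordered by decreasing expression (ties broken by
    gene ID); the score for a set is the sum over ranking positions of the
    weighted in-set ECDF minus the uniform out-of-set ECDF, with rank weights
    ``rank^alpha`` (top gene has rank N).  Cross-sample linear rescaling is
    off by default.
    """
    if m.scale not in LOG_SCALES and m.scale != "tpm":
        raise ValueError(f"ssgsea_scores expects expression-scale data, got {m.scale!r}")
    n = m.n_genes
    if n < 2:
        raise ValueError("need at least 2 genes")
    gene_arr = m.gene_ids.to_numpy(dtype=object)
    masks = {}
    for name, genes in collection:
        mask = np.asarray(m.gene_ids.isin(genes))
        if not mask.any():
            raise ValueError(f"no member genes present for set {name!r}")
        if mask.all():
            raise ValueError(f"set {name!r} covers the entire matrix")
        masks[name] = mask
    ranks_w = (np.arange(n, 0, -1).astype(float)) ** alpha   # weight by position
    out = np.zeros((m.n_samples, len(masks)))
    vals = m.values.to_numpy(dtype=float)
    for j in range(m.n_samples):
        x = vals[:, j]
        # descending expression, ties by gene ID ascending
        order = np.lexsort((gene_arr, -x))
        for s_idx, (name, mask) in enumerate(masks.items()):
            mm = mask[order]
            w = np.where(mm, ranks_w, 0.0)
            ecdf_in = np.cumsum(w) / w.sum()
            ecdf_out = np.cumsum(~mm) / (n - mm.sum())
            out[j, s_idx] = float((ecdf_in - ecdf_out).sum())
    df = pd.DataFrame(out, index=m.sample_ids, columns=list(masks))
    if rescale:
        span = df.to_numpy().max() - df.to_numpy().min()
        if span > 0:
            df = df / span
    return df


# --------------------------------------------------------------------------
# Correlation transfer profiles
# --------------------------------------------------------------------------

def correlate_signature(sig_primary: pd.Series, pathways_primary: pd.DataFrame,
                        sig_transfer: pd.Series | None = None,
                        pathways_transfer: pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """Pearson correlation of a signature with each pathway score, per context.

    Returns one row per set with ``r_primary``/``p_primary`` (tumour-cohort
    role), optionally ``r_transfer``/``p_transfer`` (cell-panel role) and
    ``delta_r = r_transfer - r_primary``.  Zero-variance vectors give NaN and
    are excluded from the per-context BH adjustment.
    """

    def _context(sig: pd.Series, paths: pd.DataFrame) -> pd.DataFrame:
        common = sig.index.intersection(paths.index)
        if len(common) < 3:
            raise ValueError(f"need >= 3 aligned samples, got {len(common)}")
        s = sig.loc[common].to_numpy(dtype=float)
        rows = {}
        for name in paths.columns:
            v = paths.loc[common, name].to_numpy(dtype=float)
            if np.std(s) == 0 or np.std(v) == 0:
                logger.warning("correlate_signature: zero variance for %r", name)
                rows[name] = (np.nan, np.nan)
            else:
                r, p = stats.pearsonr(s, v)
                rows[name] = (float(r), float(p))
        df = pd.DataFrame(rows, index=["r", "p"]).T
        ok = df["p"].notna()
        df["p_adj"] = np.nan
        if ok.any():
            df.loc[ok, "p_adj"] = bh_adjust(df.loc[ok, "p"].to_numpy())
        return df

    prim = _context(sig_primary, pathways_primary)
    out = prim.rename(columns={"r": "r_primary", "p": "p_primary",
                               "p_adj": "p_adj_primary"})
    if sig_transfer is not None and pathways_transfer is not None:
        tran = _context(sig_transfer, pathways_transfer)
        out["r_transfer"] = tran["r"]
        out["p_transfer"] = tran["p"]
        out["p_adj_transfer"] = tran["p_adj"]
        out["delta_r"] = out["r_transfer"] - out["r_primary"]
    out.index.name = "set_name"
    return out
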