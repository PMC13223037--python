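"""Expression containers, count filtering, normalisation and z-standardisation.

Every downstream stage (differential expression, signature scoring, pathway
scoring, model features) consumes :class:`ExpressionMatrix` objects produced
here.  Conventions are fixed once:

* matrices are genes x samples,
* RNA-seq style data are analysed as ``log2(TPM + 1)`` (or ``log1p`` for
  external cohorts),
* gene-wise z-scores use the sample standard deviation (denominator n-1),
* zero-variance genes are kept as all-zero rows and flagged so that scorers
  can exclude them without destabilising module membership.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rair_axis")

#: Recognised scale tags, in the order data typically moves through them.
SCALES = ("counts", "tpm", "log2p1", "log1p", "zscore")

#: Scale tags that count as "log scale" for scorers and models.
LOG_SCALES = ("log2p1", "log1p")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a scale tag and optional groups.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns.
    scale
        One of :data:`SCALES`; records what the numbers mean.
    sample_groups
        Optional Series mapping sample ID -> group label, aligned to columns.
    zero_variance
        Gene IDs flagged as zero-variance by :func:`zscore_genes`.
    """

    values: pd.DataFrame
    scale: str
    sample_groups: pd.Series | None = None
    zero_variance: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}; expected one of {SCALES}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        if self.sample_groups is not None:
            self.sample_groups = self.sample_groups.reindex(self.values.columns)
            if self.sample_groups.isna().any():
                missing = self.sample_groups.index[self.sample_groups.isna()].tolist()
                raise ValueError(f"samples without group labels: {missing[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_columns(self) -> dict[str, list[str]]:
        """Sample IDs per group label (insertion order of first appearance)."""
        if self.sample_groups is None:
            raise ValueError("matrix has no sample group labels")
        out: dict[str, list[str]] = {}
        for sample, grp in self.sample_groups.items():
            out.setdefault(str(grp), []).append(str(sample))
        return out

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path) -> None:
        """Write as TSV with the scale tag on a leading comment line."""
        with open(path, "w") as fh:
            fh.write(f"# scale={self.scale}\n")
            self.values.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, scale: str | None = None,
                 sample_groups: pd.Series | None = None) -> "ExpressionMatrix":
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# scale="):
                tag = first.strip().split("=", 1)[1]
                df = pd.read_csv(fh, sep="\t", index_col=0)
            else:
                tag = None
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", index_col=0)
        scale = scale or tag
        if scale is None:
            raise ValueError(f"{path}: no scale tag in file and none supplied")
        return cls(values=df, scale=scale, sample_groups=sample_groups)


def write_groups_tsv(groups: pd.Series, path) -> None:
    groups.rename("group").to_csv(path, sep="\t", index_label="sample_id")


def read_groups_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


# --------------------------------------------------------------------------
# Adaptive count filter
# --------------------------------------------------------------------------

def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def cpm_threshold(library_sizes: np.ndarray, min_count: float = 10.0) -> float:
    """Adaptive CPM cutoff: ``min_count`` scaled by the median library size.

    Rounded to 2 significant figures so the cutoff is stable across nearly
    identical libraries.
    """
    median_lib = float(np.median(library_sizes))
    if median_lib <= 0:
        raise ValueError("median library size must be positive")
    return _round_sig(min_count / (median_lib / 1e6), 2)


def filter_low_expression(m: ExpressionMatrix, min_count: float = 10.0) -> ExpressionMatrix:
    """Drop lowly expressed genes from a count matrix, group-aware.

    A gene is kept when its counts-per-million reach the adaptive threshold in
    at least ``k`` samples, with ``k`` the smallest group size — so a gene
    expressed only within the smaller condition still survives.  Row order of
    retained genes is preserved.
    """
    if m.scale != "counts":
        raise ValueError(f"filter_low_expression requires counts, got {m.scale!r}")
    groups = m.group_columns()
    sizes = {g: len(cols) for g, cols in groups.items()}
    if any(s == 0 for s in sizes.values()) or not sizes:
        raise ValueError(f"empty group(s): {sizes}")
    k = min(sizes.values())
    lib = m.values.sum(axis=0).to_numpy(dtype=float)
    thresh = cpm_threshold(lib, min_count=min_count)
    cpm = m.values.to_numpy(dtype=float) / lib * 1e6
    keep = (cpm >= thresh).sum(axis=1) >= k
    logger.info("filter_low_expression: CPM threshold %.4g, kept %d/%d genes",
                thresh, int(keep.sum()), m.n_genes)
    return ExpressionMatrix(values=m.values.loc[keep], scale="counts",
                            sample_groups=m.sample_groups)


# --------------------------------------------------------------------------
# Normalisation
# --------------------------------------------------------------------------

def normalize(m: ExpressionMatrix, method: str = "log2_tpm1") -> ExpressionMatrix:
    """Elementwise ``log2(x+1)`` (``log2_tpm1``) or ``ln(x+1)`` (``log1p``)."""
    if (m.values.to_numpy() < 0).any():
        raise ValueError("normalize requires non-negative values")
    if method == "log2_tpm1":
        vals = np.log2(m.values + 1.0)
        scale = "log2p1"
    elif method == "log1p":
        vals = np.log1p(m.values)
        scale = "log1p"
    else:
        raise ValueError(f"unknown normalisation method {method!r}")
    return ExpressionMatrix(values=vals, scale=scale, sample_groups=m.sample_groups)


def zscore_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardise each gene across samples (mean 0, sd 1 with ddof=1).

    Zero-variance genes become all-zero rows and are flagged in
    ``zero_variance`` rather than dropped, so module gene lists keep stable
    membership while scorers can still skip them.
    """
    if m.n_samples < 2:
        raise ValueError("zscore_genes requires at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd[:, 0] == 0
    sd[degenerate, :] = 1.0
    z = (vals - mu) / sd
    z[degenerate, :] = 0.0
    flagged = frozenset(m.gene_ids[degenerate])
    if flagged:
        logger.info("zscore_genes: %d zero-variance gene(s) flagged", len(flagged))
    return ExpressionMatrix(
        values=pd.DataFrame(z, index=m.gene_ids, columns=m.sample_ids),
        scale="zscore", sample_groups=m.sample_groups, zero_variance=flagged)
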