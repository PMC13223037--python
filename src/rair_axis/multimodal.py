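"""Multimodal ridge regression for drug-response AUC prediction.

Each (cell, drug) pair gets a feature vector concatenating cell-level
features (the panel's leading expression principal components, 16 by
default, plus optionally the signature score) and drug-level features (a
one-hot indicator per unique compound).  Three configurations are supported:
``cell_only``, ``drug_only`` and ``multimodal``.

Columns are standardised to zero mean and unit variance (population
convention, denominator N) with the parameters recorded so held-out rows are
transformed with training-fold statistics only.  The ridge coefficients
solve ``(X'X + lambda I) beta = X'y`` with an unpenalised intercept
(implemented by centring).  Five-fold cross-validation concatenates
out-of-fold predictions, scored by RMSE, Pearson r, and R^2 (both
``1 - SSE/SST`` — the decomposable flavour used for delta-R^2 benchmarking —
and squared Pearson, reported alongside).

PCA is fitted once on the full cell panel before cross-validation.  This is
deliberate (cell features are unsupervised and shared across pairs) but is a
known leakage channel at the cell level; ``strict_no_leakage`` refits PCA
inside each training fold instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .diffexpr import GeneModule
from .preprocess import ExpressionMatrix, LOG_SCALES, zscore_genes
from .signature import score_signature

logger = logging.getLogger("rair_axis")

MODEL_CONFIGS = ("cell_only", "drug_only", "multimodal")
DEFAULT_N_COMPONENTS = 16
DEFAULT_LAMBDA = 1.0
DEFAULT_K = 5
DEFAULT_FOLD_SEED = 42


@dataclass
class PairFeatureMatrix:
    """Features and response for cell-drug pairs, with block layout."""

    X: np.ndarray                       # N pairs x P features
    y: np.ndarray                       # AUC per pair
    pairs: pd.DataFrame                 # columns cell_id, drug_id
    feature_names: list[str]
    blocks: dict[str, slice]            # block name -> column slice
    config: str

    @property
    def n_pairs(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def cell_pc_scores(panel: ExpressionMatrix, n_components: int = DEFAULT_N_COMPONENTS
                   ) -> pd.DataFrame:
    """Leading principal-component scores of the cell panel.

    Genes are centred across cells on the log scale and the cells projected
    onto the top components (capped at n_cells - 1 and n_genes).
    """
    if panel.scale not in LOG_SCALES:
        raise ValueError(f"cell panel must be log scale, got {panel.scale!r}")
    n_comp = min(n_components, panel.n_samples - 1, panel.n_genes)
    if n_comp < 1:
        raise ValueError("panel too small for PCA")
    # cells as observations, genes as variables; PCA centres columns itself
    mat = panel.values.to_numpy(dtype=float).T
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(mat)
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    return pd.DataFrame(scores, index=panel.sample_ids, columns=cols)


def build_features(panel: ExpressionMatrix, response: pd.DataFrame,
                   config: str, module: GeneModule | None = None,
                   n_components: int = DEFAULT_N_COMPONENTS,
                   include_signature: bool | None = None) -> PairFeatureMatrix:
    """Assemble the pair feature matrix for one model configuration.

    ``include_signature`` defaults to True for cell-bearing configs when a
    module is supplied; pass ``include_signature=True`` with
    ``config="drug_only"`` to build the drug-baseline-plus-signature variant
    used for delta-R^2 benchmarking.
    """
    if config not in MODEL_CONFIGS:
        raise ValueError(f"config must be one of {MODEL_CONFIGS}, got {config!r}")
    required = {"cell_id", "drug_id", "auc"}
    if not required <= set(response.columns):
        raise ValueError(f"response table needs columns {sorted(required)}")
    if include_signature is None:
        include_signature = config in ("cell_only", "multimodal") and module is not None
    if include_signature and module is None:
        raise ValueError("include_signature requires a module")

    known_cells = set(panel.sample_ids)
    resp = response[response["cell_id"].isin(known_cells)].reset_index(drop=True)
    n_dropped = len(response) - len(resp)
    if n_dropped:
        logger.warning("build_features: dropped %d pair(s) with no expression", n_dropped)
    if resp.empty:
        raise ValueError("no response pair has expression data")

    blocks: dict[str, slice] = {}
    names: list[str] = []
    parts: list[np.ndarray] = []
    start = 0

    if config in ("cell_only", "multimodal"):
        pcs = cell_pc_scores(panel, n_components)
        block = pcs.loc[resp["cell_id"]].to_numpy(dtype=float)
        blocks["cell_pcs"] = slice(start, start + block.shape[1])
        start += block.shape[1]
        names.extend(pcs.columns)
        parts.append(block)

    if include_signature:
        sig = score_signature(zscore_genes(panel), module)
        col = sig.scores.loc[resp["cell_id"]].to_numpy(dtype=float)[:, None]
        blocks["signature"] = slice(start, start + 1)
        start += 1
        names.append(f"sig_{sig.module_name}")
        parts.append(col)

    if config in ("drug_only", "multimodal"):
        vocab = sorted(response["drug_id"].unique())   # fixed from the full table
        idx = {d: i for i, d in enumerate(vocab)}
        onehot = np.zeros((len(resp), len(vocab)))
        onehot[np.arange(len(resp)),
               resp["drug_id"].map(idx).to_numpy()] = 1.0
        blocks["drug_onehot"] = slice(start, start + len(vocab))
        start += len(vocab)
        names.extend(f"drug_{d}" for d in vocab)
        parts.append(onehot)

    X = np.hstack(parts)
    y = resp["auc"].to_numpy(dtype=float)
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in features or response")
    return PairFeatureMatrix(X=X, y=y, pairs=resp[["cell_id", "drug_id"]],
                             feature_names=names, blocks=blocks, config=config)


@dataclass
class Standardizer:
    """Column-wise standardisation parameters (population sd, denominator N)."""

    mu: np.ndarray
    sigma: np.ndarray
    flagged: np.ndarray          # zero-variance columns left at 0

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        if X.shape[0] < 2:
            raise ValueError("standardisation needs N >= 2 rows")
        mu = X.mean(axis=0)
        sigma = X.std(axis=0, ddof=0)
        flagged = sigma == 0
        return cls(mu=mu, sigma=np.where(flagged, 1.0, sigma), flagged=flagged)

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mu) / self.sigma
        Z[:, self.flagged] = 0.0
        return Z


def standardize(X: np.ndarray) -> tuple[np.ndarray, Standardizer]:
    """Standardise columns to mean 0, population sd 1; params returned for reuse."""
    st = Standardizer.fit(X)
    return st.transform(X), st


@dataclass
class RidgeModel:
    """L2-regularised linear model with unpenalised intercept."""

    beta: np.ndarray
    intercept: float
    lam: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta + self.intercept


def ridge_fit(X: np.ndarray, y: np.ndarray, lam: float = DEFAULT_LAMBDA) -> RidgeModel:
    """Solve ``min ||y - Xb||^2 + lambda ||b||^2`` with a free intercept."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite inputs")
    model = Ridge(alpha=lam, fit_intercept=True, solver="cholesky")
    model.fit(X, y)
    return RidgeModel(beta=model.coef_.copy(), intercept=float(model.intercept_),
                      lam=lam)


@dataclass
class CVResult:
    """Concatenated out-of-fold predictions and summary metrics."""

    y: np.ndarray
    y_hat_cv: np.ndarray
    fold: np.ndarray             # fold index per pair
    rmse: float
    pearson_r: float
    r2: float                    # 1 - SSE/SST on out-of-fold predictions
    r2_pearson: float            # squared Pearson, reported alongside
    config: str = ""
    lam: float = DEFAULT_LAMBDA

    def metrics(self) -> dict[str, float]:
        return {"rmse": self.rmse, "pearson_r": self.pearson_r,
                "r2": self.r2, "r2_pearson": self.r2_pearson}


def _summarise(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, float, float, float]:
    rmse = float(np.sqrt(np.mean((y - y_hat) ** 2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - y_hat) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    if sst > 0 and np.std(y_hat) > 0:
        r = float(np.corrcoef(y, y_hat)[0, 1])
    else:
        r = np.nan
    return rmse, r, r2, (r ** 2 if np.isfinite(r) else np.nan)


def cross_validate(features: PairFeatureMatrix, k: int = DEFAULT_K,
                   lam: float = DEFAULT_LAMBDA, seed: int = DEFAULT_FOLD_SEED,
                   ) -> CVResult:
    """k-fold CV with per-fold standardisation (no train/test leakage).

    Pairs are shuffled once under ``seed`` and split into k near-equal folds;
    standardisation parameters are fitted on each training fold only and
    applied to its test fold; predictions from all folds are concatenated.
    """
    n = features.n_pairs
    if k < 2 or n < k:
        raise ValueError(f"need 2 <= k <= N, got k={k}, N={n}")
    y = features.y
    y_hat = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (train, test) in enumerate(kf.split(features.X)):
        Xtr, st = standardize(features.X[train])
        Xte = st.transform(features.X[test])
        model = ridge_fit(Xtr, y[train], lam)
        y_hat[test] = model.predict(Xte)
        fold_of[test] = f
    rmse, r, r2, r2p = _summarise(y, y_hat)
    return CVResult(y=y, y_hat_cv=y_hat, fold=fold_of, rmse=rmse, pearson_r=r,
                    r2=r2, r2_pearson=r2p, config=features.config, lam=lam)


def compare_models(results: dict[str, CVResult]) -> pd.DataFrame:
    """Metric table for several configurations run on the same folds."""
    folds = [res.fold for res in results.values()]
    for f in folds[1:]:
        if len(f) != len(folds[0]) or (f != folds[0]).any():
            raise ValueError("compared configurations must share fold assignments")
    return pd.DataFrame({name: res.metrics() for name, res in results.items()}).T


def delta_r2(baseline: CVResult, augmented: CVResult) -> float:
    """Change in cross-validated R^2 (1 - SSE/SST) from adding features.

    Both results must come from identical fold assignments so the comparison
    isolates the feature contribution.
    """
    if len(baseline.fold) != len(augmented.fold) or \
            (baseline.fold != augmented.fold).any():
        raise ValueError("fold assignments differ between compared models")
    return float(augmented.r2 - baseline.r2)
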