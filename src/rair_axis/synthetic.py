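"""Synthetic cohorts, cell panels and drug screens with planted ground truth.

The generators here define the study conditions under which the pipeline is
verified: two-group tumour cohorts with a planted up/down module of
differential genes, noisy replicate cohorts sharing a core module, a
cell-line panel whose expression engages the planted module to varying
degrees, and a long-format drug screen in which the area under the viability
curve (AUC) is a sum of drug potency, cell offset, a class-specific
interaction with the planted signature, and noise.

Expression is generated directly on the log2 scale with Gaussian noise; a
separate negative-binomial count generator exists only to exercise the
adaptive count filter.  One integer seed fans out to per-generator child
seeds by fixed offsets so stages are reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

# Fixed offsets fanning one config-level seed out to the generators.
SEED_OFFSETS = {
    "cohort": 11,
    "atc_cohorts": 23,
    "panel": 37,
    "screen": 53,
    "counts": 71,
    "collection": 89,
}

#: Default baseline log2-expression range genes are drawn from.
BASELINE_RANGE = (4.0, 10.0)

#: Targeted drug classes used throughout, in annotation priority order.
DRUG_CLASSES = ("RAF/BRAF", "VEGFR/KDR", "FGFR", "RET", "mTOR")


def child_seed(seed: int, stage: str) -> int:
    """Derive a per-stage child seed from the global seed (kept below 2^31)."""
    return (int(seed) * 1000003 + SEED_OFFSETS[stage]) % (2**31 - 1)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with a planted module of shifted genes.

    ``planted_up`` genes have their group-2 (case) mean shifted by
    ``+effect_size`` log2 units, ``planted_down`` genes by ``-effect_size``.
    """

    n_genes: int
    n_per_group: tuple[int, int]
    planted_up: frozenset[int] = frozenset()
    planted_down: frozenset[int] = frozenset()
    effect_size: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0
    group_labels: tuple[str, str] = ("control", "case")

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(self.n_per_group) != 2 or any(n <= 0 for n in self.n_per_group):
            raise ValueError(f"both group sizes must be positive, got {self.n_per_group}")
        if self.planted_up & self.planted_down:
            raise ValueError("planted_up and planted_down overlap")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for idx in self.planted_up | self.planted_down:
            if not 0 <= idx < self.n_genes:
                raise ValueError(f"planted index {idx} outside [0, {self.n_genes})")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a two-group log2-scale cohort; returns matrix + truth table.

    The truth table has one row per gene with columns ``planted``
    (up/down/null) and ``true_lfc`` (the planted case-minus-control shift).
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_per_group
    genes = _gene_ids(spec.n_genes)
    baseline = rng.uniform(*BASELINE_RANGE, size=spec.n_genes)
    vals = baseline[:, None] + rng.normal(0.0, spec.noise_sd,
                                          size=(spec.n_genes, n1 + n2))
    true_lfc = np.zeros(spec.n_genes)
    up = sorted(spec.planted_up)
    down = sorted(spec.planted_down)
    true_lfc[up] = spec.effect_size
    true_lfc[down] = -spec.effect_size
    vals[:, n1:] += true_lfc[:, None]

    g1, g2 = spec.group_labels
    samples = [f"{g1}_{i + 1:02d}" for i in range(n1)] + \
              [f"{g2}_{i + 1:02d}" for i in range(n2)]
    groups = pd.Series([g1] * n1 + [g2] * n2, index=samples, name="group")
    matrix = ExpressionMatrix(
        values=pd.DataFrame(vals, index=genes, columns=samples),
        scale="log2p1", sample_groups=groups)
    planted = np.where(true_lfc > 0, "up", np.where(true_lfc < 0, "down", "null"))
    truth = pd.DataFrame({"gene_id": genes, "planted": planted,
                          "true_lfc": true_lfc}).set_index("gene_id")
    return matrix, truth


def replicate_cohorts(base: CohortSpec, n_cohorts: int, core_up: frozenset[int],
                      n_private: int = 0, seed: int | None = None,
                      ) -> list[tuple[ExpressionMatrix, pd.DataFrame]]:
    """Cohorts sharing a planted up-module core plus per-cohort private genes.

    Emulates several independent case/control studies of the same disease
    state: each cohort plants the shared ``core_up`` genes plus ``n_private``
    cohort-specific genes drawn from the non-core pool.
    """
    seed = base.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    pool = np.array(sorted(set(range(base.n_genes)) - core_up))
    out = []
    for i in range(n_cohorts):
        private = frozenset(rng.choice(pool, size=n_private, replace=False).tolist()) \
            if n_private else frozenset()
        spec = replace(base, planted_up=core_up | private,
                       seed=int(rng.integers(0, 2**31 - 1)))
        out.append(generate_cohort(spec))
    return out


# --------------------------------------------------------------------------
# Cell panel
# --------------------------------------------------------------------------

def _cell_ids(n: int) -> list[str]:
    return [f"CL{i + 1:02d}" for i in range(n)]


def generate_cell_panel(spec: CohortSpec, engagement: Sequence[float]
                        ) -> ExpressionMatrix:
    """Cell-line panel whose planted-up genes scale with per-cell engagement.

    Each cell ``i`` expresses the planted up-module shifted by
    ``engagement[i] * effect_size`` log2 units over background, so a
    downstream signature score rank-orders cells by engagement.
    """
    eng = np.asarray(engagement, dtype=float)
    if eng.ndim != 1 or eng.size == 0:
        raise ValueError("engagement must be a non-empty 1-D vector")
    if (eng < 0).any() or (eng > 1).any():
        raise ValueError("engagement values must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    n_cells = eng.size
    genes = _gene_ids(spec.n_genes)
    baseline = rng.uniform(*BASELINE_RANGE, size=spec.n_genes)
    vals = baseline[:, None] + rng.normal(0.0, spec.noise_sd,
                                          size=(spec.n_genes, n_cells))
    up = sorted(spec.planted_up)
    if up:
        vals[np.asarray(up)[:, None], np.arange(n_cells)] += eng * spec.effect_size
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=genes, columns=_cell_ids(n_cells)),
        scale="log2p1")


# --------------------------------------------------------------------------
# Drug screen
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSpec:
    """Long-format drug screen: AUC = potency + cell offset + class
    interaction x engagement + noise, clipped to ``auc_range``."""

    n_cells: int
    n_drugs: int
    class_map: Mapping[str, str]            # drug_id -> class label
    drug_potency: Mapping[str, float]       # drug_id -> baseline AUC
    interaction_effect: Mapping[str, float] = field(default_factory=dict)
    cell_effect_sd: float = 0.05
    noise_sd: float = 0.05
    auc_range: tuple[float, float] = (0.0, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_drugs <= 0:
            raise ValueError("n_cells and n_drugs must be positive")
        if self.auc_range[0] >= self.auc_range[1]:
            raise ValueError(f"invalid auc_range {self.auc_range}")
        drugs = list(self.class_map)
        if len(drugs) != self.n_drugs or len(set(drugs)) != self.n_drugs:
            raise ValueError("class_map must assign exactly one class per drug")
        if set(self.drug_potency) != set(drugs):
            raise ValueError("drug_potency keys must match class_map keys")
        for cls, coef in self.interaction_effect.items():
            if not np.isfinite(coef):
                raise ValueError(f"non-finite interaction for class {cls!r}")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.class_map)


def default_screen_spec(seed: int = 0, n_cells: int = 18, n_drugs: int = 150,
                        interaction_effect: Mapping[str, float] | None = None,
                        noise_sd: float = 0.05, cell_effect_sd: float = 0.05,
                        class_sizes: Mapping[str, int] | None = None,
                        ) -> ScreenSpec:
    """Scaled-down PRISM-like thyroid screen.

    Defaults: 18 cell lines, 150 compounds split over the targeted classes
    (RAF/BRAF 12, VEGFR/KDR 15, FGFR 6, RET 5, mTOR 18) plus an
    other/unspecified remainder; planted class interactions default to the
    class-mean differential sensitivities reported for the real screen
    (RAF/BRAF -0.193, VEGFR/KDR -0.096, mTOR -0.029, other classes 0).
    """
    if class_sizes is None:
        class_sizes = {"RAF/BRAF": 12, "VEGFR/KDR": 15, "FGFR": 6,
                       "RET": 5, "mTOR": 18}
    if interaction_effect is None:
        interaction_effect = {"RAF/BRAF": -0.193, "VEGFR/KDR": -0.096,
                              "mTOR": -0.029}
    n_classed = sum(class_sizes.values())
    if n_classed > n_drugs:
        raise ValueError("class sizes exceed n_drugs")
    rng = np.random.default_rng(child_seed(seed, "screen"))
    labels: list[str] = []
    for cls, n in class_sizes.items():
        labels.extend([cls] * n)
    labels.extend(["Other/unspecified"] * (n_drugs - n_classed))
    drug_ids = [f"D{i + 1:03d}" for i in range(n_drugs)]
    class_map = dict(zip(drug_ids, labels))
    # Potencies spread over the usable AUC range; targeted-like agents a bit
    # more potent on average, mirroring the real screen's descriptive shift.
    potency = {}
    for d, cls in class_map.items():
        base = rng.uniform(0.45, 1.05)
        if cls != "Other/unspecified":
            base -= 0.1
        potency[d] = float(np.clip(base, 0.1, 1.1))
    return ScreenSpec(n_cells=n_cells, n_drugs=n_drugs, class_map=class_map,
                      drug_potency=potency,
                      interaction_effect=dict(interaction_effect),
                      cell_effect_sd=cell_effect_sd, noise_sd=noise_sd,
                      seed=child_seed(seed, "screen"))


def generate_screen(spec: ScreenSpec, engagement: Sequence[float]
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the screen; returns (long response table, per-drug truth).

    The response table has one row per (cell, drug) pair with columns
    ``cell_id, drug_id, auc``.  The truth table records each drug's class and
    planted interaction coefficient.
    """
    eng = np.asarray(engagement, dtype=float)
    if eng.size != spec.n_cells:
        raise ValueError(f"engagement length {eng.size} != n_cells {spec.n_cells}")
    rng = np.random.default_rng(spec.seed)
    cells = _cell_ids(spec.n_cells)
    drugs = spec.drug_ids
    cell_offset = rng.normal(0.0, spec.cell_effect_sd, size=spec.n_cells)
    potency = np.array([spec.drug_potency[d] for d in drugs])
    inter = np.array([spec.interaction_effect.get(spec.class_map[d], 0.0)
                      for d in drugs])
    # cells x drugs
    auc = (potency[None, :] + cell_offset[:, None]
           + eng[:, None] * inter[None, :]
           + rng.normal(0.0, spec.noise_sd, size=(spec.n_cells, spec.n_drugs)))
    auc = np.clip(auc, *spec.auc_range)
    table = pd.DataFrame({
        "cell_id": np.repeat(cells, spec.n_drugs),
        "drug_id": np.tile(drugs, spec.n_cells),
        "auc": auc.ravel(),
    })
    if table.duplicated(["cell_id", "drug_id"]).any():
        raise ValueError("duplicate (cell, drug) pairs generated")
    truth = pd.DataFrame({
        "drug_id": drugs,
        "drug_class": [spec.class_map[d] for d in drugs],
        "interaction": inter,
        "potency": potency,
    }).set_index("drug_id")
    return table, truth


def annotation_table(spec: ScreenSpec) -> pd.DataFrame:
    """Free-text mechanism/target annotations consistent with the class map.

    Produces the kind of annotation text a repurposing screen ships (e.g.
    ``"BRAF inhibitor"``), so the keyword annotator can be exercised
    end-to-end against the known class labels.
    """
    moa_text = {
        "RAF/BRAF": ("RAF inhibitor", "BRAF"),
        "VEGFR/KDR": ("VEGFR inhibitor", "KDR"),
        "FGFR": ("FGFR inhibitor", "FGFR1"),
        "RET": ("RET inhibitor", "RET"),
        "mTOR": ("mTOR inhibitor", "MTOR"),
        "Other/unspecified": ("", ""),
    }
    rows = []
    for d, cls in spec.class_map.items():
        moa, target = moa_text[cls]
        rows.append({"drug_id": d, "moa": moa, "target": target})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Counts (for the adaptive filter only)
# --------------------------------------------------------------------------

def generate_counts(n_genes: int, n_per_group: tuple[int, int],
                    mean_counts: float = 200.0, dispersion: float = 0.1,
                    low_genes: Sequence[int] = (), low_mean: float = 0.2,
                    seed: int = 0) -> ExpressionMatrix:
    """Negative-binomial count matrix for exercising the count filter.

    ``low_genes`` are forced to near-zero expression (mean ``low_mean``);
    dispersion is the NB overdispersion (var = mu + dispersion * mu^2).
    """
    rng = np.random.default_rng(seed)
    n1, n2 = n_per_group
    n_samples = n1 + n2
    mu = np.full(n_genes, float(mean_counts))
    if len(low_genes):
        mu[np.asarray(sorted(low_genes))] = low_mean
    # NB via gamma-Poisson mixture
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu[:, None] / shape, size=(n_genes, n_samples))
    counts = rng.poisson(lam)
    genes = _gene_ids(n_genes)
    samples = [f"ctrl_{i + 1:02d}" for i in range(n1)] + \
              [f"case_{i + 1:02d}" for i in range(n2)]
    groups = pd.Series(["ctrl"] * n1 + ["case"] * n2, index=samples, name="group")
    return ExpressionMatrix(values=pd.DataFrame(counts, index=genes, columns=samples),
                            scale="counts", sample_groups=groups)


# --------------------------------------------------------------------------
# Gene-set collections with a planted pathway
# --------------------------------------------------------------------------

def make_collection(gene_ids: Sequence[str], planted_genes: Sequence[str],
                    n_sets: int = 20, set_size: int = 30,
                    n_planted_sets: int = 3, overlap: float = 0.6,
                    seed: int = 0) -> dict[str, frozenset[str]]:
    """Hallmark-like collection: a few sets enriched in the planted module.

    ``n_planted_sets`` sets draw a fraction ``overlap`` of their members from
    ``planted_genes``; the rest are uniform random sets, giving a known
    positive-control/negative-control split for enrichment and correlation
    stages.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    planted = [g for g in planted_genes if g in set(gene_ids)]
    others = sorted(set(gene_ids) - set(planted))
    sets: dict[str, frozenset[str]] = {}
    n_core = min(int(round(overlap * set_size)), len(planted))
    for i in range(n_sets):
        if i < n_planted_sets and n_core > 0:
            core = rng.choice(planted, size=n_core, replace=False).tolist()
            rest = rng.choice(others, size=set_size - n_core, replace=False).tolist()
            sets[f"PLANTED_PATHWAY_{i + 1}"] = frozenset(core + rest)
        else:
            sets[f"RANDOM_SET_{i + 1}"] = frozenset(
                rng.choice(gene_ids, size=set_size, replace=False).tolist())
    return sets
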