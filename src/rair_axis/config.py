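"""Pipeline configuration: one YAML document, one top-level seed.

The configuration mirrors the pipeline stages.  A single integer ``seed``
fans out to per-generator child seeds by fixed offsets (see
:mod:`rair_axis.synthetic`), so stages are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class CohortConfig:
    n_genes: int = 2000
    n_per_group: tuple[int, int] = (20, 20)
    n_planted_up: int = 50
    n_planted_down: int = 50
    effect_size: float = 2.0
    noise_sd: float = 0.3


@dataclass
class ReplicateConfig:
    """Replicate case/control cohorts sharing the planted up-core."""

    n_cohorts: int = 3
    n_private: int = 20
    min_support: int = 1


@dataclass
class PanelConfig:
    n_cells: int = 18
    noise_sd: float = 0.3
    engagement: str = "linspace"       # evenly spaced in [0, 1]


@dataclass
class ScreenConfig:
    n_drugs: int = 150
    noise_sd: float = 0.05
    cell_effect_sd: float = 0.05
    class_sizes: dict[str, int] = field(default_factory=lambda: {
        "RAF/BRAF": 12, "VEGFR/KDR": 15, "FGFR": 6, "RET": 5, "mTOR": 18})
    interaction_effect: dict[str, float] = field(default_factory=lambda: {
        "RAF/BRAF": -0.193, "VEGFR/KDR": -0.096, "mTOR": -0.029})
    auc_range: tuple[float, float] = (0.0, 1.2)


@dataclass
class ThresholdConfig:
    p: float = 1e-2
    lfc: float = 0.5
    n_perm: int = 1000
    ridge_lambda: float = 1.0
    cv_folds: int = 5
    fold_seed: int = 42
    n_components: int = 16
    network_q: float = 0.05
    network_delta: float = -0.05       # class must shift by at least 0.05 AUC


@dataclass
class PipelineConfig:
    seed: int = 0
    stratify: str = "tertile"          # cohort stratification mode
    cohort: CohortConfig = field(default_factory=CohortConfig)
    replicates: ReplicateConfig = field(default_factory=ReplicateConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "de", "enrich", "score", "deltaauc", "model", "network"])

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {"cohort": CohortConfig, "replicates": ReplicateConfig,
               "panel": PanelConfig, "screen": ScreenConfig,
               "thresholds": ThresholdConfig}
        kwargs = {}
        for key, val in d.items():
            if key in sub:
                val = dict(val)
                for tup_key in ("n_per_group", "auc_range"):
                    if tup_key in val and isinstance(val[tup_key], list):
                        val[tup_key] = tuple(val[tup_key])
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
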