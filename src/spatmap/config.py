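"""Run configuration: every downstream tunable, with field-standard defaults.

Defaults follow the established spatial/temporal proteomics workflow: RBF-SVM
with sigma 0.2 and C = 8, left-censored imputation with a 1.8 SD downshift and
0.3 SD width, permutation-based ANOVA FDR at 0.01, and a diploid human DNA
mass of 6.5 pg per cell for histone-based copy-number scaling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields

import yaml


class ConfigError(ValueError):
    """Unknown key or out-of-range value in a run configuration."""


@dataclass
class RunConfig:
    # SVM organelle classification
    svm_sigma: float = 0.2          # RBF width: K(x,y) = exp(-||x-y||^2 / (2 sigma^2))
    svm_c: float = 8.0
    cv_folds: int = 5
    confidence_threshold: float = 0.5
    assignment_floor: float | None = None  # None -> 1 / n_classes
    exclude_compartments: tuple[str, ...] = ()

    # secondary localization (alpha mixing)
    alpha_grid_step: float = 0.05

    # PCP profile handling
    min_observed_fractions: int = 3
    missing_as_zero_in_features: bool = True

    # temporal statistics
    n_permutations: int = 250
    fdr: float = 0.01
    paired_fdr: float = 0.05
    min_valid: int = 2
    imputation_downshift: float = 1.8
    imputation_width: float = 0.3
    fold_change_threshold: float = 10.0
    n_clusters: int = 4
    linkage_method: str = "average"

    # proteomic ruler
    dna_mass_per_cell_pg: float = 6.5

    # enrichment
    enrichment_min_fold: float = 2.0
    enrichment_fdr: float = 0.1

    # meta-analysis
    meta_random_effects: bool = False

    seed: int = 0

    def __post_init__(self) -> None:
        if self.svm_sigma <= 0 or self.svm_c <= 0:
            raise ConfigError("svm_sigma and svm_c must be positive")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        for name in ("fdr", "paired_fdr", "enrichment_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if not 0 < self.alpha_grid_step <= 0.5:
            raise ConfigError("alpha_grid_step must lie in (0, 0.5]")
        if self.imputation_width <= 0:
            raise ConfigError("imputation_width must be positive")
        if self.dna_mass_per_cell_pg <= 0:
            raise ConfigError("dna_mass_per_cell_pg must be positive")
        if not 0 <= self.confidence_threshold <= 1:
            raise ConfigError("confidence_threshold must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exclude_compartments"] = list(self.exclude_compartments)
        return d


def read_config(path) -> RunConfig:
    """Read a YAML or JSON mapping; unspecified fields take the defaults.

    Unknown keys are a hard error (no silently ignored typos). The returned
    object is total: every downstream tunable has a value.
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    if "exclude_compartments" in data and data["exclude_compartments"] is not None:
        data["exclude_compartments"] = tuple(data["exclude_compartments"])
    return RunConfig(**data)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
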