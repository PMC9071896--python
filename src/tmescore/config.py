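"""Run configuration: every tunable of the pipeline with its default."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """Defaults for the full analysis run.

    Thresholds follow the published filters: cluster markers at
    adjusted P < 0.05 with fold change > 1.5; downstream differential
    mRNA/miRNA at adjusted P < 0.05 with |log2FC| > 1; methylation at
    adjusted P < 0.05 with |delta beta| > 0.15.
    """

    seed: int = 0
    # deconvolution
    nu_grid: tuple = (0.25, 0.5, 0.75)
    n_perm: int = 1000
    # clustering
    k_min: int = 1
    k_max: int = 10
    n_ref: int = 50
    n_restarts: int = 10
    consensus_reps: int = 1000
    p_item: float = 0.8
    # marker / scoring filters
    marker_p: float = 0.05
    marker_fc: float = 1.5
    rf_trees: int = 500
    # mutational signatures
    nmf_rank: int = 3
    nmf_restarts: int = 20
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    # differential omics
    de_p: float = 0.05
    de_lfc: float = 1.0
    dm_delta: float = 0.15
    screen_p: float = 0.05
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in (
            "n_perm", "n_ref", "n_restarts", "consensus_reps", "p_item",
            "marker_p", "marker_fc", "rf_trees", "nmf_restarts",
            "nmf_max_iter", "nmf_tol", "de_p", "de_lfc", "dm_delta",
            "screen_p",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"config field {name} must be strictly positive")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML config; unspecified fields keep their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "nu_grid" in data:
        data["nu_grid"] = tuple(data["nu_grid"])
    return RunConfig(**data)
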