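"""Pipeline configuration: every tunable with validated defaults.

Values of record: K=65 superpixels, strip width w=36, deformable-model
weights alpha=beta=1.4, gamma=1, GVF regularization mu_g=0.2.  The remaining
fields are documented package defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # oversegmentation and saliency features
    n_superpixels: int = 65
    sigma_p: float = 0.25
    sigma_c: float = 0.2
    n_bins: int = 64
    # trimap and graph cut
    tf: float = 0.7
    tb: float = 0.3
    n_trees: int = 200
    max_outer: int = 4
    max_inner: int = 5
    band_px: int = 10
    # boundary refinement
    ts: float = 50.0
    alpha: float = 1.4
    beta: float = 1.4
    gamma: float = 1.0
    energy_sigma: float = 2.0
    n_snaxels: int = 200
    snake_iters: int = 300
    a_min: int = 500
    # hemisphere midline
    strip_width: int = 36
    mu_g: float = 0.2
    gvf_iters: int = 80
    midline_snaxels: int = 60
    midline_iters: int = 200
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_superpixels < 2:
            raise ValueError("n_superpixels must be >= 2")
        if not 0.0 <= self.tb <= self.tf <= 1.0:
            raise ValueError("thresholds must satisfy 0 <= tb <= tf <= 1")
        if min(self.sigma_p, self.sigma_c, self.energy_sigma, self.mu_g) <= 0:
            raise ValueError("sigma_p, sigma_c, energy_sigma and mu_g must be positive")
        if not 0 <= self.ts <= 255:
            raise ValueError("ts must lie in [0, 255]")
        if min(self.alpha, self.beta) < 0:
            raise ValueError("alpha and beta must be non-negative")
        for name in (
            "n_bins", "n_trees", "max_outer", "max_inner", "band_px", "n_snaxels",
            "snake_iters", "a_min", "strip_width", "gvf_iters", "midline_snaxels",
            "midline_iters",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
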