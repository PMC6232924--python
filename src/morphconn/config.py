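"""Run configuration: every knob of the pipeline in one YAML-serializable record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .kernels import DEFAULT_K_GRID, DEFAULT_SIGMA_GRID

VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Resolved settings of one end-to-end run.

    ``cohort_path`` reads an existing long/wide CSV cohort; when it is None
    a synthetic cohort is drawn from the ``simulate`` block instead.
    """

    cohort_path: str | None = None
    cohort_format: str = "long_csv"
    hemisphere: str = "left"
    order: str = "high"  # low -> concatenated LON views (CON), high -> HON
    sigma_grid: list[float] = field(default_factory=lambda: list(DEFAULT_SIGMA_GRID))
    k_grid: list[int] = field(default_factory=lambda: list(DEFAULT_K_GRID))
    n_clusters: int = 4
    beta: float = 0.8
    gamma: float = 1.0
    rho: float = 1.0
    diffusion_steps: int = 1
    diffusion_knn: int | None = None
    max_iter: int = 30
    tol: float = 1e-6
    kmeans_restarts: int = 50
    k_folds: int = 5
    repeats: int = 20
    top_k: int = 3
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SimSpec overrides
    version: str = VERSION

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def simlr_kwargs(self) -> dict:
        return dict(
            n_clusters=self.n_clusters, sigma_grid=self.sigma_grid,
            k_grid=self.k_grid, beta=self.beta, gamma=self.gamma, rho=self.rho,
            diffusion_steps=self.diffusion_steps, diffusion_knn=self.diffusion_knn,
            max_iter=self.max_iter, tol=self.tol,
            kmeans_restarts=self.kmeans_restarts, random_state=self.seed,
        )
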