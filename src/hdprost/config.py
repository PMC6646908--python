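"""Reconstruction configuration with the published default parameter sets."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml


@dataclass
class ReconConfig:
    """All knobs of the ADMM reconstruction, serializable to YAML.

    Defaults are mode-specific: :meth:`mrf_defaults` reproduces the 2D radial
    fingerprinting settings (7x7 patches, K=20, search radius 20, offset 3,
    mu=5e-3, 5 ADMM iterations, CG 1e-4/15, subspace rank 10, lambda from the
    spoke-count rule) and :meth:`mt_defaults` the 3D Cartesian multi-contrast
    settings (7^3 patches, K=30, lambda=0.1, mu=5e-3, 5 iterations, CG
    1e-7/10).
    """

    mode: str = "cartesian-multicontrast"
    patch_edge: int = 7
    n_similar: int = 20
    search_radius: int = 20
    patch_offset: int = 3
    lam: float = 0.1
    mu: float = 5e-3
    admm_iters: int = 5
    cg_eps: float = 1e-4
    cg_iters: int = 15
    subspace_rank: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("cartesian-multicontrast", "radial-mrf"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.patch_edge < 1 or self.patch_edge % 2 == 0:
            raise ValueError("patch_edge must be odd and >= 1")
        if self.n_similar < 1:
            raise ValueError("n_similar (K) must be >= 1")
        if self.search_radius < self.patch_edge:
            raise ValueError("search_radius must be >= patch_edge")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.admm_iters < 1:
            raise ValueError("admm_iters must be >= 1")

    @classmethod
    def mrf_defaults(cls, lam: float = 1e-3) -> "ReconConfig":
        return cls(mode="radial-mrf", patch_edge=7, n_similar=20, search_radius=20,
                   patch_offset=3, lam=lam, mu=5e-3, admm_iters=5, cg_eps=1e-4,
                   cg_iters=15, subspace_rank=10)

    @classmethod
    def mt_defaults(cls) -> "ReconConfig":
        return cls(mode="cartesian-multicontrast", patch_edge=7, n_similar=30,
                   search_radius=20, patch_offset=3, lam=0.1, mu=5e-3,
                   admm_iters=5, cg_eps=1e-7, cg_iters=10)

    @property
    def tau(self) -> float:
        return 2.0 * self.lam / self.mu

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ReconConfig":
        with open(path) as f:
            data = yaml.safe_load(f)
        return cls(**data)
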