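"""Run configuration: defaults, YAML loading, and config hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .errors import InvalidInputError
from .fuzzy import FCMConfig
from .imaging import WindowConfig


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the image-to-cohort pipeline.

    Defaults reflect the standard operating point for 150-pixel IHC
    tiles: 7x7 windows (m=3), c=20 clusters, alpha=2, up to 100 FCM
    iterations at tolerance 1e-5, no edge threshold, and reciprocal
    similarity-to-length transform.  ``node_stride`` subsamples window
    centers to keep dense networks tractable (see WindowConfig).
    """

    m: int = 3
    node_stride: int = 4
    tile_size: int = 150
    white_luminance_frac: float = 0.9
    max_background_frac: float = 0.5
    c: int = 20
    alpha: float = 2.0
    max_iter: int = 100
    tol: float = 1e-5
    tau: float = 0.0
    length_transform: str = "reciprocal"
    cc_ratio_range: tuple[float, float] = (0.97, 1.05)
    cp_ratio_range: tuple[float, float] = (0.99, 1.10)
    cc_survival_range: tuple[float, float] = (101, 288)
    cp_survival_range: tuple[float, float] = (126, 288)
    seed: int = 0

    def __post_init__(self) -> None:
        self.window_config()  # validates m, node_stride
        self.fcm_config()  # validates c, alpha, max_iter, tol
        if self.tile_size < 2 * self.m + 1:
            raise InvalidInputError(
                f"tile_size {self.tile_size} smaller than window side {2 * self.m + 1}"
            )
        for name in ("white_luminance_frac", "max_background_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must lie in [0, 1], got {v}")
        if self.tau < 0:
            raise InvalidInputError("tau must be >= 0")
        if self.length_transform not in ("reciprocal", "one_minus"):
            raise InvalidInputError(
                f"unknown length_transform {self.length_transform!r}"
            )
        for name in ("cc_ratio_range", "cp_ratio_range",
                     "cc_survival_range", "cp_survival_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidInputError(f"{name} must satisfy lo <= hi")

    def window_config(self) -> WindowConfig:
        return WindowConfig(m=self.m, node_stride=self.node_stride)

    def fcm_config(self, seed: int | None = None) -> FCMConfig:
        return FCMConfig(
            c=self.c,
            alpha=self.alpha,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.seed if seed is None else seed,
        )

    def hash(self) -> str:
        """Stable short hash of the full configuration."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides win over file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InvalidInputError(f"config file {path} must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cc_ratio_range", "cp_ratio_range",
                    "cc_survival_range", "cp_survival_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if overrides:
            cfg = replace(cfg, **{k: v for k, v in overrides.items() if v is not None})
        return cfg
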