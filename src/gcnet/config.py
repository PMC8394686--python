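"""Run configuration shared by the CLI and the scanning/benchmark harnesses."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a single inference run needs besides the data.

    ``order`` is used directly when ``order_criterion`` is ``"fixed"``;
    otherwise the order is chosen by AIC/BIC over ``1..p_max``.  ``B`` and
    ``bonferroni`` only matter for the DPC bootstrap; ``n_freq``, ``rule``
    and ``fraction`` only for rPDC.  ``seed`` drives every source of
    randomness through named substreams.
    """

    method: str = "rpdc"
    order: int = 2
    order_criterion: str = "fixed"
    p_max: int = 10
    alpha: float = 0.05
    B: int = 10000
    n_freq: int = 64
    rule: str = "all_frequencies"
    fraction: float = 0.5
    seed: int = 0
    max_depth: int = 3
    min_channels: int = 3
    bonferroni: bool = False
    center: bool = False
    sigma_divisor: str = "T"
    surrogate_max_iter: int = 100

    def __post_init__(self) -> None:
        if self.method not in ("rpdc", "dpc"):
            raise ValueError(f"method must be 'rpdc' or 'dpc', got {self.method!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.method == "dpc" and self.B < 100:
            raise ValueError("B must be at least 100 for the DPC bootstrap")
        if self.seed is None:
            raise ValueError("a seed is required")
        if self.order_criterion not in ("fixed", "aic", "bic"):
            raise ValueError(f"unknown order criterion {self.order_criterion!r}")
        if self.order_criterion == "fixed" and self.order < 1:
            raise ValueError("fixed order must be >= 1")

    def with_overrides(self, **kwargs) -> "RunConfig":
        """Copy with the given fields replaced (None values ignored)."""
        clean = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **clean)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus flag overrides."""
    base: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        base = loaded
    cfg = RunConfig(**base)
    return cfg.with_overrides(**overrides)
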