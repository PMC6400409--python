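"""Run configuration: YAML-backed parameters with CLI overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .screw import OMEGA_MIN, PHI_MIN, S_MIN

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    Thresholds: ``phi_min`` (rad) below which a step axis is undefined,
    ``omega_min`` (rad/s) below which the helical-axis point is
    undefined, ``s_min`` the quaternion-scalar switch to the near-pi
    extraction branch.  ``alpha`` is the two-tailed significance level of
    the confidence bands.
    """

    scenario: str = "fresh"
    seed: int = 0
    n_trials: int = 25
    marker_noise_sigma: float = 0.012  # mm
    surface_noise_sigma: float = 0.02  # mm
    n_surface_points: int = 2000
    grid_spacing_deg: float = 1.0
    alpha: float = 0.05
    phi_min: float = PHI_MIN
    omega_min: float = OMEGA_MIN
    s_min: float = S_MIN
    limb_side: str = "right"
    translation_uncertainty_mm: float = 0.012
    out_dir: str = "screwkin_out"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("phi_min", "omega_min", "s_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.limb_side not in ("right", "left"):
            raise ValueError("limb_side must be 'right' or 'left'")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    params: dict = {}
    if path is not None:
        params.update(yaml.safe_load(Path(path).read_text()) or {})
    params.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**params)
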