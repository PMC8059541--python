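"""Central home for every named analysis constant.

All thresholds used anywhere in the pipeline live in :class:`Params` so a run
is fully described by one (YAML-serializable) object plus a seed.  Field
defaults are the study conditions: the 80 % bottom-phase depth fraction, the
0.3 g jaw-surge threshold, the 7-day / <50 % ice break-out rule, the 140 m
shallowing threshold, the 35-day bloom window and the three published current
velocities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class Params:
    # dive processing
    bottom_fraction: float = 0.8          # bottom phase = depth >= fraction * max depth
    surface_threshold_m: float = 2.0      # depth above which a sample counts as submerged
    min_dive_depth_m: float = 10.0
    min_dive_duration_s: float = 30.0
    wiggle_min_excursion_m: float = 1.0   # both limbs of a reversal must span this
    benthic_depth_ratio: float = 0.9      # of the 7-day rolling max depth
    benthic_cv_max: float = 0.02          # bottom-phase depth coefficient of variation
    benthic_window_days: int = 7
    gap_factor: float = 2.0               # gaps > factor * nominal step break a dive

    # prey capture
    capture_threshold_g: float = 0.3
    capture_refractory_s: float = 1.0
    highpass_cutoff_hz: float = 1.0

    # ice phenology
    ice_window_days: int = 7
    ice_threshold_pct: float = 50.0
    bloom_days: int = 35
    velocities_km_day: list[float] = field(default_factory=lambda: [6.5, 10.3, 12.0])
    earth_radius_km: float = 6371.0

    # phenology statistics
    shallow_threshold_m: float = 140.0
    flank_days: int = 10
    spline_order: int = 4                 # order 4 = cubic B-splines
    basis_dim: int = 20                   # knots must resolve the ~24-day feature
    plateau_tol_m: float = 5.0            # near-minimum span tolerance
    likelihood: str = "ml"                # "ml" or "reml"; ML for AIC comparisons

    # isotope mixing
    dirichlet_alpha: float = 1.0
    mcmc_walkers: int = 24
    mcmc_steps: int = 3000
    mcmc_burn: int = 1000
    rhat_max: float = 1.05

    def __post_init__(self) -> None:
        numeric = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in ("velocities_km_day", "likelihood")
        }
        for name, value in numeric.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not self.velocities_km_day:
            raise ValueError("velocities_km_day must be non-empty")
        if any(v <= 0 for v in self.velocities_km_day):
            raise ValueError("velocities must be positive")
        if self.likelihood not in ("ml", "reml"):
            raise ValueError("likelihood must be 'ml' or 'reml'")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Params":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "Params":
        return cls.from_dict(yaml.safe_load(text) or {})
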