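"""Pipeline configuration: defaults, validation and lossless round-trip.

All fixed constants of the assay's analysis live here with their defaults:
the single-cell volume gate (280, 10000) µm³, the diffusive-fraction lag
t_D = 10 h, the 10 µm z-step and the 1 h frame interval. ``validate_config``
parses YAML text, fills defaults, rejects unknown keys and out-of-range
values with named errors, and the dataclass serializes back to YAML without
loss.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

import yaml

from tumotrack.scenario import ValidationError


@dataclass
class PipelineConfig:
    # I/O
    input_stack: str | None = None
    output_dir: str = "tumotrack_out"
    channel_roles: Dict[str, int] = field(
        default_factory=lambda: {"nuclei": 0, "pi": 1, "tcell": 2})
    # calibration
    lateral_pixel_size_um: float = 2.0
    z_step_um: float = 10.0           # confocal sampling: one image every 10 µm
    frame_interval_h: float = 1.0     # hourly time-lapse
    # segmentation
    smoothing_sigma_um: float = 2.0
    threshold: float | str = "otsu"
    min_area_um2: float = 10.0
    max_area_um2: float = 10_000.0
    split_touching: bool = True
    closing_radius_um: float = 20.0
    # tracking
    tcell_threshold: float | str = "otsu"
    volume_gate_low_um3: float = 280.0    # single-cell size gate, strict
    volume_gate_high_um3: float = 10_000.0
    max_displacement_um: float = 30.0
    min_duration_h: float = 10.0
    # motility
    max_lag_h: float = 25.0
    t_d_h: float = 10.0               # lag at which f_D is evaluated
    dunn_adjust: str = "bonferroni"
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.volume_gate_low_um3 < self.volume_gate_high_um3:
            raise ValidationError(
                f"volume gate must satisfy low < high, got "
                f"({self.volume_gate_low_um3}, {self.volume_gate_high_um3})")
        for name in ("lateral_pixel_size_um", "z_step_um", "frame_interval_h",
                     "max_displacement_um", "max_lag_h", "t_d_h"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.min_duration_h < 2 * self.frame_interval_h:
            raise ValidationError("min_duration_h must span at least 2 frames")
        if self.min_area_um2 < 0 or self.max_area_um2 <= self.min_area_um2:
            raise ValidationError("area bounds must satisfy 0 <= min < max")
        if self.dunn_adjust not in ("bonferroni", "none"):
            raise ValidationError(f"unknown dunn_adjust {self.dunn_adjust!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    # defaults a run log can attribute to the assay's fixed analysis constants
    DEFAULT_PROVENANCE = {
        "volume_gate_low_um3": "single-cell volume gate lower bound (µm³)",
        "volume_gate_high_um3": "single-cell volume gate upper bound (µm³)",
        "t_d_h": "fixed lag for the diffusive fraction (h)",
        "z_step_um": "confocal z sampling step (µm)",
        "frame_interval_h": "time-lapse frame interval (h)",
    }


def validate_config(raw: str | None) -> PipelineConfig:
    """Parse YAML config text into a validated :class:`PipelineConfig`.

    Empty or ``None`` input yields the full default set. Unknown keys and
    out-of-range values raise :class:`ValidationError` with the offending
    name.
    """
    data = yaml.safe_load(raw) if raw else None
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError("config must be a YAML mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    try:
        return PipelineConfig(**data)
    except TypeError as exc:
        raise ValidationError(str(exc)) from exc
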