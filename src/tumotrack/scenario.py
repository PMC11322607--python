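"""Scenario and parameter containers for the synthetic co-culture assay.

Geometry and timing defaults mirror the wet assay this package emulates:
a roughly spherical tumoroid of ~150 µm initial diameter embedded in a
collagen volume, imaged as confocal z-stacks with a 10 µm z-step and a 1 h
frame interval over 72 h. Cell numbers are desk-scale (300 nuclei standing
in for ~5000 tumor cells, 100 T-cells for ~50,000 added on top of the gel)
so that a full scenario simulates, renders and re-analyzes in minutes on
one CPU; the scaling is recorded in the written config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple


class ValidationError(ValueError):
    """A parameter violates its documented range or consistency rule."""


@dataclass(frozen=True)
class AssayScenario:
    """Geometry, timing and population sizes of one synthetic co-culture.

    Parameters
    ----------
    volume_size
        (x, y, z) extent of the imaged volume in µm.
    lateral_pixel_size
        µm per pixel in x and y.
    z_step
        µm between consecutive z-planes (confocal sampling step).
    frame_interval
        Hours between consecutive time frames.
    n_frames
        Number of time frames.
    tumoroid_center
        3D position of the tumoroid center, µm.
    tumoroid_radius
        Tumoroid radius in µm (default 75, i.e. ~150 µm diameter).
    n_nuclei
        Tumor nuclei packed into the tumoroid sphere.
    n_tcells
        T-cells added to the volume.
    tcell_entry
        "top": T-cells start in a thin layer under the upper gel surface,
        spread over the whole lateral extent. "offset-top": the entry layer
        is confined to one lateral half of the volume, emulating the
        tilted-gel layout in which cells must actively change direction to
        reach the tumoroid.
    n_seed_contact
        Number of T-cells that start adjacent to the tumoroid surface,
        emulating the few cells that have already reached the tumoroid when
        time-lapse acquisition starts.
    nucleus_spacing
        Minimum center-to-center distance between packed nuclei, µm.
    seed
        Base seed for all stochastic steps of the scenario.
    """

    volume_size: Tuple[float, float, float] = (400.0, 400.0, 200.0)
    lateral_pixel_size: float = 2.0
    z_step: float = 10.0
    frame_interval: float = 1.0
    n_frames: int = 72
    tumoroid_center: Tuple[float, float, float] = (200.0, 200.0, 100.0)
    tumoroid_radius: float = 75.0
    n_nuclei: int = 300
    n_tcells: int = 100
    tcell_entry: str = "top"
    n_seed_contact: int = 5
    nucleus_spacing: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.volume_size):
            raise ValidationError("volume_size extents must be > 0")
        for name in ("lateral_pixel_size", "z_step", "frame_interval",
                     "tumoroid_radius", "nucleus_spacing"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.n_nuclei < 0 or self.n_tcells < 0:
            raise ValidationError("cell counts must be >= 0")
        if not 0 <= self.n_seed_contact <= self.n_tcells:
            raise ValidationError("n_seed_contact must be in [0, n_tcells]")
        if self.tcell_entry not in ("top", "offset-top"):
            raise ValidationError(
                f"tcell_entry must be 'top' or 'offset-top', got {self.tcell_entry!r}")
        c, r = self.tumoroid_center, self.tumoroid_radius
        for axis in range(3):
            if c[axis] - r < 0 or c[axis] + r > self.volume_size[axis]:
                raise ValidationError("tumoroid does not fit inside the volume")

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        """(n_z, n_y, n_x) voxel grid implied by extents and calibration."""
        nx = int(round(self.volume_size[0] / self.lateral_pixel_size))
        ny = int(round(self.volume_size[1] / self.lateral_pixel_size))
        nz = int(round(self.volume_size[2] / self.z_step))
        return nz, ny, nx

    @property
    def duration_h(self) -> float:
        return (self.n_frames - 1) * self.frame_interval

    def to_dict(self) -> dict:
        d = asdict(self)
        d["volume_size"] = list(self.volume_size)
        d["tumoroid_center"] = list(self.tumoroid_center)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AssayScenario":
        d = dict(d)
        d["volume_size"] = tuple(d["volume_size"])
        d["tumoroid_center"] = tuple(d["tumoroid_center"])
        return cls(**d)


@dataclass(frozen=True)
class MotilityParams:
    """Generative motility parameters of simulated T-cells.

    ``d_axis`` is the per-axis diffusion coefficient (µm²/h): each axis of a
    purely diffusive cell takes Gaussian steps of variance ``2 d_axis dt``,
    so the 3D squared displacement grows as ``6 d_axis t``. The MSD model
    fitted downstream uses the 2D-form coefficient ``4 D t`` on 3D
    displacements, so a pure random walk generated with ``d_axis`` is
    recovered as ``D = 1.5 d_axis``.

    ``speed`` is the directed drift magnitude v (µm/h) applied to recruited
    cells; ``sensing_radius`` limits recruitment to cells within that
    distance of the tumoroid surface; ``contact_radius`` defines
    T-cell–tumoroid and T-cell–nucleus contact.

    ``switch_mode``: "never" keeps all cells diffusive; "on_first_contact"
    turns drift on for in-range cells once any T-cell first touches the
    tumoroid (the recruitment-wave scenario); "always" applies drift from
    t = 0 (useful for ballistic limits).
    """

    d_axis: float = 2.0
    speed: float = 6.0
    sensing_radius: float = 400.0
    contact_radius: float = 10.0
    switch_mode: str = "on_first_contact"

    def __post_init__(self) -> None:
        for name in ("d_axis", "speed", "sensing_radius", "contact_radius"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.switch_mode not in ("never", "on_first_contact", "always"):
            raise ValidationError(
                f"switch_mode must be 'never', 'on_first_contact' or 'always', "
                f"got {self.switch_mode!r}")


@dataclass(frozen=True)
class KillingParams:
    """Contact-killing kinetics.

    A nucleus contacted by at least ``contacts_required`` T-cells dies with
    hazard ``kill_rate_per_contact`` (1/h); PI positivity is rendered
    ``pi_onset_delay`` hours after death.
    """

    kill_rate_per_contact: float = 1.0
    pi_onset_delay: float = 1.0
    contacts_required: int = 1

    def __post_init__(self) -> None:
        if self.kill_rate_per_contact < 0:
            raise ValidationError("kill_rate_per_contact must be >= 0")
        if self.pi_onset_delay < 0:
            raise ValidationError("pi_onset_delay must be >= 0")
        if self.contacts_required < 1:
            raise ValidationError("contacts_required must be >= 1")


@dataclass(frozen=True)
class RenderParams:
    """Optical model for rendering ground truth into image stacks.

    One isotropic-lateral Gaussian blob per object per channel, with
    channel-specific lateral/axial widths (µm), a constant background and
    optional Poisson shot noise. Widths default to nucleus-scale blobs for
    the Hoechst/PI channels and slightly larger ones for T-cells.
    """

    sigma_xy: Tuple[float, float, float] = (3.0, 3.0, 4.0)  # nuclei, pi, tcell
    sigma_z: Tuple[float, float, float] = (5.0, 5.0, 6.0)
    amplitude: float = 1000.0
    background: float = 20.0
    poisson_noise: bool = True

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma_xy) or any(s <= 0 for s in self.sigma_z):
            raise ValidationError("blob sigmas must be > 0")
        if self.amplitude <= 0 or self.background < 0:
            raise ValidationError("amplitude must be > 0 and background >= 0")
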