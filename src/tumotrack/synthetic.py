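"""Ground-truthed synthetic co-culture generator.

Emulates the statistical structure of a bsAb/T-cell/tumoroid co-culture
time-lapse: a sphere of densely packed nuclei, T-cells entering from the
top of the collagen volume, an initial random-walk phase, a contact-
triggered recruitment wave in which cells gain a directed drift toward the
tumoroid, contact killing with delayed PI onset, and rendering of the three
fluorescence channels (nuclei / PI / T-cell) with background and shot
noise. Every downstream stage of the package can be validated against the
returned ground truth without any external data.

The recruitment scenario is deliberately reduced to a binary
"switch + drift toward the tumoroid surface" rule rather than a chemokine
reaction–diffusion field: it is sufficient to produce clearly separated
diffusive and directed motility populations. Once a recruited cell reaches
the tumoroid boundary it heads for the nearest live nucleus (infiltration);
when no live nuclei remain the drift reverses outward, emulating the loss
of T-cell localization observed after killing is complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from tumotrack.scenario import (
    AssayScenario,
    KillingParams,
    MotilityParams,
    RenderParams,
    ValidationError,
)
from tumotrack.stack import DEFAULT_CHANNELS, ImageStack
from tumotrack.tracking import Trajectory

SIM_DT = 0.1  # h; fixed sub-step of the agent simulation


class PackingError(RuntimeError):
    """Nucleus packing failed at the requested density."""


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover.

    ``death_times`` uses NaN for nuclei that stay alive;
    ``phase_switch_times`` uses NaN for cells that never gain drift.
    """

    nucleus_positions: np.ndarray          # (n_nuclei, 3) µm
    death_times: np.ndarray                # (n_nuclei,) h, NaN = alive
    trajectories: List[Trajectory]
    phase_switch_times: np.ndarray         # (n_tcells,) h, NaN = never
    pi_onset_delay: float = 0.0            # h between death and PI signal

    def pi_positive(self, t_h: float) -> np.ndarray:
        """Boolean mask of nuclei showing PI signal at time ``t_h``."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.death_times, nan=np.inf) + self.pi_onset_delay <= t_h


def make_tumoroid(scenario: AssayScenario, rng_seed: int) -> np.ndarray:
    """Pack ``n_nuclei`` points into the tumoroid sphere by dart throwing.

    Points are uniform in the sphere subject to a minimum pairwise spacing
    of ``scenario.nucleus_spacing`` µm. Deterministic for a fixed seed.

    Raises
    ------
    PackingError
        If the requested density cannot be placed within a bounded number
        of attempts.
    """
    rng = np.random.default_rng(rng_seed)
    n = scenario.n_nuclei
    if n == 0:
        return np.empty((0, 3))
    center = np.asarray(scenario.tumoroid_center, dtype=float)
    r = scenario.tumoroid_radius
    spacing = scenario.nucleus_spacing
    max_attempts = max(1000, 200 * n)
    points: List[np.ndarray] = []
    attempts = 0
    while len(points) < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place {n} nuclei with spacing {spacing} µm in a "
                f"{r} µm sphere after {max_attempts} attempts; density too high")
        attempts += 1
        # uniform in sphere: direction × cube-root radial
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        candidate = center + u * r * rng.random() ** (1.0 / 3.0)
        if points:
            d2 = np.sum((np.asarray(points) - candidate) ** 2, axis=1)
            if d2.min() < spacing ** 2:
                continue
        points.append(candidate)
    return np.asarray(points)


def _initial_tcell_positions(scenario: AssayScenario,
                             rng: np.random.Generator) -> np.ndarray:
    """Entry layout: a thin layer near the top face plus a few seed-contact
    cells already adjacent to the tumoroid surface."""
    sx, sy, sz = scenario.volume_size
    n = scenario.n_tcells
    n_seed = scenario.n_seed_contact
    pos = np.empty((n, 3))
    # seed-contact cells: random upper-hemisphere directions in the contact
    # band at the tumoroid boundary
    center = np.asarray(scenario.tumoroid_center)
    if n_seed:
        u = rng.normal(size=(n_seed, 3))
        u[:, 2] = np.abs(u[:, 2])
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pos[:n_seed] = center + u * (scenario.tumoroid_radius - 5.0)
    n_top = n - n_seed
    if n_top:
        layer = min(10.0, sz * 0.05)
        if scenario.tcell_entry == "offset-top":
            xs = rng.uniform(0.0, sx / 2.0, n_top)
        else:
            xs = rng.uniform(0.0, sx, n_top)
        pos[n_seed:, 0] = xs
        pos[n_seed:, 1] = rng.uniform(0.0, sy, n_top)
        pos[n_seed:, 2] = rng.uniform(sz - layer, sz, n_top)
    return np.clip(pos, 0.0, np.asarray(scenario.volume_size))


def _reflect(pos: np.ndarray, size: np.ndarray) -> np.ndarray:
    """Reflecting boundaries on all volume faces (steps are << extents)."""
    pos = np.where(pos < 0.0, -pos, pos)
    pos = np.where(pos > size, 2.0 * size - pos, pos)
    return np.clip(pos, 0.0, size)


def simulate_tcells(scenario: AssayScenario,
                    motility: MotilityParams,
                    killing: KillingParams,
                    rng_seed: int,
                    dt: float = SIM_DT) -> GroundTruth:
    """Agent-based simulation of T-cell motion and contact killing.

    Each cell takes per-axis Gaussian steps of variance ``2 d_axis dt``.
    Depending on ``motility.switch_mode``, cells within ``sensing_radius``
    of the tumoroid surface additionally drift at ``motility.speed`` µm/h:
    never, from the first T-cell–tumoroid contact (within
    ``contact_radius``), or from t = 0. A live nucleus simultaneously
    contacted by at least ``killing.contacts_required`` cells dies with
    hazard ``kill_rate_per_contact`` per hour. Boundaries reflect.

    Positions are advanced with fixed sub-steps ``dt`` and sampled at the
    frame interval into :class:`~tumotrack.tracking.Trajectory` objects.
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    if dt > scenario.frame_interval:
        raise ValidationError("dt must not exceed the frame interval")
    n_sub = int(round(scenario.frame_interval / dt))
    if abs(n_sub * dt - scenario.frame_interval) > 1e-9:
        raise ValidationError("frame_interval must be a multiple of dt")

    rng = np.random.default_rng(rng_seed)
    nuclei = make_tumoroid(scenario, rng_seed=int(rng.integers(2 ** 31)))
    center = np.asarray(scenario.tumoroid_center)
    size = np.asarray(scenario.volume_size, dtype=float)
    radius = scenario.tumoroid_radius

    n_cells = scenario.n_tcells
    pos = _initial_tcell_positions(scenario, rng)
    alive = np.ones(len(nuclei), dtype=bool)
    death_times = np.full(len(nuclei), np.nan)
    phase_switch = np.full(n_cells, np.nan)
    switched = motility.switch_mode == "always"
    step_sigma = np.sqrt(2.0 * motility.d_axis * dt)
    p_kill = 1.0 - np.exp(-killing.kill_rate_per_contact * dt)

    frames = np.empty((scenario.n_frames, n_cells, 3))
    frames[0] = pos
    nuc_tree: Optional[cKDTree] = cKDTree(nuclei[alive]) if alive.any() else None

    total_steps = (scenario.n_frames - 1) * n_sub
    for step in range(total_steps):
        t = (step + 1) * dt
        if n_cells:
            if motility.d_axis > 0:
                pos = pos + rng.normal(0.0, step_sigma, size=pos.shape)
            dist_c = np.linalg.norm(pos - center, axis=1)
            if (motility.switch_mode == "on_first_contact" and not switched
                    and np.any(dist_c <= radius + motility.contact_radius)):
                switched = True
            if switched and motility.speed > 0:
                active = (dist_c - radius) <= motility.sensing_radius
                newly = active & np.isnan(phase_switch)
                phase_switch[newly] = t - dt
                if active.any():
                    pos = _apply_drift(pos, active, dist_c, center, radius,
                                       nuclei, alive, nuc_tree,
                                       motility.speed * dt,
                                       motility.contact_radius)
            pos = _reflect(pos, size)
        # contact killing
        if (killing.kill_rate_per_contact > 0 and alive.any() and n_cells):
            cell_tree = cKDTree(pos)
            idx_alive = np.flatnonzero(alive)
            counts = cell_tree.query_ball_point(
                nuclei[idx_alive], motility.contact_radius, return_length=True)
            contacted = idx_alive[counts >= killing.contacts_required]
            if len(contacted):
                dies = contacted[rng.random(len(contacted)) < p_kill]
                if len(dies):
                    alive[dies] = False
                    death_times[dies] = t
                    nuc_tree = cKDTree(nuclei[alive]) if alive.any() else None
        if (step + 1) % n_sub == 0:
            frames[(step + 1) // n_sub] = pos

    times = np.arange(scenario.n_frames) * scenario.frame_interval
    trajectories = [
        Trajectory(cell_id=i, times=times.copy(), positions=frames[:, i].copy())
        for i in range(n_cells)
    ]
    return GroundTruth(nucleus_positions=nuclei, death_times=death_times,
                       trajectories=trajectories,
                       phase_switch_times=phase_switch,
                       pi_onset_delay=killing.pi_onset_delay)


def _apply_drift(pos: np.ndarray, active: np.ndarray, dist_c: np.ndarray,
                 center: np.ndarray, radius: float,
                 nuclei: np.ndarray, alive: np.ndarray,
                 nuc_tree: Optional[cKDTree], step_len: float,
                 contact_radius: float) -> np.ndarray:
    """Move active cells one drift step.

    Outside the boundary zone cells head straight for the tumoroid surface
    (i.e. toward the center); at or inside it they head for the nearest
    live nucleus; with no live nuclei left they drift outward (egress).
    """
    pos = pos.copy()
    idx = np.flatnonzero(active)
    outside = dist_c[idx] > radius + contact_radius
    far = idx[outside]
    near = idx[~outside]
    if len(far):
        direction = center - pos[far]
        norms = np.linalg.norm(direction, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        pos[far] += direction / norms * step_len
    if len(near):
        if nuc_tree is not None:
            _, target_idx = nuc_tree.query(pos[near])
            targets = nuclei[alive][target_idx]
            direction = targets - pos[near]
            dist = np.linalg.norm(direction, axis=1, keepdims=True)
            step = np.minimum(step_len, dist)  # do not overshoot the target
            safe = np.where(dist == 0, 1.0, dist)
            pos[near] += direction / safe * step
        else:
            direction = pos[near] - center
            norms = np.linalg.norm(direction, axis=1, keepdims=True)
            fallback = np.zeros_like(direction)
            fallback[:, 2] = 1.0
            direction = np.where(norms == 0, fallback, direction / np.where(norms == 0, 1.0, norms))
            pos[near] += direction * step_len
    return pos


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _clamped_sigmas(render: RenderParams, scenario: AssayScenario
                    ) -> Tuple[np.ndarray, np.ndarray]:
    sigma_xy = np.asarray(render.sigma_xy, dtype=float)
    sigma_z = np.asarray(render.sigma_z, dtype=float)
    if np.any(sigma_xy < scenario.lateral_pixel_size):
        warnings.warn("lateral blob sigma below one pixel; clamping to pixel size",
                      stacklevel=2)
        sigma_xy = np.maximum(sigma_xy, scenario.lateral_pixel_size)
    if np.any(sigma_z < scenario.z_step / 2.0):
        warnings.warn("axial blob sigma below half a z-step; clamping",
                      stacklevel=2)
        sigma_z = np.maximum(sigma_z, scenario.z_step / 2.0)
    return sigma_xy, sigma_z


def _add_blobs(volume: np.ndarray, points: np.ndarray, sigma_xy: float,
               sigma_z: float, amplitude: float, px: float, zs: float) -> None:
    """Accumulate Gaussian blobs (sampled at voxel centers) into (Z,Y,X)."""
    nz, ny, nx = volume.shape
    half_xy = max(1, int(np.ceil(4.0 * sigma_xy / px)))
    half_z = max(1, int(np.ceil(4.0 * sigma_z / zs)))
    for x_um, y_um, z_um in points:
        # index-space blob centers under the pixel-center convention
        cx, cy, cz = x_um / px - 0.5, y_um / px - 0.5, z_um / zs - 0.5
        x0, x1 = max(0, int(np.floor(cx)) - half_xy), min(nx, int(np.ceil(cx)) + half_xy + 1)
        y0, y1 = max(0, int(np.floor(cy)) - half_xy), min(ny, int(np.ceil(cy)) + half_xy + 1)
        z0, z1 = max(0, int(np.floor(cz)) - half_z), min(nz, int(np.ceil(cz)) + half_z + 1)
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            continue
        gx = np.exp(-((np.arange(x0, x1) - cx) * px) ** 2 / (2.0 * sigma_xy ** 2))
        gy = np.exp(-((np.arange(y0, y1) - cy) * px) ** 2 / (2.0 * sigma_xy ** 2))
        gz = np.exp(-((np.arange(z0, z1) - cz) * zs) ** 2 / (2.0 * sigma_z ** 2))
        volume[z0:z1, y0:y1, x0:x1] += (
            amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :])


def render_frames(ground_truth: GroundTruth, scenario: AssayScenario,
                  render: RenderParams | None = None,
                  rng_seed: int = 0) -> ImageStack:
    """Render ground truth into a calibrated T,Z,C,Y,X fluorescence stack.

    One Gaussian blob per object per channel: all nuclei in the nuclei
    channel, PI blobs only on nuclei whose death (plus PI onset delay)
    precedes the frame time, T-cell blobs at the per-frame trajectory
    positions. Constant background plus optional Poisson shot noise.
    """
    render = render or RenderParams()
    rng = np.random.default_rng(rng_seed)
    nz, ny, nx = scenario.grid_shape
    n_t = scenario.n_frames
    sigma_xy, sigma_z = _clamped_sigmas(render, scenario)
    px, zs = scenario.lateral_pixel_size, scenario.z_step
    data = np.zeros((n_t, nz, 3, ny, nx), dtype=np.float32)
    roles = dict(DEFAULT_CHANNELS)

    tcell_frames = None
    if ground_truth.trajectories:
        tcell_frames = np.stack(
            [tr.positions for tr in ground_truth.trajectories], axis=1)
    for t in range(n_t):
        t_h = t * scenario.frame_interval
        vol = np.zeros((nz, ny, nx), dtype=np.float64)
        if len(ground_truth.nucleus_positions):
            _add_blobs(vol, ground_truth.nucleus_positions,
                       sigma_xy[0], sigma_z[0], render.amplitude, px, zs)
        data[t, :, roles["nuclei"]] = vol
        vol = np.zeros((nz, ny, nx), dtype=np.float64)
        pi_mask = ground_truth.pi_positive(t_h)
        if pi_mask.any():
            _add_blobs(vol, ground_truth.nucleus_positions[pi_mask],
                       sigma_xy[1], sigma_z[1], render.amplitude, px, zs)
        data[t, :, roles["pi"]] = vol
        vol = np.zeros((nz, ny, nx), dtype=np.float64)
        if tcell_frames is not None:
            _add_blobs(vol, tcell_frames[t], sigma_xy[2], sigma_z[2],
                       render.amplitude, px, zs)
        data[t, :, roles["tcell"]] = vol

    data += render.background
    if render.poisson_noise:
        for t in range(n_t):  # frame-wise to bound peak memory
            data[t] = rng.poisson(data[t]).astype(np.float32)
    return ImageStack(data=data.astype(np.float32), channel_roles=roles,
                      lateral_pixel_size=px, z_step=zs,
                      frame_interval=scenario.frame_interval)


# ---------------------------------------------------------------------------
# scenario presets and disk round-trip
# ---------------------------------------------------------------------------

def effective_scenario(seed: int = 0) -> Tuple[AssayScenario, MotilityParams, KillingParams]:
    """Defaults emulating an effective bsAb: contact-triggered recruitment
    wave followed by near-complete killing."""
    return (AssayScenario(seed=seed),
            MotilityParams(switch_mode="on_first_contact"),
            KillingParams())


def ineffective_scenario(seed: int = 0) -> Tuple[AssayScenario, MotilityParams, KillingParams]:
    """Same geometry and baseline motility, but no recruitment switch and
    no killing (ineffective bsAb / missing target arm)."""
    return (AssayScenario(seed=seed),
            MotilityParams(switch_mode="never"),
            KillingParams(kill_rate_per_contact=0.0))


def write_scenario(stack: ImageStack, ground_truth: GroundTruth,
                   scenario: AssayScenario, directory: str | Path) -> dict:
    """Write stack (OME-TIFF), ground-truth tables (CSV) and scenario config
    (YAML) into ``directory``; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": directory / "stack.ome.tif",
        "trajectories": directory / "trajectories.csv",
        "nuclei": directory / "nuclei.csv",
        "tcells": directory / "tcells.csv",
        "config": directory / "scenario.yaml",
    }
    stack.write(paths["stack"])
    rows = []
    for tr in ground_truth.trajectories:
        for t, p in zip(tr.times, tr.positions):
            rows.append((tr.cell_id, t, p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=["cell_id", "t_h", "x_um", "y_um", "z_um"]
                 ).to_csv(paths["trajectories"], index=False, float_format="%.17g")
    pd.DataFrame({
        "nucleus_id": np.arange(len(ground_truth.nucleus_positions)),
        "x_um": ground_truth.nucleus_positions[:, 0],
        "y_um": ground_truth.nucleus_positions[:, 1],
        "z_um": ground_truth.nucleus_positions[:, 2],
        "death_time_h": ground_truth.death_times,
    }).to_csv(paths["nuclei"], index=False, float_format="%.17g")
    pd.DataFrame({
        "cell_id": np.arange(len(ground_truth.phase_switch_times)),
        "phase_switch_time_h": ground_truth.phase_switch_times,
    }).to_csv(paths["tcells"], index=False, float_format="%.17g")
    config = {
        "scenario": scenario.to_dict(),
        "pi_onset_delay": float(ground_truth.pi_onset_delay),
        "note": ("desk-scale stand-in: 300 nuclei emulate a ~5000-cell "
                 "tumoroid, 100 T-cells emulate ~50,000 added on the gel"),
    }
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=False))
    return paths


def read_scenario(directory: str | Path
                  ) -> Tuple[ImageStack, GroundTruth, AssayScenario]:
    """Read back what :func:`write_scenario` wrote; arrays round-trip
    bit-exactly."""
    directory = Path(directory)
    stack = ImageStack.read(directory / "stack.ome.tif")
    config = yaml.safe_load((directory / "scenario.yaml").read_text())
    scenario = AssayScenario.from_dict(config["scenario"])
    nuclei = pd.read_csv(directory / "nuclei.csv", float_precision="round_trip")
    traj_df = pd.read_csv(directory / "trajectories.csv", float_precision="round_trip")
    trajectories = []
    for cell_id, grp in traj_df.groupby("cell_id", sort=True):
        trajectories.append(Trajectory(
            cell_id=int(cell_id),
            times=grp["t_h"].to_numpy(),
            positions=grp[["x_um", "y_um", "z_um"]].to_numpy()))
    tcells = pd.read_csv(directory / "tcells.csv", float_precision="round_trip")
    gt = GroundTruth(
        nucleus_positions=nuclei[["x_um", "y_um", "z_um"]].to_numpy(),
        death_times=nuclei["death_time_h"].to_numpy(),
        trajectories=trajectories,
        phase_switch_times=tcells["phase_switch_time_h"].to_numpy(),
        pi_onset_delay=float(config["pi_onset_delay"]))
    return stack, gt, scenario
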