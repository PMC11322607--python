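"""MSD analysis of T-cell trajectories: directed-plus-diffusive model.

T-cell motion near the tumoroid is modeled as a superposition of random
(diffusive) and active directed motion, under which the mean squared
displacement grows with time-lag as

    msd(t_lag) = 4 D t_lag + v² t_lag²

with diffusion constant D (µm²/h) and persistent speed v (µm/h). The
relative weight of the two modes is summarized by the diffusive fraction
at a fixed lag t_D (default 10 h):

    f_D = 1 / (1 + v² t_D / (4 D))

which approaches 1 for purely diffusive motion and 0 for purely directed
motion.

The 2D-form coefficient 4 D is applied verbatim to 3D displacements, as in
the assay's original analysis; a pure random walk simulated with per-axis
diffusion coefficient ``d_axis`` (3D MSD = 6 d_axis t) is therefore
recovered as D = 1.5 d_axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from tumotrack.scenario import ValidationError
from tumotrack.tracking import Trajectory
from tumotrack import stats as _stats

DEFAULT_T_D = 10.0        # h, lag at which f_D is evaluated
DEFAULT_MAX_LAG = 25.0    # h, per-cell fit range (population analyses use 30)


@dataclass
class MSDCurve:
    """Time-averaged MSD per integer lag."""

    lags_h: np.ndarray       # strictly increasing
    msd: np.ndarray          # µm², >= 0
    n_pairs: np.ndarray      # contributing displacement pairs per lag

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags_h) <= 0):
            raise ValidationError("lags must be strictly increasing")
        if np.any(self.msd < 0) or np.any(self.n_pairs < 1):
            raise ValidationError("msd must be >= 0 with >= 1 pair per lag")


@dataclass
class MotilityFit:
    """Per-trajectory model parameters with fit diagnostics.

    ``f_D`` is NaN with ``undefined`` set when D = v = 0 (a stationary
    fit, for which the diffusive fraction has no meaning).
    """

    D: float                 # µm²/h
    v: float                 # µm/h
    f_D: float
    residual: float
    n_lags: int
    undefined: bool = False
    cell_id: int | None = None


@dataclass
class PopulationSummary:
    """Median and SD of D, v and f_D over fitted trajectories."""

    median: Dict[str, float]
    sd: Dict[str, float]
    n: int
    n_undefined: int
    single_fit: bool = False


def compute_msd(traj: Trajectory, max_lag_h: float) -> MSDCurve:
    """Time-averaged MSD of one trajectory.

    For each integer lag τ (in frame-interval steps up to ``max_lag_h``)
    the MSD is the mean squared 3D Euclidean displacement over all ordered
    position pairs separated by τ (overlapping windows).
    """
    n = len(traj)
    if n < 2:
        raise ValidationError("trajectory needs at least two points")
    dt = float(traj.times[1] - traj.times[0])
    if max_lag_h >= traj.duration:
        raise ValidationError("max_lag must be below the trajectory duration")
    max_lag_frames = int(np.floor(max_lag_h / dt + 1e-9))
    if max_lag_frames < 1:
        raise ValidationError("max_lag shorter than one frame interval")
    lags, msd, pairs = [], [], []
    pos = traj.positions
    for lag in range(1, max_lag_frames + 1):
        disp = pos[lag:] - pos[:-lag]
        sq = np.einsum("ij,ij->i", disp, disp)
        lags.append(lag * dt)
        msd.append(float(sq.mean()))
        pairs.append(len(sq))
    return MSDCurve(lags_h=np.asarray(lags), msd=np.asarray(msd),
                    n_pairs=np.asarray(pairs))


def fit_msd(curve: MSDCurve, weight_by_pairs: bool = False) -> MotilityFit:
    """Least-squares fit of ``msd(τ) = 4 D τ + v² τ²`` with D, v ≥ 0.

    The linear problem in (a = 4D, b = v²) is solved with nonnegativity
    enforced (NNLS); unweighted by default, optionally weighted by the
    per-lag pair count.
    """
    if len(curve.lags_h) < 3:
        raise ValidationError("fit requires at least three lags")
    tau = curve.lags_h
    design = np.column_stack([tau, tau ** 2])
    target = curve.msd.astype(float)
    if weight_by_pairs:
        w = np.sqrt(curve.n_pairs.astype(float))
        design = design * w[:, None]
        target = target * w
    coeffs, residual = nnls(design, target)
    a, b = coeffs
    d = a / 4.0
    v = float(np.sqrt(b))
    f_d, undefined = _diffusive_fraction_value(d, v, DEFAULT_T_D)
    return MotilityFit(D=float(d), v=v, f_D=f_d, residual=float(residual),
                       n_lags=len(tau), undefined=undefined)


def _diffusive_fraction_value(d: float, v: float, t_d: float):
    if d == 0.0 and v == 0.0:
        return float("nan"), True
    if v == 0.0:
        return 1.0, False
    if d == 0.0:
        return 0.0, False
    return 1.0 / (1.0 + v ** 2 * t_d / (4.0 * d)), False


def diffusive_fraction(fit: MotilityFit, t_d: float = DEFAULT_T_D) -> float:
    """Diffusive fraction ``f_D = 1 / (1 + v² t_D / (4 D))`` at lag ``t_d``.

    Limits: v = 0 → 1 (pure diffusion); D = 0, v > 0 → 0 (pure directed
    motion); D = v = 0 → NaN with the fit flagged undefined.
    """
    if t_d <= 0:
        raise ValidationError("t_D must be > 0")
    value, undefined = _diffusive_fraction_value(fit.D, fit.v, t_d)
    fit.f_D = value
    fit.undefined = undefined
    return value


def fit_trajectory(traj: Trajectory, max_lag_h: float = DEFAULT_MAX_LAG,
                   t_d: float = DEFAULT_T_D,
                   cap_at_half_duration: bool = True) -> MotilityFit:
    """MSD + model fit + f_D for one trajectory.

    The fit range defaults to lags 1..25 h but is capped at half the track
    duration to avoid the poorly averaged high-lag tail.
    """
    max_lag = max_lag_h
    if cap_at_half_duration:
        max_lag = min(max_lag, np.floor(traj.duration / 2.0))
    dt = float(traj.times[1] - traj.times[0]) if len(traj) > 1 else 1.0
    max_lag = max(max_lag, 3 * dt)  # fit needs >= 3 lags
    curve = compute_msd(traj, max_lag)
    fit = fit_msd(curve)
    diffusive_fraction(fit, t_d)
    fit.cell_id = traj.cell_id
    return fit


def population_msd(trajectories: Sequence[Trajectory], max_lag_h: float
                   ) -> pd.DataFrame:
    """Population-level MSD: per lag, mean ± SD over per-trajectory MSDs.

    Trajectories too short for a lag simply do not contribute to it, so n
    may decrease with lag. Columns: ``lag_h, msd_mean, msd_sd, n``.
    """
    if len(trajectories) < 2:
        raise ValidationError("population MSD needs at least two trajectories")
    per_lag: Dict[float, List[float]] = {}
    for traj in trajectories:
        lag_cap = min(max_lag_h, np.nextafter(traj.duration, 0.0))
        try:
            curve = compute_msd(traj, lag_cap)
        except ValidationError:
            continue
        for lag, value in zip(curve.lags_h, curve.msd):
            per_lag.setdefault(float(lag), []).append(float(value))
    rows = []
    for lag in sorted(per_lag):
        values = np.asarray(per_lag[lag])
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        rows.append((lag, float(values.mean()), sd, len(values)))
    return pd.DataFrame(rows, columns=["lag_h", "msd_mean", "msd_sd", "n"])


def summarize_population(fits: Sequence[MotilityFit]) -> PopulationSummary:
    """Median and SD of D, v, f_D over fits; undefined fits are excluded
    from the f_D summary with their count reported.

    A single-fit population reports SD = 0 by convention and is flagged.
    """
    if not fits:
        raise ValidationError("no fits to summarize")
    defined = [f for f in fits if not f.undefined]
    n_undefined = len(fits) - len(defined)
    values = {
        "D": np.asarray([f.D for f in fits]),
        "v": np.asarray([f.v for f in fits]),
        "f_D": np.asarray([f.f_D for f in defined]) if defined else np.asarray([]),
    }
    median, sd = {}, {}
    single = False
    for key, arr in values.items():
        if len(arr) == 0:
            median[key] = float("nan")
            sd[key] = float("nan")
        elif len(arr) == 1:
            median[key] = float(arr[0])
            sd[key] = 0.0
            single = True
        else:
            median[key] = float(np.median(arr))
            sd[key] = float(arr.std(ddof=1))
    return PopulationSummary(median=median, sd=sd, n=len(fits),
                             n_undefined=n_undefined, single_fit=single)


def fits_to_frame(fits: Sequence[MotilityFit]) -> pd.DataFrame:
    """Tidy per-cell fit table `cell_id, D_um2_h, v_um_h, fD, n_lags`."""
    return pd.DataFrame(
        [(f.cell_id, f.D, f.v, f.f_D, f.n_lags, f.undefined) for f in fits],
        columns=["cell_id", "D_um2_h", "v_um_h", "fD", "n_lags", "undefined"])


def compare_fd(groups: Dict[str, Sequence[float]],
               adjust: str = "bonferroni") -> Dict[str, object]:
    """Kruskal–Wallis across f_D groups plus Dunn's pairwise post hoc.

    Each group needs n ≥ 3. Returns ``{"kruskal": {"H", "p"},
    "dunn": DataFrame}``.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if any(len(v) < 3 for v in groups.values()):
        raise ValidationError("every group needs n >= 3")
    kw = _stats.kruskal_wallis(groups)
    dunn = _stats.dunn_test(groups, adjust=adjust)
    return {"kruskal": kw, "dunn": dunn}
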