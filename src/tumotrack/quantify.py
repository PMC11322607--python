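"""Whole-tumoroid killing fraction and in-tumoroid T-cell counts.

The two assay readouts are built plane by plane: PI objects are related to
nucleus objects (a nucleus is dead iff at least one PI centroid falls on
its footprint; PI signal on background is discarded), per-plane counts are
summed over the z-stack, and the killing fraction is the stack-wide ratio
of dead to total nuclei. T-cell recruitment is the sum of in-mask T-cells
over all z-sections — a cell spanning two adjacent 10 µm sections is
counted in both, a deliberate fidelity-over-accuracy choice documented in
the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from tumotrack.scenario import ValidationError
from tumotrack.segmentation import PlaneObjects
from tumotrack import stats as _stats


@dataclass(frozen=True)
class PlaneCounts:
    """Counts for one z-plane at one timepoint."""

    t: int
    z: int
    n_nuclei: int
    n_dead_nuclei: int
    n_tcells_inside: int

    def __post_init__(self) -> None:
        if min(self.n_nuclei, self.n_dead_nuclei, self.n_tcells_inside) < 0:
            raise ValidationError("counts must be >= 0")
        if self.n_dead_nuclei > self.n_nuclei:
            raise ValidationError("dead nuclei cannot exceed total nuclei")


@dataclass
class TumoroidTimeSeries:
    """Per-timepoint whole-tumoroid readouts."""

    times_h: np.ndarray
    killing_fraction: np.ndarray          # ∈ [0, 1]
    tcell_count: np.ndarray               # integer z-sum
    zero_denominator: np.ndarray          # True where no nuclei were counted
    normalized_killing_pct: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "timepoint_h": self.times_h,
            "killing_fraction": self.killing_fraction,
            "tcell_count": self.tcell_count,
            "zero_denominator": self.zero_denominator,
        })
        if self.normalized_killing_pct is not None:
            df["killing_normalized_pct"] = self.normalized_killing_pct
        return df


def relate_pi(pi: PlaneObjects, nuclei: PlaneObjects) -> Set[int]:
    """Dead-nucleus labels: nuclei whose footprint contains ≥ 1 PI centroid.

    PI objects whose centroid falls on background are discarded. The
    relation is idempotent — several PI objects in one nucleus mark it dead
    once.
    """
    if pi.labels.shape != nuclei.labels.shape:
        raise ValidationError("PI and nuclei planes must share geometry")
    dead: Set[int] = set()
    px = nuclei.pixel_size
    for row in pi.table.itertuples(index=False):
        col = min(nuclei.labels.shape[1] - 1, max(0, int(row.x_um / px)))
        r = min(nuclei.labels.shape[0] - 1, max(0, int(row.y_um / px)))
        parent = int(nuclei.labels[r, col])
        if parent > 0:
            dead.add(parent)
    return dead


def plane_counts(nuclei: PlaneObjects, pi: PlaneObjects,
                 tcells_inside: PlaneObjects) -> PlaneCounts:
    """Counts for one plane; all three object sets must share (t, z)."""
    if not (nuclei.t == pi.t == tcells_inside.t
            and nuclei.z == pi.z == tcells_inside.z):
        raise ValidationError("plane indices (t, z) are inconsistent")
    dead = relate_pi(pi, nuclei)
    return PlaneCounts(t=nuclei.t, z=nuclei.z,
                       n_nuclei=nuclei.count,
                       n_dead_nuclei=len(dead),
                       n_tcells_inside=tcells_inside.count)


def aggregate_stack(counts: Sequence[PlaneCounts]) -> Tuple[float, int, bool]:
    """Whole-tumoroid readouts for one timepoint.

    Returns ``(killing_fraction, tcell_count, zero_denominator)`` with
    ``killing_fraction = Σ dead / Σ nuclei`` over all planes (0 with the
    flag set when no nuclei were counted) and ``tcell_count`` the z-sum of
    in-mask T-cells.
    """
    if not counts:
        raise ValidationError("aggregate_stack needs at least one plane")
    total = sum(c.n_nuclei for c in counts)
    dead = sum(c.n_dead_nuclei for c in counts)
    tcells = sum(c.n_tcells_inside for c in counts)
    if total == 0:
        return 0.0, tcells, True
    return dead / total, tcells, False


def build_time_series(counts: Iterable[PlaneCounts]) -> TumoroidTimeSeries:
    """Group per-plane counts by timepoint and aggregate each stack."""
    by_t: Dict[int, List[PlaneCounts]] = {}
    for c in counts:
        by_t.setdefault(c.t, []).append(c)
    if not by_t:
        raise ValidationError("no plane counts supplied")
    times = sorted(by_t)
    killing, tcount, flags = [], [], []
    for t in times:
        k, n, flag = aggregate_stack(by_t[t])
        killing.append(k)
        tcount.append(n)
        flags.append(flag)
    return TumoroidTimeSeries(
        times_h=np.asarray(times, dtype=float),
        killing_fraction=np.asarray(killing),
        tcell_count=np.asarray(tcount, dtype=int),
        zero_denominator=np.asarray(flags, dtype=bool))


def normalize_killing(series: TumoroidTimeSeries,
                      positive_control_fraction: float) -> TumoroidTimeSeries:
    """Express killing as percent of the positive (cisplatin-like) control.

    ``normalized = 100 · killing_fraction / control_fraction``; values may
    exceed 100 when a condition outperforms the control.
    """
    if positive_control_fraction <= 0:
        raise ValidationError("positive control fraction must be > 0")
    series.normalized_killing_pct = (
        100.0 * series.killing_fraction / positive_control_fraction)
    return series


def compare_killing(data: pd.DataFrame, reference: str = "NC",
                    value: str = "value", condition: str = "condition",
                    concentration: str = "concentration") -> Dict[str, pd.DataFrame]:
    """Two-way ANOVA (condition × concentration) on normalized killing with
    Bonferroni pairwise comparisons against the reference condition.

    ``data`` is tidy: one row per replicate with the three named columns.
    Returns the ANOVA table and the pairwise table.
    """
    anova = _stats.two_way_anova(data, value=value, factor_a=condition,
                                 factor_b=concentration)
    pairwise = _stats.bonferroni_pairwise_vs_reference(
        data, reference=reference, value=value, factor_a=condition,
        factor_b=concentration)
    return {"anova": anova, "pairwise": pairwise}
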