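"""Group-comparison statistics used by the killing and motility readouts.

Two procedures mirror the assay's analysis conventions: a two-way ANOVA
(condition × concentration) with Bonferroni-adjusted pairwise comparisons
against a reference condition for the killing dose–response, and a
Kruskal–Wallis test followed by Dunn's multiple-comparison post hoc for the
per-cell diffusive fractions.

Dunn's test is implemented here directly: pairwise z statistics on mean
ranks of the pooled sample with the standard tie correction, two-sided
normal p-values and (by default) Bonferroni adjustment.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from tumotrack.scenario import ValidationError


def kruskal_wallis(groups: Dict[str, Sequence[float]]) -> Dict[str, float]:
    """Kruskal–Wallis H and p across named groups.

    A fully degenerate input (every value identical across all groups) is
    defined to give H = 0, p = 1 rather than an error.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(a) < 1 for a in arrays):
        raise ValidationError("every group needs at least one value")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return {"H": 0.0, "p": 1.0}
    h, p = sps.kruskal(*arrays)
    return {"H": float(h), "p": float(p)}


def dunn_test(groups: Dict[str, Sequence[float]],
              adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise post-hoc test on mean ranks.

    For groups i, j with mean ranks R̄ and sizes n over a pooled sample of
    size N, ``z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j))``
    where ``T = Σ(t³ − t) / (12(N − 1))`` corrects for ties. Returns a table
    with raw and adjusted two-sided p-values.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    pooled = np.concatenate([arrays[k] for k in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    offset = 0
    for k in names:
        n_k = len(arrays[k])
        mean_ranks[k] = float(ranks[offset:offset + n_k].mean())
        sizes[k] = n_k
        offset += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    m = len(pairs)
    for a, b in pairs:
        se = np.sqrt(variance_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z)) if se > 0 else 1.0
        p_adj = min(1.0, m * p_raw) if adjust == "bonferroni" else p_raw
        rows.append((a, b, z, p_raw, p_adj))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw", "p_adj"])


def two_way_anova(data: pd.DataFrame, value: str = "value",
                  factor_a: str = "condition",
                  factor_b: str = "concentration") -> pd.DataFrame:
    """Two-way ANOVA table (main effects + interaction) via OLS."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise ValidationError(f"missing column {col!r}")
    if data[factor_a].nunique() < 2 or data[factor_b].nunique() < 2:
        raise ValidationError("both factors need at least two levels")
    model = ols(f"{value} ~ C({factor_a}) * C({factor_b})", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return table


def bonferroni_pairwise_vs_reference(data: pd.DataFrame, reference: str,
                                     value: str = "value",
                                     factor_a: str = "condition",
                                     factor_b: str = "concentration",
                                     ) -> pd.DataFrame:
    """Bonferroni-adjusted Welch t-tests of each condition against the
    reference, within each level of the second factor.

    Identical zero-variance groups are defined to give p = 1. The adjusted
    p is ``min(1, m · p_raw)`` with m the total number of comparisons.
    """
    conditions = [c for c in data[factor_a].unique() if c != reference]
    if not conditions:
        raise ValidationError("no non-reference conditions to compare")
    rows = []
    for level in data[factor_b].unique():
        ref_vals = data[(data[factor_a] == reference)
                        & (data[factor_b] == level)][value].to_numpy()
        for cond in conditions:
            vals = data[(data[factor_a] == cond)
                        & (data[factor_b] == level)][value].to_numpy()
            if len(ref_vals) == 0 or len(vals) == 0:
                continue
            if (np.ptp(ref_vals) == 0 and np.ptp(vals) == 0
                    and ref_vals[0] == vals[0]):
                p_raw = 1.0
            else:
                _, p_raw = sps.ttest_ind(vals, ref_vals, equal_var=False)
                p_raw = float(p_raw)
            rows.append((cond, reference, level, p_raw))
    m = len(rows)
    return pd.DataFrame(
        [(a, b, lvl, p, min(1.0, m * p)) for a, b, lvl, p in rows],
        columns=["condition", "reference", "level", "p_raw", "p_adj"])
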