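"""Group comparison of topological properties and demographics.

Topological properties are z-scored across the pooled subjects (per metric,
per weighting, per node) before parametric comparison, then tested with a
one-way ANOVA; p-values are Benjamini-Hochberg FDR corrected across nodes
within one (property, weighting) family, and families passing FDR get
uncorrected pairwise Welch post-hoc tests.

Demographics utilities reproduce the summary-statistic comparisons of a
typical cohort table: an unpaired t-test from printed mean +/- SE rows, and a
Fisher exact test on 2x2 or 2x3 count tables by full enumeration of tables
with fixed margins (Freeman-Halton for 2x3).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import ValidationError

__all__ = [
    "SummaryStat",
    "z_transform",
    "oneway_anova",
    "bh_fdr",
    "posthoc_pairwise",
    "ttest_from_summary",
    "fisher_exact_counts",
    "group_metric_analysis",
]

#: Sentinel F for a degenerate ANOVA (between-group spread with zero
#: within-group variance); mirrors the edge-wise NBS convention.
F_SENTINEL = 1e12


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def z_transform(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Z-score a pooled sample (sample SD, ddof=1).

    Returns ``(z, degenerate)``; a zero-variance input yields all zeros with
    ``degenerate=True``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("z-transform needs at least 2 values")
    sd = values.std(ddof=1)
    # values identical up to float rounding carry no group signal
    if not np.isfinite(sd) or sd <= 1e-12 * max(np.abs(values).max(), 1e-300):
        return np.zeros_like(values), True
    return (values - values.mean()) / sd, False


def oneway_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way F with df (k-1, sum n - k) and its p-value."""
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    for g in groups:
        if g.size < 2:
            raise ValidationError("every group needs at least 2 values")
    allv = np.concatenate(groups)
    grand = allv.mean()
    k = len(groups)
    n = allv.size
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = k - 1, n - k
    if ssw <= 1e-300 * max(ssb + ssw, 1.0):
        if ssb > 0:
            return F_SENTINEL, 0.0
        return 0.0, 1.0
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f, dfb, dfw))
    return float(f), p


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def posthoc_pairwise(groups: dict[str, np.ndarray]) -> dict[str, float]:
    """Two-sided Welch t-test for every pair of groups (uncorrected)."""
    out: dict[str, float] = {}
    for (na, a), (nb, b) in combinations(groups.items(), 2):
        a, b = np.asarray(a, float), np.asarray(b, float)
        if a.size < 2 or b.size < 2:
            raise ValidationError("post-hoc groups need at least 2 values")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            import warnings
            with warnings.catch_warnings():
                # near-identical groups trip scipy's precision-loss warning;
                # the resulting p ~ 1 is the correct answer here
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        out[f"{na}-{nb}"] = p
    return out


# ---------------------------------------------------------------------------
# Demographics from printed summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStat:
    """A printed 'mean +/- SE (n)' table row."""

    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError("standard error must be > 0")
        if self.n < 2:
            raise ValidationError("n must be >= 2")


def ttest_from_summary(a: SummaryStat, b: SummaryStat) -> tuple[float, float]:
    """Unpaired two-sided t-test from summary statistics.

    t = (m_a - m_b) / sqrt(se_a^2 + se_b^2), df = n_a + n_b - 2.
    """
    t = (a.mean - b.mean) / np.sqrt(a.se ** 2 + b.se ** 2)
    df = a.n + b.n - 2
    p = float(2 * sps.t.sf(abs(t), df))
    return float(t), p


def fisher_exact_counts(table) -> float:
    """Fisher's exact test on a 2x2 or 2x3 count table by full enumeration.

    All tables with the observed margins are enumerated; the p-value sums the
    hypergeometric point probabilities not exceeding the observed one
    (Freeman-Halton extension for 2x3).
    """
    t = np.asarray(table)
    if not np.issubdtype(t.dtype, np.integer):
        if not np.all(t == np.floor(t)):
            raise ValidationError("counts must be integers")
        t = t.astype(int)
    if np.any(t < 0):
        raise ValidationError("counts must be nonnegative")
    if t.shape not in ((2, 2), (2, 3)):
        raise ValidationError(f"table must be 2x2 or 2x3, got {t.shape}")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    total = int(t.sum())
    if total == 0:
        return 1.0

    const = (sum(lgamma(r + 1) for r in rows)
             + sum(lgamma(c + 1) for c in cols) - lgamma(total + 1))

    def logp(cells: np.ndarray) -> float:
        return const - sum(lgamma(x + 1) for x in cells.flat)

    lp_obs = logp(t)
    p = 0.0
    ncols = t.shape[1]
    # enumerate first rows; the second row is determined by the margins
    if ncols == 2:
        firsts = (np.array([a, rows[0] - a])
                  for a in range(min(rows[0], cols[0]) + 1))
    else:
        firsts = (np.array([a, b, rows[0] - a - b])
                  for a in range(min(rows[0], cols[0]) + 1)
                  for b in range(min(rows[0] - a, cols[1]) + 1))
    for first in firsts:
        second = cols - first
        if np.any(first < 0) or np.any(second < 0):
            continue
        cand = np.vstack([first, second])
        lp = logp(cand)
        if lp <= lp_obs + 1e-10:
            p += float(np.exp(lp))
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Metric tables -> ANOVA / FDR / post-hoc
# ---------------------------------------------------------------------------

def group_metric_analysis(df: pd.DataFrame, metrics: list[str], *,
                          by_node: bool = False, fdr_alpha: float = 0.05,
                          use_z: bool = True) -> pd.DataFrame:
    """ANOVA + FDR + post-hoc over a tidy per-subject metric table.

    ``df`` must carry columns (subject, group, weighting[, node]) plus one
    column per metric.  The FDR family is the set of nodes within one
    (metric, weighting) pair when ``by_node``, else each (metric, weighting)
    is a singleton family.  Post-hoc Welch p-values are reported for rows
    whose q passes ``fdr_alpha``.
    """
    keys = ["weighting"] + (["node"] if by_node else [])
    group_names = list(dict.fromkeys(df["group"]))
    rows = []
    for metric in metrics:
        if metric not in df.columns:
            continue
        for key_vals, sub in df.groupby(keys, sort=False):
            if not isinstance(key_vals, tuple):
                key_vals = (key_vals,)
            vals = sub[metric].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                continue
            if use_z:
                z, degenerate = z_transform(vals)
            else:
                z, degenerate = vals, False
            sub = sub.assign(_z=z)
            groups = {g: sub.loc[sub["group"] == g, "_z"].to_numpy()
                      for g in group_names}
            f, p = oneway_anova(list(groups.values()))
            row = dict(zip(keys, key_vals))
            row.update(metric=metric, F=f, p=p, degenerate=degenerate,
                       _groups=groups)
            rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out

    out["q_fdr"] = np.nan
    for _, ix in out.groupby(["metric", "weighting"], sort=False).groups.items():
        out.loc[ix, "q_fdr"] = bh_fdr(out.loc[ix, "p"].to_numpy())

    pair_names = [f"{a}-{b}" for a, b in combinations(group_names, 2)]
    for pn in pair_names:
        out[f"posthoc_{pn}"] = np.nan
    for i in out.index:
        if out.at[i, "q_fdr"] < fdr_alpha and not out.at[i, "degenerate"]:
            ph = posthoc_pairwise(out.at[i, "_groups"])
            for pn, pv in ph.items():
                out.at[i, f"posthoc_{pn}"] = pv
    return out.drop(columns=["_groups"])
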