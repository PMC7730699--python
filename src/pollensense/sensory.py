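"""Quantitative descriptive profile statistics.

Per attribute: fixed-effects two-way ANOVA (score = sample + assessor +
sample × assessor) on a balanced panel design, Tukey HSD pairwise comparison
of sample means with a compact letter display, and panel repeatability as
the root mean square of the residual.  A one-way ANOVA reconstructed from
per-sample means and SDs lets published summary tables be re-analysed
without the raw scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("panellist", "session", "sample", "attribute", "score")


def validate_sensory_scores(scores: pd.DataFrame) -> None:
    """Check the long-table contract: required columns, 0–100 scale,
    balanced panellist × session × sample design per attribute."""
    missing = [c for c in REQUIRED_COLUMNS if c not in scores.columns]
    if missing:
        raise ValueError(f"sensory table is missing columns: {missing}")
    s = scores["score"].to_numpy(dtype=float)
    if np.any(~np.isfinite(s)) or s.min() < 0 or s.max() > 100:
        raise ValueError("scores must be finite and within [0, 100]")
    for attr, sub in scores.groupby("attribute"):
        counts = sub.groupby(["panellist", "session", "sample"]).size()
        n_cells = (
            sub["panellist"].nunique()
            * sub["session"].nunique()
            * sub["sample"].nunique()
        )
        if len(counts) != n_cells or counts.nunique() != 1:
            raise ValueError(
                f"attribute {attr!r}: unbalanced design (every panellist × "
                "session × sample cell must be present the same number of times)"
            )


@dataclass
class AnovaResult:
    """Two-way ANOVA surface for one attribute."""

    attribute: str
    table: pd.DataFrame          # effects × (df, sum_sq, mean_sq, F, p)
    sample_means: pd.Series
    letters: dict[str, str]      # compact letter display per sample
    repeatability_rmse: float    # sqrt(residual mean square)
    alpha: float

    def summary(self) -> str:
        lines = [f"Two-way ANOVA: {self.attribute}", self.table.to_string()]
        lines.append(f"panel repeatability RMSE: {self.repeatability_rmse:.3f}")
        lines.append("Tukey HSD groups (alpha = %.2f):" % self.alpha)
        for s, m in self.sample_means.sort_values(ascending=False).items():
            lines.append(f"  {s:<28s} {m:7.2f}  {self.letters[s]}")
        return "\n".join(lines)


def _balanced_two_way(scores: pd.DataFrame) -> pd.DataFrame:
    """Sums of squares for the balanced sample × assessor design with
    replication (sessions as replicates)."""
    y = scores["score"].to_numpy(dtype=float)
    grand = y.mean()
    n_total = y.size
    samples = scores["sample"].to_numpy()
    assessors = scores["panellist"].to_numpy()
    s_levels, s_idx = np.unique(samples, return_inverse=True)
    a_levels, a_idx = np.unique(assessors, return_inverse=True)
    a_n, s_n = a_levels.size, s_levels.size
    r = n_total // (a_n * s_n)  # replicates per cell (balanced by contract)

    s_means = np.array([y[s_idx == j].mean() for j in range(s_n)])
    a_means = np.array([y[a_idx == j].mean() for j in range(a_n)])
    cell_means = np.zeros((s_n, a_n))
    ss_resid = 0.0
    for i in range(s_n):
        for j in range(a_n):
            cell = y[(s_idx == i) & (a_idx == j)]
            cell_means[i, j] = cell.mean()
            ss_resid += ((cell - cell.mean()) ** 2).sum()
    ss_sample = r * a_n * ((s_means - grand) ** 2).sum()
    ss_assessor = r * s_n * ((a_means - grand) ** 2).sum()
    ss_cells = r * ((cell_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_sample - ss_assessor

    df_sample = s_n - 1
    df_assessor = a_n - 1
    df_inter = df_sample * df_assessor
    df_resid = n_total - s_n * a_n
    rows = {
        "sample": (df_sample, ss_sample),
        "assessor": (df_assessor, ss_assessor),
        "sample:assessor": (df_inter, ss_inter),
        "residual": (df_resid, ss_resid),
    }
    table = pd.DataFrame(
        {
            "df": {k: v[0] for k, v in rows.items()},
            "sum_sq": {k: v[1] for k, v in rows.items()},
        }
    )
    table["mean_sq"] = table["sum_sq"] / table["df"].replace(0, np.nan)
    ms_resid = table.loc["residual", "mean_sq"]
    table["F"] = table["mean_sq"] / ms_resid
    table.loc["residual", "F"] = np.nan
    table["p"] = [
        stats.f.sf(f, d, df_resid) if np.isfinite(f) else np.nan
        for f, d in zip(table["F"], table["df"])
    ]
    # zero residual variance: effects with positive SS are infinitely
    # significant, effects with zero SS are absent
    if ms_resid == 0.0 or not np.isfinite(ms_resid):
        for k in ("sample", "assessor", "sample:assessor"):
            if table.loc[k, "sum_sq"] > 0:
                table.loc[k, "F"], table.loc[k, "p"] = np.inf, 0.0
            else:
                table.loc[k, "F"], table.loc[k, "p"] = 0.0, 1.0
    return table


def _tukey_letters(
    means: pd.Series, n_per_group: int, ms_error: float, df_error: int, alpha: float
) -> dict[str, str]:
    """Compact letter display via insert-and-absorb on descending means.

    Samples sharing a letter are not significantly different by the Tukey
    HSD criterion at level alpha.
    """
    names = list(means.sort_values(ascending=False).index)
    k = len(names)

    def differ(a: str, b: str) -> bool:
        diff = abs(means[a] - means[b])
        if ms_error <= 0.0:
            return diff > 0.0
        q = diff / np.sqrt(ms_error / n_per_group)
        return stats.studentized_range.sf(q, k, df_error) < alpha

    # greedy insert-and-absorb: groups are maximal sets of mutually
    # non-different samples, built from the highest mean down
    groups: list[list[str]] = []
    for name in names:
        placed = False
        for g in groups:
            if all(not differ(name, other) for other in g):
                g.append(name)
                placed = True
        if not placed:
            groups.append([name])
    # absorb groups fully contained in another
    groups = [
        g for i, g in enumerate(groups)
        if not any(i != j and set(g) < set(h) for j, h in enumerate(groups))
    ]
    letters = {n: "" for n in names}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for n in g:
            letters[n] += letter
    return letters


def two_way_anova_tukey(
    scores: pd.DataFrame, attribute: str, alpha: float = 0.05
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction plus Tukey HSD grouping.

    ``scores`` is the long sensory table; the design must be balanced and
    replicated (sessions replicate each panellist × sample cell).  Tukey
    comparisons of sample means use the residual mean square.
    """
    sub = scores[scores["attribute"] == attribute]
    if sub.empty:
        raise ValueError(f"attribute {attribute!r} not present in the table")
    validate_sensory_scores(sub)
    if sub["session"].nunique() < 2:
        raise ValueError("the interaction model needs replicated cells (>= 2 sessions)")
    table = _balanced_two_way(sub)
    means = sub.groupby("sample")["score"].mean()
    n_per = sub["panellist"].nunique() * sub["session"].nunique()
    ms_resid = float(table.loc["residual", "mean_sq"])
    df_resid = int(table.loc["residual", "df"])
    letters = _tukey_letters(means, n_per, ms_resid, df_resid, alpha)
    return AnovaResult(
        attribute=attribute,
        table=table,
        sample_means=means,
        letters=letters,
        repeatability_rmse=float(np.sqrt(max(ms_resid, 0.0))),
        alpha=alpha,
    )


class SummaryAnova(NamedTuple):
    F: float
    p: float
    significant: bool


def oneway_anova_from_summary(
    means: Sequence[float],
    sds: Sequence[float],
    n_per_group: int,
    alpha: float = 0.05,
) -> SummaryAnova:
    """One-way ANOVA reconstructed from per-group means and sample SDs.

    For a balanced design the between-group mean square is
    n·Σ(mᵢ − m̄)²/(k−1) and the pooled within-group mean square the average
    of the group variances; F follows F(k−1, k(n−1)).  SDs are read as
    sample SDs (n−1 denominator).  If every group is identical (all SDs
    zero, equal means) F is defined as 0.
    """
    m = np.asarray(means, dtype=float)
    s = np.asarray(sds, dtype=float)
    if m.size < 2:
        raise ValueError("at least two groups are required")
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    if np.any(s < 0):
        raise ValueError("standard deviations must be non-negative")
    k = m.size
    msb = n_per_group * ((m - m.mean()) ** 2).sum() / (k - 1)
    msw = float((s**2).mean())
    if msw == 0.0:
        F = 0.0 if msb == 0.0 else np.inf
    else:
        F = msb / msw
    p = float(stats.f.sf(F, k - 1, k * (n_per_group - 1)))
    return SummaryAnova(float(F), p, bool(p < alpha))


def count_significant_attributes(
    summaries: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    n_per_group: int,
    alpha: float = 0.05,
) -> int:
    """Number of attributes whose summary one-way ANOVA is significant."""
    return sum(
        oneway_anova_from_summary(means, sds, n_per_group, alpha).significant
        for means, sds in summaries.values()
    )
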