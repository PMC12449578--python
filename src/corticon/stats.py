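"""Longitudinal change summaries and treatment-arm statistics.

Per-subject baseline/follow-up metric values are reduced to absolute and
percent changes, arm-level mean +- SD, a one-way ANOVA across arms on the
change scores, pairwise two-sample Student's t-tests between arms and
paired t-tests within arms against baseline, with significance flagged at
p < .05 and no multiple-testing correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CorticonError

__all__ = [
    "CohortResult",
    "summarize_changes",
    "run_tests",
    "percent_change_ratio_of_means",
]

ALPHA = 0.05


@dataclass
class CohortResult:
    """Per-subject changes plus arm-level summaries and test results."""

    subjects: pd.DataFrame  # one row per subject x metric, with changes
    arms: pd.DataFrame  # arm x metric summary (mean/sd of each column)
    anova: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    within_arm: pd.DataFrame = field(default_factory=pd.DataFrame)


def percent_change_ratio_of_means(baseline_mean: float, change_mean: float) -> float:
    """Ratio-of-means percent change: 100 x mean change / mean baseline."""
    if baseline_mean <= 0:
        raise CorticonError("baseline mean must be positive")
    return 100.0 * change_mean / baseline_mean


def summarize_changes(subject_table: pd.DataFrame) -> CohortResult:
    """Compute per-subject changes and arm-level summaries.

    ``subject_table`` is long-form with columns ``subject_id``, ``arm``,
    ``metric``, ``baseline``, ``followup``.  Subjects missing either time
    point are excluded with a warning.  Percent change is computed per
    subject then averaged; the ratio-of-group-means percent change is also
    reported per arm for cross-checking.
    """
    required = {"subject_id", "arm", "metric", "baseline", "followup"}
    missing = required - set(subject_table.columns)
    if missing:
        raise CorticonError(f"subject table missing columns {sorted(missing)}")
    df = subject_table.copy()
    bad = df["baseline"].isna() | df["followup"].isna()
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} subject-metric rows with a missing time point"
        )
        df = df[~bad]
    if df.empty:
        raise CorticonError("no complete subject data")
    df["change"] = df["followup"] - df["baseline"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["pct_change"] = np.where(
            df["baseline"] > 0, 100.0 * df["change"] / df["baseline"], np.nan
        )

    def _agg(g: pd.DataFrame) -> pd.Series:
        out = {"n": len(g)}
        for col in ("baseline", "followup", "change", "pct_change"):
            out[f"{col}_mean"] = g[col].mean()
            out[f"{col}_sd"] = g[col].std(ddof=1)
        out["pct_change_ratio_of_means"] = (
            percent_change_ratio_of_means(out["baseline_mean"], out["change_mean"])
            if out["baseline_mean"] > 0
            else np.nan
        )
        return pd.Series(out)

    arms = (
        df.groupby(["metric", "arm"], sort=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return CohortResult(subjects=df.reset_index(drop=True), arms=arms)


def run_tests(cohort: CohortResult, welch: bool = False) -> CohortResult:
    """Annotate a cohort result with ANOVA, pairwise and within-arm t-tests.

    Arms with fewer than two subjects are skipped with a warning.  Equal
    variances are assumed for the between-arm tests unless ``welch``.
    """
    df = cohort.subjects
    anova_rows, pair_rows, within_rows = [], [], []
    for metric, g in df.groupby("metric", sort=False):
        arms = {a: ag for a, ag in g.groupby("arm", sort=False)}
        usable = {a: ag for a, ag in arms.items() if len(ag) >= 2}
        skipped = set(arms) - set(usable)
        if skipped:
            warnings.warn(f"{metric}: arms {sorted(skipped)} have n < 2; tests skipped")
        if len(usable) >= 2:
            groups = [ag["change"].to_numpy() for ag in usable.values()]
            F, p = sps.f_oneway(*groups)
            anova_rows.append(
                {"metric": metric, "F": float(F), "p": float(p),
                 "significant": bool(p < ALPHA)}
            )
        for a1, a2 in itertools.combinations(usable, 2):
            t, p = sps.ttest_ind(
                usable[a1]["change"], usable[a2]["change"], equal_var=not welch
            )
            pair_rows.append(
                {"metric": metric, "arm_1": a1, "arm_2": a2,
                 "t": float(t), "p": float(p), "significant": bool(p < ALPHA)}
            )
        for a, ag in usable.items():
            t, p = sps.ttest_rel(ag["followup"], ag["baseline"])
            within_rows.append(
                {"metric": metric, "arm": a, "t": float(t), "p": float(p),
                 "significant": bool(p < ALPHA)}
            )
    cohort.anova = pd.DataFrame(anova_rows)
    cohort.pairwise = pd.DataFrame(pair_rows)
    cohort.within_arm = pd.DataFrame(within_rows)
    return cohort
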