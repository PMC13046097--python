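"""Subgroup hypothesis tests on per-participant error measures.

Kruskal-Wallis compares the median error between subgroups (age, BMI,
sex, bed partner, mattress, questionnaire-derived groupings, ...);
Brown-Forsythe (the Levene variant centered on group medians) compares
the error variance. Holm-Bonferroni step-down correction controls the
family-wise error rate, with one family per test type spanning all
grouping x measure combinations by default. The module also tabulates
the paired ordinal sleep-quality survey (with vs without the reference
montage on the mattress).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import GroupingError, HypnovalError, VocabularyError

__all__ = [
    "QUALITY_LEVELS",
    "kruskal_wallis",
    "brown_forsythe",
    "holm_bonferroni",
    "run_subgroup_family",
    "survey_summary",
    "add_derived_groups",
]

#: Fixed 5-level ordinal self-report scale, worst to best.
QUALITY_LEVELS: tuple[str, ...] = ("very poor", "poor", "quite good", "good", "very good")

DEFAULT_AGE_BINS: tuple[float, ...] = (-np.inf, 30, 45, 60, np.inf)
DEFAULT_AGE_LABELS: tuple[str, ...] = ("<30", "30-44", "45-59", ">=60")
DEFAULT_BMI_BINS: tuple[float, ...] = (-np.inf, 18.5, 25, 30, np.inf)
DEFAULT_BMI_LABELS: tuple[str, ...] = ("<18.5", "18.5-25", "25-30", ">=30")


def _check_groups(values_by_group, min_per_group: int = 1):
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2:
        raise GroupingError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < min_per_group:
            raise GroupingError(f"group {i} has fewer than {min_per_group} values")
    return groups


def kruskal_wallis(values_by_group) -> tuple[float, float]:
    """Rank-based H test of equal medians; (H, p) with chi-square p.

    All-identical values across groups give (0, 1) rather than an error.
    """
    groups = _check_groups(values_by_group, min_per_group=1)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def brown_forsythe(values_by_group) -> tuple[float, float]:
    """Brown-Forsythe test of equal spread: ANOVA on |x - group median|."""
    groups = _check_groups(values_by_group, min_per_group=2)
    deviations = [np.abs(g - np.median(g)) for g in groups]
    if all(np.ptp(d) == 0 for d in deviations):
        # no within-group spread of the deviations: F is 0/0 -> 0 when the
        # group deviation levels coincide, infinite otherwise
        if len({round(float(d.mean()), 12) for d in deviations}) == 1:
            return 0.0, 1.0
        return float("inf"), 0.0
    f, p = stats.levene(*groups, center="median")
    return float(f), float(p)


def holm_bonferroni(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjusted p values and reject flags at ``alpha``.

    Adjusted p is the running max of ``(m - i + 1) * p_(i)`` in sorted
    order, capped at 1, mapped back to the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise HypnovalError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject


def add_derived_groups(
    metadata: pd.DataFrame,
    age_bins=DEFAULT_AGE_BINS,
    age_labels=DEFAULT_AGE_LABELS,
    bmi_bins=DEFAULT_BMI_BINS,
    bmi_labels=DEFAULT_BMI_LABELS,
) -> pd.DataFrame:
    """Attach ``age_group`` / ``bmi_group`` columns from configurable bins."""
    out = metadata.copy()
    if "age_years" in out:
        out["age_group"] = pd.cut(out["age_years"], bins=list(age_bins), labels=list(age_labels), right=False).astype(str)
    if "bmi" in out:
        out["bmi_group"] = pd.cut(out["bmi"], bins=list(bmi_bins), labels=list(bmi_labels), right=False).astype(str)
    return out


def run_subgroup_family(
    per_participant_errors: pd.DataFrame,
    metadata: pd.DataFrame,
    groupings,
    measures,
    alpha: float = 0.05,
    family: str = "per_test",
) -> pd.DataFrame:
    """KW and BF tests for every grouping x measure pair, Holm-corrected.

    ``per_participant_errors`` has one row per participant (indexed or
    keyed by ``subject_id``) and one column per error measure;
    ``metadata`` holds the grouping columns. Holm families: one family
    per test type across all combinations (default) or one per grouping
    (``family='per_grouping'``).

    Returns a tidy table with one row per (grouping, measure, test).
    """
    if family not in ("per_test", "per_grouping"):
        raise ValueError(f"unknown family policy {family!r}")
    err = per_participant_errors
    if "subject_id" in err.columns:
        err = err.set_index("subject_id")
    meta = metadata
    if "subject_id" in meta.columns:
        meta = meta.set_index("subject_id")
    missing = [g for g in groupings if g not in meta.columns]
    if missing:
        raise GroupingError(f"metadata lacks grouping columns {missing}")
    missing = [m for m in measures if m not in err.columns]
    if missing:
        raise GroupingError(f"error table lacks measures {missing}")
    joined = err.join(meta, how="inner")

    rows = []
    for grouping in groupings:
        for measure in measures:
            sub = joined[[measure, grouping]].dropna()
            by_group = [g[measure].to_numpy() for _, g in sub.groupby(grouping, observed=True)]
            by_group = [g for g in by_group if g.size > 0]
            if len(by_group) < 2:
                continue
            summaries = {
                str(name): {
                    "n": int(g[measure].size),
                    "median": float(np.median(g[measure])),
                    "variance": float(np.var(g[measure], ddof=1)) if g[measure].size > 1 else float("nan"),
                }
                for name, g in sub.groupby(grouping, observed=True)
            }
            kw_h, kw_p = kruskal_wallis(by_group)
            rows.append(
                {"grouping": grouping, "measure": measure, "test": "kruskal_wallis",
                 "stat": kw_h, "p": kw_p, "group_summaries": summaries}
            )
            if all(g.size >= 2 for g in by_group):
                bf_f, bf_p = brown_forsythe(by_group)
                rows.append(
                    {"grouping": grouping, "measure": measure, "test": "brown_forsythe",
                     "stat": bf_f, "p": bf_p, "group_summaries": summaries}
                )
    table = pd.DataFrame(rows)
    if table.empty:
        raise GroupingError("no testable grouping x measure combination")

    table["p_holm"] = np.nan
    table["reject"] = False
    if family == "per_test":
        fam_keys = [(t,) for t in table["test"].unique()]
        sel = lambda key: table["test"] == key[0]
    else:
        fam_keys = [
            (t, g) for t in table["test"].unique() for g in table["grouping"].unique()
        ]
        sel = lambda key: (table["test"] == key[0]) & (table["grouping"] == key[1])
    for key in fam_keys:
        mask = sel(key)
        if mask.any():
            adj, rej = holm_bonferroni(table.loc[mask, "p"].to_numpy(), alpha=alpha)
            table.loc[mask, "p_holm"] = adj
            table.loc[mask, "reject"] = rej
    return table


def survey_summary(responses: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Tabulate the paired sleep-quality survey across the two nights.

    ``responses`` needs one row per participant with columns
    ``quality_with_psg`` and ``quality_without_psg`` on the fixed
    5-level ordinal scale, and boolean-ish ``disturbance_with_psg`` /
    ``disturbance_without_psg``. Returns per-condition level counts and
    percentages (1 decimal), the improved / identical / deteriorated
    transition partition, and the disturbance yes/no table.
    """
    order = {level: i for i, level in enumerate(QUALITY_LEVELS)}
    for col in ("quality_with_psg", "quality_without_psg"):
        bad = set(responses[col]) - set(QUALITY_LEVELS)
        if bad:
            raise VocabularyError(f"{col}: unknown levels {sorted(bad)}")
    n = len(responses)
    quality = pd.DataFrame(index=list(QUALITY_LEVELS))
    for label, col in (("with_psg", "quality_with_psg"), ("without_psg", "quality_without_psg")):
        counts = responses[col].value_counts().reindex(QUALITY_LEVELS, fill_value=0)
        quality[f"{label}_n"] = counts
        quality[f"{label}_pct"] = (100.0 * counts / n).round(1)

    before = responses["quality_with_psg"].map(order)
    after = responses["quality_without_psg"].map(order)
    trans_counts = {
        "improved": int((after > before).sum()),
        "identical": int((after == before).sum()),
        "deteriorated": int((after < before).sum()),
    }
    transitions = pd.DataFrame(
        {"n": trans_counts, "pct": {k: round(100.0 * v / n, 1) for k, v in trans_counts.items()}}
    )

    dist = pd.DataFrame(index=["yes", "no"])
    for label, col in (
        ("with_psg", "disturbance_with_psg"),
        ("without_psg", "disturbance_without_psg"),
    ):
        yes = int(responses[col].astype(bool).sum())
        dist[f"{label}_n"] = [yes, n - yes]
        dist[f"{label}_pct"] = [round(100.0 * yes / n, 1), round(100.0 * (n - yes) / n, 1)]

    return {"quality": quality, "transitions": transitions, "disturbance": dist}
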