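"""Cohort-description statistics (the demographics table).

Group comparisons use a Pearson chi-square test of independence (no
continuity correction) for categorical rows and a one-way ANOVA for
continuous rows.  Because a one-way ANOVA depends on the data only through
per-group (mean, SD, n), it can be reconstructed losslessly from printed
summary statistics; the same pooled within-group variance drives Fisher-LSD
post-hoc pairwise tests.

The module also ships the published cohort's printed counts and summaries
(`TABLE1_CATEGORICAL`, `TABLE1_CONTINUOUS`, enrolment/exclusion tallies) so
the reported statistics can be recomputed from their stated inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "GroupSummaries",
    "chi_square_independence",
    "anova_from_summary",
    "posthoc_pairwise_from_summary",
    "build_table1",
    "apply_exclusions",
    "summaries_from_raw",
    "TABLE1_CATEGORICAL",
    "TABLE1_CONTINUOUS",
    "ENROLLED",
    "EXCLUDED_QC",
    "INCLUDED",
]


@dataclass
class ContingencyTable:
    """Group x category count table."""

    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=1) == 0) or np.any(self.counts.sum(axis=0) == 0):
            raise ValueError("contingency table has an all-zero row or column")


@dataclass
class GroupSummaries:
    """Per-group (mean, sd, n) summary of one continuous variable."""

    groups: list  # of (label, mean, sd, n)

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise ValueError("at least one group required")
        for label, mean, sd, n in self.groups:
            if sd < 0:
                raise ValueError(f"{label}: sd must be non-negative")
            if n < 2:
                raise ValueError(f"{label}: n must be at least 2")


def chi_square_independence(table: ContingencyTable):
    """Pearson chi-square of independence, no continuity correction.

    Returns ``(chi2, df, p)``.
    """
    chi2, p, df, _ = stats.chi2_contingency(table.counts, correction=False)
    return float(chi2), int(df), float(p)


def anova_from_summary(groups: GroupSummaries):
    """One-way ANOVA reconstructed exactly from per-group (mean, sd, n).

    F = (SSB / (k-1)) / MSW with SSB = sum n_i (m_i - m)^2 and
    MSW = sum (n_i - 1) s_i^2 / sum (n_i - 1).  Returns (F, df1, df2, p);
    F is +inf when MSW is zero but the group means differ.
    """
    if len(groups.groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    m = np.array([g[1] for g in groups.groups], dtype=float)
    s = np.array([g[2] for g in groups.groups], dtype=float)
    n = np.array([g[3] for g in groups.groups], dtype=float)
    k = len(m)
    grand = (n * m).sum() / n.sum()
    ssb = (n * (m - grand) ** 2).sum()
    df1 = k - 1
    df2 = int((n - 1).sum())
    msw = ((n - 1) * s**2).sum() / (n - 1).sum()
    if msw == 0:
        if ssb == 0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    F = (ssb / df1) / msw
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p


def posthoc_pairwise_from_summary(groups: GroupSummaries) -> pd.DataFrame:
    """Fisher-LSD pairwise t tests using the pooled within-group variance.

    Each pair (a, b) gets t = (m_a - m_b) / sqrt(MSW (1/n_a + 1/n_b)) with
    the ANOVA's within-group df; two-tailed p.
    """
    if len(groups.groups) < 2:
        raise ValueError("need at least two groups")
    n = np.array([g[3] for g in groups.groups], dtype=float)
    s = np.array([g[2] for g in groups.groups], dtype=float)
    msw = ((n - 1) * s**2).sum() / (n - 1).sum()
    df = int((n - 1).sum())
    rows = []
    for i, j in combinations(range(len(groups.groups)), 2):
        la, ma, _, na = groups.groups[i]
        lb, mb, _, nb = groups.groups[j]
        diff = ma - mb
        if msw == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / np.sqrt(msw * (1.0 / na + 1.0 / nb))
            p = float(2.0 * stats.t.sf(abs(t), df))
        rows.append({"pair": (la, lb), "t": float(t), "p": p, "df": df})
    return pd.DataFrame(rows)


def summaries_from_raw(records: pd.DataFrame, column: str, group_col: str = "group") -> GroupSummaries:
    """Lossless (mean, sd, n) summaries of a raw data column per group."""
    rows = []
    for label, sub in records.groupby(group_col, sort=False):
        vals = sub[column].astype(float).dropna()
        rows.append((label, float(vals.mean()), float(vals.std(ddof=1)), int(len(vals))))
    return GroupSummaries(rows)


CONTINUOUS_VARS = (
    "age",
    "education",
    "gmv",
    "max_abs_motion",
    "cognition_baseline",
    "hippocampal_volume",
)
CATEGORICAL_VARS = {"sex": ("M", "F"), "cevd": ("Y", "N")}


def build_table1(records: pd.DataFrame) -> pd.DataFrame:
    """Cohort-description table: mean (sd) or counts per group, with the
    appropriate omnibus statistic and p-value per row."""
    groups = list(dict.fromkeys(records["group"]))
    rows = []
    single = len(groups) < 2
    for var in CONTINUOUS_VARS:
        if var not in records.columns:
            continue
        cells = {}
        for g in groups:
            vals = records.loc[records["group"] == g, var].astype(float).dropna()
            cells[g] = f"{vals.mean():.2f} ({vals.std(ddof=1):.2f})"
        if single:
            rows.append({"variable": var, **cells, "stat": "", "p": ""})
        else:
            F, _, _, p = anova_from_summary(summaries_from_raw(records, var))
            rows.append({"variable": var, **cells, "stat": f"F={F:.2f}", "p": f"{p:.3g}"})
    for var, levels in CATEGORICAL_VARS.items():
        if var not in records.columns:
            continue
        counts = np.array(
            [[int((records.loc[records["group"] == g, var] == l).sum()) for l in levels] for g in groups]
        )
        cells = {g: "/".join(str(c) for c in counts[i]) for i, g in enumerate(groups)}
        if single or np.any(counts.sum(axis=0) == 0):
            rows.append({"variable": var, **cells, "stat": "", "p": ""})
        else:
            chi2, _, p = chi_square_independence(
                ContingencyTable(groups, list(levels), counts)
            )
            rows.append(
                {"variable": var, **cells, "stat": f"chi2={chi2:.2f}", "p": f"{p:.3g}"}
            )
    return pd.DataFrame(rows)


def apply_exclusions(enrolled: dict, excluded: dict) -> dict:
    """Included n per group after the stated quality-control exclusions."""
    out = {}
    for g, n in enrolled.items():
        ex = excluded.get(g, 0)
        if ex > n:
            raise ValueError(f"cannot exclude {ex} of {n} in group {g}")
        out[g] = n - ex
    return out


# ---------------------------------------------------------------------------
# Published cohort inputs (printed counts and summary statistics)

ENROLLED = {"AD": 124, "aMCI": 103, "HC": 49}
EXCLUDED_QC = {"AD": 28, "aMCI": 5, "HC": 1}
INCLUDED = {"AD": 96, "aMCI": 98, "HC": 48}

#: group order of all printed rows
TABLE1_GROUPS = ("HC", "aMCI", "AD")

#: categorical rows: {name: (column labels, counts per group, printed chi2)}
TABLE1_CATEGORICAL = {
    "sex": (("M", "F"), [[21, 27], [52, 46], [37, 59]], 4.19),
    "handedness": (("R", "L"), [[45, 3], [95, 3], [94, 2]], 1.77),
    "ethnicity": (("C", "non-C"), [[43, 5], [81, 17], [74, 22]], 3.44),
    "cevd": (("Y", "N"), [[0, 48], [52, 46], [46, 50]], 41.28),
    "ischemic_heart_disease": (("Y", "N"), [[2, 46], [9, 89], [8, 88]], 1.17),
    "hypertension": (("Y", "N"), [[26, 22], [68, 30], [74, 22]], 7.92),
}

#: continuous rows: {name: ([(group, mean, sd, n)], printed F)}
TABLE1_CONTINUOUS = {
    "age": ([("HC", 72.04, 4.07, 48), ("aMCI", 72.39, 7.24, 98), ("AD", 74.43, 7.13, 96)], 3.04),
    "education": ([("HC", 10.08, 4.78, 48), ("aMCI", 6.88, 4.91, 98), ("AD", 4.92, 4.93, 96)], 17.93),
    "cognitive_decline": (
        [("HC", -0.07, 0.48, 48 - 16), ("aMCI", -0.05, 1.20, 98 - 25), ("AD", -1.81, 2.20, 96 - 43)],
        23.20,
    ),
    "cdr_sob": ([("HC", 0.14, 0.35, 48), ("aMCI", 0.90, 0.90, 98), ("AD", 6.70, 2.73, 96)], 321.85),
    "mmse": ([("HC", 27.46, 1.90, 48), ("aMCI", 23.91, 3.74, 98), ("AD", 16.10, 4.40, 96)], 179.85),
    "moca": ([("HC", 24.38, 2.50, 48), ("aMCI", 19.15, 4.66, 98), ("AD", 11.13, 4.67, 96)], 170.51),
}
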