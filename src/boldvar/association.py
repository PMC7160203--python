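"""Cluster-wise brain-behaviour associations in the patient groups.

For each cluster of interest, the mean z-fSD is partially correlated with
baseline global cognition, hippocampal volume and two-year cognitive
decline (year 2 minus baseline; negative values mean worsening) in the
combined patient sample (aMCI + AD), controlling for age, sex, education
and total grey-matter volume.  Bonferroni correction multiplies raw
p-values by the number of clusters in the frequency band under test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "cognitive_decline",
    "partial_correlation",
    "run_association_suite",
    "OUTCOMES",
]

OUTCOMES = ("cognition_baseline", "hippocampal_volume", "cognitive_decline")
DEFAULT_COVARIATES = ("age", "sex", "education", "gmv")


@dataclass
class AssociationResult:
    cluster_id: str
    outcome: str
    band: str
    partial_r: float
    p_raw: float
    p_bonferroni: float
    n_used: int

    def __post_init__(self) -> None:
        if np.isfinite(self.partial_r) and not -1.0 - 1e-9 <= self.partial_r <= 1.0 + 1e-9:
            raise ValueError("partial_r out of range")


def cognitive_decline(records: pd.DataFrame) -> pd.Series:
    """Two-year global cognitive decline: year 2 minus baseline.

    Missing year-2 scores propagate as NaN; nothing is imputed.
    """
    return records["cognition_year2"] - records["cognition_baseline"]


def partial_correlation(x, y, covariates=None):
    """Partial Pearson correlation of x and y given covariates.

    Both variables are OLS-residualised on [intercept, covariates] after
    listwise deletion of incomplete rows; the two-tailed p-value comes from
    the t distribution with ``n - n_cov - 2`` degrees of freedom.
    Returns ``(r, p, n_used)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        C = np.empty((len(x), 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(x):
            C = C.T
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    x, y, C = x[ok], y[ok], C[ok]
    n = len(x)
    k = C.shape[1]
    if n < k + 3:
        raise ValueError(f"insufficient complete cases: n={n}, covariates={k}")
    X = np.column_stack([np.ones(n), C])
    H = X @ np.linalg.pinv(X)
    rx = x - H @ x
    ry = y - H @ y
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(tstat), df))
    return r, p, n


def run_association_suite(
    roi_values: pd.DataFrame,
    records: pd.DataFrame,
    band: str,
    patients_only: bool = True,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Partial correlations of every cluster ROI with every outcome.

    ``roi_values`` is a subjects x clusters table aligned with ``records``
    (same row order).  The Bonferroni factor m equals the number of
    clusters in the band; results are sorted by raw p-value.
    """
    if roi_values.shape[1] == 0:
        raise ValueError("no clusters provided")
    if len(roi_values) != len(records):
        raise ValueError("roi_values and records must have the same rows")
    rec = records.reset_index(drop=True)
    rois = roi_values.reset_index(drop=True)
    if patients_only:
        sel = rec["group"].isin(["aMCI", "AD"]).to_numpy()
        rec = rec.loc[sel].reset_index(drop=True)
        rois = rois.loc[sel].reset_index(drop=True)

    cov_mat = np.column_stack(
        [
            (rec[c] == "M").astype(float) if c == "sex" else rec[c].astype(float)
            for c in covariates
        ]
    )
    outcome_values = {
        "cognition_baseline": rec["cognition_baseline"].to_numpy(dtype=float),
        "hippocampal_volume": rec["hippocampal_volume"].to_numpy(dtype=float),
        "cognitive_decline": cognitive_decline(rec).to_numpy(dtype=float),
    }

    m = rois.shape[1]
    rows = []
    for cluster_id in rois.columns:
        x = rois[cluster_id].to_numpy(dtype=float)
        for outcome, y in outcome_values.items():
            try:
                r, p, n_used = partial_correlation(x, y, cov_mat)
            except ValueError:
                # too few complete cases (e.g. missing year-2 visits):
                # report the row as not estimable rather than failing
                n_used = int(
                    (np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(cov_mat), axis=1)).sum()
                )
                r, p = np.nan, np.nan
            rows.append(
                AssociationResult(
                    cluster_id=str(cluster_id),
                    outcome=outcome,
                    band=band,
                    partial_r=r,
                    p_raw=p,
                    p_bonferroni=min(1.0, m * p),
                    n_used=n_used,
                )
            )
    out = pd.DataFrame([vars(r) for r in rows])
    return out.sort_values("p_raw", kind="stable").reset_index(drop=True)
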