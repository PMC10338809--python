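"""Association analysis between dynamic lymphatic metrics and clinical
covariates.

Each metric-covariate pair is analyzed by simple linear regression (OLS),
reporting the slope, intercept, Pearson r and the two-sided p-value from
t = r * sqrt(n - 2) / sqrt(1 - r^2) on n - 2 degrees of freedom — identical
to the regression t/F test for a single predictor.  The T2 lesion load is
cube-root transformed before regression to tame its skew.  No
multiple-testing correction is applied by default, mirroring common
practice in small feasibility cohorts; a Benjamini-Hochberg option exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ComputationError, InputError
from .metrics import METRIC_NAMES

SIGNIFICANCE_LEVEL = 0.05

#: Covariates entering the regression grid; t2lv enters cube-root
#: transformed under the name ``t2lv_cbrt``.
COVARIATE_NAMES = ("age", "bmi", "disease_duration", "edss", "t2lv_cbrt", "bpf")

GRID_COLUMNS = [
    "metric", "covariate", "slope", "intercept", "r", "p", "n", "significant", "band",
]


@dataclass(frozen=True)
class RegressionResult:
    """One cell of the metric x covariate regression grid."""

    metric_name: str
    covariate_name: str
    slope: float
    intercept: float
    r: float
    p: float
    n: int

    def __post_init__(self):
        if self.n < 3:
            raise InputError("regression needs at least 3 complete pairs")
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ComputationError("Pearson r outside [-1, 1]")

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_LEVEL

    @property
    def band(self) -> str:
        """Three-level p-value band used for the grid display."""
        if self.p < 0.05:
            return "p<.05"
        if self.p < 0.1:
            return ".05<=p<.1"
        return "p>=.1"


def transform_t2lv(t2lv):
    """Cube-root transform of the T2 lesion volume (mL)."""
    v = np.asarray(t2lv, dtype=float)
    if np.any(v < 0):
        raise InputError("t2lv must be nonnegative")
    out = np.cbrt(v)
    return float(out) if out.ndim == 0 else out


def correlate(
    metric_values,
    covariate_values,
    metric_name: str = "metric",
    covariate_name: str = "covariate",
) -> RegressionResult:
    """OLS fit plus Pearson correlation for one metric-covariate pair.

    Rows where either side is missing (NaN) are dropped pairwise — this is
    how subjects with an undefined washout slope leave that cell.
    """
    y = np.asarray(metric_values, dtype=float)
    x = np.asarray(covariate_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("metric and covariate must be matching 1-D arrays")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InputError(f"fewer than 3 complete pairs for {metric_name} ~ {covariate_name}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ComputationError(
            f"zero variance in {metric_name} ~ {covariate_name}: r undefined"
        )
    fit = sps.linregress(x, y)
    return RegressionResult(
        metric_name=metric_name,
        covariate_name=covariate_name,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        n=int(x.size),
    )


def stats_grid(
    metrics_table: pd.DataFrame,
    covariate_table: pd.DataFrame,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """All metric x covariate regressions on subject-joined tables.

    ``metrics_table`` holds the five metrics indexed (or columned) by
    ``subject_id`` — summary rows from :func:`duralymph.metrics.metrics_table`
    are ignored; ``covariate_table`` is the cohort covariate CSV layout.
    Returns one row per cell with slope/intercept/r/p/n, the significance
    flag at p < .05 and the three-level p band.  With ``bh_correction`` a
    ``q`` column of Benjamini-Hochberg adjusted p-values is appended.
    """
    met = metrics_table.copy()
    if met.index.name != "subject_id":
        if "subject_id" not in met.columns:
            raise InputError("metrics table needs a subject_id index or column")
        met = met.set_index("subject_id")
    met = met.loc[~met.index.isin(["mean", "sd", "n"])]
    cov = covariate_table.copy()
    if cov.index.name != "subject_id":
        if "subject_id" not in cov.columns:
            raise InputError("covariate table needs a subject_id index or column")
        cov = cov.set_index("subject_id")
    for name, table in (("metrics", met), ("covariates", cov)):
        dup = table.index[table.index.duplicated()].unique()
        if len(dup):
            raise InputError(f"duplicated subject ids in {name} table: {list(dup)}")
    missing = met.index.difference(cov.index)
    if len(missing):
        raise InputError(f"subjects missing from covariate table: {list(missing)}")

    joined = met.join(cov, how="inner")
    if "t2lv_cbrt" not in joined.columns:
        source = "t2lv_ml" if "t2lv_ml" in joined.columns else "t2lv"
        if source not in joined.columns:
            raise InputError("covariate table needs a t2lv_ml (or t2lv) column")
        joined["t2lv_cbrt"] = transform_t2lv(joined[source].to_numpy())

    rows = []
    for metric in METRIC_NAMES:
        for covariate in COVARIATE_NAMES:
            res = correlate(
                joined[metric].to_numpy(float),
                joined[covariate].to_numpy(float),
                metric_name=metric,
                covariate_name=covariate,
            )
            rows.append(
                {
                    "metric": metric,
                    "covariate": covariate,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                    "significant": res.significant,
                    "band": res.band,
                }
            )
    grid = pd.DataFrame(rows, columns=GRID_COLUMNS)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        grid["q"] = multipletests(grid["p"].to_numpy(), method="fdr_bh")[1]
    return grid
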