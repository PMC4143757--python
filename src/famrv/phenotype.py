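"""Baseline phenotype extraction and trait/covariate preparation.

Longitudinal blood-pressure style tables (one row per individual per exam)
are reduced to one analysis-ready record per individual:

1. baseline = the first exam at which age, SBP, DBP, medication status and
   smoking are all non-missing; individuals never complete are dropped;
2. individuals on antihypertensive medication at that baseline are excluded;
3. the (right-skewed) SBP trait is rank-based inverse-normal transformed,
   DBP is analyzed untransformed.

The rank-normal transform uses Blom offsets by default,
``Phi^{-1}((r - 3/8) / (n + 1/4))``, with average ranks for ties; the offset
is configurable (``c=0.5`` gives Van der Waerden-like Tukey scores, etc.).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_phenotypes",
    "select_baseline",
    "exclude_medicated",
    "rank_normalize",
    "build_analysis_table",
    "AnalysisTable",
]

log = logging.getLogger("famrv")

#: columns that must all be non-missing at the baseline exam
BASELINE_REQUIRED = ("age", "sbp", "dbp", "bp_meds", "smoke")

#: default covariate columns (plus intercept) used in every model
DEFAULT_COVARIATES = ("sex", "age", "smoke")


def load_phenotypes(path) -> pd.DataFrame:
    """Read a longitudinal phenotype TSV.

    Expected header columns: ``id, exam, age, sex, sbp, dbp, bp_meds, smoke``;
    missing values encoded as ``NA``.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"id": str})
    required = {"id", "exam", "age", "sex", "sbp", "dbp", "bp_meds", "smoke"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file missing columns: {sorted(missing)}")
    return df


def select_baseline(records: pd.DataFrame) -> pd.DataFrame:
    """Per individual, keep the first exam with all required fields present.

    Individuals with no complete exam are dropped.  Duplicate
    ``(id, exam)`` pairs are a malformed-input error.
    """
    if records.duplicated(subset=["id", "exam"]).any():
        bad = records[records.duplicated(subset=["id", "exam"], keep=False)]
        raise ValueError(
            f"duplicate (id, exam) pairs: {bad[['id', 'exam']].values.tolist()[:5]}"
        )
    complete = records.dropna(subset=list(BASELINE_REQUIRED))
    # earliest complete exam per individual, preserving the input's
    # individual order (downstream matrices are aligned by row order)
    baseline = (
        complete.sort_values("exam", kind="stable")
        .groupby("id", sort=False)
        .head(1)
    )
    first_seen = {i: k for k, i in enumerate(records["id"].drop_duplicates())}
    baseline = baseline.sort_values(
        "id", key=lambda s: s.map(first_seen), kind="stable"
    )
    n_dropped = records["id"].nunique() - len(baseline)
    if n_dropped:
        log.info("select_baseline: dropped %d individuals with no complete exam",
                 n_dropped)
    return baseline.reset_index(drop=True)


def exclude_medicated(baseline: pd.DataFrame) -> pd.DataFrame:
    """Remove individuals on BP medication at their baseline exam."""
    if baseline.empty:
        return baseline
    if baseline["bp_meds"].isna().any():
        raise ValueError("bp_meds missing at baseline; run select_baseline first")
    meds = baseline["bp_meds"].astype(bool)
    log.info("exclude_medicated: removed %d of %d individuals",
             int(meds.sum()), len(baseline))
    return baseline[~meds].reset_index(drop=True)


def rank_normalize(values, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with offset ``c`` (Blom default).

    Returns ``Phi^{-1}((r - c) / (n - 2c + 1))`` where ``r`` are average
    ranks.  Strictly monotone on distinct values; ties map to equal scores.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("rank_normalize requires a 1-d vector with n >= 2")
    if np.isnan(x).any():
        raise ValueError("rank_normalize input contains missing values")
    if np.ptp(x) == 0:
        raise ValueError("all values identical; ranks are degenerate")
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - c) / (x.size - 2 * c + 1))


class AnalysisTable:
    """Aligned trait vector and covariate design for one analysis.

    Attributes
    ----------
    ids : list of individual ids, defining the row order every other
        matrix (kinship, dosages) must be aligned to.
    y : trait vector, length n.
    x : n x p covariate matrix with a leading intercept column.
    covariate_names : column labels of ``x``.
    """

    def __init__(self, ids, y, x, covariate_names):
        self.ids = list(ids)
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.covariate_names = list(covariate_names)
        n = len(self.ids)
        if self.y.shape != (n,) or self.x.shape[0] != n:
            raise ValueError("misaligned Y/X/ids")
        if np.isnan(self.y).any() or np.isnan(self.x).any():
            raise ValueError("analysis table contains missing values")
        if np.linalg.matrix_rank(self.x) < self.x.shape[1]:
            raise ValueError("covariate matrix is rank-deficient")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": self.ids, "Y": self.y})
        for j, name in enumerate(self.covariate_names):
            out[name] = self.x[:, j]
        return out


def build_analysis_table(
    baseline: pd.DataFrame,
    trait: str,
    covariates=DEFAULT_COVARIATES,
    rank_normal: bool | None = None,
) -> AnalysisTable:
    """Build the trait vector and covariate design from baseline records.

    ``trait`` is a column name (``"sbp"``, ``"dbp"``, or any other numeric
    column).  ``rank_normal`` defaults to True for SBP (its distribution is
    right-skewed) and False otherwise.
    """
    if rank_normal is None:
        rank_normal = trait == "sbp"
    y = baseline[trait].to_numpy(dtype=float)
    if rank_normal:
        y = rank_normalize(y)
    cols = [np.ones(len(baseline))]
    for c in covariates:
        cols.append(baseline[c].to_numpy(dtype=float))
    x = np.column_stack(cols)
    return AnalysisTable(baseline["id"], y, x, ["intercept", *covariates])
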