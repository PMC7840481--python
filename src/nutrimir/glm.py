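"""Covariate-adjusted confirmation of screened NC–miRNA pairs.

Each pair surviving the correlation screen is re-examined with a
Gaussian linear model fitted on all subjects pooled across diet
groups: log2(normalized count + 1) regressed on age, sex, BMI and the
NC intake.  Two verdicts are recorded: whether the model as a whole
beats the intercept-only null (F-test p < 0.05), and whether the NC
term *dominates* the nuisance covariates — its p-value below 0.05 and
strictly smaller than each of the age, sex and BMI p-values (ties are
not dominant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .intake import IntakeTable
from .normalization import CountMatrix

logger = logging.getLogger(__name__)

_COVARIATES = ("age", "sex", "bmi")


@dataclass
class GlmResult:
    mirna_id: str
    nc_id: str
    coefficients: dict[str, float]
    p_values: dict[str, float]
    model_p: float
    model_significant: bool
    nc_dominant: bool

    def as_row(self) -> dict:
        row = {"mirna_id": self.mirna_id, "nc_id": self.nc_id}
        for term, coef in self.coefficients.items():
            row[f"coef_{term}"] = coef
        for term, p in self.p_values.items():
            row[f"p_{term}"] = p
        row.update(
            model_p=self.model_p,
            model_significant=self.model_significant,
            nc_dominant=self.nc_dominant,
        )
        return row


def _check_design(X: pd.DataFrame) -> None:
    for col in X.columns:
        if np.ptp(X[col].to_numpy()) == 0:
            raise ValueError(f"degenerate design: column {col!r} is constant")
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # identify an offending column by leave-one-out rank
        for col in X.columns:
            reduced = np.column_stack(
                [np.ones(len(X)), X.drop(columns=col).to_numpy(dtype=float)]
            )
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(mat):
                raise ValueError(f"collinear design: column {col!r} is redundant")
        raise ValueError("collinear design matrix")


def fit_glm(
    y: np.ndarray,
    covariates: pd.DataFrame | None,
    nc: np.ndarray,
    mirna_id: str = "",
    nc_id: str = "",
    alpha: float = 0.05,
) -> GlmResult:
    """OLS fit of (transformed) expression on age, sex, BMI and NC intake.

    ``covariates`` needs columns age, sex (binary or F/M) and bmi; pass
    None for an NC-only model (used by diagnostics).  The model F-test
    compares the full fit against the intercept-only null.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = pd.DataFrame(index=pd.RangeIndex(n))
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        X["age"] = cov["age"].astype(float)
        sex = cov["sex"]
        X["sex"] = (sex == "M").astype(float) if sex.dtype == object else sex.astype(float)
        X["bmi"] = cov["bmi"].astype(float)
    X["nc"] = np.asarray(nc, dtype=float)
    if n <= X.shape[1] + 1:
        raise ValueError(f"need more observations ({n}) than parameters ({X.shape[1] + 1})")
    _check_design(X)
    model = sm.OLS(y, sm.add_constant(X)).fit()
    coeffs = {t: float(model.params[t]) for t in model.params.index}
    pvals = {t: float(model.pvalues[t]) for t in model.pvalues.index}
    model_p = float(model.f_pvalue)
    model_significant = model_p < alpha
    p_nc = pvals["nc"]
    if covariates is not None:
        p_cov = min(pvals[c] for c in _COVARIATES)
        nc_dominant = model_significant and p_nc < alpha and p_nc < p_cov
    else:
        nc_dominant = model_significant and p_nc < alpha
    return GlmResult(
        mirna_id=mirna_id,
        nc_id=nc_id,
        coefficients=coeffs,
        p_values=pvals,
        model_p=model_p,
        model_significant=model_significant,
        nc_dominant=nc_dominant,
    )


def confirm(
    records: pd.DataFrame,
    cm: CountMatrix,
    intake: IntakeTable,
    metadata: pd.DataFrame,
    transform: str = "log2",
) -> tuple[pd.DataFrame, dict]:
    """Fit the confirmatory model for every screen-significant record.

    Subjects from all diet groups are pooled.  Records referencing a
    miRNA or NC absent from the data are skipped with a warning.
    Returns the per-pair results table and a summary with counts of
    model-significant and NC-dominant pairs.
    """
    if transform not in {"log2", "raw"}:
        raise ValueError(f"unknown expression transform {transform!r}")
    norm = cm.normalized
    values = intake.analysis_values()
    meta = metadata.set_index("subject_id") if "subject_id" in metadata.columns else metadata
    subjects = [s for s in norm.columns if s in values.index and s in meta.index]
    cov = meta.loc[subjects, ["age", "sex", "bmi"]]

    rows = []
    n_skipped = 0
    for rec in records.itertuples(index=False):
        if rec.mirna_id not in norm.index or rec.nc_id not in values.columns:
            logger.warning("skipping pair (%s, %s): absent from data", rec.mirna_id, rec.nc_id)
            n_skipped += 1
            continue
        expr = norm.loc[rec.mirna_id, subjects].to_numpy(dtype=float)
        y = np.log2(expr + 1.0) if transform == "log2" else expr
        res = fit_glm(
            y,
            cov,
            values.loc[subjects, rec.nc_id].to_numpy(dtype=float),
            mirna_id=rec.mirna_id,
            nc_id=rec.nc_id,
        )
        rows.append(res.as_row())
    table = pd.DataFrame(rows)
    summary = {
        "n_fitted": len(table),
        "n_skipped": n_skipped,
        "n_model_significant": int(table["model_significant"].sum()) if len(table) else 0,
        "n_nc_dominant": int(table["nc_dominant"].sum()) if len(table) else 0,
    }
    return table, summary
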