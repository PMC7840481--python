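"""Target-gene scoring and logistic gene-set enrichment.

Differential-expression evidence for each miRNA is pushed onto its
annotated target genes: a miRNA contributes the weight

    w = -sign(log2FC) * (-log10 adjusted_p)

to every gene it targets (the sign is flipped because an up-regulated
miRNA represses its targets), and a gene's score is the sum over the
miRNAs targeting it.  Each gene set is then tested by a logistic
regression of the membership indicator on the gene score over the
whole scored-gene universe; the slope, its Wald p-value, and BH
adjustment across sets are reported.  A set is *retained* when its
adjusted p is below 0.05, the absolute slope exceeds 0.5, and at least
two scored target genes fall in the set.  The analysis is run
separately on positively and negatively regulated miRNA subsets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .de import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_id: str
    coefficient: float
    p_value: float
    adjusted_p: float
    n_target_genes_in_set: int
    retained: bool
    separable: bool = False


def merge_target_annotations(*tables: pd.DataFrame) -> pd.DataFrame:
    """Union of (mirna_id, gene_id) annotations from several sources."""
    merged = pd.concat(tables, ignore_index=True)
    for col in ("mirna_id", "gene_id"):
        if col not in merged.columns:
            raise ValueError(f"target annotation missing column {col!r}")
    return merged.drop_duplicates(["mirna_id", "gene_id"]).reset_index(drop=True)


def gene_scores(de: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """Aggregate DE evidence onto target genes.

    ``de`` needs columns mirna_id, log2fc and adjusted_p; ``targets``
    needs mirna_id and gene_id.  Genes with no targeting miRNA in the
    DE table are absent from the output.
    """
    de = de.dropna(subset=["log2fc", "adjusted_p"]).copy()
    if (de["adjusted_p"] == 0).any():
        logger.warning("capping %d zero p-values at machine minimum",
                       int((de["adjusted_p"] == 0).sum()))
        de.loc[de["adjusted_p"] == 0, "adjusted_p"] = np.finfo(float).tiny
    de["weight"] = -np.sign(de["log2fc"]) * (-np.log10(de["adjusted_p"]))
    merged = targets.merge(de[["mirna_id", "weight"]], on="mirna_id", how="inner")
    grouped = merged.groupby("gene_id", sort=True)
    out = grouped.agg(
        score=("weight", "sum"),
        n_supporting_mirnas=("mirna_id", "nunique"),
    ).reset_index()
    return out


def _ridge_logistic(y: np.ndarray, x: np.ndarray, lam: float = 1e-3) -> float:
    """Newton-iterated ridge-penalized logistic slope (separation fallback)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(100):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - lam * beta
        hess = (X * W[:, None]).T @ X + lam * np.eye(2)
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.max(np.abs(step)) < 1e-10:
            break
    return float(beta[1])


def logistic_gsa(
    scores: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    alpha: float = 0.05,
    coef_threshold: float = 0.5,
    min_targets: int = 2,
) -> pd.DataFrame:
    """Logistic-regression enrichment of gene sets against gene scores.

    Sets with fewer than two scored member genes are reported untested
    (NaN statistics, never retained).  Perfect separation triggers a
    ridge-penalized fallback: the slope is reported, the p-value is
    undefined and the set is flagged ``separable``.
    """
    if len(scores) < 2:
        raise ValueError("need >= 2 scored genes for enrichment")
    universe = scores["gene_id"].to_numpy()
    x = scores["score"].to_numpy(dtype=float)
    rows = []
    for set_id, members in gene_sets.items():
        member_set = set(members)
        y = np.isin(universe, list(member_set)).astype(float)
        n_in = int(y.sum())
        if n_in < min_targets or n_in == len(universe):
            rows.append(
                EnrichmentResult(set_id, np.nan, np.nan, np.nan, n_in, False)
            )
            continue
        coef, p, separable = _fit_membership(y, x)
        rows.append(EnrichmentResult(set_id, coef, p, np.nan, n_in, False, separable))
    table = pd.DataFrame([vars(r) for r in rows])
    tested = table["p_value"].notna().to_numpy()
    adj = np.full(len(table), np.nan)
    if tested.any():
        adj[tested] = bh_adjust(table.loc[tested, "p_value"].to_numpy())
    table["adjusted_p"] = adj
    table["retained"] = (
        tested
        & (table["adjusted_p"] < alpha)
        & (table["coefficient"].abs() > coef_threshold)
        & (table["n_target_genes_in_set"] >= min_targets)
    )
    return table


def _fit_membership(y: np.ndarray, x: np.ndarray) -> tuple[float, float, bool]:
    # with one continuous predictor, perfect separation is exactly a
    # non-overlap of the member and non-member score ranges
    if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
        logger.warning("perfect separation in logistic GSA; penalized fallback")
        return _ridge_logistic(y, x), np.nan, True
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.isfinite(res.bse).all() or np.abs(res.params[1]) > 1e3:
            raise np.linalg.LinAlgError("unstable fit")
        return float(res.params[1]), float(res.pvalues[1]), False
    except Exception:
        logger.warning("perfect separation in logistic GSA; penalized fallback")
        return _ridge_logistic(y, x), np.nan, True


def enrich_by_direction(
    de: pd.DataFrame,
    targets: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    direction: str = "both",
    **kwargs,
) -> pd.DataFrame:
    """Run the enrichment on the up-regulated and/or down-regulated miRNA subset.

    ``positive`` keeps miRNAs with log2FC > 0 (up in high-intake
    subjects, i.e. NC-correlated), ``negative`` keeps log2FC < 0, and
    ``both`` concatenates the two runs with a ``direction`` column.
    """
    if direction not in {"positive", "negative", "both"}:
        raise ValueError(f"unknown direction {direction!r}")
    directions = ["positive", "negative"] if direction == "both" else [direction]
    out = []
    for d in directions:
        subset = de[de["log2fc"] > 0] if d == "positive" else de[de["log2fc"] < 0]
        if subset.empty:
            continue
        scores = gene_scores(subset, targets)
        if len(scores) < 2:
            logger.warning("direction %s: fewer than two scored genes; skipped", d)
            continue
        table = logistic_gsa(scores, gene_sets, **kwargs)
        table.insert(0, "direction", d)
        out.append(table)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)


def top_sets(table: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Top-``k`` retained-or-nominal sets per direction, ranked by p-value."""
    if table.empty:
        return table
    cols = ["direction"] if "direction" in table.columns else []
    return (
        table.dropna(subset=["p_value"])
        .sort_values([*cols, "p_value"])
        .groupby(cols, sort=False)
        .head(k)
        .reset_index(drop=True)
        if cols
        else table.dropna(subset=["p_value"]).sort_values("p_value").head(k).reset_index(drop=True)
    )
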