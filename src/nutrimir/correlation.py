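"""Diet-stratified Spearman screen of NC–miRNA associations.

For every (analysis-set miRNA, NC) pair the screen computes a Spearman
rank correlation within each diet group separately, then applies three
filters: *coherence* (all per-group coefficients share one strict
sign), a minimum number of groups with p < 0.05 (default two), and an
absolute average rho above 0.3.  Surviving pairs are classified by
trend: whether |rho| strictly increases or decreases along the
omnivore -> vegetarian -> vegan order.

The Spearman p-value uses the t approximation
``t = rho * sqrt((n - 2) / (1 - rho^2))`` on n - 2 degrees of freedom,
matching the common Hmisc/rcorr behaviour at all sample sizes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DIET_GROUPS
from .intake import IntakeTable
from .normalization import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    rho_threshold: float = 0.3
    p_threshold: float = 0.05
    min_sig_groups: int = 2
    group_order: tuple[str, ...] = DIET_GROUPS
    #: apply rho_threshold to the |average rho| ("average") or to every
    #: group's |rho| ("per_group")
    rho_scope: str = "average"

    def validate(self) -> None:
        if not 0 < self.rho_threshold < 1:
            raise ValueError(f"rho_threshold must be in (0, 1), got {self.rho_threshold}")
        if not 0 < self.p_threshold < 1:
            raise ValueError(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        if not 1 <= self.min_sig_groups <= len(self.group_order):
            raise ValueError(
                f"min_sig_groups must be in [1, {len(self.group_order)}], "
                f"got {self.min_sig_groups}"
            )
        if self.rho_scope not in {"average", "per_group"}:
            raise ValueError(f"unknown rho_scope {self.rho_scope!r}")


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided t-approximation p for one pair.

    Ties receive mean ranks; constant input raises (the caller flags
    and excludes such records).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need n >= 4 paired observations, got {n}")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant vector: Spearman correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, _t_approx_p(np.array([rho]), n)[0]


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation, elementwise; |rho|=1 -> 0."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return p


def _rank_correlation_block(
    intake_block: np.ndarray, expr_block: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and p between intake columns and miRNA columns.

    Both blocks are subjects x variables for one diet group.  Constant
    columns yield NaN rho/p (flagged upstream).
    """
    n = intake_block.shape[0]
    rx = np.apply_along_axis(stats.rankdata, 0, intake_block)
    ry = np.apply_along_axis(stats.rankdata, 0, expr_block)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean(axis=0)
    sx = np.sqrt((rx**2).sum(axis=0))
    sy = np.sqrt((ry**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx.T @ ry) / np.outer(sx, sy)
    rho[:, sy == 0] = np.nan
    rho[sx == 0, :] = np.nan
    p = _t_approx_p(rho, n)
    p = np.where(np.isnan(rho), np.nan, p)
    return rho, p


@dataclass
class ScreenResult:
    """Correlation records plus screening bookkeeping."""

    records: pd.DataFrame
    groups: tuple[str, ...]
    n_tested: int
    n_dropped_constant: int
    config: ScreenConfig = field(repr=False, default_factory=ScreenConfig)


def screen(
    cm: CountMatrix,
    intake: IntakeTable,
    metadata: pd.DataFrame,
    config: ScreenConfig | None = None,
    analysis_members: list[str] | None = None,
) -> ScreenResult:
    """Run the full diet-stratified correlation screen.

    Produces one record per (miRNA, NC) pair with per-group rho and p,
    the average rho, and the coherence / significance / trend verdicts.
    Pairs involving a constant vector in any group are dropped and
    counted in ``n_dropped_constant``.
    """
    config = config or ScreenConfig()
    config.validate()
    norm = cm.normalized
    if analysis_members is not None:
        norm = norm.loc[analysis_members]
    values = intake.analysis_values()
    meta = metadata.set_index("subject_id") if "subject_id" in metadata.columns else metadata
    common = [s for s in norm.columns if s in values.index and s in meta.index]
    if len(common) < len(norm.columns):
        logger.warning("dropping %d samples without intake/metadata", len(norm.columns) - len(common))
    groups = tuple(config.group_order)
    mirnas = list(norm.index)
    ncs = list(values.columns)
    n_mirna, n_nc = len(mirnas), len(ncs)

    rho_by_group: dict[str, np.ndarray] = {}
    p_by_group: dict[str, np.ndarray] = {}
    for g in groups:
        subjects = [s for s in common if meta.loc[s, "diet_group"] == g]
        if len(subjects) < 4:
            raise ValueError(f"diet group {g!r} has {len(subjects)} subjects; need >= 4")
        rho, p = _rank_correlation_block(
            values.loc[subjects, ncs].to_numpy(dtype=float),
            norm[subjects].T.to_numpy(dtype=float),
        )
        rho_by_group[g] = rho  # nc x mirna
        p_by_group[g] = p

    pair_index = pd.MultiIndex.from_product([ncs, mirnas], names=["nc_id", "mirna_id"])
    records = pd.DataFrame(index=pair_index).reset_index()[["mirna_id", "nc_id"]]
    for g in groups:
        records[f"rho_{g}"] = rho_by_group[g].ravel()
        records[f"p_{g}"] = p_by_group[g].ravel()

    rho_cols = [f"rho_{g}" for g in groups]
    p_cols = [f"p_{g}" for g in groups]
    rho_mat = records[rho_cols].to_numpy()
    p_mat = records[p_cols].to_numpy()

    dropped = np.isnan(rho_mat).any(axis=1)
    n_dropped = int(dropped.sum())
    if n_dropped:
        logger.warning("dropping %d pairs with a constant vector in some group", n_dropped)
    records = records.loc[~dropped].reset_index(drop=True)
    rho_mat = rho_mat[~dropped]
    p_mat = p_mat[~dropped]

    records["average_rho"] = rho_mat.mean(axis=1)
    records["coherent"] = (rho_mat > 0).all(axis=1) | (rho_mat < 0).all(axis=1)
    records["n_sig_groups"] = (p_mat < config.p_threshold).sum(axis=1)
    if config.rho_scope == "average":
        rho_pass = np.abs(records["average_rho"].to_numpy()) > config.rho_threshold
    else:
        rho_pass = (np.abs(rho_mat) > config.rho_threshold).all(axis=1)
    records["significant"] = (
        records["coherent"]
        & (records["n_sig_groups"] >= config.min_sig_groups)
        & rho_pass
    )
    records["trend"] = [
        classify_trend(row, groups) for row in np.abs(rho_mat)
    ]
    return ScreenResult(
        records=records,
        groups=groups,
        n_tested=n_mirna * n_nc,
        n_dropped_constant=n_dropped,
        config=config,
    )


def classify_trend(abs_rho, group_order=None) -> str:
    """Progressive-trend label from |rho| along the diet-group order.

    ``increasing`` if strictly increasing along the order,
    ``decreasing`` if strictly decreasing, otherwise ``none`` (any tie
    breaks strictness).  Accepts either a vector of |rho| already in
    order, or a mapping group -> rho with ``group_order`` giving the
    order.
    """
    if isinstance(abs_rho, dict):
        if group_order is None:
            raise ValueError("group_order required with a mapping input")
        missing = [g for g in group_order if g not in abs_rho]
        if missing:
            raise ValueError(f"missing groups in record: {missing}")
        vals = np.abs([abs_rho[g] for g in group_order])
    else:
        vals = np.abs(np.asarray(abs_rho, dtype=float))
    if np.isnan(vals).any():
        raise ValueError("trend undefined with missing rho values")
    diffs = np.diff(vals)
    if (diffs > 0).all():
        return "increasing"
    if (diffs < 0).all():
        return "decreasing"
    return "none"


def cohort_checks(metadata: pd.DataFrame, intake: IntakeTable | None = None) -> dict:
    """Baseline-comparability tests across diet groups.

    Chi-square for sex x group and BMI-class x group, Kruskal–Wallis
    for age, and pairwise two-sided Wilcoxon rank-sum (Mann–Whitney)
    tests for BMI.  Groups with fewer than two subjects cause the
    affected test to be skipped with a warning.
    """
    meta = metadata.reset_index() if "subject_id" not in metadata.columns else metadata
    groups = sorted(meta["diet_group"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 diet groups for cohort checks")
    sizes = meta.groupby("diet_group").size()
    report: dict = {"group_sizes": sizes.to_dict(), "skipped": []}
    usable = [g for g in groups if sizes[g] >= 2]
    if len(usable) < len(groups):
        skipped = sorted(set(groups) - set(usable))
        logger.warning("groups too small for cohort checks: %s", skipped)
        report["skipped"] = skipped

    sex_tab = pd.crosstab(meta["sex"], meta["diet_group"])
    chi2, p, _, _ = stats.chi2_contingency(sex_tab)
    report["sex_chi2"] = {"statistic": float(chi2), "p_value": float(p)}

    bmi_tab = pd.crosstab(meta["bmi_class"], meta["diet_group"])
    if bmi_tab.shape[0] > 1:
        chi2, p, _, _ = stats.chi2_contingency(bmi_tab)
        report["bmi_class_chi2"] = {"statistic": float(chi2), "p_value": float(p)}

    age_by_group = [meta.loc[meta["diet_group"] == g, "age"] for g in usable]
    if len(age_by_group) >= 2:
        stat, p = stats.kruskal(*age_by_group)
        report["age_kruskal"] = {"statistic": float(stat), "p_value": float(p)}

    pairwise = {}
    for g1, g2 in itertools.combinations(usable, 2):
        x = meta.loc[meta["diet_group"] == g1, "bmi"]
        y = meta.loc[meta["diet_group"] == g2, "bmi"]
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        pairwise[f"{g1}_vs_{g2}"] = {"statistic": float(stat), "p_value": float(p)}
    report["bmi_wilcoxon_pairwise"] = pairwise
    return report
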