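"""Median-of-ratios count normalization and detectability filtering.

Raw small RNA-seq counts are scaled by per-sample size factors computed
with the median-of-ratios method: each miRNA with strictly positive
counts in every sample contributes the ratio of its count to its
geometric mean across samples, and a sample's size factor is the median
of those ratios.  Normalized counts (raw / size factor) feed two
filters: a per-sample detectability call (normalized reads strictly
greater than a threshold, default 15) and the analysis-set rule used by
the correlation screen (median normalized reads above the threshold in
at least one diet group).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DETECTABILITY_THRESHOLD


@dataclass
class CountMatrix:
    """miRNA x sample counts with optional size factors.

    ``counts`` rows are miRNAs, columns are samples.  ``normalized`` is
    computed lazily as raw counts divided column-wise by size factors.
    """

    counts: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.size_factors is not None:
            sf = self.size_factors
            if not sf.index.equals(self.counts.columns):
                sf = sf.reindex(self.counts.columns)
                if sf.isna().any():
                    raise ValueError("size_factors index does not match sample ids")
                self.size_factors = sf
            if not (self.size_factors > 0).all():
                raise ValueError("size_factors must be > 0")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors not computed; call size_factors() first")
        return self.counts.div(self.size_factors, axis=1)


@dataclass
class FilterReport:
    """Outcome of the detectability and/or analysis-set filters."""

    n_input_mirnas: int
    n_detectable: int | None = None
    n_analysis_set: int | None = None
    detectable: pd.DataFrame | None = None  # miRNA x sample booleans
    analysis_members: list[str] | None = None
    group_medians: pd.DataFrame | None = None  # miRNA x group

    def __post_init__(self) -> None:
        for n in (self.n_detectable, self.n_analysis_set):
            if n is not None and n > self.n_input_mirnas:
                raise ValueError("filter counts cannot exceed the input miRNA count")


def size_factors(cm: CountMatrix, reference: str = "all-positive") -> CountMatrix:
    """Compute median-of-ratios size factors and return a new matrix.

    Parameters
    ----------
    reference : "all-positive" restricts the reference set to miRNAs
        with strictly positive counts in every sample (the geometric
        mean is undefined through zeros); "poscounts" falls back to
        geometric means over the positive entries only, for sparse
        matrices where no miRNA is everywhere positive.
    """
    counts = cm.counts.to_numpy(dtype=float)
    n_mirna, n_sample = counts.shape
    if n_sample < 2:
        raise ValueError("size factor estimation needs >= 2 samples")
    if reference not in {"all-positive", "poscounts"}:
        raise ValueError(f"unknown reference mode {reference!r}")

    all_pos = (counts > 0).all(axis=1)
    if reference == "all-positive":
        if not all_pos.any():
            raise ValueError(
                "no miRNA has positive counts in every sample; "
                "retry with reference='poscounts' (pseudo-reference fallback)"
            )
        ref_rows = counts[all_pos]
        gm = np.exp(np.log(ref_rows).mean(axis=1))
        # linear-scale median of ratios; even reference sets use the
        # midpoint of the two central order statistics
        sf = np.median(ref_rows / gm[:, None], axis=0)
    else:
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(counts), np.nan)
        log_gm = np.nanmean(logc, axis=1)
        usable = np.isfinite(log_gm)
        if not usable.any():
            raise ValueError("all-zero count matrix; size factors undefined")
        ratios = np.exp(logc[usable] - log_gm[usable, None])
        sf = np.nanmedian(ratios, axis=0)
        if not np.isfinite(sf).all() or (sf <= 0).any():
            raise ValueError("poscounts fallback produced undefined size factors")
    return CountMatrix(
        counts=cm.counts.copy(),
        size_factors=pd.Series(sf, index=cm.counts.columns, name="size_factor"),
    )


def detectability_filter(
    cm: CountMatrix, threshold: float = DETECTABILITY_THRESHOLD
) -> FilterReport:
    """Per-sample detectability: normalized reads strictly above ``threshold``.

    A miRNA counts as detectable overall if it is detectable in at
    least one sample.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    norm = cm.normalized  # raises if size factors absent
    flags = norm > threshold
    return FilterReport(
        n_input_mirnas=len(cm.counts),
        n_detectable=int(flags.any(axis=1).sum()),
        detectable=flags,
    )


def analysis_set(
    cm: CountMatrix,
    groups: pd.Series,
    threshold: float = DETECTABILITY_THRESHOLD,
) -> FilterReport:
    """Keep miRNAs whose median normalized count exceeds ``threshold`` in
    at least one diet group.

    ``groups`` maps sample id -> group label and must cover every
    sample; medians use the midpoint convention for even group sizes.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    norm = cm.normalized
    groups = groups.reindex(norm.columns)
    if groups.isna().any():
        missing = list(norm.columns[groups.isna()])[:5]
        raise ValueError(f"samples without a group assignment: {missing}")
    medians = {}
    for g, cols in norm.T.groupby(groups, sort=True).groups.items():
        if len(cols) == 0:
            raise ValueError(f"empty diet group {g!r}")
        medians[g] = norm[list(cols)].median(axis=1)
    med = pd.DataFrame(medians)
    keep = (med > threshold).any(axis=1)
    return FilterReport(
        n_input_mirnas=len(cm.counts),
        n_analysis_set=int(keep.sum()),
        analysis_members=list(med.index[keep]),
        group_medians=med,
    )
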