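"""End-to-end orchestration of the synthetic-cohort analysis pipeline.

One call chains every stage on a synthetic cohort: generation,
median-of-ratios normalization, analysis-set filtering, the
diet-stratified correlation screen, GLM confirmation, per-NC
differential expression for the NCs with most significant
correlations, and the network / report exports.  All outputs are
deterministic functions of the cohort spec (including its seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .constants import nc_class
from .correlation import ScreenConfig, cohort_checks, screen
from .de import de_analysis
from .glm import confirm
from .network import build_network, summarize_run, write_network, write_report
from .normalization import analysis_set, size_factors
from .simulate import CohortSpec, generate_cohort


@dataclass
class PipelineResult:
    counts: object
    metadata: pd.DataFrame
    intake: object
    ground_truth: dict
    filter_report: object
    screen_result: object
    glm_table: pd.DataFrame
    glm_summary: dict
    de_tables: dict[str, pd.DataFrame]
    report: dict
    checks: dict = field(default_factory=dict)


def run_pipeline(
    spec: CohortSpec,
    config: ScreenConfig | None = None,
    outdir: str | Path | None = None,
    n_de_ncs: int = 2,
    threshold: float = 15.0,
) -> PipelineResult:
    """Run every stage on a synthetic cohort; optionally write all outputs.

    ``n_de_ncs`` limits the differential-expression stage to the NCs
    with the largest number of screen-significant correlations (the
    compounds a study would follow up), keeping run time proportionate.
    """
    config = config or ScreenConfig(group_order=spec.groups)
    cm, metadata, intake, truth = generate_cohort(spec)
    cm = size_factors(cm)
    groups = metadata.set_index("subject_id")["diet_group"]
    freport = analysis_set(cm, groups, threshold=threshold)
    sres = screen(cm, intake, metadata, config, analysis_members=freport.analysis_members)
    records = sres.records
    sig = records[records["significant"]]
    glm_table, glm_summary = confirm(sig, cm, intake, metadata)

    de_tables: dict[str, pd.DataFrame] = {}
    if n_de_ncs > 0 and len(sig):
        top_ncs = sig["nc_id"].value_counts().head(n_de_ncs).index
        for nc in top_ncs:
            de_tables[str(nc)] = de_analysis(
                cm, intake, metadata, str(nc),
                mirna_ids=sorted(sig.loc[sig["nc_id"] == nc, "mirna_id"].unique()),
                threshold=threshold,
            )

    nc_classes = {nc: nc_class(nc) for nc in intake.analysis_values().columns}
    net = build_network(sig, glm_table if len(glm_table) else None, nc_classes)

    trend_counts = sig["trend"].value_counts().to_dict() if len(sig) else {}
    sign_counts = {}
    for nc, sub in sig.groupby("nc_id"):
        sign_counts[str(nc)] = {
            "positive": int((sub["average_rho"] > 0).sum()),
            "negative": int((sub["average_rho"] < 0).sum()),
            "total": int(len(sub)),
        }
    stages = {
        "n_tested": int(sres.n_tested),
        "n_coherent": int(records["coherent"].sum()),
        "n_significant": int(len(sig)),
        "n_model_significant": glm_summary["n_model_significant"],
        "n_nc_dominant": glm_summary["n_nc_dominant"],
        "trend_counts": {str(k): int(v) for k, v in trend_counts.items()},
        "sign_counts": sign_counts,
        "de_significant": {
            nc: int(t["significant"].sum()) for nc, t in de_tables.items()
        },
        "n_analysis_set": int(freport.n_analysis_set),
        "n_dropped_constant": int(sres.n_dropped_constant),
    }
    report = summarize_run(
        stages,
        config={**asdict(config), "threshold": threshold, "n_per_group": spec.n_per_group},
        seed=spec.seed,
    )
    report["n_analysis_set"] = stages["n_analysis_set"]
    checks = cohort_checks(metadata, intake)
    report["cohort_checks"] = {
        k: v for k, v in checks.items() if k in ("sex_chi2", "age_kruskal")
    }

    result = PipelineResult(
        counts=cm,
        metadata=metadata,
        intake=intake,
        ground_truth=truth,
        filter_report=freport,
        screen_result=sres,
        glm_table=glm_table,
        glm_summary=glm_summary,
        de_tables=de_tables,
        report=report,
        checks=checks,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_counts(result.counts, outdir / "counts_raw.tsv")
    io.write_normalized(result.counts, outdir / "counts_normalized.tsv")
    io.write_size_factors(result.counts, outdir / "size_factors.tsv")
    io.write_metadata(result.metadata, outdir / "metadata.tsv")
    io.write_intake(result.intake, outdir / "intake.tsv")
    io.write_table(result.screen_result.records, outdir / "correlations.tsv")
    if len(result.glm_table):
        io.write_table(result.glm_table, outdir / "glm_results.tsv")
    for nc, table in result.de_tables.items():
        io.write_table(table, outdir / f"de_{nc}.tsv")
    sig = result.screen_result.records.query("significant")
    nc_classes = {nc: nc_class(nc) for nc in result.intake.analysis_values().columns}
    net = build_network(sig, result.glm_table if len(result.glm_table) else None, nc_classes)
    write_network(net, outdir)
    write_report(result.report, outdir)
    (outdir / "ground_truth.json").write_text(
        __import__("json").dumps(result.ground_truth, indent=2, sort_keys=True)
    )
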