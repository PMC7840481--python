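"""Bipartite miRNA–NC association network and run-level summary.

Every screen-significant pair becomes an edge between a miRNA node and
an NC node.  Edge attributes carry the average Spearman rho (signed,
for colouring), its absolute value (for width), the trend label, and
whether the pair was confirmed by the covariate-adjusted model; a
confirmed pair gets a solid edge, an unconfirmed one a dashed edge.
NC nodes carry their compound class (lipid-related, micro-element,
vitamin-related); node degree is stored on every node.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd


def build_network(
    records: pd.DataFrame,
    glm_results: pd.DataFrame | None,
    nc_classes: dict[str, str],
) -> nx.Graph:
    """Assemble the bipartite association network from significant records.

    ``records`` must already be restricted to screen-significant pairs
    (columns mirna_id, nc_id, average_rho, trend).  ``glm_results``
    (columns mirna_id, nc_id, nc_dominant), if given, marks confirmed
    edges.  Every NC appearing in the records must have a class in
    ``nc_classes``.
    """
    g = nx.Graph()
    if records.empty:
        return g
    confirmed: set[tuple[str, str]] = set()
    if glm_results is not None and len(glm_results):
        dom = glm_results[glm_results["nc_dominant"]]
        confirmed = set(zip(dom["mirna_id"], dom["nc_id"]))
    for rec in records.itertuples(index=False):
        if rec.nc_id not in nc_classes:
            raise ValueError(f"NC {rec.nc_id!r} has no assigned class")
        g.add_node(rec.mirna_id, kind="mirna", nc_class="none")
        g.add_node(rec.nc_id, kind="nc", nc_class=nc_classes[rec.nc_id])
        is_conf = (rec.mirna_id, rec.nc_id) in confirmed
        g.add_edge(
            rec.mirna_id,
            rec.nc_id,
            average_rho=float(rec.average_rho),
            abs_rho=abs(float(rec.average_rho)),
            width=abs(float(rec.average_rho)),
            glm_confirmed=bool(is_conf),
            style="solid" if is_conf else "dashed",
            trend=str(getattr(rec, "trend", "none")),
        )
    degrees = dict(g.degree())
    nx.set_node_attributes(g, degrees, "degree")
    return g


def write_network(g: nx.Graph, outdir: str | Path, stem: str = "network") -> dict[str, Path]:
    """Write GraphML plus node/edge TSVs; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "graphml": outdir / f"{stem}.graphml",
        "nodes": outdir / f"{stem}_nodes.tsv",
        "edges": outdir / f"{stem}_edges.tsv",
    }
    nx.write_graphml(g, paths["graphml"])
    nodes = pd.DataFrame(
        [{"id": n, **attrs} for n, attrs in sorted(g.nodes(data=True))]
    )
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, **attrs}
            for u, v, attrs in sorted(g.edges(data=True))
        ]
    )
    nodes.to_csv(paths["nodes"], sep="\t", index=False)
    edges.to_csv(paths["edges"], sep="\t", index=False)
    return paths


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def percent(part: int | float, total: int | float) -> float:
    """Share of ``part`` in ``total`` as a percentage, one decimal."""
    if total == 0:
        raise ValueError("total must be non-zero")
    return round(100.0 * part / total, 1)


def summarize_run(stages: dict, config: dict | None = None, seed: int | None = None) -> dict:
    """Run-level funnel summary across pipeline stages.

    ``stages`` may provide any of: n_tested, n_coherent,
    n_significant, n_model_significant, n_nc_dominant, trend_counts
    (mapping), de_significant (mapping nc -> count), retained_sets.
    Missing stages are reported explicitly under ``missing``.
    """
    expected = [
        "n_tested",
        "n_coherent",
        "n_significant",
        "n_model_significant",
        "n_nc_dominant",
    ]
    report: dict = {
        "funnel": {k: stages[k] for k in expected if k in stages},
        "missing": [k for k in expected if k not in stages],
        "config": config or {},
        "seed": seed,
    }
    funnel = report["funnel"]
    chain = [funnel[k] for k in expected if k in funnel]
    report["funnel_monotone"] = all(a >= b for a, b in zip(chain, chain[1:]))
    if "n_significant" in funnel and funnel["n_significant"]:
        n_sig = funnel["n_significant"]
        if "trend_counts" in stages:
            tc = stages["trend_counts"]
            n_trending = sum(v for k, v in tc.items() if k != "none")
            report["trend"] = {
                "counts": tc,
                "n_progressive": n_trending,
                "percent_progressive": percent(n_trending, n_sig),
            }
        if "n_model_significant" in funnel:
            report["percent_model_significant"] = percent(
                funnel["n_model_significant"], n_sig
            )
    for key in ("de_significant", "retained_sets", "sign_counts"):
        if key in stages:
            report[key] = stages[key]
    if "sign_counts" in stages:
        sc = stages["sign_counts"]
        report["sign_percent"] = {
            nc: percent(v.get("positive", 0), v.get("total", 0))
            for nc, v in sc.items()
            if v.get("total")
        }
    try:
        from importlib.metadata import version

        report["versions"] = {"nutrimir": version("nutrimir")}
    except Exception:
        report["versions"] = {}
    return report


def write_report(report: dict, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    txt = outdir / "report.txt"
    lines = ["nutrimir run summary", "===================="]
    for k, v in report.get("funnel", {}).items():
        lines.append(f"{k:24s} {v}")
    if "trend" in report:
        lines.append(
            f"progressive trends       {report['trend']['n_progressive']} "
            f"({report['trend']['percent_progressive']}%)"
        )
    if report.get("missing"):
        lines.append(f"missing stages: {', '.join(report['missing'])}")
    txt.write_text("\n".join(lines) + "\n")
    return path
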