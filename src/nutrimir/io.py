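"""Readers and writers for the pipeline's plain-text formats.

Counts travel as GEO-style TSV (rows = miRNAs, first column the miRNA
id, one column per sample); metadata, intake, size-factor, target and
result tables as TSV; gene-set libraries as GMT (set name, description,
then member genes, tab-separated).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .intake import IntakeTable
from .normalization import CountMatrix

_FLOAT_FMT = "%.10g"


def read_counts(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(counts=df)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    df = cm.counts.copy()
    df.index.name = "mirna_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_normalized(cm: CountMatrix, path: str | Path) -> None:
    df = cm.normalized.copy()
    df.index.name = "mirna_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_size_factors(cm: CountMatrix, path: str | Path) -> None:
    if cm.size_factors is None:
        raise ValueError("size factors not computed")
    sf = cm.size_factors.rename_axis("sample_id").reset_index()
    sf.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_intake(path: str | Path) -> IntakeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "energy_kcal_day" not in df.columns:
        raise ValueError("intake table missing energy_kcal_day column")
    energy = df.pop("energy_kcal_day")
    return IntakeTable(raw=df.copy(), energy_kcal_day=energy, normalized=df.copy())


def write_intake(intake: IntakeTable, path: str | Path) -> None:
    """Write the kcal-normalized intake table plus the energy column."""
    df = intake.analysis_values().copy()
    df["energy_kcal_day"] = intake.energy_kcal_day.loc[df.index]
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_ffq(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ffq(ffq: pd.DataFrame, path: str | Path) -> None:
    ffq.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_composition(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_composition(comp: pd.DataFrame, path: str | Path) -> None:
    comp.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_targets(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("mirna_id", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"target annotation missing column {col!r}")
    return df


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set library into {set_id: [genes...]}."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *genes = fields
        sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
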