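"""TSV table dialects, configuration files and run manifests.

All tables move as tab-separated text with ``NA`` for missing values (a
not-detected marker distinct from zero).  Each table kind has a dialect
naming its required columns; reading validates the header and reports
malformed rows with line numbers, and ``read_table(write_table(x))``
round-trips losslessly (floats are written with full repr precision).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

ND_TOKEN = "NA"


@dataclass(frozen=True)
class TableDialect:
    name: str
    required_columns: tuple[str, ...]
    int_columns: tuple[str, ...] = ()


DIALECTS: dict[str, TableDialect] = {
    d.name: d
    for d in [
        TableDialect(
            "peptide",
            (
                "protein_id",
                "peptide_id",
                "condition_id",
                "orientation",
                "replicate",
                "heavy_intensity",
                "light_intensity",
            ),
            ("replicate",),
        ),
        TableDialect(
            "oriented_peptide",
            (
                "protein_id",
                "peptide_id",
                "condition_id",
                "orientation",
                "replicate",
                "tagged_intensity",
                "wildtype_intensity",
            ),
            ("replicate",),
        ),
        TableDialect("bulk", ("protein_id", "orientation", "ratio")),
        TableDialect(
            "abundance",
            (
                "protein_id",
                "cell_line",
                "condition_id",
                "replicate",
                "log2_abundance",
                "n_unique_peptides",
            ),
            ("replicate", "n_unique_peptides"),
        ),
        TableDialect("ground_truth", ("protein_id",)),
        TableDialect(
            "specificity_calls",
            (
                "protein_id",
                "condition_id",
                "mean_ratio_forward",
                "mean_ratio_swap",
                "bayes_factor",
                "in_ellipse",
                "is_specific",
                "category",
            ),
        ),
        TableDialect(
            "contrasts",
            ("protein_id", "ko_line", "condition_id", "log2fc", "p_value"),
        ),
        TableDialect(
            "profiles",
            ("protein_id", "ko_line", "avg_log2fc", "n_sig_conditions"),
        ),
    ]
}


def write_table(table: pd.DataFrame, path: str | Path, dialect: str | None = None) -> None:
    """Write a table as TSV with ``NA`` for missing entries."""
    if dialect is not None:
        _validate_columns(table.columns, DIALECTS[dialect], str(path))
    table.to_csv(path, sep="\t", index=False, na_rep=ND_TOKEN)


def _validate_columns(columns, dialect: TableDialect, where: str) -> None:
    missing = [c for c in dialect.required_columns if c not in set(columns)]
    if missing:
        raise ValueError(
            f"{where}: missing required column(s) {missing} for "
            f"dialect {dialect.name!r}"
        )


def read_table(path: str | Path, dialect: str) -> pd.DataFrame:
    """Read a TSV table, validating against a named dialect.

    ``NA`` parses as missing (never as zero); malformed rows are reported
    with their line number.
    """
    d = DIALECTS[dialect]
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            na_values=[ND_TOKEN],
            keep_default_na=False,
            on_bad_lines="error",
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV — {exc}") from exc
    _validate_columns(df.columns, d, str(path))
    for col in d.int_columns:
        if col in df.columns and df[col].notna().all():
            df[col] = df[col].astype(int)
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Condition x protein matrix TSV; first column is the condition id."""
    matrix.to_csv(path, sep="\t", index=True, index_label="condition_id", na_rep=ND_TOKEN)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", na_values=[ND_TOKEN], keep_default_na=False
    )
    if "condition_id" not in df.columns:
        raise ValueError(f"{path}: missing required column(s) ['condition_id']")
    return df.set_index("condition_id")


def read_config(path: str | Path) -> dict[str, Any]:
    """Plain-text key-value (YAML subset) configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return dict(data)


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    stages: list[str] = field(default_factory=list)
    thresholds: dict[str, Any] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    extra: dict[str, Any] = field(default_factory=dict)

    def record_stage(self, name: str, rows: int, output: str | None = None) -> None:
        self.stages.append(name)
        self.row_counts[name] = int(rows)
        if output is not None:
            self.outputs[name] = str(output)

    def write(self, path: str | Path) -> None:
        payload = {
            "stages": self.stages,
            "thresholds": self.thresholds,
            "seeds": self.seeds,
            "row_counts": self.row_counts,
            "outputs": self.outputs,
            **self.extra,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_manifest(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)
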