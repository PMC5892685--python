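"""Plain-text readers and writers for the package's tabular formats.

Cohort tables and deficit panels are TSV with one row per subject (NA for
missing deficit values); beta matrices are CSV with CpG IDs as row keys and
sample IDs as the header; weight/threshold tables are 3-column TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_cohort", "write_cohort",
    "read_betas", "write_betas",
    "read_deficits", "write_deficits",
    "read_weight_table", "write_weight_table",
    "read_threshold_table", "write_threshold_table",
    "write_table",
]


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index_label="subject_id")


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")


def write_betas(betas: pd.DataFrame, path: str | Path) -> None:
    betas.to_csv(path, index_label="cpg_id")


def read_betas(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="cpg_id")


def write_deficits(deficits: pd.DataFrame, path: str | Path) -> None:
    deficits.to_csv(path, sep="\t", index_label="subject_id", na_rep="NA")


def read_deficits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id", na_values=["NA"])


def write_weight_table(weights: pd.DataFrame, path: str | Path) -> None:
    weights.to_csv(path, sep="\t", index_label="cpg_id")


def read_weight_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cpg_id")


write_threshold_table = write_weight_table
read_threshold_table = read_weight_table


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV without the positional index."""
    table.to_csv(path, sep="\t", index=False)
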