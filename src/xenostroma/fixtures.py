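"""Packaged in-study fixtures: the TMA staging/progression contingency
table and the proteomic fraction species-annotation counts."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

STAGES = ("2a", "2b", "3a", "3b", "4")


@dataclass
class CohortContingency:
    """Staging x (PSA progression, clinical progression) patient counts."""

    table: pd.DataFrame  # columns psa_progression, clinical_progression, stage, count

    def cell(self, psa: str, clinical: str, stage: str) -> int:
        sel = self.table[(self.table["psa_progression"] == psa) &
                         (self.table["clinical_progression"] == clinical) &
                         (self.table["stage"] == str(stage))]
        if len(sel) != 1:
            raise KeyError(f"no unique cell ({psa}, {clinical}, {stage})")
        return int(sel["count"].iloc[0])

    @property
    def total(self) -> int:
        return int(self.table["count"].sum())

    def marginal(self, column: str, value: str) -> int:
        return int(self.table.loc[self.table[column] == value, "count"].sum())


def _packaged(name: str) -> str:
    return str(resources.files("xenostroma").joinpath(f"data/{name}"))


def parse_cohort_table(path: str | Path | None = None) -> CohortContingency:
    """Load the staging/progression contingency fixture.

    Validates the schema: binary yes/no progression flags, the five
    pathological stages, non-negative integer counts.
    """
    path = path or _packaged("empact_staging.tsv")
    df = pd.read_csv(path, sep="\t", dtype={"stage": str})
    required = {"psa_progression", "clinical_progression", "stage", "count"}
    if set(df.columns) != required:
        raise ValueError(f"malformed cohort table: columns {list(df.columns)}")
    if not set(df["psa_progression"]) <= {"yes", "no"}:
        raise ValueError("psa_progression must be yes/no")
    if not set(df["clinical_progression"]) <= {"yes", "no"}:
        raise ValueError("clinical_progression must be yes/no")
    if not set(df["stage"]) <= set(STAGES):
        raise ValueError("unknown pathological stage")
    if (df["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if df.duplicated(["psa_progression", "clinical_progression", "stage"]).any():
        raise ValueError("duplicate contingency cells")
    return CohortContingency(df)


def load_fraction_counts(path: str | Path | None = None) -> pd.DataFrame:
    """Per-fraction protein species-annotation counts.

    Columns: human_specific, shared, mouse_specific, printed_total (the
    total as printed, which need not equal the category sum) and
    category_sum (computed).
    """
    path = path or _packaged("fraction_species_counts.tsv")
    df = pd.read_csv(path, sep="\t", index_col="fraction")
    for col in ("human_specific", "shared", "mouse_specific", "printed_total"):
        if col not in df.columns:
            raise ValueError(f"malformed fraction-count fixture: missing {col}")
    df["category_sum"] = df[["human_specific", "shared", "mouse_specific"]].sum(axis=1)
    return df
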