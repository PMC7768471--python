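"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODELS = ("BM18like", "LAPC9like")
CONDITIONS = ("intact", "castrated", "replaced")


@dataclass(frozen=True)
class SampleMeta:
    """One PDX sample: which model, which androgen state, which replicate."""

    sample_id: str
    model: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


def design_frame(design: list[SampleMeta]) -> pd.DataFrame:
    keys = {(m.model, m.condition, m.replicate) for m in design}
    if len(keys) != len(design):
        raise ValueError("(model, condition, replicate) must be unique in a design")
    return pd.DataFrame(
        {
            "model": [m.model for m in design],
            "condition": [m.condition for m in design],
            "replicate": [m.replicate for m in design],
        },
        index=pd.Index([m.sample_id for m in design], name="sample_id"),
    )


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts with sample metadata.

    ``counts`` is a genes-by-samples DataFrame; ``meta`` is indexed by
    sample_id with columns model/condition/replicate; ``species`` tags the
    compartment the counts belong to (e.g. ``"human"`` or ``"mouse"``).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    species: str = ""

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        if not self.counts.columns.equals(self.meta.index):
            # allow meta given in any order
            if set(self.counts.columns) != set(self.meta.index):
                raise ValueError("counts columns and meta index must agree")
            self.meta = self.meta.loc[self.counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, mask: pd.Series | np.ndarray | list) -> "CountMatrix":
        cols = self.samples[np.asarray(mask)] if np.asarray(mask).dtype == bool else pd.Index(mask)
        return CountMatrix(self.counts[cols], self.meta.loc[cols], self.species)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class GeneSet:
    """A named gene list with its species and a provenance note."""

    name: str
    members: list[str]
    species: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name}: members must be unique")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass
class OrthologTable:
    """Rows of (mouse_gene, human_gene, confidence in {0, 1})."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["mouse_gene", "human_gene", "confidence"]))

    def __post_init__(self) -> None:
        t = self.table
        if not set(t["confidence"].unique()) <= {0, 1}:
            raise ValueError("confidence must be binary")
        if t.duplicated(["mouse_gene", "human_gene"]).any():
            raise ValueError("ortholog pairs must be unique")

    def confident(self) -> pd.DataFrame:
        return self.table[self.table["confidence"] == 1]

    def __len__(self) -> int:
        return len(self.table)
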