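"""Core in-memory containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Canonical tissue panel: brain regions plus the two blood compartments.
TISSUES = ("PFC", "CRE", "PBMC", "WB", "ACC", "AMY", "HPC", "STR")

#: Required per-sample metadata columns.
META_COLUMNS = ("tissue", "status", "batch", "age", "sex", "ph")


class DataError(ValueError):
    """Raised when input data violates a documented contract."""


class ConfigError(ValueError):
    """Raised when a configuration value is outside its documented domain."""


@dataclass
class ExpressionDataset:
    """A gene-by-sample expression matrix with aligned sample metadata.

    Parameters
    ----------
    expr:
        DataFrame with genes as rows and samples as columns.  May be on
        linear or log2 scale; stages that care (e.g. ``log2_normalise``)
        inspect the value range.
    meta:
        DataFrame indexed by sample id with at least the columns in
        :data:`META_COLUMNS`.  ``status`` is ``"case"``/``"control"``,
        ``batch`` identifies the originating dataset.
    name:
        Free-form identifier, conventionally ``"<tissue>_<dataset>"``.
    """

    expr: pd.DataFrame
    meta: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        if list(self.expr.columns) != list(self.meta.index):
            raise DataError(
                f"dataset {self.name!r}: expression columns and metadata rows "
                "must list the same samples in the same order"
            )
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise DataError(f"dataset {self.name!r}: metadata lacks columns {missing}")

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    @property
    def tissue(self) -> str:
        tissues = self.meta["tissue"].unique()
        if len(tissues) != 1:
            raise DataError(f"dataset {self.name!r} spans several tissues: {list(tissues)}")
        return str(tissues[0])

    def subset_samples(self, samples) -> "ExpressionDataset":
        return ExpressionDataset(
            self.expr.loc[:, samples], self.meta.loc[samples], name=self.name
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(self.expr.copy(), self.meta.copy(), name=self.name)


@dataclass
class MergedTissueMatrix:
    """Column-wise concatenation of same-tissue datasets.

    ``expr`` holds log2 expression (genes x samples); ``batch`` labels each
    sample with its dataset of origin; ``tissue`` is the shared tissue.
    ``deg_genes`` records the DEG union that defined the gene space.
    """

    expr: pd.DataFrame
    batch: pd.Series
    tissue: str
    deg_genes: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if list(self.expr.columns) != list(self.batch.index):
            raise DataError("merged matrix: batch labels must index the sample columns")

    @property
    def n_batches(self) -> int:
        return self.batch.nunique()
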