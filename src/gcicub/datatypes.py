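"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionDataset`: a genes x conditions matrix
of log-scale abundances (log-TPM for RNA-seq, or 6 + log10(a/sum(a)) for
absolute protein/transcript counts) together with a per-condition growth rate
(1/hr) and condition metadata (alignment score, replicate grouping, strain
flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: metadata columns every ExpressionDataset carries (missing ones are filled
#: with permissive defaults on construction)
META_COLUMNS = ("alignment_score", "replicate_group", "is_ale", "is_mutant_or_ko")

SCALE_LOG_TPM = "logTPM"
SCALE_LOG_ABSOLUTE = "log_absolute"


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


def default_meta(condition_ids) -> pd.DataFrame:
    """Permissive metadata: perfect alignment, singleton replicate groups,
    no ALE/mutant flags."""
    idx = pd.Index(condition_ids, name="condition")
    return pd.DataFrame(
        {
            "alignment_score": 100.0,
            "replicate_group": list(idx),
            "is_ale": False,
            "is_mutant_or_ko": False,
        },
        index=idx,
    )


@dataclass
class ExpressionDataset:
    """Genes x conditions log-scale expression with growth rates.

    Parameters
    ----------
    X : pd.DataFrame
        Log-scale abundances, rows indexed by gene id, columns by condition id.
    growth : pd.Series
        Growth rate in 1/hr per condition, indexed like ``X.columns``.
        NaN marks an unknown growth rate (removed by condition filtering).
    meta : pd.DataFrame
        Per-condition metadata with columns ``alignment_score``,
        ``replicate_group``, ``is_ale``, ``is_mutant_or_ko``.
    scale : str
        ``"logTPM"`` or ``"log_absolute"``.
    """

    X: pd.DataFrame
    growth: pd.Series
    meta: pd.DataFrame = None
    scale: str = SCALE_LOG_TPM

    def __post_init__(self):
        if self.meta is None:
            self.meta = default_meta(self.X.columns)
        if not self.X.columns.is_unique:
            raise ValidationError("condition ids must be unique")
        if not self.X.index.is_unique:
            raise ValidationError("gene ids must be unique")
        self.growth = self.growth.reindex(self.X.columns)
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            defaults = default_meta(self.X.columns)
            for c in missing:
                self.meta[c] = defaults[c]
        self.meta = self.meta.reindex(self.X.columns)
        if self.scale not in (SCALE_LOG_TPM, SCALE_LOG_ABSOLUTE):
            raise ValidationError(f"unknown scale {self.scale!r}")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.X.shape[1]

    @property
    def gene_ids(self) -> list:
        return list(self.X.index)

    @property
    def condition_ids(self) -> list:
        return list(self.X.columns)

    def select_conditions(self, condition_ids) -> "ExpressionDataset":
        """Column subset preserving growth and metadata alignment."""
        ids = list(condition_ids)
        if not ids:
            raise ValidationError("condition subset is empty")
        return replace(
            self,
            X=self.X[ids],
            growth=self.growth.loc[ids],
            meta=self.meta.loc[ids],
        )

    def select_genes(self, gene_ids) -> "ExpressionDataset":
        ids = list(gene_ids)
        if not ids:
            raise ValidationError("gene subset is empty")
        return replace(self, X=self.X.loc[ids], growth=self.growth, meta=self.meta)

    # ------------------------------------------------------------------ I/O

    def write(self, outdir, prefix: str = "expression") -> None:
        """Write matrix and metadata TSVs (first column gene id / condition)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        X = self.X.copy()
        X.index.name = "gene"
        X.to_csv(outdir / f"{prefix}_matrix.tsv", sep="\t")
        meta = self.meta.copy()
        meta.insert(0, "growth_rate", self.growth)
        meta.index.name = "condition"
        meta.to_csv(outdir / f"{prefix}_meta.tsv", sep="\t")

    @classmethod
    def read(cls, matrix_tsv, meta_tsv, scale: str = SCALE_LOG_TPM) -> "ExpressionDataset":
        X = pd.read_csv(matrix_tsv, sep="\t", index_col=0)
        meta = pd.read_csv(meta_tsv, sep="\t", index_col=0)
        growth = meta["growth_rate"] if "growth_rate" in meta else pd.Series(
            np.nan, index=meta.index
        )
        meta = meta.drop(columns=["growth_rate"], errors="ignore")
        return cls(X=X, growth=growth, meta=meta, scale=scale)


@dataclass
class RawAbundanceTable:
    """Non-negative raw abundances (protein copies/cell, fmol/mgDW, ...)."""

    A: pd.DataFrame
    growth: pd.Series = None
    meta: pd.DataFrame = None

    def __post_init__(self):
        if (self.A.values < 0).any():
            raise ValidationError("raw abundances must be non-negative")
        if self.growth is None:
            self.growth = pd.Series(np.nan, index=self.A.columns)
        if self.meta is None:
            self.meta = default_meta(self.A.columns)
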