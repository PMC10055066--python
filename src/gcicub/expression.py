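"""Condition-level expression processing.

Turns a raw genes x conditions compendium into a clean analysis matrix:
drop conditions with unknown/zero growth or poor alignment, average
biological replicates (on the stored log scale), flag and remove duplicated
conditions, normalize absolute abundances to log-TPM-like units, and subset
genes/conditions for robustness analyses.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .datatypes import (
    SCALE_LOG_ABSOLUTE,
    ExpressionDataset,
    RawAbundanceTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


def filter_conditions(ds: ExpressionDataset, min_alignment: float = 80) -> ExpressionDataset:
    """Drop conditions with missing/zero growth rate or alignment score
    below ``min_alignment`` (a score exactly at the threshold is retained)."""
    keep, dropped = [], []
    for c in ds.condition_ids:
        mu = ds.growth.loc[c]
        score = ds.meta.loc[c, "alignment_score"]
        if pd.isna(mu) or mu <= 0:
            dropped.append((c, "missing_or_zero_growth"))
        elif pd.notna(score) and score < min_alignment:
            dropped.append((c, f"alignment_score<{min_alignment}"))
        else:
            keep.append(c)
    for c, reason in dropped:
        logger.info("dropping condition %s: %s", c, reason)
    if not keep:
        raise ValidationError("all conditions removed by growth/alignment filters")
    return ds.select_conditions(keep)


def average_replicates(ds: ExpressionDataset) -> ExpressionDataset:
    """Collapse replicate columns to one column per replicate group.

    Expression and growth rates are arithmetic means on the stored (log)
    scale.  Strain flags must agree within a group; alignment scores are
    averaged.
    """
    groups = ds.meta["replicate_group"]
    if groups.isna().any():
        raise ValidationError("replicate_group missing for some conditions")
    order = list(dict.fromkeys(groups))  # first-appearance order
    X_cols, growth, meta_rows = {}, {}, {}
    for g in order:
        members = groups.index[groups == g]
        sub = ds.meta.loc[members]
        for flag in ("is_ale", "is_mutant_or_ko"):
            if sub[flag].nunique() > 1:
                raise ValidationError(
                    f"conflicting {flag} within replicate group {g!r}"
                )
        X_cols[g] = ds.X[members].mean(axis=1)
        growth[g] = float(ds.growth.loc[members].mean())
        meta_rows[g] = {
            "alignment_score": float(sub["alignment_score"].mean()),
            "replicate_group": g,
            "is_ale": bool(sub["is_ale"].iloc[0]),
            "is_mutant_or_ko": bool(sub["is_mutant_or_ko"].iloc[0]),
        }
    X = pd.DataFrame(X_cols)[order]
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").loc[order]
    meta.index.name = "condition"
    return replace(ds, X=X, growth=pd.Series(growth).loc[order], meta=meta)


def detect_duplicate_conditions(ds: ExpressionDataset, tol: float = 1e-12) -> list:
    """All-by-all Spearman over conditions; return pairs with rho = 1
    (within ``tol``).  Rank correlation catches duplicates that differ only
    by a monotone transform."""
    if ds.n_conditions < 2:
        raise ValidationError("need at least 2 conditions")
    rho = ds.X.corr(method="spearman")
    pairs = []
    cols = list(rho.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = rho.iloc[i, j]
            if pd.notna(r) and 1.0 - r <= tol:
                pairs.append(((cols[i], cols[j]), float(r)))
    return pairs


def drop_duplicate_conditions(ds: ExpressionDataset, policy: str = "drop_both",
                              tol: float = 1e-12) -> ExpressionDataset:
    """Remove duplicated conditions.  ``drop_both`` removes both members of
    each flagged pair (duplicated measurements with differing growth rates
    cannot be trusted on either side); ``drop_one`` keeps the first."""
    pairs = detect_duplicate_conditions(ds, tol=tol)
    if not pairs:
        return ds
    to_drop = set()
    for (a, b), r in pairs:
        logger.info("duplicate conditions %s / %s (rho=%.12f)", a, b, r)
        if policy == "drop_both":
            to_drop.update((a, b))
        elif policy == "drop_one":
            to_drop.add(b)
        else:
            raise ValidationError(f"unknown duplicate policy {policy!r}")
    keep = [c for c in ds.condition_ids if c not in to_drop]
    if not keep:
        raise ValidationError("duplicate removal dropped every condition")
    return ds.select_conditions(keep)


def normalize_absolute(raw: RawAbundanceTable, log_base: float = 10) -> ExpressionDataset:
    """Transform raw absolute abundances to log-TPM-like units.

    Zeros are replaced by the smallest non-zero value of the whole table,
    then each entry becomes ``6 + log_base(a / sum_a)`` where ``sum_a`` is
    the condition (column) total computed after replacement.  With base 10
    this equals log10(TPM).
    """
    A = raw.A.to_numpy(dtype=float, copy=True)
    nonzero = A[A > 0]
    if nonzero.size == 0:
        raise ValidationError("all-zero abundance table")
    min_nonzero = nonzero.min()
    n_replaced = int((A == 0).sum())
    if n_replaced:
        logger.info("replacing %d zero counts with %g", n_replaced, min_nonzero)
        A[A == 0] = min_nonzero
    col_sums = A.sum(axis=0)
    X = 6 + np.log(A / col_sums) / np.log(log_base)
    return ExpressionDataset(
        X=pd.DataFrame(X, index=raw.A.index, columns=raw.A.columns),
        growth=raw.growth,
        meta=raw.meta.copy(),
        scale=SCALE_LOG_ABSOLUTE,
    )


def filter_complete_genes(ds: ExpressionDataset) -> ExpressionDataset:
    """Keep genes measured in every condition; deduplicate byte-identical
    expression profiles (first occurrence kept)."""
    complete = ds.X.dropna(axis=0)
    n_dropped = ds.n_genes - complete.shape[0]
    if n_dropped:
        logger.info("dropped %d genes with missing values", n_dropped)
    dup = complete.duplicated(keep="first")
    if dup.any():
        for g in complete.index[dup]:
            logger.info("gene %s has a duplicated expression profile; removed", g)
        complete = complete[~dup]
    if complete.empty:
        raise ValidationError("no complete genes remain")
    return replace(ds, X=complete)


def subset_conditions(ds: ExpressionDataset, exclude_ale: bool = False,
                      exclude_mutants: bool = False) -> ExpressionDataset:
    """Neutral-condition subsets: optionally drop ALE strains and/or
    mutant / knock-out strains."""
    mask = pd.Series(True, index=ds.X.columns)
    if exclude_ale:
        mask &= ~ds.meta["is_ale"].astype(bool)
    if exclude_mutants:
        mask &= ~ds.meta["is_mutant_or_ko"].astype(bool)
    keep = list(mask.index[mask])
    if not keep:
        raise ValidationError("condition subset is empty")
    return ds.select_conditions(keep)


def exclude_genes(ds: ExpressionDataset, gene_list) -> ExpressionDataset:
    """Drop the listed genes (e.g. AT-rich outliers); unknown ids are
    logged, not fatal."""
    gene_list = set(gene_list)
    unknown = gene_list - set(ds.X.index)
    if unknown:
        logger.info("%d listed genes not present in the matrix", len(unknown))
    keep = [g for g in ds.X.index if g not in gene_list]
    if not keep:
        raise ValidationError("gene exclusion removed every gene")
    return ds.select_genes(keep)
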