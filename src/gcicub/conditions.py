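"""Condition-level structure of an expression compendium.

Pairwise condition correlations, per-condition predictivity of codon usage
bias from expression, the growth-rate trend in that predictivity, and the
iterative pruning algorithm that thins highly correlated conditions down to
a maximally distinct subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionDataset, ValidationError


@dataclass
class ConditionCorrMatrix:
    """Symmetric all-by-all Pearson correlation between conditions."""

    R: pd.DataFrame

    @property
    def R2(self) -> pd.DataFrame:
        return self.R**2

    @property
    def condition_ids(self) -> list:
        return list(self.R.columns)


@dataclass
class PredictivityProfile:
    """Per-condition R^2 between expression and a CUB score, with growth."""

    r2: pd.Series
    growth: pd.Series


def condition_correlation_matrix(ds: ExpressionDataset) -> ConditionCorrMatrix:
    """Pearson correlation between every pair of conditions, computed over
    genes on the stored log scale.  Genes missing in either column are
    excluded pairwise; zero-variance columns yield NaN for their pairs."""
    if ds.n_conditions < 2:
        raise ValidationError("need at least 2 conditions")
    if ds.n_genes < 3:
        raise ValidationError("need at least 3 genes")
    R = ds.X.corr(method="pearson")  # pairwise-complete by construction
    np.fill_diagonal(R.values, 1.0)
    return ConditionCorrMatrix(R=R)


def per_condition_cub_r2(ds: ExpressionDataset, scores,
                         rank_based: bool = False) -> PredictivityProfile:
    """For each condition, the R^2 of the correlation between per-gene log
    expression and the CUB score, over the genes present in both inputs.

    ``scores`` is a mapping or Series of gene id -> score (e.g. the
    ``score`` column of :func:`gcicub.cub.score_sequences`).
    """
    s = pd.Series(scores, dtype=float) if not isinstance(scores, pd.Series) else scores.astype(float)
    common = ds.X.index.intersection(s.index)
    if len(common) < 3:
        raise ValidationError(
            f"only {len(common)} genes shared between expression and scores"
        )
    sub = ds.X.loc[common]
    sv = s.loc[common]
    method = stats.spearmanr if rank_based else stats.pearsonr
    r2 = {}
    for c in sub.columns:
        r = method(sub[c].to_numpy(), sv.to_numpy())[0]
        r2[c] = float(r) ** 2
    return PredictivityProfile(
        r2=pd.Series(r2).loc[ds.X.columns], growth=ds.growth.copy()
    )


def growth_predictivity_trend(profile: PredictivityProfile) -> tuple:
    """Spearman rank correlation (two-sided) between condition growth rate
    and the expression->CUB predictivity R^2."""
    r2 = profile.r2.to_numpy()
    mu = profile.growth.loc[profile.r2.index].to_numpy()
    if len(r2) < 3:
        raise ValidationError("need at least 3 conditions")
    if np.allclose(r2, r2[0]):
        raise ValidationError("constant R^2 vector: trend undefined")
    rho, p = stats.spearmanr(mu, r2)
    return float(rho), float(p)


def prune_redundant_conditions(ds: ExpressionDataset, target_n: int,
                               seed: int, method: str = "spearman") -> tuple:
    """Iteratively remove one member of the most correlated condition pair
    until ``target_n`` conditions remain.

    At each iteration the all-by-all Spearman matrix is recomputed, the
    maximum off-diagonal pair located (ties broken by lowest column index),
    and one member of that pair removed uniformly at random (seeded).

    Returns ``(pruned_dataset, removal_log)`` where the log is a DataFrame
    with one row per iteration (pair, removed member, max correlation).
    """
    if not (2 <= target_n <= ds.n_conditions):
        raise ValidationError(
            f"target_n={target_n} outside [2, {ds.n_conditions}]"
        )
    rng = np.random.default_rng(seed)
    current = ds
    log_rows = []
    it = 0
    while current.n_conditions > target_n:
        R = current.X.corr(method=method).to_numpy()
        np.fill_diagonal(R, -np.inf)
        R[np.isnan(R)] = -np.inf
        # lowest-index pair among ties: flatten scan is row-major, i<j half
        iu, ju = np.triu_indices(R.shape[0], k=1)
        vals = R[iu, ju]
        k = int(np.argmax(vals))
        i, j = int(iu[k]), int(ju[k])
        cols = current.condition_ids
        removed = cols[i] if rng.integers(2) == 0 else cols[j]
        log_rows.append(
            {
                "iteration": it,
                "condition_a": cols[i],
                "condition_b": cols[j],
                "removed": removed,
                "max_correlation": float(vals[k]),
            }
        )
        current = current.select_conditions([c for c in cols if c != removed])
        it += 1
    return current, pd.DataFrame(
        log_rows,
        columns=["iteration", "condition_a", "condition_b", "removed", "max_correlation"],
    )
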