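"""Gene-set comparisons and over-representation analysis.

Two complementary views of GCI against gene function: (i) mean-GCI
comparisons between binary gene labelings (essential vs non-essential, core
vs accessory) with a pooled-variance Student's t-test; (ii) one-sided
hypergeometric over-representation analysis (ORA) of a gene set against a
universe, using a pre-propagated gene -> term mapping, Benjamini-Hochberg
FDR control, and odds ratios for ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    means: dict          # group label -> mean GCI
    t: float
    df: float
    p: float
    n: dict              # group label -> size


def compare_groups(gci, labels, welch: bool = False) -> GroupComparison:
    """Two-sided t-test for a difference in mean GCI between two labeled
    gene groups (pooled-variance Student's test by default).

    ``gci`` is a gene-indexed Series of r values (NaN = undefined);
    ``labels`` maps gene id -> one of exactly two labels.
    """
    g = pd.Series(gci, dtype=float).dropna()
    lab = pd.Series(labels)
    lab = lab.loc[lab.index.intersection(g.index)]
    groups = sorted(lab.unique())
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 labels, got {list(groups)}")
    a = g.loc[lab.index[lab == groups[0]]].to_numpy()
    b = g.loc[lab.index[lab == groups[1]]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 genes with defined GCI")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    df = (len(a) + len(b) - 2) if not welch else _welch_df(a, b)
    return GroupComparison(
        means={groups[0]: float(a.mean()), groups[1]: float(b.mean())},
        t=float(t),
        df=float(df),
        p=float(p),
        n={groups[0]: len(a), groups[1]: len(b)},
    )


def _welch_df(a, b) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))


def split_by_gci_sign(gci) -> tuple:
    """Partition genes with defined GCI into positive and negative sets.

    Genes with r exactly 0 belong to neither set (logged)."""
    g = pd.Series(gci, dtype=float).dropna()
    zeros = g.index[g == 0]
    if len(zeros):
        logger.info("%d genes with GCI exactly 0 excluded from both sets", len(zeros))
    positive = list(g.index[g > 0])
    negative = list(g.index[g < 0])
    return positive, negative


def read_term_mapping(path) -> pd.DataFrame:
    """Read a gene<TAB>term mapping (multiple rows per gene allowed)."""
    df = pd.read_csv(path, sep="\t", header=0)
    df.columns = ["gene", "term"] + list(df.columns[2:])
    return df[["gene", "term"]]


def read_labels(path) -> pd.Series:
    """Read a 2-column gene<TAB>label TSV into a gene-indexed Series."""
    df = pd.read_csv(path, sep="\t", header=0)
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over ranks j >= i of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(gene_set, universe, mapping: pd.DataFrame,
           p_max: float = 0.04, q_max: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric over-representation analysis.

    For each term with at least one annotated universe gene, the 2x2 table is

        a = |set & term|       b = |set \\ term|
        c = |(universe\\set) & term|   d = remainder

    with p = P[X >= a] under Hypergeom(N=|universe|, K=a+c, n=a+b).
    BH adjustment runs over all tested terms; rows are then filtered by
    ``p <= p_max`` and ``q <= q_max``.  The odds ratio (a*d)/(b*c) uses a
    Haldane 0.5 correction when any cell is zero (flagged).

    Returns a DataFrame with one row per retained term.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not gene_set or not universe:
        raise ValidationError("empty gene set or universe")
    if not gene_set <= universe:
        raise ValidationError("gene set must be a subset of the universe")
    term_genes = {
        term: set(sub["gene"]) & universe
        for term, sub in mapping.groupby("term")
    }
    term_genes = {t: g for t, g in term_genes.items() if g}
    if not term_genes:
        raise ValidationError("term mapping covers no universe gene")
    N = len(universe)
    n_set = len(gene_set)
    rows = []
    for term, annotated in sorted(term_genes.items()):
        a = len(gene_set & annotated)
        b = n_set - a
        c = len(annotated) - a
        d = N - a - b - c
        p = float(stats.hypergeom.sf(a - 1, N, len(annotated), n_set))
        haldane = any(x == 0 for x in (a, b, c, d))
        if haldane:
            orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append(
            {
                "term": term, "a": a, "b": b, "c": c, "d": d,
                "p": p, "odds_ratio": float(orr), "haldane": haldane,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"])
    df = df[(df["p"] <= p_max) & (df["q"] <= q_max)].reset_index(drop=True)
    return df[["term", "a", "b", "c", "d", "p", "q", "odds_ratio", "haldane"]]


def top_by_odds_ratio(rows: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """The k terms with the largest odds ratios (ties broken by ascending p,
    then term id)."""
    if k < 0:
        raise ValidationError("k must be non-negative")
    if rows.empty or k == 0:
        return rows.iloc[0:0]
    ordered = rows.sort_values(
        by=["odds_ratio", "p", "term"], ascending=[False, True, True]
    )
    return ordered.head(min(k, len(ordered))).reset_index(drop=True)
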