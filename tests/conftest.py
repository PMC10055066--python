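"""Shared fixtures: tiny hand-built datasets and weight tables."""

import numpy as np
import pandas as pd
import pytest

from gcicub.cub import SENSE_CODONS, STOP_CODONS, CodonWeightTable
from gcicub.datatypes import ExpressionDataset, default_meta


def make_toy_table(weights: dict, metric: str = "toy") -> CodonWeightTable:
    """Weight table covering only the given codons; everything else is
    explicitly excluded so validation passes on tiny examples."""
    excluded = frozenset(set(SENSE_CODONS) - set(weights)) | STOP_CODONS
    return CodonWeightTable(metric=metric, weights=weights,
                            excluded_codons=excluded)


def make_dataset(X, growth, meta=None, scale="logTPM") -> ExpressionDataset:
    """ExpressionDataset from plain arrays with generated ids."""
    X = np.asarray(X, dtype=float)
    genes = [f"g{i}" for i in range(X.shape[0])]
    conds = [f"c{j}" for j in range(X.shape[1])]
    Xdf = pd.DataFrame(X, index=genes, columns=conds)
    growth = pd.Series(np.asarray(growth, dtype=float), index=conds)
    if meta is None:
        meta = default_meta(conds)
    return ExpressionDataset(X=Xdf, growth=growth, meta=meta, scale=scale)


@pytest.fixture
def toy_aaa_table():
    """The two-codon lysine family toy table."""
    return make_toy_table({"AAA": 1.0, "AAG": 0.25})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
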