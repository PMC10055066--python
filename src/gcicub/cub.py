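"""Codon usage bias metrics from pluggable weight tables.

Both the codon adaptation index (CAI) and the tRNA adaptation index (tAI)
score a coding sequence as the geometric mean of per-codon weights w in
(0, 1], where w = 1 marks the optimal codon.  The weights themselves are an
input (a two-column TSV), so any geometric-mean CUB metric can be plugged in.
Coding sequences are extracted from GenBank annotation, spliced and
strand-corrected, and filtered for basic quality (length divisible by 3,
consistent with the annotated intervals, and not absurdly long).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from statistics import median

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
#: single-codon amino-acid families (Met, Trp): no synonymous choice exists,
#: so CAI conventionally excludes them
SINGLE_CODON_FAMILIES = frozenset({"ATG", "TGG"})
SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))  # 61 codons

#: amino acid -> tuple of synonymous codons (sense codons only)
CODON_FAMILIES: dict = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    CODON_FAMILIES.setdefault(_aa, []).append(_codon)
CODON_FAMILIES = {aa: tuple(sorted(cs)) for aa, cs in CODON_FAMILIES.items()}


class CubError(ValueError):
    pass


@dataclass
class CodingSequence:
    """One spliced, coding-strand CDS with its source coordinates.

    ``intervals`` are 1-based inclusive (GenBank convention), listed in
    annotation order.
    """

    id: str
    seq: str
    gene_name: str | None = None
    strand: int = 1
    intervals: tuple = ()

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def has_ambiguous(self) -> bool:
        return any(b not in "ACGT" for b in self.seq)

    @property
    def interval_length(self) -> int:
        return sum(end - start + 1 for start, end in self.intervals)


@dataclass
class CodonWeightTable:
    """Sense-codon -> weight map for one geometric-mean CUB metric."""

    metric: str
    weights: dict
    excluded_codons: frozenset = frozenset(STOP_CODONS)
    provenance: str = ""

    def __post_init__(self):
        if not self.weights:
            raise CubError("empty weight table")
        bad = [c for c, w in self.weights.items() if w < 0]
        if bad:
            raise CubError(f"negative weight for codon {bad[0]}")
        missing = [
            c
            for c in SENSE_CODONS
            if c not in self.weights and c not in self.excluded_codons
        ]
        if missing:
            raise CubError(
                f"weight table missing sense codons (e.g. {missing[0]}); "
                "list them in excluded_codons or provide weights"
            )

    def normalized(self) -> "CodonWeightTable":
        """Rescale so the maximum weight is 1 (both metrics are defined
        relative to the optimal codon)."""
        wmax = max(self.weights.values())
        if wmax <= 0:
            raise CubError("all weights are zero")
        return replace(self, weights={c: w / wmax for c, w in self.weights.items()})

    def with_zero_policy(self) -> "CodonWeightTable":
        """Replace zero weights by the geometric mean of the non-zero weights
        (the standard tAI convention for codons without a matching tRNA)."""
        nonzero = [w for w in self.weights.values() if w > 0]
        if not nonzero:
            raise CubError("all weights are zero")
        gm = math.exp(np.mean(np.log(nonzero)))
        return replace(
            self, weights={c: (w if w > 0 else gm) for c, w in self.weights.items()}
        )

    @classmethod
    def from_tsv(cls, path, metric: str | None = None,
                 excluded_codons=frozenset(STOP_CODONS)) -> "CodonWeightTable":
        """Read a 2-column TSV (codon, weight); the header names the metric."""
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise CubError(f"{path}: expected 2 columns (codon, weight)")
        metric = metric or str(df.columns[1])
        weights = {
            str(c).upper().replace("U", "T"): float(w)
            for c, w in zip(df.iloc[:, 0], df.iloc[:, 1])
        }
        table = cls(
            metric=metric,
            weights=weights,
            excluded_codons=frozenset(excluded_codons),
            provenance=str(path),
        )
        return table.normalized()

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"codon": list(self.weights), self.metric: list(self.weights.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class CubScore:
    gene_id: str
    metric: str
    score: float
    n_codons_scored: int


# --------------------------------------------------------------- extraction


def extract_cds(record) -> list:
    """Extract all CDS features from a parsed GenBank record.

    Minus-strand features are reverse-complemented and joined (multi-exon)
    features spliced in annotation order, so the returned sequence always
    reads in the coding direction.  Features with coordinates outside the
    record are skipped with a warning.
    """
    out = []
    n = len(record.seq)
    for i, feat in enumerate(record.features):
        if feat.type != "CDS":
            continue
        loc = feat.location
        if loc is None:
            logger.warning("CDS #%d has no location; skipped", i)
            continue
        if int(loc.start) < 0 or int(loc.end) > n:
            logger.warning(
                "CDS #%d coordinates [%s] outside record of length %d; skipped",
                i, loc, n,
            )
            continue
        seq = str(feat.extract(record.seq)).upper()
        intervals = tuple(
            (int(part.start) + 1, int(part.end)) for part in loc.parts
        )
        quals = feat.qualifiers
        locus = quals.get("locus_tag", quals.get("protein_id", [f"cds_{i}"]))[0]
        gene = quals.get("gene", [None])[0]
        out.append(
            CodingSequence(
                id=locus,
                gene_name=gene,
                seq=seq,
                strand=int(loc.strand or 1),
                intervals=intervals,
            )
        )
    return out


def filter_cds(cds_list) -> tuple:
    """Quality-filter coding sequences.

    Kept entries satisfy all of: length divisible by 3; length equal to the
    summed annotated interval lengths (catches malformed joins); length at
    most 5x the median length of the *full input* (the median is computed
    before any removal).

    Returns ``(kept, removed)``.
    """
    cds_list = list(cds_list)
    if not cds_list:
        raise CubError("empty CDS list")
    med = median(len(c) for c in cds_list)
    threshold = 5 * med
    kept, removed = [], []
    for c in cds_list:
        ok = (
            len(c) % 3 == 0
            and (not c.intervals or len(c) == c.interval_length)
            and len(c) <= threshold
        )
        (kept if ok else removed).append(c)
    return kept, removed


# ------------------------------------------------------------------ scoring


def geometric_mean_score(seq: str, table: CodonWeightTable,
                         gene_id: str = "") -> CubScore:
    """Geometric mean of codon weights over a coding sequence.

    Codons in ``table.excluded_codons`` are skipped and not counted; codons
    containing ambiguous bases (anything outside ACGT) are skipped with a
    warning.  A sense codon absent from the table is an error.
    """
    seq = seq.upper()
    if len(seq) < 3 or len(seq) % 3 != 0:
        raise CubError(f"sequence length {len(seq)} not a positive multiple of 3")
    log_weights = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in table.excluded_codons:
            continue
        if any(b not in "ACGT" for b in codon):
            logger.warning("ambiguous codon %s at position %d skipped", codon, i)
            continue
        try:
            w = table.weights[codon]
        except KeyError:
            raise CubError(f"codon {codon} absent from {table.metric} weight table")
        if w <= 0:
            raise CubError(
                f"codon {codon} has non-positive weight; apply a zero policy first"
            )
        log_weights.append(math.log(w))
    if not log_weights:
        raise CubError("no scorable codons remain after exclusions")
    return CubScore(
        gene_id=gene_id,
        metric=table.metric,
        score=math.exp(float(np.mean(log_weights))),
        n_codons_scored=len(log_weights),
    )


def cai(seq: str, table: CodonWeightTable, gene_id: str = "",
        exclude_single_codon_families: bool = True) -> CubScore:
    """Codon adaptation index: geometric-mean score with stop codons always
    excluded and the single-codon families ATG/TGG excluded by default."""
    excluded = set(table.excluded_codons) | set(STOP_CODONS)
    if exclude_single_codon_families:
        excluded |= set(SINGLE_CODON_FAMILIES)
    return geometric_mean_score(
        seq, replace(table, metric="CAI", excluded_codons=frozenset(excluded)),
        gene_id=gene_id,
    )


def tai(seq: str, table: CodonWeightTable, gene_id: str = "",
        zero_policy: bool = True) -> CubScore:
    """tRNA adaptation index: stop codons excluded; zero-weight codons
    (no matching tRNA) receive the geometric mean of non-zero weights."""
    t = table.with_zero_policy() if zero_policy else table
    excluded = frozenset(set(t.excluded_codons) | set(STOP_CODONS))
    return geometric_mean_score(
        seq, replace(t, metric="tAI", excluded_codons=excluded), gene_id=gene_id
    )


def score_sequences(cds_list, table: CodonWeightTable, metric: str = "cai",
                    **kwargs) -> pd.DataFrame:
    """Score many coding sequences; returns a tidy frame indexed by gene id."""
    scorer = {"cai": cai, "tai": tai, "geometric": geometric_mean_score}[metric.lower()]
    rows = []
    for c in cds_list:
        s = scorer(c.seq, table, gene_id=c.id, **kwargs)
        rows.append((c.id, c.gene_name, s.metric, s.score, s.n_codons_scored))
    df = pd.DataFrame(
        rows, columns=["gene", "gene_name", "metric", "score", "n_codons"]
    ).set_index("gene")
    return df


def write_scores(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
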