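"""Synthetic expression compendia and coding sequences with known truth.

The generator emulates the statistical structure of a microbial expression
compendium with per-condition growth rates:

* per-gene baseline log expression (lognormal abundance, stored on the log
  scale),
* a per-gene growth-rate slope b_g drawn from a two-component Gaussian
  mixture -- a negative-mode majority and a positive minority -- matching
  the observation that most genes decrease in relative abundance during
  rapid growth while a minority (e.g. ribosomal proteins) increase,
* growth rates uniform on a configurable range, replicate columns sharing a
  condition's growth rate, and i.i.d. Gaussian noise on the log scale.

For each gene the *theoretical* GCI implied by the generative model is

    GCI_g = b_g * sd(mu) / sqrt(b_g^2 * var(mu) + noise_sd^2)

which the empirical GCI recovers as the number of conditions grows.  Coding
sequences are generated with a per-gene bias coupling beta_g >= 0: each
amino-acid position draws a synonymous codon with probability proportional
to w^beta_g, so genes with larger beta_g have higher CUB scores and the
planted CUB-GCI relationship can be recovered end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cub import (
    CODON_FAMILIES,
    SENSE_CODONS,
    STOP_CODONS,
    CodingSequence,
    CodonWeightTable,
    CubError,
)
from .datatypes import ExpressionDataset, ValidationError

_STOPS = tuple(sorted(STOP_CODONS))


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic compendium.

    Defaults emulate a bacterial RNA-seq compendium: ~100 distinct growth
    conditions spanning roughly 0.05-1.5 /hr, a minority (25%) of genes with
    positive growth slopes, slope magnitudes centred near 0.3 log units per
    unit growth rate (placing the theoretical GCI mode near -0.3 at the
    default noise level), and 0.4 log units of measurement noise.
    """

    n_genes: int = 500
    n_conditions: int = 60
    growth_range: tuple = (0.05, 1.5)
    slope_mix: float = 0.25       # fraction of genes with positive slope
    slope_scale: float = 0.3      # sd of slope magnitude around the mode
    slope_mode: float = 0.3       # |slope| mixture component centre
    noise_sd: float = 0.4         # log-expression units
    baseline_mean: float = 2.0    # log-expression units
    baseline_sd: float = 1.0
    n_replicates: int = 1
    bias_coupling_max: float = 2.0  # beta_g at theoretical GCI = +1
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValidationError("n_genes must be >= 2")
        if self.n_conditions < 3:
            raise ValidationError("n_conditions must be >= 3")
        lo, hi = self.growth_range
        if lo <= 0 or hi <= lo:
            raise ValidationError("growth_range must satisfy 0 < min < max")
        if not 0 <= self.slope_mix <= 1:
            raise ValidationError("slope_mix must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.baseline_sd < 0:
            raise ValidationError("baseline_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValidationError("seed must be a non-negative integer")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator.

    ``table`` is gene-indexed with columns ``slope`` (b_g, log-expression
    per unit growth rate), ``theoretical_gci`` and ``bias_coupling``
    (beta_g >= 0, monotone in theoretical GCI).
    """

    table: pd.DataFrame
    growth_sd: float
    noise_sd: float

    def write(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def theoretical_gci(slope: np.ndarray, growth_sd: float, noise_sd: float) -> np.ndarray:
    """GCI implied by the linear-plus-noise generative model."""
    slope = np.asarray(slope, dtype=float)
    if noise_sd == 0:
        return np.sign(slope)
    return slope * growth_sd / np.sqrt(slope**2 * growth_sd**2 + noise_sd**2)


def generate_dataset(spec: SyntheticSpec) -> tuple:
    """Generate an expression compendium with known per-gene growth slopes.

    Returns ``(ExpressionDataset, SyntheticTruth)``; fully reproducible
    from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    conditions = [f"cond{j:04d}" for j in range(spec.n_conditions)]

    lo, hi = spec.growth_range
    mu_cond = rng.uniform(lo, hi, size=spec.n_conditions)

    # two-component slope mixture: magnitude ~ |N(mode, scale)|, sign by mix
    positive = rng.random(spec.n_genes) < spec.slope_mix
    magnitude = np.abs(rng.normal(spec.slope_mode, spec.slope_scale, spec.n_genes))
    slope = np.where(positive, magnitude, -magnitude)

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)

    # replicate columns share the condition growth rate
    col_ids, col_mu, col_group = [], [], []
    for j, c in enumerate(conditions):
        for r in range(spec.n_replicates):
            col_ids.append(c if spec.n_replicates == 1 else f"{c}_r{r+1}")
            col_mu.append(mu_cond[j])
            col_group.append(c)
    col_mu = np.array(col_mu)

    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, len(col_ids)))
    X = baseline[:, None] + slope[:, None] * col_mu[None, :] + noise

    growth_sd = float(np.std(col_mu, ddof=1))
    tgci = theoretical_gci(slope, growth_sd, spec.noise_sd)
    beta = spec.bias_coupling_max * (tgci + 1) / 2  # monotone, >= 0

    truth = SyntheticTruth(
        table=pd.DataFrame(
            {"slope": slope, "theoretical_gci": tgci, "bias_coupling": beta},
            index=pd.Index(genes, name="gene"),
        ),
        growth_sd=growth_sd,
        noise_sd=spec.noise_sd,
    )
    meta = pd.DataFrame(
        {
            "alignment_score": 100.0,
            "replicate_group": col_group,
            "is_ale": False,
            "is_mutant_or_ko": False,
        },
        index=pd.Index(col_ids, name="condition"),
    )
    ds = ExpressionDataset(
        X=pd.DataFrame(X, index=genes, columns=col_ids),
        growth=pd.Series(col_mu, index=col_ids),
        meta=meta,
    )
    return ds, truth


# ------------------------------------------------------------- sequences


def generate_weight_table(seed: int, metric: str = "cai") -> CodonWeightTable:
    """Random but realistic weight table: within each synonymous family one
    codon gets weight 1 and the rest draw uniformly from (0.05, 1)."""
    rng = np.random.default_rng(seed)
    weights = {}
    for aa, codons in sorted(CODON_FAMILIES.items()):
        best = codons[rng.integers(len(codons))]
        for c in codons:
            weights[c] = 1.0 if c == best else float(rng.uniform(0.05, 1.0))
    return CodonWeightTable(metric=metric, weights=weights,
                            provenance=f"synthetic(seed={seed})")


def generate_sequences(truth: SyntheticTruth, table: CodonWeightTable,
                       n_codons: int = 100, seed: int = 0) -> list:
    """Coding sequences whose codon bias is coupled to the per-gene latent
    bias score beta_g.

    Each of ``n_codons`` internal positions draws an amino acid uniformly
    and then a synonymous codon with probability proportional to
    w^beta_g (computed in log space, so the beta -> infinity limit cleanly
    selects only max-weight codons).  Sequences start with ATG, end with a
    stop codon, and have length divisible by 3.
    """
    if n_codons < 10:
        raise ValidationError("n_codons must be >= 10")
    if not table.weights:
        raise CubError("empty weight table")
    rng = np.random.default_rng(seed)
    families = sorted(CODON_FAMILIES.items())
    log_w = {
        aa: np.log([max(table.weights[c], 1e-300) for c in codons])
        for aa, codons in families
    }
    out = []
    for gene, row in truth.table.iterrows():
        beta = float(row["bias_coupling"])
        codons = ["ATG"]
        aa_idx = rng.integers(len(families), size=n_codons)
        for k in aa_idx:
            aa, fam = families[k]
            logits = beta * log_w[aa]
            logits = logits - logits.max()
            p = np.exp(logits)
            p /= p.sum()
            codons.append(fam[rng.choice(len(fam), p=p)])
        codons.append(_STOPS[rng.integers(len(_STOPS))])
        seq = "".join(codons)
        out.append(
            CodingSequence(id=str(gene), seq=seq, strand=1,
                           intervals=((1, len(seq)),))
        )
    return out


# ----------------------------------------------- labels and term mappings


def generate_gene_labels(truth: SyntheticTruth, seed: int = 0,
                         positive_label: str = "essential",
                         negative_label: str = "non-essential",
                         flip_rate: float = 0.1) -> pd.Series:
    """Binary labeling coupled to the planted growth response: genes with
    positive theoretical GCI get ``positive_label``, with labels flipped at
    ``flip_rate`` to emulate annotation noise."""
    rng = np.random.default_rng(seed)
    tgci = truth.table["theoretical_gci"].to_numpy()
    lab = np.where(tgci > 0, positive_label, negative_label)
    flips = rng.random(len(lab)) < flip_rate
    other = {positive_label: negative_label, negative_label: positive_label}
    lab = np.array([other[l] if f else l for l, f in zip(lab, flips)])
    return pd.Series(lab, index=truth.table.index, name="label")


def generate_term_mapping(truth: SyntheticTruth, seed: int = 0,
                          n_random_terms: int = 20, genes_per_term: int = 30,
                          planted_term: str = "T:planted",
                          enrichment: float = 4.0) -> pd.DataFrame:
    """Gene -> term mapping with random terms plus one planted term whose
    members are drawn preferentially (odds ``enrichment``:1) from genes
    with positive theoretical GCI."""
    rng = np.random.default_rng(seed)
    genes = np.array(truth.table.index)
    rows = []
    for t in range(n_random_terms):
        members = rng.choice(genes, size=min(genes_per_term, len(genes)),
                             replace=False)
        rows += [{"gene": g, "term": f"T:{t:04d}"} for g in members]
    w = np.where(truth.table["theoretical_gci"].to_numpy() > 0, enrichment, 1.0)
    p = w / w.sum()
    members = rng.choice(genes, size=min(genes_per_term, len(genes)),
                         replace=False, p=p)
    rows += [{"gene": g, "term": planted_term} for g in members]
    return pd.DataFrame(rows, columns=["gene", "term"])


# ----------------------------------------------------------------- output


def write_sequences(cds_list, path) -> None:
    """Write coding sequences as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(c.seq), id=c.id, description=c.gene_name or "")
        for c in cds_list
    ]
    seqio_write(records, str(path), "fasta")


def write_all(spec: SyntheticSpec, outdir, weight_seed: int | None = None,
              n_codons: int = 100) -> dict:
    """Generate and write a full synthetic bundle (expression, metadata,
    truth, weight table, FASTA).  Returns the in-memory objects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds, truth = generate_dataset(spec)
    table = generate_weight_table(weight_seed if weight_seed is not None
                                  else spec.seed + 1)
    cds_list = generate_sequences(truth, table, n_codons=n_codons,
                                  seed=spec.seed + 2)
    ds.write(outdir)
    truth.write(outdir / "truth.tsv")
    table.to_tsv(outdir / "codon_weights.tsv")
    write_sequences(cds_list, outdir / "sequences.fasta")
    return {"dataset": ds, "truth": truth, "weights": table, "cds": cds_list}
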