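"""End-to-end orchestration: simulate -> score -> process -> conditions ->
GCI -> models -> gene sets, driven by a single YAML config, with seeded
determinism, a manifest of outputs, and a plain-text report of headline
statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conditions as cond_mod
from . import cub, expression, gci as gci_mod, genesets, models, synthetic
from .datatypes import ExpressionDataset, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration for a full run.

    ``mode`` is ``synthetic`` (generate inputs) or ``files`` (load the
    expression matrix/metadata, weight table, FASTA, labels and terms from
    the given paths).
    """

    outdir: str = "run"
    mode: str = "synthetic"
    seed: int = 0
    # synthetic generator parameters (mode == synthetic)
    synthetic: dict = field(default_factory=dict)
    n_codons: int = 100
    # input paths (mode == files)
    expression_matrix: str | None = None
    expression_meta: str | None = None
    weights: str | None = None
    fasta: str | None = None
    labels: str | None = None
    terms: str | None = None
    # thresholds, all surfaced with their standard defaults
    min_alignment: float = 80.0
    prune_to: int | None = None
    p_max: float = 0.04
    q_max: float = 0.05
    top_k: int = 15
    # flags
    metric: str = "cai"
    log_base: float = 10.0
    duplicate_policy: str = "drop_both"
    exclude_ale: bool = False
    exclude_mutants: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def validate_config(config: PipelineConfig) -> list:
    """Return a list of human-readable validation errors (empty = valid)."""
    errors = []
    if config.mode not in ("synthetic", "files"):
        errors.append(f"mode must be 'synthetic' or 'files', got {config.mode!r}")
    if not isinstance(config.seed, int) or config.seed < 0:
        errors.append(f"seed must be a non-negative integer, got {config.seed!r}")
    if config.mode == "files":
        for key in ("expression_matrix", "expression_meta", "weights", "fasta"):
            path = getattr(config, key)
            if path is None:
                errors.append(f"{key} is required in files mode")
            elif not Path(path).exists():
                errors.append(f"{key} path does not exist: {path}")
        for key in ("labels", "terms"):
            path = getattr(config, key)
            if path is not None and not Path(path).exists():
                errors.append(f"{key} path does not exist: {path}")
    if config.mode == "synthetic":
        try:
            synthetic.SyntheticSpec(**config.synthetic).validate()
        except (TypeError, ValidationError) as exc:
            errors.append(f"synthetic spec invalid: {exc}")
    if config.prune_to is not None and config.prune_to < 2:
        errors.append("prune_to must be >= 2")
    for key in ("p_max", "q_max"):
        v = getattr(config, key)
        if not 0 < v <= 1:
            errors.append(f"{key} must lie in (0, 1]")
    if config.metric not in ("cai", "tai"):
        errors.append(f"metric must be 'cai' or 'tai', got {config.metric!r}")
    return errors


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage, writing TSV outputs, a manifest and a report.

    Stage failures abort with the stage name attached to the exception.
    """
    errors = validate_config(config)
    if errors:
        raise ValidationError("invalid config: " + "; ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    stage = "inputs"
    try:
        # ---------------------------------------------------------- inputs
        if config.mode == "synthetic":
            spec = synthetic.SyntheticSpec(**{**config.synthetic,
                                              "seed": config.seed})
            bundle = synthetic.write_all(spec, outdir / "inputs",
                                         n_codons=config.n_codons)
            ds, truth = bundle["dataset"], bundle["truth"]
            table, cds_list = bundle["weights"], bundle["cds"]
            labels = synthetic.generate_gene_labels(truth, seed=config.seed + 3)
            terms = synthetic.generate_term_mapping(truth, seed=config.seed + 4)
        else:
            ds = ExpressionDataset.read(config.expression_matrix,
                                        config.expression_meta)
            table = cub.CodonWeightTable.from_tsv(config.weights)
            from Bio import SeqIO
            cds_list = [
                cub.CodingSequence(id=rec.id, seq=str(rec.seq).upper(),
                                   intervals=((1, len(rec.seq)),))
                for rec in SeqIO.parse(config.fasta, "fasta")
            ]
            labels = genesets.read_labels(config.labels) if config.labels else None
            terms = genesets.read_term_mapping(config.terms) if config.terms else None
            truth = None

        # ------------------------------------------------------------ cub
        stage = "cub"
        kept, removed = cub.filter_cds(cds_list)
        scores_df = cub.score_sequences(kept, table, metric=config.metric)
        cub.write_scores(scores_df, outdir / "cub_scores.tsv")
        report["n_cds_input"] = len(cds_list)
        report["n_cds_kept"] = len(kept)
        report["n_cds_removed"] = len(removed)

        # ----------------------------------------------------- expression
        stage = "expression"
        n0 = ds.n_conditions
        ds = expression.filter_conditions(ds, min_alignment=config.min_alignment)
        ds = expression.average_replicates(ds)
        ds = expression.drop_duplicate_conditions(ds,
                                                  policy=config.duplicate_policy)
        if config.exclude_ale or config.exclude_mutants:
            ds = expression.subset_conditions(
                ds, exclude_ale=config.exclude_ale,
                exclude_mutants=config.exclude_mutants,
            )
        ds = expression.filter_complete_genes(ds)
        ds.write(outdir, prefix="processed")
        report["n_conditions_input"] = n0
        report["n_conditions_final"] = ds.n_conditions
        report["n_genes_final"] = ds.n_genes

        # ----------------------------------------------------- conditions
        stage = "conditions"
        corr = cond_mod.condition_correlation_matrix(ds)
        corr.R.to_csv(outdir / "condition_correlation.tsv", sep="\t")
        profile = cond_mod.per_condition_cub_r2(ds, scores_df["score"])
        pd.DataFrame({"r2": profile.r2, "growth_rate": profile.growth}).to_csv(
            outdir / "per_condition_r2.tsv", sep="\t"
        )
        rho, p_trend = cond_mod.growth_predictivity_trend(profile)
        offdiag = corr.R2.where(~np.eye(len(corr.R2), dtype=bool))
        report["condition_r2_min"] = float(offdiag.min().min())
        report["condition_r2_max"] = float(offdiag.max().max())
        report["per_condition_cub_r2_min"] = float(profile.r2.min())
        report["per_condition_cub_r2_max"] = float(profile.r2.max())
        report["growth_trend_spearman_rho"] = rho
        report["growth_trend_p"] = p_trend
        if config.prune_to is not None and config.prune_to < ds.n_conditions:
            pruned, prune_log = cond_mod.prune_redundant_conditions(
                ds, config.prune_to, seed=config.seed + 5
            )
            prune_log.to_csv(outdir / "prune_log.tsv", sep="\t", index=False)
            pruned.write(outdir, prefix="sparse")
            report["n_conditions_sparse"] = pruned.n_conditions

        # ------------------------------------------------------------ gci
        stage = "gci"
        observed = gci_mod.compute_gci(ds)
        null = gci_mod.permuted_gci(ds, seed=config.seed + 6)
        observed.to_csv(outdir / "gci.tsv", sep="\t")
        null.to_csv(outdir / "gci_null.tsv", sep="\t")
        summary = gci_mod.gci_summary(observed, null)
        r2_mean, p_mean = gci_mod.gci_vs_mean_expression(observed, ds)
        summary["gci_vs_mean_expr_r2"] = r2_mean
        summary["gci_vs_mean_expr_p"] = p_mean
        report.update({f"gci_{k}": v for k, v in summary.items()})

        # --------------------------------------------------------- models
        stage = "models"
        mean_expr = ds.X.mean(axis=1)
        gci_series = observed.loc[observed["defined"], "r"]
        fits = models.fit_models(scores_df["score"], mean_expr, gci_series)
        models.fits_to_frame(fits).to_csv(outdir / "model_fits.tsv", sep="\t",
                                          index=False)
        for mid, fit in fits.items():
            report[f"adj_r2_{mid}"] = fit.adj_r2
        vifs = models.vif(mean_expr.loc[gci_series.index.intersection(mean_expr.index)],
                          gci_series)
        report["vif"] = max(vifs.values())

        # ------------------------------------------------------- genesets
        stage = "genesets"
        if labels is not None:
            comp = genesets.compare_groups(gci_series, labels)
            report["group_means"] = comp.means
            report["group_t"] = comp.t
            report["group_p"] = comp.p
        if terms is not None:
            pos, neg = split = genesets.split_by_gci_sign(gci_series)
            universe = set(gci_series.index) & set(terms["gene"])
            for name, gene_set in (("positive", pos), ("negative", neg)):
                gene_set = [g for g in gene_set if g in universe]
                if not gene_set:
                    continue
                rows = genesets.enrich(gene_set, universe, terms,
                                       p_max=config.p_max, q_max=config.q_max)
                top = genesets.top_by_odds_ratio(rows, k=config.top_k)
                top.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t",
                           index=False)
                report[f"n_enriched_{name}"] = len(rows)
                if len(top):
                    report[f"top_term_{name}"] = str(top.iloc[0]["term"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ------------------------------------------------------ manifest/report
    manifest = {
        "config": {k: v for k, v in asdict(config).items()},
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name not in ("manifest.json", "report.txt")
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    lines = ["gcicub pipeline report", "======================"]
    for k, v in report.items():
        lines.append(f"{k}: {v}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return outdir
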