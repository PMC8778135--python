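"""End-to-end orchestration: ingest/simulate → preprocess → diversity →
screen → covariate selection → differential abundance → attribution →
subgroup analysis, with every stage artifact persisted as TSV/JSON.

A single global seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence`` so each stage is individually reproducible
and the whole run is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diff_abundance as da
from . import diversity as dv
from . import preprocessing as pp
from . import synthetic_data as syn
from . import variable_screen as vs
from .data_model import (
    CountTable, MetadataFrame, PhyloTree, TaxonomyTable, ValidationError,
    read_count_table, read_metadata, read_taxonomy, read_tree,
    write_count_table, write_metadata,
)

log = logging.getLogger("microconfound")

DEFAULT_METRICS = ("bray_curtis", "canberra", "unweighted_unifrac",
                   "weighted_unifrac")


@dataclass
class RunConfig:
    """Validated settings of one pipeline run; serialized into the outputs."""

    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    sim_scenario: str = "default"  # default | null | confounded
    sim_options: dict = field(default_factory=dict)
    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    tree_path: str | None = None
    schema: dict[str, str] = field(default_factory=dict)
    target: str = "group"
    subgroup: str | None = None
    candidates: list[str] | None = None
    rank: str | None = None
    min_prevalence: float = 0.10
    metrics: list[str] = field(default_factory=lambda: list(DEFAULT_METRICS))
    n_permutations: int = 9999
    alpha: float = 0.05
    size_factor_method: str = "poscounts"
    generalized_alpha: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.min_prevalence <= 1:
            raise ValidationError("min_prevalence must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not self.simulate and not (self.counts_path and self.metadata_path):
            raise ValidationError(
                "either simulate=True or counts/metadata paths are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


@dataclass
class RunReport:
    config: RunConfig
    alpha_table: pd.DataFrame
    covariate_matrix: pd.DataFrame
    screen: vs.ScreenReport
    covariates: list[str]
    confounders: list[str]
    ibd: da.SuiteResult
    ibdcc: da.SuiteResult
    nofs: da.NofReport
    skipped_metrics: list[str] = field(default_factory=list)


def _load_inputs(config: RunConfig, seeds):
    if config.simulate:
        scenarios = {"default": syn.SyntheticConfig.default,
                     "null": syn.SyntheticConfig.null,
                     "confounded": syn.SyntheticConfig.confounded}
        if config.sim_scenario not in scenarios:
            raise ValidationError(f"unknown scenario {config.sim_scenario!r}")
        cfg = scenarios[config.sim_scenario](seed=int(seeds[0]),
                                             **config.sim_options)
        return syn.generate_cohort(cfg)
    table = read_count_table(config.counts_path)
    meta = read_metadata(config.metadata_path, config.schema, config.target,
                         config.subgroup)
    tax = read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
    tree = read_tree(Path(config.tree_path)) if config.tree_path else None
    return table, meta, tax, tree, None


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2 ** 31)

    table, meta, tax, tree, truth = _load_inputs(config, seeds)
    meta = meta.aligned_to(table.sample_ids)
    write_count_table(table, out / "counts_raw.tsv")
    write_metadata(meta, out / "metadata.tsv")
    if truth is not None:
        truth.to_json(out / "truth.json")

    # --- preprocessing --------------------------------------------------
    if config.rank and tax is not None:
        table = pp.agglomerate(table, tax, config.rank)
        log.info("agglomerated to rank %s: %d taxa", config.rank, table.shape[0])
    table, removed = pp.prevalence_filter(table, config.min_prevalence)
    log.info("prevalence filter removed %d taxa", len(removed))
    s = pp.size_factors(table, config.size_factor_method)
    norm = pp.normalize(table, s)
    write_count_table(table, out / "counts_filtered.tsv")
    s.factors.to_csv(out / "size_factors.tsv", sep="\t",
                     index_label="sample_id", header=["size_factor"])

    # --- diversity ------------------------------------------------------
    groups = meta.data[config.target]
    alpha_res = dv.alpha_diversity(table.data, groups)
    alpha_table = pd.DataFrame(
        {m: {"H": r.statistic, "p_value": r.p_value}
         for m, r in alpha_res.items()}).T
    alpha_table.to_csv(out / "alpha_diversity.tsv", sep="\t",
                       index_label="metric")
    pd.DataFrame({m: r.values for m, r in alpha_res.items()}).to_csv(
        out / "alpha_per_sample.tsv", sep="\t", index_label="sample_id")

    distances = {}
    skipped_metrics = []
    for metric in config.metrics:
        try:
            d = dv.beta_distance(norm, metric, tree=tree,
                                 alpha=config.generalized_alpha)
        except ValidationError as exc:
            log.warning("metric %s skipped: %s", metric, exc)
            skipped_metrics.append(metric)
            continue
        distances[metric] = d
        pd.DataFrame(np.asarray(d.data), index=list(d.ids),
                     columns=list(d.ids)).to_csv(
            out / f"beta_{metric}.tsv", sep="\t", index_label="sample_id")
    if not distances:
        raise ValidationError("no beta-diversity metric could be computed")

    # --- screening and covariate selection ------------------------------
    candidates = config.candidates
    if candidates is None:
        candidates = [v for v in meta.variables(exclude_target=True)]
    screen = vs.unbalance_screen(meta, variables=candidates,
                                 alpha=config.alpha, seed=int(seeds[1]))
    screen.table.to_csv(out / "screen.tsv", sep="\t")
    covset = vs.stepwise_covariate_selection(
        distances, meta, candidates, alpha=config.alpha,
        n_perm=config.n_permutations, seed=int(seeds[2]))
    cov_matrix = vs.covariate_matrix(covset, config.target)
    cov_matrix.to_csv(out / "covariate_matrix.tsv", sep="\t",
                      index_label="term")
    covariates = covset.union
    confounders = [v for v in screen.confounders if v not in covariates]
    log.info("covariates: %s; extra confounders: %s", covariates, confounders)

    # --- differential abundance -----------------------------------------
    ibd = da.run_model_suite(table, meta, s=s, mode="IBD", alpha=config.alpha)
    ibdcc = da.run_model_suite(table, meta, covariates=covariates,
                               confounders=confounders, s=s, mode="IBDCC",
                               alpha=config.alpha)
    ibd.results.to_csv(out / "da_ibd.tsv", sep="\t")
    ibdcc.results.to_csv(out / "da_ibdcc.tsv", sep="\t")
    nofs = da.identify_nofs(ibd, ibdcc)
    for taxon in nofs.nofs:
        nofs.attribution[taxon] = da.attribute_nof(
            taxon, table, meta, variables=covariates + confounders, s=s,
            alpha=config.alpha)
    (out / "nof_report.json").write_text(json.dumps({
        "ibd_only": nofs.ibd_only, "ibdcc_only": nofs.ibdcc_only,
        "both": nofs.both,
        "attribution": {t: a.reset_index().to_dict(orient="records")
                        for t, a in nofs.attribution.items()}}, indent=1))

    return RunReport(config, alpha_table, cov_matrix, screen, covariates,
                     confounders, ibd, ibdcc, nofs, skipped_metrics)
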