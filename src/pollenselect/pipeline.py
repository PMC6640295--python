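"""End-to-end assembly: from raw inputs (or a synthetic dataset) to the
per-gene statistics table and the covariate-controlled group comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import compare as cmp
from . import consequences, covariates, divergence, diversity, gene_classes
from .io_formats import GeneModel, VariantRecord
from .synthetic_data import SyntheticDataset

logger = logging.getLogger(__name__)

#: statistics compared between groups (the Bonferroni family)
STATISTICS = ("omega", "theta_n", "pi_n", "stop_allele_frequency", "frameshift_frequency")

COVARIATE_COLUMNS = (
    "expression_level",
    "gc_percent",
    "rscu_variance",
    "gene_length",
    "avg_intron_length",
    "gene_density",
)


@dataclass
class AnalysisResult:
    profiles: pd.DataFrame
    gene_table: pd.DataFrame
    spectra: dict
    comparisons: dict[str, cmp.GroupComparison] = field(default_factory=dict)
    pcr_models: dict[str, cmp.PCRModel] = field(default_factory=dict)


def build_gene_table(
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    expression: pd.DataFrame,
    records: Sequence[VariantRecord],
    strains: Sequence[str],
    tissue_sides: Mapping[str, str],
    cds_a: Mapping[str, str] | None = None,
    cds_b: Mapping[str, str] | None = None,
    hits_ab=None,
    hits_ba=None,
    presence_threshold: float = 0.9,
    fold: bool = True,
    min_identity: float = 30.0,
    min_length: int = 150,
    ds_max: float = 2.0,
) -> AnalysisResult:
    """Classify genes, compute diversity/consequence/covariate statistics
    and (when ortholog inputs are given) counting dN/dS, merged per gene."""
    profiles = gene_classes.classify_table(expression, tissue_sides, presence_threshold)
    levels = dict(zip(profiles["gene_id"], profiles["expression_level"]))
    cov = covariates.covariate_table(models, genome, levels)
    div_df, spectra = diversity.diversity_table(models, genome, records, strains, fold=fold)
    del_df = consequences.deleterious_table(models, genome, records, strains)
    table = (
        profiles.drop(columns=["expression_level"])  # cov carries it already
        .merge(cov, on="gene_id")
        .merge(div_df, on="gene_id")
        .merge(del_df, on="gene_id")
    )
    if cds_a is not None and hits_ab is not None:
        pairs = divergence.reciprocal_best_hits(
            hits_ab, hits_ba, min_identity=min_identity, min_length=min_length
        )
        dnds = divergence.divergence_table(cds_a, cds_b, pairs, ds_max=ds_max)
        dnds = dnds.loc[~dnds["excluded"], ["gene_id_a", "dN", "dS", "omega"]]
        dnds = dnds.rename(columns={"gene_id_a": "gene_id"})
        table = table.merge(dnds, on="gene_id", how="left")
    return AnalysisResult(profiles=profiles, gene_table=table, spectra=spectra)


def run_comparisons(
    result: AnalysisResult,
    grouping: str = "pollen_vs_sporophyte",
    statistics: Sequence[str] = STATISTICS,
    alpha: float = 0.05,
) -> AnalysisResult:
    """Mann-Whitney + PCR + ANCOVA for each statistic between the groups
    of ``grouping``; the Bonferroni family is the statistic list."""
    groups = gene_classes.select_comparison_groups(result.profiles, grouping)
    if not groups["pollen"] or not groups["other"]:
        logger.warning("empty comparison group for %s; tests skipped", grouping)
        return result
    table = result.gene_table.set_index("gene_id")
    family = len([s for s in statistics if s in table.columns])
    for stat in statistics:
        if stat not in table.columns:
            continue
        values = table[stat].replace([np.inf, -np.inf], np.nan).dropna()
        try:
            comparison, pcr = cmp.compare_statistic(
                values,
                table.loc[values.index, list(COVARIATE_COLUMNS)],
                groups,
                family_size=family,
                alpha=alpha,
                statistic=stat,
            )
        except ValueError as exc:
            logger.warning("comparison of %s skipped: %s", stat, exc)
            continue
        result.comparisons[stat] = comparison
        result.pcr_models[stat] = pcr
    return result


def analyze_dataset(
    ds: SyntheticDataset,
    min_quality: float = 25.0,
    grouping: str = "pollen_vs_sporophyte",
    run_tests: bool = True,
) -> AnalysisResult:
    """Full pipeline on one synthetic dataset."""
    merged = gene_classes.merge_pollen_tube(ds.expression, "pollen_tube_a", "pollen_tube_b")
    sides = ds.config.tissue_sides()
    sides.pop("pollen_tube_a", None)
    sides.pop("pollen_tube_b", None)
    sides["pollen_tube"] = "pollen"
    records = [v for v in ds.variants if v.quality >= min_quality]
    result = build_gene_table(
        ds.models, ds.genome, merged, records, ds.strains, sides,
        cds_a=ds.cds_a, cds_b=ds.cds_b, hits_ab=ds.hits_ab, hits_ba=ds.hits_ba,
        min_length=50,  # synthetic proteins start at ~100 aa
    )
    if run_tests:
        result = run_comparisons(result, grouping=grouping)
    return result


def class_spectra(
    result: AnalysisResult, truth: pd.DataFrame
) -> dict[str, "diversity.SFSPair"]:
    """Sum per-gene spectra within each true gene class (DFE input)."""
    class_of = dict(zip(truth["gene_id"], truth["life_stage_class"]))
    out: dict = {}
    for gene_id, pair in result.spectra.items():
        cls = class_of.get(gene_id)
        if cls is None:
            continue
        out[cls] = pair if cls not in out else out[cls] + pair
    return out
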