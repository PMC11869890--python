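"""Glue running the featurization chain end to end.

Turns a drug table, gene-set collection, omics matrices and mutation
profiles into the eight named feature blocks the modeling layer consumes,
and runs the full synthetic-study loop (generate, featurize, label,
train, evaluate) used for signal-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .cell_features import (
    filter_and_impute,
    gsva_scores,
    mutation_pathway_jaccard,
    transform_log2,
)
from .drug_features import (
    filter_descriptors,
    filter_toxicity_terms,
    maccs_matrix,
    pair_feature_block,
    toxicity_matrix,
)
from .io_formats import DrugRecord, GeneSetCollection, OmicsMatrix
from .labeling import assign_labels, clean_response_records, comb_score
from .modeling import (
    FeatureTable,
    Metrics,
    TrainConfig,
    _fit_eval,
    assemble_features,
    split_and_scale,
)
from .pathway_bridge import (
    all_pairs,
    build_combination_pathway_features,
    build_drug_pathway_matrix,
    build_pathway_similarity,
    filter_drugs_and_pathways,
    refine_drug_pathway,
)
from .synthetic_data import SimulationConfig, Universe, generate_responses, generate_universe

__all__ = ["build_feature_blocks", "EndToEndResult", "synthetic_end_to_end"]


def build_feature_blocks(
    drugs: Sequence[DrugRecord],
    genesets: GeneSetCollection,
    omics: Mapping[str, OmicsMatrix],
    mutations: Mapping[str, frozenset[str]],
    maccs: pd.DataFrame | None = None,
    probe_to_gene: Mapping[str, str] | None = None,
    min_targets: int = 10,
    min_genes: int = 10,
    min_drug_fraction: float = 0.5,
    min_descriptor_drugs: int = 10,
    min_toxicity_drugs: int = 1,
) -> tuple[dict[str, pd.DataFrame], list[DrugRecord], GeneSetCollection]:
    """All eight feature blocks after the coverage screening.

    ``maccs`` may supply a precomputed drugs x bits matrix (synthetic
    fingerprints); otherwise bits are computed from each drug's SMILES.
    Returns (blocks, retained drugs, retained gene sets); pair blocks are
    indexed by canonical pair, cell blocks by cell line, and every
    pathway-indexed block uses the retained collection's column order.
    """
    kept_drugs, kept_sets = filter_drugs_and_pathways(
        drugs, genesets, min_targets, min_genes, min_drug_fraction
    )
    drug_ids = [d.drug_id for d in kept_drugs]
    pairs = all_pairs(drug_ids)

    D = build_drug_pathway_matrix(kept_drugs, kept_sets)
    P = build_pathway_similarity(kept_sets)
    ddp = build_combination_pathway_features(D, refine_drug_pathway(D, P), pairs)

    if maccs is None:
        maccs = maccs_matrix(kept_drugs)
    else:
        maccs = maccs.loc[drug_ids]
    kept_bits = filter_descriptors(maccs, min_descriptor_drugs)
    dd_maccs = pair_feature_block(maccs[kept_bits], pairs)

    kept_terms = filter_toxicity_terms(kept_drugs, min_toxicity_drugs)
    dd_tox = pair_feature_block(toxicity_matrix(kept_drugs, kept_terms), pairs)

    blocks: dict[str, pd.DataFrame] = {
        "DD_MACCS": dd_maccs,
        "DD_TOX": dd_tox,
        "DDP": ddp,
    }
    for assay in ("EXP", "CNV"):
        blocks[assay] = gsva_scores(transform_log2(omics[assay]), kept_sets).scores
    for assay in ("METHY", "RNAi"):
        imputed = filter_and_impute(omics[assay], probe_to_gene=probe_to_gene)
        blocks[assay] = gsva_scores(imputed, kept_sets).scores
    blocks["MUT"] = mutation_pathway_jaccard(mutations, kept_sets).scores
    return blocks, kept_drugs, kept_sets


@dataclass
class EndToEndResult:
    """Outcome of one synthetic study run."""

    metrics: Metrics
    prevalence: float
    threshold: float
    model: object
    train: FeatureTable
    test: FeatureTable
    blocks: dict[str, pd.DataFrame]
    universe: Universe


def synthetic_end_to_end(
    sim_config: SimulationConfig,
    train_config: TrainConfig | None = None,
    block_selection: Sequence[str] | None = None,
) -> EndToEndResult:
    """Generate a universe, featurize, label, train and evaluate.

    The train/test split seed follows the simulation seed so distinct
    simulated studies get distinct splits.
    """
    if train_config is None:
        train_config = TrainConfig(seed=sim_config.seed)
    universe = generate_universe(sim_config)
    records, truth = generate_responses(universe, sim_config)
    blocks, kept_drugs, _ = build_feature_blocks(
        universe.drugs,
        universe.genesets,
        universe.omics,
        universe.mutations,
        maccs=universe.maccs,
        probe_to_gene=universe.probe_to_gene,
    )
    scores = comb_score(clean_response_records(records, excluded_drug_ids=frozenset()))
    kept_ids = {d.drug_id for d in kept_drugs}
    scores = scores[
        [a in kept_ids and b in kept_ids for a, b, _ in scores.index]
    ]
    labels = assign_labels(scores, threshold=truth.threshold)
    table = assemble_features(blocks, labels, block_selection=block_selection)
    train, test, _ = split_and_scale(table, train_config.test_fraction, train_config.seed)
    metrics, model = _fit_eval(train, test, train_config)
    prevalence = float(test.y.mean())
    return EndToEndResult(
        metrics=metrics,
        prevalence=prevalence,
        threshold=truth.threshold,
        model=model,
        train=train,
        test=test,
        blocks=blocks,
        universe=universe,
    )
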