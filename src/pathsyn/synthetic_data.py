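"""Synthetic study universes with a planted pathway-mediated synergy signal.

The generator emits every input the pipeline consumes — drugs with target
and toxicity sets, pathway gene sets, fingerprint bits, omics matrices,
mutation profiles, dose-response records and replicate viability tables —
internally consistent and fully determined by a seed.

The synergy signal is planted *through the pathway bridge*: each drug is
biased toward a few "home" pathways, a small set of driver pathways
carries a per-cell-line activity weight, and the true synergy of a pair
in a cell line is ``alpha * <a_pair, w_cell>`` plus noise, where
``a_pair`` is the combination-pathway vector the featurization computes.
Expression values of driver-pathway genes are shifted by the same cell
activity, so both the DDP block and the cell-line pathway scores carry
recoverable signal. Dose-response records are constructed so that the
combination score (mean expected-minus-observed growth) recovers the
planted value exactly when noise is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .idacombo import ViabilityTable, idacombo_score
from .io_formats import (
    DrugRecord,
    GeneSetCollection,
    OmicsMatrix,
    ResponseRecord,
    write_drug_table,
    write_gmt,
    write_mutation_profiles,
    write_omics_matrix,
    write_response_table,
)
from .pathway_bridge import (
    all_pairs,
    build_combination_pathway_features,
    build_drug_pathway_matrix,
    build_pathway_similarity,
    refine_drug_pathway,
)

__all__ = [
    "SimulationConfig",
    "Universe",
    "GroundTruth",
    "generate_universe",
    "generate_responses",
    "generate_viability_table",
    "write_universe",
]


@dataclass
class SimulationConfig:
    """Desk-scale study conditions; see docs/methods.md for rationale."""

    n_genes: int = 500
    n_drugs: int = 20
    n_pathways: int = 30
    n_cell_lines: int = 12
    pathway_size: tuple[int, int] = (10, 50)
    targets_per_drug: tuple[int, int] = (15, 40)
    n_maccs_bits: int = 166
    maccs_bit_prob: float = 0.55
    n_tox_terms: int = 120
    tox_term_prob: float = 0.08
    dose_points: int = 9  # emulates a 3x3 concentration grid
    alpha: float = 1.0  # planted signal strength
    sigma: float = 0.5  # pair-level noise sd
    sigma_dose: float = 2.0  # per-dose-point noise sd
    n_driver_pathways: int = 3
    home_pathways_per_drug: tuple[int, int] = (1, 3)
    home_target_fraction: float = 0.6
    expression_shift: float = 1.5  # log2 shift of driver genes per activity unit
    target_prevalence: float = 0.1
    label_threshold: float | None = None  # None: calibrate to target_prevalence
    na_rate: float = 0.1
    probe_duplicate_fraction: float = 0.2
    mutation_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_drugs", "n_pathways", "n_cell_lines", "dose_points"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.targets_per_drug[0] < 10:
            raise ValueError("targets per drug must be >= 10 so screening is satisfiable")
        if self.targets_per_drug[1] > self.n_genes:
            raise ValueError("more targets per drug than genes in the universe")
        if self.pathway_size[1] > self.n_genes:
            raise ValueError("pathway size exceeds the gene universe")
        if self.alpha < 0 or self.sigma < 0 or self.sigma_dose < 0:
            raise ValueError("alpha and noise sds must be non-negative")


@dataclass
class Universe:
    """Everything upstream of the dose-response records."""

    drugs: list[DrugRecord]
    genesets: GeneSetCollection
    maccs: pd.DataFrame  # drugs x MACCS-like bits
    omics: dict[str, OmicsMatrix]  # EXP (TPM), CNV (ratio), METHY, RNAi
    mutations: dict[str, frozenset[str]]
    probe_to_gene: dict[str, str]
    cell_lines: list[str]
    pathway_activity: pd.DataFrame  # cells x pathways latent weights
    driver_pathways: list[str]


@dataclass
class GroundTruth:
    """Planted values kept alongside the generated data for recovery tests."""

    synergy: pd.Series  # (drug_a, drug_b, cell_line) -> planted value
    weights: pd.DataFrame  # cells x pathways
    threshold: float


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_universe(config: SimulationConfig) -> Universe:
    """Drugs, pathways, fingerprints, omics and mutations from one seed."""
    rng = _rng(config.seed)
    genes = np.array([f"g{i:04d}" for i in range(config.n_genes)])
    cells = [f"C{j:02d}" for j in range(config.n_cell_lines)]

    # pathways: gene sets sampled without replacement within each set
    names = [f"PW{k:03d}" for k in range(config.n_pathways)]
    sizes = rng.integers(
        config.pathway_size[0], config.pathway_size[1] + 1, config.n_pathways
    )
    sets = {
        name: frozenset(rng.choice(genes, size=int(s), replace=False))
        for name, s in zip(names, sizes)
    }
    genesets = GeneSetCollection(sets)
    # drivers: the largest pathways, so the coverage filters retain them
    drivers = [
        names[k] for k in np.argsort(-sizes, kind="stable")[: config.n_driver_pathways]
    ]

    # drugs: targets biased toward 1-3 home pathways
    drugs = []
    for i in range(config.n_drugs):
        n_home = int(rng.integers(*config.home_pathways_per_drug, endpoint=True))
        home = rng.choice(names, size=n_home, replace=False)
        home_genes = np.array(sorted(set().union(*(sets[h] for h in home))))
        n_targets = int(rng.integers(*config.targets_per_drug, endpoint=True))
        n_from_home = min(
            int(round(config.home_target_fraction * n_targets)), len(home_genes)
        )
        picked = set(rng.choice(home_genes, size=n_from_home, replace=False))
        rest = np.array(sorted(set(genes) - picked))
        picked |= set(rng.choice(rest, size=n_targets - n_from_home, replace=False))
        drugs.append(
            DrugRecord(
                drug_id=f"D{i:03d}",
                smiles=None,
                target_genes=frozenset(picked),
                toxicity_terms=frozenset(
                    f"T{t:03d}"
                    for t in range(config.n_tox_terms)
                    if rng.random() < config.tox_term_prob
                ),
            )
        )

    maccs = pd.DataFrame(
        (rng.random((config.n_drugs, config.n_maccs_bits)) < config.maccs_bit_prob)
        .astype(np.int64),
        index=[d.drug_id for d in drugs],
        columns=[f"MACCS_{k:03d}" for k in range(1, config.n_maccs_bits + 1)],
    )

    # latent per-cell pathway activity: drivers share a cell-level magnitude
    gamma = np.clip(rng.normal(1.0, 0.3, config.n_cell_lines), 0.2, None)
    W = pd.DataFrame(0.0, index=cells, columns=names)
    for d in drivers:
        W[d] = gamma

    # expression: log2-scale baseline plus driver-pathway shift
    mu = rng.normal(3.0, 1.5, config.n_genes)
    log_expr = mu[:, None] + rng.normal(0.0, 0.7, (config.n_genes, config.n_cell_lines))
    for d in drivers:
        member = np.isin(genes, list(sets[d]))
        log_expr[member] += config.expression_shift * gamma[None, :]
    exp_tpm = np.clip(np.exp2(log_expr) - 1.0, 0.0, None)
    omics = {
        "EXP": OmicsMatrix("EXP", pd.DataFrame(exp_tpm, index=genes, columns=cells)),
        "CNV": OmicsMatrix(
            "CNV",
            pd.DataFrame(
                np.exp2(rng.normal(0.0, 0.15, (config.n_genes, config.n_cell_lines))),
                index=genes,
                columns=cells,
            ),
        ),
    }

    # methylation: beta-like values, some genes carried by two probes
    n_dup = int(round(config.probe_duplicate_fraction * config.n_genes))
    dup_genes = set(rng.choice(genes, size=n_dup, replace=False))
    probe_rows, probe_ids, probe_to_gene = [], [], {}
    base_meth = rng.beta(2.0, 2.0, (config.n_genes, config.n_cell_lines))
    for gi, g in enumerate(genes):
        n_probes = 2 if g in dup_genes else 1
        for p in range(n_probes):
            pid = f"{g}::p{p + 1}"
            probe_ids.append(pid)
            probe_to_gene[pid] = g
            probe_rows.append(
                np.clip(
                    base_meth[gi] + rng.normal(0.0, 0.05, config.n_cell_lines), 0.0, 1.0
                )
            )
    methy = np.array(probe_rows)
    if config.na_rate > 0:
        methy[rng.random(methy.shape) < config.na_rate] = np.nan
    omics["METHY"] = OmicsMatrix(
        "METHY", pd.DataFrame(methy, index=probe_ids, columns=cells)
    )

    rnai = rng.normal(0.0, 0.5, (config.n_genes, config.n_cell_lines))
    if config.na_rate > 0:
        rnai[rng.random(rnai.shape) < config.na_rate] = np.nan
    omics["RNAi"] = OmicsMatrix("RNAi", pd.DataFrame(rnai, index=genes, columns=cells))

    mutations = {
        cell: frozenset(genes[rng.random(config.n_genes) < config.mutation_rate])
        for cell in cells
    }

    return Universe(
        drugs=drugs,
        genesets=genesets,
        maccs=maccs,
        omics=omics,
        mutations=mutations,
        probe_to_gene=probe_to_gene,
        cell_lines=cells,
        pathway_activity=W,
        driver_pathways=drivers,
    )


def generate_responses(
    universe: Universe, config: SimulationConfig
) -> tuple[list[ResponseRecord], GroundTruth]:
    """Dose-point records whose combination score recovers the planted signal.

    For each (pair, cell line) the planted synergy is
    ``s = alpha * <a_pair, w_cell> + eps`` with ``eps ~ N(0, sigma^2)``;
    each of the ``dose_points`` records carries an expected growth E and
    an observed growth ``E - s - eta`` with ``eta ~ N(0, sigma_dose^2)``,
    so the group mean of (expected - observed) equals s plus mean noise.
    """
    rng = _rng(config.seed + 1)
    D = build_drug_pathway_matrix(universe.drugs, universe.genesets)
    P = build_pathway_similarity(universe.genesets)
    A = build_combination_pathway_features(
        D, refine_drug_pathway(D, P), all_pairs(list(D.index))
    )
    W = universe.pathway_activity

    keys, planted = [], []
    for a, b in A.index:
        a_vec = A.loc[(a, b)].to_numpy()
        for cell in universe.cell_lines:
            s = config.alpha * float(a_vec @ W.loc[cell].to_numpy())
            if config.sigma > 0:
                s += rng.normal(0.0, config.sigma)
            keys.append((a, b, cell))
            planted.append(s)
    synergy = pd.Series(
        planted,
        index=pd.MultiIndex.from_tuples(keys, names=["drug_a", "drug_b", "cell_line"]),
        name="synergy",
    )

    if config.label_threshold is not None:
        threshold = config.label_threshold
    else:
        threshold = float(np.quantile(synergy, 1.0 - config.target_prevalence))

    records = []
    for (a, b, cell), s in synergy.items():
        expected = rng.uniform(60.0, 100.0, config.dose_points)
        noise = (
            rng.normal(0.0, config.sigma_dose, config.dose_points)
            if config.sigma_dose > 0
            else np.zeros(config.dose_points)
        )
        for e, eta in zip(expected, noise):
            records.append(
                ResponseRecord(
                    drug_a=a,
                    drug_b=b,
                    cell_line=cell,
                    expected_growth=float(e),
                    observed_growth=float(e - s - eta),
                )
            )
    truth = GroundTruth(synergy=synergy, weights=W.copy(), threshold=threshold)
    return records, truth


def generate_viability_table(
    arm_means: tuple[float, float, float] = (0.84, 0.77, 0.66),
    sd: float = 0.05,
    n_replicates: int = 8,
    seed: int = 0,
) -> tuple[ViabilityTable, float]:
    """Replicate viability table with a known closed-form combination score.

    Arms are (mono_a, mono_b, combo); replicates are Normal(mean, sd).
    The returned true score is the zero-noise value computed from the arm
    means.
    """
    rng = _rng(seed)
    names = ("mono_a", "mono_b", "combo")
    arms = {
        name: rng.normal(mean, sd, n_replicates) if sd > 0 else np.full(n_replicates, mean)
        for name, mean in zip(names, arm_means)
    }
    best = min(arm_means[0], arm_means[1])
    delta = best - arm_means[2]
    true_score = delta - delta * (arm_means[2] / best)
    return ViabilityTable(arms=arms), true_score


def write_universe(
    universe: Universe,
    records: list[ResponseRecord],
    truth: GroundTruth,
    outdir,
) -> None:
    """Write every generated input as the text formats the readers accept."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_drug_table(universe.drugs, out / "drugs.tsv")
    write_gmt(universe.genesets, out / "pathways.gmt")
    universe.maccs.to_csv(out / "maccs.tsv", sep="\t", index_label="drug_id")
    for assay, matrix in universe.omics.items():
        write_omics_matrix(matrix, out / f"{assay.lower()}.tsv")
    write_mutation_profiles(universe.mutations, out / "mutations.tsv")
    with open(out / "probe_map.tsv", "w", encoding="utf-8") as fh:
        fh.write("probe\tgene\n")
        for probe, gene in universe.probe_to_gene.items():
            fh.write(f"{probe}\t{gene}\n")
    write_response_table(records, out / "responses.csv")
    truth_df = truth.synergy.reset_index()
    truth_df["threshold"] = truth.threshold
    truth_df.to_csv(out / "truth.csv", index=False)
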