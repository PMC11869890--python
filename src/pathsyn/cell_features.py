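"""Omics preprocessing and cell-line x pathway scoring.

Continuous assays (expression, copy number, methylation, RNAi) are scored
per cell line and pathway with a gene set variation analysis (GSVA):
a Gaussian-kernel estimate of each gene's expression CDF across cell
lines, per-sample gene ranks, and a Kolmogorov-Smirnov-like random walk
over each gene set whose maximum deviation from zero is the enrichment
score. Mutation data are scored as the Jaccard overlap between a cell
line's mutated-gene set and each pathway's gene set.

Upstream preprocessing: log2(x+1) transforms for expression (TPM) and
copy-number ratios, and NA filtering + K-nearest-neighbor imputation +
probe-to-gene collapse for methylation and RNAi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_formats import GeneSetCollection, OmicsMatrix

__all__ = [
    "CellLinePathwayMatrix",
    "transform_log2",
    "filter_and_impute",
    "gsva_scores",
    "mutation_pathway_jaccard",
]


@dataclass
class CellLinePathwayMatrix:
    """Cell lines x pathways scores for one assay block.

    Column order equals the gene-set collection order; GSVA scores lie in
    [-1, 1], mutation-Jaccard scores in [0, 1].
    """

    assay: str
    scores: pd.DataFrame  # index: cell lines, columns: pathways


def transform_log2(matrix: OmicsMatrix) -> OmicsMatrix:
    """Elementwise log2(x+1); for TPM expression and copy-number ratios."""
    if matrix.assay not in ("EXP", "CNV"):
        raise ValueError(f"log2(x+1) transform is not defined for {matrix.assay}")
    if (matrix.values.to_numpy() < 0).any():
        raise ValueError(f"{matrix.assay}: negative values cannot be log2(x+1) transformed")
    return OmicsMatrix(assay=matrix.assay, values=np.log2(matrix.values + 1.0))


def filter_and_impute(
    matrix: OmicsMatrix,
    max_na_fraction: float = 0.7,
    k: int = 5,
    probe_to_gene: Mapping[str, str] | None = None,
) -> OmicsMatrix:
    """Drop high-NA rows, KNN-impute the rest, collapse probes to genes.

    Rows whose NA fraction strictly exceeds ``max_na_fraction`` are
    removed. A missing entry (row g, cell c) is imputed as the mean value
    at c of the ``k`` rows nearest to g, with Euclidean distance computed
    over jointly observed cells and rescaled by the number of such cells
    (the scikit-learn ``nan_euclidean`` convention). Rows sharing a gene
    id under ``probe_to_gene`` are then averaged per cell line; rows
    absent from the mapping keep their own id.
    """
    if matrix.assay not in ("METHY", "RNAi"):
        raise ValueError(f"filter_and_impute applies to METHY/RNAi, not {matrix.assay}")
    values = matrix.values
    na_frac = values.isna().mean(axis=1)
    kept = values.loc[na_frac <= max_na_fraction]
    if kept.empty:
        raise ValueError("all rows exceeded the NA-fraction limit")
    if kept.notna().sum(axis=1).eq(0).any():
        raise ValueError("row with zero observed entries")
    if kept.isna().any().any():
        from sklearn.impute import KNNImputer

        imputer = KNNImputer(n_neighbors=min(k, len(kept) - 1))
        imputed = pd.DataFrame(
            imputer.fit_transform(kept.to_numpy()),
            index=kept.index,
            columns=kept.columns,
        )
    else:
        imputed = kept
    if probe_to_gene is not None:
        genes = [probe_to_gene.get(rid, rid) for rid in imputed.index]
        imputed = imputed.groupby(pd.Index(genes, name=imputed.index.name)).mean()
    return OmicsMatrix(assay=matrix.assay, values=imputed)


# ---------------------------------------------------------------------------
# GSVA

#: floor on the kernel bandwidth, as a fraction of the matrix value range,
#: so constant gene rows get a tiny but positive bandwidth
_BANDWIDTH_FLOOR = 1e-8


def _gene_density_ranks(values: np.ndarray) -> np.ndarray:
    """Per-sample gene ranks of the kernel-CDF scores (1 = lowest score).

    For gene i and sample j the score is the Gaussian-kernel CDF estimate
    ``mean_k Phi((x_ij - x_ik) / h_i)`` with bandwidth ``h_i = sd_i / 4``
    (sample sd), floored to survive constant rows.
    """
    p, n = values.shape
    span = float(values.max() - values.min()) if values.size else 1.0
    floor = _BANDWIDTH_FLOOR * max(span, 1.0)
    z = np.empty_like(values, dtype=float)
    for i in range(p):
        h = max(values[i].std(ddof=1) / 4.0, floor)
        z[i] = norm.cdf((values[i][:, None] - values[i][None, :]) / h).mean(axis=1)
    # increasing ranks per sample: highest CDF score -> rank p
    ranks = np.empty_like(z, dtype=np.int64)
    for j in range(n):
        order = np.argsort(z[:, j], kind="stable")
        ranks[order, j] = np.arange(1, p + 1)
    return ranks


def _walk_es(ranks_j: np.ndarray, member: np.ndarray, tau: float) -> float:
    """Max-deviation KS-like walk statistic for one sample and gene set."""
    p = ranks_j.shape[0]
    k = int(member.sum())
    order = np.argsort(-ranks_j, kind="stable")  # decreasing density order
    mem = member[order]
    weight = np.abs(ranks_j[order] - p / 2.0) ** tau
    up = np.where(mem, weight, 0.0)
    total = up.sum()
    walk = np.cumsum(up / total - (~mem) / (p - k))
    return float(walk[np.argmax(np.abs(walk))])


def gsva_scores(
    matrix: OmicsMatrix,
    genesets: GeneSetCollection,
    tau: float = 1.0,
) -> CellLinePathwayMatrix:
    """GSVA enrichment scores per cell line and pathway.

    Pathways with no gene present in the matrix rows are scored 0 with a
    warning. Scores are deterministic, bounded in [-1, 1], and invariant
    to the row order of the omics matrix.
    """
    values = matrix.values
    if values.shape[1] < 2:
        raise ValueError("GSVA needs at least two cell lines")
    if values.isna().any().any():
        raise ValueError("impute missing values before GSVA")
    genes = list(values.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    ranks = _gene_density_ranks(values.to_numpy(dtype=float))
    p, n = ranks.shape
    scores = np.zeros((n, len(genesets)))
    for col, name in enumerate(genesets.names):
        member = np.zeros(p, dtype=bool)
        for g in genesets[name]:
            i = gene_pos.get(g)
            if i is not None:
                member[i] = True
        if not member.any():
            warnings.warn(
                f"pathway {name!r} shares no genes with the {matrix.assay} matrix; scored 0",
                stacklevel=2,
            )
            continue
        if member.all():
            raise ValueError(f"pathway {name!r} covers every gene row; walk undefined")
        for j in range(n):
            scores[j, col] = _walk_es(ranks[:, j], member, tau)
    return CellLinePathwayMatrix(
        assay=matrix.assay,
        scores=pd.DataFrame(scores, index=list(values.columns), columns=genesets.names),
    )


def mutation_pathway_jaccard(
    profiles: Mapping[str, frozenset[str]] | Mapping[str, set[str]],
    genesets: GeneSetCollection,
    cell_lines: Sequence[str] | None = None,
) -> CellLinePathwayMatrix:
    """Jaccard overlap of mutated genes with each pathway's gene set.

    An empty mutated set scores 0 on every pathway (empty intersection
    over a non-empty union).
    """
    cells = list(profiles) if cell_lines is None else list(cell_lines)
    out = np.zeros((len(cells), len(genesets)))
    for i, cell in enumerate(cells):
        mutated = set(profiles[cell])
        for j, name in enumerate(genesets.names):
            pathway = genesets[name]
            union = len(mutated | pathway)
            out[i, j] = len(mutated & pathway) / union if union else 0.0
    return CellLinePathwayMatrix(
        assay="MUT",
        scores=pd.DataFrame(out, index=cells, columns=genesets.names),
    )
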