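"""Pathway-bridged featurization of drug pairs.

Pathways act as the bridge between drug-level and cell-line-level
information. The chain is:

* ``D`` — the m x n drug-pathway indicator matrix: ``d_ij = 1`` iff the
  target-gene set of drug *i* intersects the gene set of pathway *j*.
* ``P`` — the n x n pathway-pathway Jaccard matrix quantifying gene
  overlap between pathways.
* ``D~ = D P`` — the refined drug-pathway score matrix, which propagates
  a drug's direct pathway hits to correlated pathways.
* ``A`` — the drug-combination tensor with entries
  ``a_ijk = (d_ik * d~_jk + d_jk * d~_ik) / 2``, a symmetric per-pathway
  score for the unordered pair (i, j), emitted as the DDP feature block.

Upstream of the matrices sit the coverage filters: drugs need a minimum
number of target genes, pathways a minimum number of genes, and a pathway
is kept only if at least a given fraction of the retained drugs act on it.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import DrugRecord, GeneSetCollection

__all__ = [
    "canonical_pair",
    "all_pairs",
    "filter_drugs_and_pathways",
    "build_drug_pathway_matrix",
    "build_pathway_similarity",
    "refine_drug_pathway",
    "build_combination_pathway_features",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical key of an unordered drug pair: lexicographically sorted."""
    if a == b:
        raise ValueError(f"pair of a drug with itself: {a!r}")
    return (a, b) if a < b else (b, a)


def all_pairs(drug_ids: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered pairs over ``drug_ids``, canonical keys, stable order."""
    ids = list(drug_ids)
    return [canonical_pair(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


def filter_drugs_and_pathways(
    drugs: Sequence[DrugRecord],
    genesets: GeneSetCollection,
    min_targets: int = 10,
    min_genes: int = 10,
    min_drug_fraction: float = 0.5,
) -> tuple[list[DrugRecord], GeneSetCollection]:
    """Apply the three coverage criteria in one pass.

    (i) drop drugs with fewer than ``min_targets`` target genes (inclusive
    boundary: exactly ``min_targets`` is kept); (ii) drop pathways with
    fewer than ``min_genes`` genes; (iii) drop pathways on which fewer
    than ``min_drug_fraction`` of the *retained* drugs act, where a drug
    acts on a pathway iff its target set intersects the pathway's gene
    set. Input orders are preserved; filtering is a single pass, not a
    fixpoint iteration.
    """
    if not drugs or len(genesets) == 0:
        raise ValueError("empty drug table or gene-set collection")
    kept_drugs = [d for d in drugs if len(d.target_genes) >= min_targets]
    if not kept_drugs:
        raise ValueError(f"no drug has >= {min_targets} target genes")
    kept_names = []
    for name in genesets.names:
        genes = genesets[name]
        if len(genes) < min_genes:
            continue
        acting = sum(1 for d in kept_drugs if d.target_genes & genes)
        if acting >= min_drug_fraction * len(kept_drugs):
            kept_names.append(name)
    if not kept_names:
        raise ValueError("all pathways were filtered out")
    return kept_drugs, genesets.subset(kept_names)


def build_drug_pathway_matrix(
    drugs: Sequence[DrugRecord], genesets: GeneSetCollection
) -> pd.DataFrame:
    """Indicator matrix D: 1 iff the drug's targets hit the pathway."""
    data = np.zeros((len(drugs), len(genesets)), dtype=np.int64)
    for i, drug in enumerate(drugs):
        for j, name in enumerate(genesets.names):
            if drug.target_genes & genesets[name]:
                data[i, j] = 1
    return pd.DataFrame(
        data, index=[d.drug_id for d in drugs], columns=genesets.names
    )


def build_pathway_similarity(genesets: GeneSetCollection) -> pd.DataFrame:
    """Jaccard matrix P over pathway gene sets; diagonal exactly 1."""
    names = genesets.names
    n = len(names)
    out = np.ones((n, n))
    sets = [genesets[name] for name in names]
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            out[i, j] = out[j, i] = inter / union
    return pd.DataFrame(out, index=names, columns=names)


def refine_drug_pathway(D: pd.DataFrame, P: pd.DataFrame) -> pd.DataFrame:
    """Refined scores D~ = D P, spreading hits along pathway similarity."""
    if list(D.columns) != list(P.index):
        raise ValueError("pathway order of D and P differ")
    return pd.DataFrame(
        D.to_numpy(dtype=float) @ P.to_numpy(dtype=float),
        index=D.index,
        columns=P.columns,
    )


def build_combination_pathway_features(
    D: pd.DataFrame,
    D_refined: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """The DDP block: per unordered pair the vector a_ij over pathways.

    ``a_ijk = (d_ik * d~_jk + d_jk * d~_ik) / 2`` — symmetric in (i, j)
    and zero on every pathway neither drug acts on directly.
    """
    if list(D.columns) != list(D_refined.columns) or not D.index.equals(
        D_refined.index
    ):
        raise ValueError("D and D~ must share drug and pathway orders")
    keys = [canonical_pair(a, b) for a, b in pairs]
    unknown = {d for k in keys for d in k} - set(D.index)
    if unknown:
        raise KeyError(f"pairs reference unknown drugs: {sorted(unknown)}")
    Dv = D.to_numpy(dtype=float)
    Rv = D_refined.to_numpy(dtype=float)
    row = {d: i for i, d in enumerate(D.index)}
    ia = np.array([row[k[0]] for k in keys])
    ib = np.array([row[k[1]] for k in keys])
    values = 0.5 * (Dv[ia] * Rv[ib] + Dv[ib] * Rv[ia])
    return pd.DataFrame(
        values,
        index=pd.MultiIndex.from_tuples(keys, names=["drug_a", "drug_b"]),
        columns=D.columns,
    )
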