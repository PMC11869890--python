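"""Structural (MACCS) and toxicity features for drugs and drug pairs.

Single drugs are encoded as binary vectors — 166 MACCS substructure keys
for chemistry, one bit per retained side-effect term for toxicity. A drug
pair is encoded as the elementwise sum of its two drug vectors, so each
pair entry is 0 (neither drug has the feature), 1 (exactly one does) or
2 (both do); the encoding is symmetric in the pair by construction.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import DrugRecord
from .pathway_bridge import canonical_pair

__all__ = [
    "ChemistryError",
    "compute_maccs",
    "maccs_matrix",
    "toxicity_matrix",
    "filter_descriptors",
    "filter_toxicity_terms",
    "encode_pair_sum",
    "pair_feature_block",
]

N_MACCS_KEYS = 166


class ChemistryError(ValueError):
    """A SMILES string could not be parsed."""


def compute_maccs(smiles: str, drug_id: str | None = None) -> pd.Series:
    """166-key MACCS fingerprint of one molecule as a 0/1 Series.

    RDKit emits 167 bits with index 0 as a padding position; that bit is
    discarded so position ``MACCS_001`` holds key 1 of the standard
    definition. Deterministic for a given SMILES.
    """
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        who = f" for drug {drug_id!r}" if drug_id else ""
        raise ChemistryError(f"unparseable SMILES {smiles!r}{who}")
    fp = MACCSkeys.GenMACCSKeys(mol)
    bits = np.zeros(N_MACCS_KEYS, dtype=np.int64)
    for i in fp.GetOnBits():
        if i >= 1:  # bit 0 is padding in the 167-length RDKit output
            bits[i - 1] = 1
    index = [f"MACCS_{k:03d}" for k in range(1, N_MACCS_KEYS + 1)]
    return pd.Series(bits, index=index)


def maccs_matrix(drugs: Sequence[DrugRecord]) -> pd.DataFrame:
    """Drugs x 166 MACCS bit matrix; every drug needs a parseable SMILES."""
    rows = {}
    for drug in drugs:
        if drug.smiles is None:
            raise ChemistryError(f"drug {drug.drug_id!r} has no SMILES")
        rows[drug.drug_id] = compute_maccs(drug.smiles, drug.drug_id)
    return pd.DataFrame.from_dict(rows, orient="index").loc[
        [d.drug_id for d in drugs]
    ]


def toxicity_matrix(
    drugs: Sequence[DrugRecord], terms: Sequence[str] | None = None
) -> pd.DataFrame:
    """Drugs x terms 0/1 matrix from each drug's toxicity-term set.

    ``terms`` fixes the column set and order; by default it is the sorted
    union of all observed terms. Drugs with no recorded toxicity get an
    all-zero row.
    """
    if terms is None:
        universe: set[str] = set()
        for d in drugs:
            universe |= d.toxicity_terms
        terms = sorted(universe)
    data = np.zeros((len(drugs), len(terms)), dtype=np.int64)
    col = {t: j for j, t in enumerate(terms)}
    for i, d in enumerate(drugs):
        for t in d.toxicity_terms:
            if t in col:
                data[i, col[t]] = 1
    return pd.DataFrame(data, index=[d.drug_id for d in drugs], columns=list(terms))


def filter_descriptors(vectors: pd.DataFrame, min_drugs: int = 10) -> list[str]:
    """Columns (descriptor positions) set in at least ``min_drugs`` drugs.

    The count is taken over the drug rows actually supplied, i.e. the
    post-screening drug set; order of retained columns is preserved.
    """
    if len(vectors) < 1:
        raise ValueError("need at least one drug")
    keep = vectors.sum(axis=0) >= min_drugs
    return [c for c in vectors.columns if keep[c]]


def filter_toxicity_terms(
    term_sets: Mapping[str, frozenset[str]] | Sequence[DrugRecord],
    min_drugs: int = 1,
) -> list[str]:
    """Terms attached to at least ``min_drugs`` drugs, sorted for stability."""
    if not isinstance(term_sets, Mapping):
        term_sets = {d.drug_id: d.toxicity_terms for d in term_sets}
    if len(term_sets) < 1:
        raise ValueError("need at least one drug")
    counts: dict[str, int] = {}
    for terms in term_sets.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return sorted(t for t, n in counts.items() if n >= min_drugs)


def encode_pair_sum(vec_a: pd.Series, vec_b: pd.Series) -> pd.Series:
    """Elementwise sum of two aligned 0/1 vectors; entries in {0, 1, 2}."""
    if not vec_a.index.equals(vec_b.index):
        raise ValueError("position sets of the two vectors differ")
    return vec_a + vec_b


def pair_feature_block(
    single_matrix: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Pair x feature block: row for each unordered pair, entries bit_a+bit_b.

    Rows are indexed by the canonical (lexicographically sorted) pair key,
    so the block is symmetric in the order the pair was supplied.
    """
    keys = [canonical_pair(a, b) for a, b in pairs]
    unknown = {d for k in keys for d in k} - set(single_matrix.index)
    if unknown:
        raise KeyError(f"pairs reference unknown drugs: {sorted(unknown)}")
    left = single_matrix.loc[[k[0] for k in keys]].to_numpy()
    right = single_matrix.loc[[k[1] for k in keys]].to_numpy()
    return pd.DataFrame(
        left + right,
        index=pd.MultiIndex.from_tuples(keys, names=["drug_a", "drug_b"]),
        columns=single_matrix.columns,
    )
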