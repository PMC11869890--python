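"""Readers and writers for the tabular formats the pipeline exchanges.

All tables are UTF-8 text: GMT for gene sets, TSV for matrices and drug
tables, CSV for dose-response records, labels and predictions. Identifiers
(genes, drugs, cell lines, pathways) are opaque case-sensitive strings; no
symbol normalization is performed. The literal token ``NA`` marks a missing
value and is only legal in methylation and RNAi matrices prior to
imputation. Growth values are percent-growth reals and are not clamped:
NCI-ALMANAC-style growth can exceed 100 or be negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "GeneSetCollection",
    "DrugRecord",
    "ResponseRecord",
    "OmicsMatrix",
    "OMICS_ASSAYS",
    "read_gmt",
    "write_gmt",
    "read_drug_table",
    "write_drug_table",
    "read_response_table",
    "write_response_table",
    "read_omics_matrix",
    "write_omics_matrix",
    "read_mutation_profiles",
    "write_mutation_profiles",
    "write_predictions",
]

#: assays carried as continuous genes x cell-lines matrices
OMICS_ASSAYS = ("EXP", "CNV", "METHY", "RNAi")

#: assays in which a pre-imputation NA token is legal
_NA_ASSAYS = frozenset({"METHY", "RNAi"})

_FLOAT_FMT = "%.17g"  # shortest exact decimal: reals round-trip bit-exactly


class FormatError(ValueError):
    """A file violated the format contract (bad header, token, or value)."""


@dataclass
class GeneSetCollection:
    """An ordered mapping pathway id -> gene set.

    The insertion order of ``sets`` is the canonical pathway order: every
    downstream pathway-indexed matrix uses it as column order.
    """

    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        """Restrict to ``names``, preserving the given order."""
        return GeneSetCollection({n: self.sets[n] for n in names})


@dataclass(frozen=True)
class DrugRecord:
    """One drug: identity, structure, targets and known toxicity terms."""

    drug_id: str
    smiles: Optional[str] = None
    target_genes: frozenset[str] = field(default_factory=frozenset)
    toxicity_terms: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class ResponseRecord:
    """One dose point of a growth experiment.

    ``drug_b`` is ``None`` for single-agent rows (later removed by
    ``labeling.clean_response_records``). Growth values are on the percent
    growth scale relative to untreated control.
    """

    drug_a: str
    drug_b: Optional[str]
    cell_line: str
    expected_growth: float
    observed_growth: float


@dataclass
class OmicsMatrix:
    """A genes-or-probes x cell-lines matrix for one assay."""

    assay: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.assay not in OMICS_ASSAYS:
            raise FormatError(
                f"unknown assay {self.assay!r}; expected one of {OMICS_ASSAYS}"
            )
        if self.values.index.has_duplicates:
            raise FormatError(f"{self.assay}: duplicate row ids")
        if self.values.columns.has_duplicates:
            raise FormatError(f"{self.assay}: duplicate cell-line ids")
        if self.assay not in _NA_ASSAYS and self.values.isna().any().any():
            raise FormatError(f"{self.assay}: NA values are not allowed")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one gene set per line, ``name<TAB>desc<TAB>genes...``.

    Duplicate genes within a line are deduplicated; duplicate set names and
    empty gene lists are format errors. File order is preserved and becomes
    the canonical pathway order.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(genesets: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in genesets.sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Drug tables (TSV: drug_id, smiles, targets |-joined, toxicity |-joined)

_DRUG_COLUMNS = ["drug_id", "smiles", "target_genes", "toxicity_terms"]


def _split_bar(token: str) -> frozenset[str]:
    return frozenset(t for t in token.split("|") if t) if token else frozenset()


def read_drug_table(path) -> list[DrugRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _DRUG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["drug_id"].duplicated().any():
        dupes = sorted(df.loc[df["drug_id"].duplicated(), "drug_id"])
        raise FormatError(f"{path}: duplicate drug ids {dupes}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            DrugRecord(
                drug_id=row.drug_id,
                smiles=row.smiles or None,
                target_genes=_split_bar(row.target_genes),
                toxicity_terms=_split_bar(row.toxicity_terms),
            )
        )
    return records


def write_drug_table(drugs: Sequence[DrugRecord], path) -> None:
    rows = [
        {
            "drug_id": d.drug_id,
            "smiles": d.smiles or "",
            "target_genes": "|".join(sorted(d.target_genes)),
            "toxicity_terms": "|".join(sorted(d.toxicity_terms)),
        }
        for d in drugs
    ]
    pd.DataFrame(rows, columns=_DRUG_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dose-response tables (CSV)

_RESPONSE_COLUMNS = [
    "drug_a",
    "drug_b",
    "cell_line",
    "expected_growth",
    "observed_growth",
]


def read_response_table(path) -> list[ResponseRecord]:
    """Read dose-point records; an empty ``drug_b`` means single-agent."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        values = []
        for col in ("expected_growth", "observed_growth"):
            token = getattr(row, col)
            try:
                value = float(token)
            except ValueError:
                value = math.nan
            if not math.isfinite(value):
                raise FormatError(
                    f"{path}: row {i}: non-numeric {col} value {token!r}"
                )
            values.append(value)
        records.append(
            ResponseRecord(
                drug_a=row.drug_a,
                drug_b=row.drug_b or None,
                cell_line=row.cell_line,
                expected_growth=values[0],
                observed_growth=values[1],
            )
        )
    return records


def write_response_table(records: Sequence[ResponseRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(_RESPONSE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                ",".join(
                    [
                        r.drug_a,
                        r.drug_b or "",
                        r.cell_line,
                        _FLOAT_FMT % r.expected_growth,
                        _FLOAT_FMT % r.observed_growth,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Omics matrices (TSV, first column row id)


def read_omics_matrix(path, assay: str) -> OmicsMatrix:
    if assay not in OMICS_ASSAYS:
        raise FormatError(f"unknown assay {assay!r}")
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        tokens = df[col]
        is_na = tokens == "NA"
        if is_na.any() and assay not in _NA_ASSAYS:
            raise FormatError(f"{path}: NA token not allowed in {assay}")
        try:
            parsed[col] = pd.to_numeric(tokens.where(~is_na, None))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: column {col!r}: {exc}") from exc
    return OmicsMatrix(assay=assay, values=parsed)


def write_omics_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.values.to_csv(
        path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT, index_label="id"
    )


# ---------------------------------------------------------------------------
# Mutation profiles (TSV: cell_line, mutated genes |-joined)


def read_mutation_profiles(path) -> dict[str, frozenset[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("cell_line", "mutated_genes"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df["cell_line"].duplicated().any():
        raise FormatError(f"{path}: duplicate cell-line ids")
    return {
        row.cell_line: _split_bar(row.mutated_genes)
        for row in df.itertuples(index=False)
    }


def write_mutation_profiles(profiles: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cell_line\tmutated_genes\n")
        for cell, genes in profiles.items():
            fh.write(f"{cell}\t{'|'.join(sorted(genes))}\n")


# ---------------------------------------------------------------------------
# Predictions (CSV, deterministic row order)


def write_predictions(
    instances: Sequence[tuple[str, str, str]],
    scores: Sequence[float],
    labels: Sequence[int],
    path,
) -> None:
    """Write per-instance scores/labels sorted by (drug_a, drug_b, cell_line)."""
    if not (len(instances) == len(scores) == len(labels)):
        raise FormatError(
            f"length mismatch: {len(instances)} instances, "
            f"{len(scores)} scores, {len(labels)} labels"
        )
    rows = sorted(
        zip(instances, scores, labels), key=lambda item: tuple(item[0])
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_a,drug_b,cell_line,score,predicted_label\n")
        for (a, b, cell), score, label in rows:
            fh.write(f"{a},{b},{cell},{_FLOAT_FMT % score},{int(label)}\n")
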