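"""Dose-response cleaning and combination-score labeling.

A (drug pair, cell line) group of dose points is summarized by its
combination score: the mean over dose points of (expected growth minus
observed percent growth). The sign convention makes synergy positive —
the pair suppressed growth more than the two single agents predict.
Concentration identity is ignored; every dose point weighs equally.
Groups whose score strictly exceeds a threshold are labeled synergistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Mapping, Sequence

import pandas as pd

from .io_formats import ResponseRecord
from .pathway_bridge import canonical_pair

__all__ = [
    "SynergyLabel",
    "DEFAULT_EXCLUDED_DRUGS",
    "clean_response_records",
    "comb_score",
    "assign_labels",
]

#: NSC753082 and NSC761431 are the same drug (vinorelbine) under two ids;
#: the default exclusion keeps only the latter's records.
DEFAULT_EXCLUDED_DRUGS = frozenset({"NSC753082"})


@dataclass(frozen=True)
class SynergyLabel:
    """Binary synergy call for one (pair, cell line) instance."""

    drug_a: str  # canonical order: drug_a < drug_b
    drug_b: str
    cell_line: str
    comb_score: float
    threshold: float
    label: int

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.drug_a, self.drug_b, self.cell_line)


def clean_response_records(
    records: Sequence[ResponseRecord],
    excluded_drug_ids: AbstractSet[str] = DEFAULT_EXCLUDED_DRUGS,
) -> list[ResponseRecord]:
    """Drop single-agent rows and rows touching any excluded drug id."""
    kept = []
    n_single = n_excluded = 0
    for r in records:
        if r.drug_b is None:
            n_single += 1
            continue
        if r.drug_a in excluded_drug_ids or r.drug_b in excluded_drug_ids:
            n_excluded += 1
            continue
        kept.append(r)
    if n_single or n_excluded:
        import logging

        logging.getLogger(__name__).info(
            "dropped %d single-agent and %d excluded-drug dose points; %d kept",
            n_single,
            n_excluded,
            len(kept),
        )
    return kept


def comb_score(records: Sequence[ResponseRecord]) -> pd.Series:
    """Mean of (expected - observed) growth per (pair, cell line) group.

    Returns a Series indexed by (drug_a, drug_b, cell_line) with the pair
    in canonical order, so the score is invariant to dose-point row order
    and to swapping drug_a/drug_b. Single-agent rows must have been
    removed upstream.
    """
    if not records:
        raise ValueError("no dose-point records to score")
    rows = []
    for r in records:
        if r.drug_b is None:
            raise ValueError(
                f"single-agent record for {r.drug_a!r} reached comb_score; "
                "run clean_response_records first"
            )
        a, b = canonical_pair(r.drug_a, r.drug_b)
        rows.append((a, b, r.cell_line, r.expected_growth - r.observed_growth))
    df = pd.DataFrame(rows, columns=["drug_a", "drug_b", "cell_line", "diff"])
    scores = df.groupby(["drug_a", "drug_b", "cell_line"], sort=True)["diff"].mean()
    scores.name = "comb_score"
    return scores


def assign_labels(
    scores: pd.Series | Mapping[tuple[str, str, str], float],
    threshold: float = 4.0,
) -> list[SynergyLabel]:
    """Strict-inequality labeling: synergistic iff score > threshold.

    A score exactly at the threshold is non-synergistic. The conventional
    thresholds are 4 (permissive) and 10 (strict); any real is accepted.
    """
    if not isinstance(scores, pd.Series):
        scores = pd.Series(dict(scores))
    labels = []
    for (a, b, cell), score in scores.items():
        labels.append(
            SynergyLabel(
                drug_a=a,
                drug_b=b,
                cell_line=cell,
                comb_score=float(score),
                threshold=threshold,
                label=int(score > threshold),
            )
        )
    return labels
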