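"""Wet-lab validation statistics for combination-vs-monotherapy viability.

Replicate cell-viability fractions (1.0 = untreated control) are measured
for two monotherapy arms and one or more combination arms. The best
monotherapy is the arm with the lower mean viability. The combination
statistic compares the combination against it:

    delta_via = mean(best mono) - mean(combo)
    HR        = mean(combo) / mean(best mono)
    score     = delta_via - delta_via * HR

With the mean-ratio hazard-ratio estimator this simplifies to
``delta_via**2 / mean(best mono)``, which is non-negative and zero exactly
when the combination matches the best monotherapy. A combination is
called synergistic when the score exceeds a decision cutoff (default
0.004). Replicates are unpaired across arms; only arm means enter the
score. Viability values above 1 are retained, not clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import FormatError

__all__ = [
    "ViabilityTable",
    "IDAComboResult",
    "DEFAULT_CUTOFF",
    "viability_percent",
    "idacombo_score",
    "score_viability_table",
    "read_viability_table",
    "load_t47d_validation",
]

DEFAULT_CUTOFF = 0.004


@dataclass
class ViabilityTable:
    """Arm name -> replicate viability fractions."""

    arms: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for arm, values in self.arms.items():
            values = np.asarray(values, dtype=float)
            if values.size == 0:
                raise ValueError(f"arm {arm!r} has no replicates")
            if not np.isfinite(values).all() or (values < 0).any():
                raise ValueError(f"arm {arm!r} has non-finite or negative viability")
            self.arms[arm] = values


@dataclass(frozen=True)
class IDAComboResult:
    best_monotherapy: str
    delta_via: float
    hazard_ratio: float
    score: float
    synergistic: bool


def viability_percent(a_drug: float, a_control: float) -> float:
    """Percent viability of a treated well relative to untreated control."""
    if a_control <= 0:
        raise ValueError("control absorbance must be positive")
    return a_drug / a_control * 100.0


def idacombo_score(
    mono_a: Sequence[float],
    mono_b: Sequence[float],
    combo: Sequence[float],
    cutoff: float = DEFAULT_CUTOFF,
    mono_names: tuple[str, str] = ("mono_a", "mono_b"),
) -> IDAComboResult:
    """Combination score against the best (lower mean viability) monotherapy.

    Invariant under swapping the two monotherapy arms.
    """
    arms = [np.asarray(a, dtype=float) for a in (mono_a, mono_b, combo)]
    for name, values in zip((*mono_names, "combo"), arms):
        if values.size == 0:
            raise ValueError(f"arm {name!r} has no replicates")
    mean_a, mean_b, mean_combo = (float(a.mean()) for a in arms)
    if mean_a <= mean_b:
        best_name, best_mean = mono_names[0], mean_a
    else:
        best_name, best_mean = mono_names[1], mean_b
    delta_via = best_mean - mean_combo
    hazard_ratio = mean_combo / best_mean
    score = delta_via - delta_via * hazard_ratio
    return IDAComboResult(
        best_monotherapy=best_name,
        delta_via=delta_via,
        hazard_ratio=hazard_ratio,
        score=score,
        synergistic=score > cutoff,
    )


def score_viability_table(
    table: ViabilityTable,
    mono_arms: tuple[str, str],
    combo_arms: Sequence[str] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> dict[str, IDAComboResult]:
    """Score each combination arm of a table against the two monotherapies."""
    if combo_arms is None:
        combo_arms = [a for a in table.arms if a not in mono_arms]
    if not combo_arms:
        raise ValueError("table has no combination arms")
    return {
        arm: idacombo_score(
            table.arms[mono_arms[0]],
            table.arms[mono_arms[1]],
            table.arms[arm],
            cutoff=cutoff,
            mono_names=mono_arms,
        )
        for arm in combo_arms
    }


def read_viability_table(path) -> ViabilityTable:
    """CSV with columns arm, replicate_index, viability."""
    df = pd.read_csv(path)
    for col in ("arm", "replicate_index", "viability"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    arms = {
        str(arm): group.sort_values("replicate_index")["viability"].to_numpy(float)
        for arm, group in df.groupby("arm", sort=False)
    }
    return ViabilityTable(arms=arms)


def load_t47d_validation() -> ViabilityTable:
    """Bundled CCK-8 replicate viabilities for the T-47D experiment.

    Eight replicates per arm for bleomycin (200 nmol/L), bortezomib
    (40 nmol/L) and their combination administered in both orders
    (combination_1, combination_2) on the T-47D breast-cancer line.
    """
    ref = resources.files("pathsyn.data") / "t47d_viability.csv"
    with resources.as_file(ref) as path:
        return read_viability_table(path)
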