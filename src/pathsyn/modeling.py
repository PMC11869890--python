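"""Feature assembly, imbalance handling, model fitting and evaluation.

The design matrix for one (drug pair, cell line) instance concatenates up
to eight feature blocks in a fixed canonical order: three pair-level
blocks (DD_MACCS, DD_TOX, DDP) indexed by the unordered drug pair, and
five cell-line-level blocks (EXP, CNV, METHY, MUT, RNAi) indexed by cell
line. On top of that sit a stratified 80:20 split with train-only
standardization, three imbalance corrections (class weights, random
undersampling of the majority class, SMOTE oversampling of the minority
class to a target negative:positive ratio), gradient-boosted-tree and
classical baseline classifiers behind one adapter, exhaustive
feature-subset search ranked by average rank of recall/F1/AUPR, per-block
importance analysis with top-k refits, and scoring of unlabeled
(pair, cell line) instances.

Cross-validation supports two modes. ``leak_free`` (default) resamples
inside each training fold only, so synthetic or duplicated minority
points never reach a validation fold. ``resample_then_fold`` resamples the
full training set first and then folds it; with oversampling this leaks
near-duplicates across fold boundaries and inflates the metrics, which
is exactly why the mode exists: to quantify that optimism.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

from .labeling import SynergyLabel
from .pathway_bridge import all_pairs, canonical_pair

__all__ = [
    "BLOCK_ORDER",
    "PAIR_BLOCKS",
    "CELL_BLOCKS",
    "FeatureTable",
    "TrainConfig",
    "Metrics",
    "EvaluationReport",
    "make_model",
    "assemble_features",
    "split_and_scale",
    "rebalance",
    "evaluate",
    "cross_validate",
    "grid_search",
    "feature_set_search",
    "enumerate_block_subsets",
    "feature_importance_by_block",
    "top_k_refit",
    "unlabeled_keys",
    "predict_unlabeled",
]

BLOCK_ORDER = ("DD_MACCS", "DD_TOX", "DDP", "EXP", "CNV", "METHY", "MUT", "RNAi")
PAIR_BLOCKS = frozenset({"DD_MACCS", "DD_TOX", "DDP"})
CELL_BLOCKS = frozenset(BLOCK_ORDER) - PAIR_BLOCKS

#: index marker of SMOTE-synthesized rows (provenance tag)
SMOTE_MARKER = "__smote__"

#: production hyperparameter grid for the gradient-boosted model
DEFAULT_GRID: dict[str, list] = {
    "learning_rate": [0.05, 0.1],
    "max_depth": [5, 7],
    "n_estimators": [300, 700],
}


@dataclass
class FeatureTable:
    """Assembled design matrix with aligned labels and block bookkeeping."""

    X: pd.DataFrame  # rows: (drug_a, drug_b, cell_line) MultiIndex
    y: pd.Series | None
    block_columns: dict[str, list[str]]

    @property
    def width(self) -> int:
        return self.X.shape[1]

    def select_columns(self, columns: Sequence[str]) -> "FeatureTable":
        cols = list(columns)
        blocks = {
            b: [c for c in cs if c in set(cols)]
            for b, cs in self.block_columns.items()
        }
        return FeatureTable(
            X=self.X[cols], y=self.y, block_columns={b: cs for b, cs in blocks.items() if cs}
        )


@dataclass
class TrainConfig:
    """Everything a training run needs; all randomness flows from ``seed``."""

    model_family: str = "xgboost"
    params: dict = field(
        default_factory=lambda: {
            "learning_rate": 0.1,
            "max_depth": 7,
            "n_estimators": 700,
        }
    )
    grid: dict[str, list] | None = None
    imbalance_strategy: str = "weights"  # weights | undersample | oversample
    ratio: float = 2.0  # target negative:positive count ratio
    k_smote: int = 5
    test_fraction: float = 0.2
    folds: int = 5
    cv_mode: str = "leak_free"  # leak_free | resample_then_fold
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.imbalance_strategy not in ("weights", "undersample", "oversample"):
            raise ValueError(f"unknown imbalance strategy {self.imbalance_strategy!r}")
        if self.cv_mode not in ("leak_free", "resample_then_fold"):
            raise ValueError(f"unknown cv mode {self.cv_mode!r}")

    def replace(self, **kwargs) -> "TrainConfig":
        data = asdict(self)
        data.update(kwargs)
        return TrainConfig(**data)


@dataclass(frozen=True)
class Metrics:
    """The six binary-classification metrics on one evaluation set."""

    acc: float
    prec: float
    recall: float
    f1: float
    auc: float
    aupr: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ACC": self.acc,
            "PREC": self.prec,
            "recall": self.recall,
            "F1": self.f1,
            "AUC": self.auc,
            "AUPR": self.aupr,
        }


@dataclass
class EvaluationReport:
    """Per-fold metrics plus their means."""

    per_fold: list[Metrics]

    @property
    def mean(self) -> Metrics:
        arrays = np.array(
            [[m.acc, m.prec, m.recall, m.f1, m.auc, m.aupr] for m in self.per_fold]
        )
        return Metrics(*arrays.mean(axis=0))


# ---------------------------------------------------------------------------
# Model adapter

_FAMILIES = ("xgboost", "logistic", "lasso-logistic", "random-forest", "svm")


def make_model(family: str, params: Mapping | None = None, seed: int = 0):
    """Uniform constructor over the supported classifier families.

    Every returned estimator supports ``fit(X, y, sample_weight=...)`` and
    ``predict_proba``.
    """
    params = dict(params or {})
    if family == "xgboost":
        from xgboost import XGBClassifier

        params.setdefault("tree_method", "hist")
        params.setdefault("eval_metric", "logloss")
        return XGBClassifier(random_state=seed, n_jobs=1, **params)
    if family == "logistic":
        from sklearn.linear_model import LogisticRegression

        params.setdefault("max_iter", 5000)
        return LogisticRegression(random_state=seed, **params)
    if family == "lasso-logistic":
        from sklearn.linear_model import LogisticRegression

        params.setdefault("max_iter", 5000)
        return LogisticRegression(
            penalty="l1", solver="liblinear", random_state=seed, **params
        )
    if family == "random-forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "svm":
        from sklearn.svm import SVC

        params.setdefault("probability", True)
        return SVC(random_state=seed, **params)
    raise ValueError(f"unknown model family {family!r}; expected one of {_FAMILIES}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# Feature assembly


def assemble_features(
    blocks: Mapping[str, pd.DataFrame],
    labels: Sequence[SynergyLabel] | None = None,
    block_selection: Sequence[str] | None = None,
    instances: Sequence[tuple[str, str, str]] | None = None,
) -> FeatureTable:
    """Concatenate the selected blocks in canonical order for each instance.

    Pair blocks are indexed by the canonical (drug_a, drug_b) key, cell
    blocks by cell line. Instances come either from ``labels`` or from an
    explicit ``instances`` key list (for unlabeled prediction). An
    instance missing from any selected block is an error naming it.
    """
    if labels is None and instances is None:
        raise ValueError("provide labels or an explicit instance list")
    if instances is None:
        instances = [lab.key for lab in labels]  # type: ignore[union-attr]
    if block_selection is None:
        block_selection = [b for b in BLOCK_ORDER if b in blocks]
    else:
        unknown = set(block_selection) - set(BLOCK_ORDER)
        if unknown:
            raise ValueError(f"unknown blocks {sorted(unknown)}")
        block_selection = [b for b in BLOCK_ORDER if b in block_selection]
    if not block_selection:
        raise ValueError("no feature blocks selected")

    index = pd.MultiIndex.from_tuples(
        instances, names=["drug_a", "drug_b", "cell_line"]
    )
    parts = []
    block_columns: dict[str, list[str]] = {}
    for block in block_selection:
        df = blocks[block]
        if block in PAIR_BLOCKS:
            keys = [canonical_pair(a, b) for a, b, _ in instances]
            have = set(df.index)
            for key, inst in zip(keys, instances):
                if key not in have:
                    raise KeyError(f"instance {inst} missing from block {block}")
            part = df.loc[keys]
        else:
            have = set(df.index)
            cells = [c for _, _, c in instances]
            for cell, inst in zip(cells, instances):
                if cell not in have:
                    raise KeyError(f"instance {inst} missing from block {block}")
            part = df.loc[cells]
        part = part.set_axis(index, axis=0)
        renamed = [f"{block}|{c}" for c in part.columns]
        part = part.set_axis(renamed, axis=1)
        block_columns[block] = renamed
        parts.append(part)
    X = pd.concat(parts, axis=1).astype(float)
    y = None
    if labels is not None:
        y = pd.Series([lab.label for lab in labels], index=index, name="label")
    return FeatureTable(X=X, y=y, block_columns=block_columns)


def split_and_scale(
    table: FeatureTable, test_fraction: float = 0.2, seed: int = 0
) -> tuple[FeatureTable, FeatureTable, StandardScaler]:
    """Stratified train/test split with train-only standardization.

    The per-column mean and standard deviation are estimated on the
    training partition only and applied to both partitions, so no test
    information reaches the scaler.
    """
    if table.y is None:
        raise ValueError("cannot split an unlabeled table")
    if len(table.X) < 10:
        raise ValueError("need at least 10 instances to split")
    y = table.y.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present before splitting")
    idx_train, idx_test = train_test_split(
        np.arange(len(y)),
        test_size=test_fraction,
        stratify=y,
        random_state=seed,
    )
    idx_train.sort()
    idx_test.sort()
    for part in (idx_train, idx_test):
        if len(np.unique(y[part])) < 2:
            raise ValueError("a class is absent from one partition")
    scaler = StandardScaler()
    X_train = pd.DataFrame(
        scaler.fit_transform(table.X.iloc[idx_train].to_numpy()),
        index=table.X.index[idx_train],
        columns=table.X.columns,
    )
    X_test = pd.DataFrame(
        scaler.transform(table.X.iloc[idx_test].to_numpy()),
        index=table.X.index[idx_test],
        columns=table.X.columns,
    )
    train = FeatureTable(X_train, table.y.iloc[idx_train], dict(table.block_columns))
    test = FeatureTable(X_test, table.y.iloc[idx_test], dict(table.block_columns))
    return train, test, scaler


# ---------------------------------------------------------------------------
# Imbalance correction


def _smote(
    X_min: np.ndarray, n_new: int, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthesize ``n_new`` minority points by neighbor interpolation.

    Returns (synthetic rows, parent index, neighbor index) so provenance
    is traceable to the minority rows used.
    """
    from sklearn.neighbors import NearestNeighbors

    if len(X_min) < k + 1:
        raise ValueError(
            f"minority class has {len(X_min)} instances; SMOTE with k={k} "
            f"needs at least {k + 1}"
        )
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neighbors = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    base = rng.integers(0, len(X_min), size=n_new)
    pick = neighbors[base, rng.integers(0, k, size=n_new)]
    gap = rng.random(n_new)[:, None]
    synth = X_min[base] + gap * (X_min[pick] - X_min[base])
    return synth, base, pick


def rebalance(
    X: pd.DataFrame,
    y: pd.Series,
    strategy: str,
    ratio: float = 2.0,
    k_smote: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray | None]:
    """Correct the class imbalance toward a negative:positive ``ratio``.

    ``weights``   — no resampling; returns per-instance weights with the
                    positive class upweighted by the negative:positive
                    count ratio (inverse class frequency).
    ``undersample`` — randomly drop negatives until neg:pos == ratio.
    ``oversample``  — SMOTE-synthesize positives until neg:pos == ratio;
                    synthetic rows carry a ``__smote__`` index marker
                    recording their two parent rows.
    """
    yv = y.to_numpy()
    n_pos = int((yv == 1).sum())
    n_neg = int((yv == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to rebalance")
    rng = np.random.default_rng(seed)

    if strategy == "weights":
        w = np.where(yv == 1, n_neg / n_pos, 1.0)
        return X, y, w

    if strategy == "undersample":
        target_neg = int(round(n_pos * ratio))
        if n_neg <= target_neg:
            return X, y, None
        neg_pos = np.flatnonzero(yv == 0)
        keep_neg = rng.choice(neg_pos, size=target_neg, replace=False)
        keep = np.sort(np.concatenate([np.flatnonzero(yv == 1), keep_neg]))
        return X.iloc[keep], y.iloc[keep], None

    if strategy == "oversample":
        target_pos = int(round(n_neg / ratio))
        n_new = target_pos - n_pos
        if n_new <= 0:
            return X, y, None
        min_pos = np.flatnonzero(yv == 1)
        X_min = X.iloc[min_pos].to_numpy()
        synth, base, pick = _smote(X_min, n_new, k_smote, rng)
        parents = [
            (
                SMOTE_MARKER,
                f"{_key_str(X.index[min_pos[b]])}+{_key_str(X.index[min_pos[p]])}",
                str(t),
            )
            for t, (b, p) in enumerate(zip(base, pick))
        ]
        X_new = pd.DataFrame(
            synth,
            index=pd.MultiIndex.from_tuples(parents, names=X.index.names),
            columns=X.columns,
        )
        X_out = pd.concat([X, X_new])
        y_out = pd.concat(
            [y, pd.Series(np.ones(n_new, dtype=yv.dtype), index=X_new.index, name=y.name)]
        )
        return X_out, y_out, None

    raise ValueError(f"unknown strategy {strategy!r}")


def _key_str(key) -> str:
    return "/".join(map(str, key)) if isinstance(key, tuple) else str(key)


# ---------------------------------------------------------------------------
# Metrics


def evaluate(y_true, scores, threshold: float = 0.5) -> Metrics:
    """The six metrics from labels and probability scores.

    Hard calls use ``score >= threshold``; precision is 0 when nothing is
    called positive. AUC is the Mann-Whitney rank statistic (midranks for
    ties); AUPR is step-function precision-recall integration over the
    distinct score thresholds (identical to average precision).
    """
    y = np.asarray(y_true, dtype=np.int64)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must align")
    if (s < 0).any() or (s > 1).any():
        raise ValueError("scores must lie in [0, 1]")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC/AUPR are undefined for a single-class label vector")

    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = n_pos - tp
    acc = float(np.mean(pred == (y == 1)))
    prec = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn)
    f1 = 2 * prec * recall / (prec + recall) if (prec + recall) > 0 else 0.0

    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.flatnonzero(np.diff(s_sorted))
    cut = np.concatenate([distinct, [len(y_sorted) - 1]])
    tps = np.cumsum(y_sorted)[cut]
    fps = cut + 1 - tps
    precision = tps / (tps + fps)
    recall_curve = tps / n_pos
    aupr = float(np.sum(np.diff(np.concatenate([[0.0], recall_curve])) * precision))

    return Metrics(acc=acc, prec=float(prec), recall=float(recall), f1=float(f1),
                   auc=float(auc), aupr=aupr)


# ---------------------------------------------------------------------------
# Cross-validation and grid search


def _fit_model(config: TrainConfig, X, y, sample_weight=None):
    model = make_model(config.model_family, config.params, seed=config.seed)
    model.fit(np.asarray(X, dtype=float), np.asarray(y), sample_weight=sample_weight)
    return model


def cross_validate(
    X: pd.DataFrame, y: pd.Series, config: TrainConfig
) -> EvaluationReport:
    """Stratified k-fold cross-validation under the configured imbalance fix.

    ``leak_free`` applies the resampling inside each fold to the training
    split only; ``resample_then_fold`` resamples the full set first and
    folds the resampled set directly (optimistic with oversampling).
    """
    yv = y.to_numpy()
    if min((yv == 1).sum(), (yv == 0).sum()) < config.folds:
        raise ValueError("a fold would lack one of the classes")
    skf = StratifiedKFold(
        n_splits=config.folds, shuffle=True, random_state=config.seed
    )
    per_fold = []
    if config.cv_mode == "resample_then_fold":
        Xr, yr, w = rebalance(
            X, y, config.imbalance_strategy, config.ratio, config.k_smote, config.seed
        )
        w = np.ones(len(yr)) if w is None else w
        Xv, yv2 = Xr.to_numpy(), yr.to_numpy()
        for train_idx, val_idx in skf.split(Xv, yv2):
            model = _fit_model(config, Xv[train_idx], yv2[train_idx], w[train_idx])
            per_fold.append(
                evaluate(yv2[val_idx], _scores(model, Xv[val_idx]), config.threshold)
            )
    else:
        for train_idx, val_idx in skf.split(X.to_numpy(), yv):
            X_tr, y_tr, w = rebalance(
                X.iloc[train_idx],
                y.iloc[train_idx],
                config.imbalance_strategy,
                config.ratio,
                config.k_smote,
                config.seed,
            )
            model = _fit_model(config, X_tr.to_numpy(), y_tr.to_numpy(), w)
            per_fold.append(
                evaluate(
                    yv[val_idx],
                    _scores(model, X.iloc[val_idx].to_numpy()),
                    config.threshold,
                )
            )
    return EvaluationReport(per_fold=per_fold)


def grid_search(
    X: pd.DataFrame, y: pd.Series, config: TrainConfig
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid evaluation by mean cross-validated AUPR.

    Ties keep the first point in grid order. Returns the best parameter
    dict and the full results table.
    """
    grid = config.grid or DEFAULT_GRID
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    names = list(grid)
    rows = []
    best: tuple[float, dict] | None = None
    for values in itertools.product(*(grid[n] for n in names)):
        point = dict(zip(names, values))
        cfg = config.replace(params={**config.params, **point})
        aupr = cross_validate(X, y, cfg).mean.aupr
        rows.append({**point, "mean_cv_aupr": aupr})
        if best is None or aupr > best[0]:
            best = (aupr, point)
    assert best is not None
    return best[1], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feature-set search and importance analysis


def enumerate_block_subsets(block_names: Sequence[str]) -> list[tuple[str, ...]]:
    """Every non-empty subset of the blocks, in bitmask order.

    Bit i of the mask corresponds to the i-th block in canonical order;
    8 blocks give 255 subsets.
    """
    ordered = [b for b in BLOCK_ORDER if b in block_names]
    if len(ordered) != len(block_names):
        raise ValueError("block names must be drawn from the canonical order")
    subsets = []
    for mask in range(1, 2 ** len(ordered)):
        subsets.append(tuple(b for i, b in enumerate(ordered) if mask >> i & 1))
    return subsets


def _fit_eval(
    train: FeatureTable, test: FeatureTable, config: TrainConfig
) -> tuple[Metrics, object]:
    X_tr, y_tr, w = rebalance(
        train.X, train.y, config.imbalance_strategy, config.ratio,
        config.k_smote, config.seed,
    )
    model = _fit_model(config, X_tr.to_numpy(), y_tr.to_numpy(), w)
    metrics = evaluate(
        test.y.to_numpy(), _scores(model, test.X.to_numpy()), config.threshold
    )
    return metrics, model


def feature_set_search(
    blocks: Mapping[str, pd.DataFrame],
    labels: Sequence[SynergyLabel],
    config: TrainConfig,
) -> pd.DataFrame:
    """Evaluate every non-empty block subset with one shared model config.

    Each subset is trained on the same stratified split and scored on the
    held-out test partition. Subsets are ranked separately on recall, F1
    and AUPR (rank 1 = best) and ordered by the average of the three
    ranks; ties break by AUPR, then by subset bitmask.
    """
    table = assemble_features(blocks, labels)
    train, test, _ = split_and_scale(table, config.test_fraction, config.seed)
    subsets = enumerate_block_subsets(list(table.block_columns))
    rows = []
    for mask_minus_1, subset in enumerate(subsets):
        cols = [c for b in subset for c in table.block_columns[b]]
        metrics, _ = _fit_eval(
            train.select_columns(cols), test.select_columns(cols), config
        )
        rows.append(
            {
                "blocks": "+".join(subset),
                "n_blocks": len(subset),
                "bitmask": mask_minus_1 + 1,
                "width": len(cols),
                **metrics.as_dict(),
            }
        )
    df = pd.DataFrame(rows)
    for metric in ("recall", "F1", "AUPR"):
        df[f"rank_{metric}"] = rankdata(-df[metric].to_numpy(), method="min")
    df["average_rank"] = df[["rank_recall", "rank_F1", "rank_AUPR"]].mean(axis=1)
    df = df.sort_values(
        ["average_rank", "AUPR", "bitmask"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return df


def feature_importance_by_block(
    model, table: FeatureTable
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-block importance proportions and per-feature descending ranking.

    Requires a fitted tree ensemble exposing gain-type importances
    (``feature_importances_``); proportions sum to 1.
    """
    if not hasattr(model, "feature_importances_"):
        raise TypeError(
            "feature importance analysis needs a tree-ensemble model with "
            "feature_importances_"
        )
    importances = np.asarray(model.feature_importances_, dtype=float)
    if importances.shape[0] != table.width:
        raise ValueError("model was fitted on a different design matrix")
    total = importances.sum()
    if total <= 0:
        raise ValueError("all feature importances are zero")
    per_feature = pd.DataFrame(
        {
            "feature": table.X.columns,
            "block": [
                next(b for b, cs in table.block_columns.items() if c in set(cs))
                for c in table.X.columns
            ],
            "importance": importances,
        }
    )
    proportions = (
        per_feature.groupby("block")["importance"].sum() / total
    ).reindex([b for b in BLOCK_ORDER if b in table.block_columns])
    per_feature = per_feature.sort_values(
        ["block", "importance"], ascending=[True, False]
    ).reset_index(drop=True)
    per_feature["rank_in_block"] = per_feature.groupby("block").cumcount() + 1
    return proportions, per_feature


def top_k_refit(
    train: FeatureTable,
    test: FeatureTable,
    per_feature: pd.DataFrame,
    config: TrainConfig,
    ks: Sequence[int] = (1, 2, 3, 4, 5, 10),
) -> pd.DataFrame:
    """Refit on the top-k most important features of each block, per k.

    ``per_feature`` is the ranking from :func:`feature_importance_by_block`.
    A ``k`` larger than a block's width is capped at the width with a
    warning. One row per k with all six metrics.
    """
    rows = []
    for k in ks:
        cols = []
        for block, cs in train.block_columns.items():
            ranked = per_feature.loc[per_feature["block"] == block, "feature"]
            if k > len(ranked):
                warnings.warn(
                    f"k={k} exceeds width {len(ranked)} of block {block}; capped",
                    stacklevel=2,
                )
            cols.extend(ranked.head(k).tolist())
        cols = [c for c in train.X.columns if c in set(cols)]
        metrics, _ = _fit_eval(
            train.select_columns(cols), test.select_columns(cols), config
        )
        rows.append({"k": k, "width": len(cols), **metrics.as_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Unlabeled prediction


def unlabeled_keys(
    drug_ids: Sequence[str],
    cell_lines: Sequence[str],
    labeled_keys: Sequence[tuple[str, str, str]],
) -> list[tuple[str, str, str]]:
    """All (pair, cell line) instances not covered by a label.

    Labeled and unlabeled keys partition the full pair x cell-line grid.
    """
    labeled = {
        (*canonical_pair(a, b), c) for a, b, c in labeled_keys
    }
    keys = []
    for a, b in all_pairs(drug_ids):
        for c in cell_lines:
            key = (a, b, c)
            if key not in labeled:
                keys.append(key)
    return keys


def predict_unlabeled(
    model,
    scaler: StandardScaler,
    blocks: Mapping[str, pd.DataFrame],
    drug_ids: Sequence[str],
    cell_lines: Sequence[str],
    labeled_keys: Sequence[tuple[str, str, str]],
    block_selection: Sequence[str] | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score every unlabeled (pair, cell line) instance with a fitted model."""
    keys = unlabeled_keys(drug_ids, cell_lines, labeled_keys)
    table = assemble_features(blocks, instances=keys, block_selection=block_selection)
    X = scaler.transform(table.X.to_numpy())
    scores = _scores(model, X)
    return pd.DataFrame(
        {"score": scores, "predicted_label": (scores >= threshold).astype(int)},
        index=table.X.index,
    )
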