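"""Random-forest variant pathogenicity classifier.

A 1000-tree random forest over the 11 annotation features returns, for each
variant, the fraction of trees voting "pathogenic" — used downstream as a
pathogenicity probability for ranking.  Training uses stratified k-fold
cross-validation (default 5 folds) for an out-of-fold performance report,
then refits on the full table.

Tree hyperparameters beyond the ensemble size follow the classic
random-forest defaults: sqrt(p) = 3 features per split, unlimited depth,
minimum leaf size 1.  Class imbalance is left unweighted by default; a
``class_weight`` option is exposed for experimentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .annotate import FEATURE_NAMES, PROFILE_FEATURE_FIELDS, _AF_FIELDS

__all__ = [
    "LabeledFeatureTable",
    "PathogenicityModel",
    "CvReport",
    "build_training_table",
    "train_model",
    "predict_pathogenicity",
    "predict_many",
    "feature_importance",
    "save_model",
    "load_model",
]

PATHOGENIC, BENIGN = 1, 0

#: Fallback neutral values used only when a feature is entirely absent from
#: the negative pool (expectations for a selectively neutral variant).
_NEUTRAL_FALLBACK: dict[str, float] = {
    "phastcons_primates": 0.05,
    "phastcons_mammals": 0.05,
    "phylop_primates": 0.0,
    "phylop_mammals": 0.0,
    "condel": 0.2,
    "cadd_phred": 2.0,
    "eigen": -0.5,
    "mutation_assessor": 0.5,
    "segdup": 0.0,
    "abb": 1.0,
}


@dataclass
class LabeledFeatureTable:
    """Imputed feature matrix with binary labels and unique variant keys."""

    features: np.ndarray  # (n, 11)
    labels: np.ndarray  # (n,) in {0, 1}
    keys: list[tuple]
    provenance: list[str] = field(default_factory=list)
    neutral_reference: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.features.ndim != 2 or self.features.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"feature matrix must have {len(FEATURE_NAMES)} columns")
        if len(self.labels) != len(self.features) or len(self.keys) != len(self.features):
            raise ValueError("features, labels and keys must align")
        if np.isnan(self.features).any():
            raise ValueError("feature table contains missing entries after imputation")
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("variant keys must be unique")

    @property
    def n_per_class(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class PathogenicityModel:
    """A trained ensemble plus everything needed to reproduce its inputs."""

    forest: RandomForestClassifier
    neutral_reference: dict[str, float]
    feature_names: tuple[str, ...] = FEATURE_NAMES
    metadata: dict = field(default_factory=dict)
    version: int = 1


@dataclass
class CvReport:
    """Stratified out-of-fold cross-validation summary."""

    fold_aucs: list[float]
    pooled_auc: float
    importances: dict[str, float]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray

    def __post_init__(self) -> None:
        for a in [self.pooled_auc, *self.fold_aucs]:
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"AUC {a} outside [0, 1]")
        if any(v < 0 for v in self.importances.values()):
            raise ValueError("importances must be non-negative")


# ---------------------------------------------------------------------------
# Training-table construction
# ---------------------------------------------------------------------------

def _frame_keys(df: pd.DataFrame) -> list[tuple]:
    from .core import normalize_chrom

    return [
        (normalize_chrom(str(c)), int(p), str(r), str(a))
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]


def _neutral_from_negatives(negatives: pd.DataFrame) -> dict[str, float]:
    """Per-feature medians of the negative pool's *present* values."""
    ref: dict[str, float] = {}
    for name in PROFILE_FEATURE_FIELDS:
        if name in negatives.columns:
            med = negatives[name].dropna().median()
        else:
            med = float("nan")
        ref[name] = _NEUTRAL_FALLBACK[name] if math.isnan(med) else float(med)
    return ref


def _impute_frame(df: pd.DataFrame, neutral: Mapping[str, float]) -> np.ndarray:
    n = len(df)
    X = np.empty((n, len(FEATURE_NAMES)), dtype=float)
    af = np.zeros(n)
    for col in _AF_FIELDS:
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            if np.nanmax(vals, initial=0.0) > 1.0 or np.nanmin(vals, initial=0.0) < 0.0:
                raise ValueError(f"{col} outside [0, 1]")
            af = np.fmax(af, np.nan_to_num(vals, nan=0.0))
    X[:, 0] = af
    for i, name in enumerate(PROFILE_FEATURE_FIELDS, start=1):
        if name in df.columns:
            vals = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        else:
            vals = np.full(n, np.nan)
        X[:, i] = np.where(np.isnan(vals), neutral[name], vals)
    return X


def build_training_table(
    positives: pd.DataFrame,
    negatives_curated: pd.DataFrame,
    negatives_random: pd.DataFrame,
    n_pos: int = 15_000,
    n_neg_curated: int = 15_000,
    n_neg_random: int = 100_000,
    seed: int = 0,
) -> LabeledFeatureTable:
    """Sample and impute a labeled training table from annotation pools.

    The default counts mirror a curated-database training design: 15,000
    pathogenic positives, 15,000 curated non-pathogenic negatives and
    100,000 random population variants not present among the positives.
    Keys already in the positive pool are excluded from the random negative
    pool before sampling; overlap between positives and *curated* negatives
    is an error.  Requests larger than a pool fall back to the whole pool.
    The neutral reference is the per-feature median of the sampled negative
    rows and travels with the table (and later, the model).
    """
    rng = np.random.default_rng(seed)
    pos_keys = _frame_keys(positives)
    cur_keys = _frame_keys(negatives_curated)
    overlap = set(pos_keys) & set(cur_keys)
    if overlap:
        raise ValueError(f"positive/curated-negative key collision(s): {sorted(overlap)[:10]}")
    rnd_keys = _frame_keys(negatives_random)
    keep = [i for i, k in enumerate(rnd_keys) if k not in set(pos_keys)]
    negatives_random = negatives_random.iloc[keep].reset_index(drop=True)
    rnd_keys = [rnd_keys[i] for i in keep]

    def _sample(df: pd.DataFrame, keys: list[tuple], n: int):
        if n >= len(df):
            return df.reset_index(drop=True), list(keys)
        idx = np.sort(rng.choice(len(df), size=n, replace=False))
        return df.iloc[idx].reset_index(drop=True), [keys[i] for i in idx]

    pos_df, pos_k = _sample(positives, pos_keys, n_pos)
    cur_df, cur_k = _sample(negatives_curated, cur_keys, n_neg_curated)
    rnd_df, rnd_k = _sample(negatives_random, rnd_keys, n_neg_random)

    neg_df = pd.concat([cur_df, rnd_df], ignore_index=True)
    neutral = _neutral_from_negatives(neg_df)
    X = np.vstack([_impute_frame(pos_df, neutral), _impute_frame(neg_df, neutral)])
    y = np.concatenate([np.ones(len(pos_df), dtype=int), np.zeros(len(neg_df), dtype=int)])
    keys = pos_k + cur_k + rnd_k
    provenance = (
        ["pathogenic"] * len(pos_k)
        + ["curated_negative"] * len(cur_k)
        + ["random_negative"] * len(rnd_k)
    )
    return LabeledFeatureTable(
        features=X, labels=y, keys=keys, provenance=provenance, neutral_reference=neutral
    )


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------

def _make_forest(n_trees: int, seed: int, class_weight=None) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        max_depth=None,
        min_samples_leaf=1,
        class_weight=class_weight,
        random_state=seed,
        n_jobs=1,
    )


def train_model(
    table: LabeledFeatureTable,
    n_trees: int = 1000,
    n_folds: int = 5,
    seed: int = 0,
    class_weight=None,
) -> tuple[PathogenicityModel, CvReport]:
    """Train the forest and report stratified out-of-fold performance.

    The report's AUCs come from out-of-fold predictions only; the returned
    model is refit on every row.  Identical seeds give identical models and
    reports.
    """
    classes = np.unique(table.labels)
    if len(classes) < 2:
        raise ValueError("training table contains a single class")
    min_class = min(table.n_per_class.values())
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > min_class:
        raise ValueError(f"n_folds={n_folds} exceeds minority class size {min_class}")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")

    X, y = table.features, table.labels
    oof = np.empty(len(y), dtype=float)
    fold_aucs: list[float] = []
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for k, (tr, te) in enumerate(skf.split(X, y)):
        forest = _make_forest(n_trees, seed + 1 + k, class_weight)
        forest.fit(X[tr], y[tr])
        p = forest.predict_proba(X[te])[:, 1]
        oof[te] = p
        fold_aucs.append(float(roc_auc_score(y[te], p)))
    pooled = float(roc_auc_score(y, oof))
    fpr, tpr, _ = roc_curve(y, oof)

    final = _make_forest(n_trees, seed, class_weight)
    final.fit(X, y)
    importances = dict(zip(FEATURE_NAMES, final.feature_importances_.tolist()))

    model = PathogenicityModel(
        forest=final,
        neutral_reference=dict(table.neutral_reference),
        metadata={"seed": seed, "n_trees": n_trees, "n_folds": n_folds, "n_rows": len(y)},
    )
    report = CvReport(
        fold_aucs=fold_aucs,
        pooled_auc=pooled,
        importances=importances,
        roc_fpr=fpr,
        roc_tpr=tpr,
    )
    return model, report


def predict_many(model: PathogenicityModel, vectors: np.ndarray) -> np.ndarray:
    """Pathogenicity probabilities for an (n, 11) matrix of feature vectors."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[1] != len(model.feature_names):
        raise ValueError(f"expected (n, {len(model.feature_names)}) feature matrix")
    if len(vectors) == 0:
        return np.empty(0)
    return model.forest.predict_proba(vectors)[:, 1]


def predict_pathogenicity(model: PathogenicityModel, vector: Sequence[float]) -> float:
    """Probability that one (imputed) feature vector is pathogenic."""
    vec = np.asarray(vector, dtype=float)
    if vec.shape != (len(model.feature_names),):
        raise ValueError(f"feature vector must have length {len(model.feature_names)}")
    return float(predict_many(model, vec[None, :])[0])


def feature_importance(model: PathogenicityModel) -> list[tuple[str, float]]:
    """Mean-decrease-in-impurity importances, descending."""
    if not hasattr(model.forest, "feature_importances_"):
        raise ValueError("model is not trained")
    pairs = list(zip(model.feature_names, model.forest.feature_importances_.tolist()))
    return sorted(pairs, key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: PathogenicityModel, path: str | Path) -> None:
    joblib.dump(model, path)


def load_model(path: str | Path) -> PathogenicityModel:
    model = joblib.load(path)
    if not isinstance(model, PathogenicityModel):
        raise ValueError(f"{path} does not contain a pathogenicity model")
    return model
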