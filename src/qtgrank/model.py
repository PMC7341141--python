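"""Negative-resampling random-forest ensemble.

Causal-gene prioritization is a positive-unlabelled problem: tens to a
few hundred known positives against a genome of unlabelled genes.  The
ensemble handles this by training many forests, each on all positives
plus an independent uniform draw of "negative" genes from the genome,
and scoring a gene by the fraction of forests that vote it positive.

All randomness flows from a single integer seed; per-iteration seeds
are derived with :class:`numpy.random.SeedSequence` so iterations are
independent yet the whole train -> score path is reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from itertools import product
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import FeatureTable

__all__ = [
    "ModelConfig",
    "Ensemble",
    "CVResult",
    "sample_negatives",
    "train_ensemble",
    "score_genes",
    "cross_validate",
    "optimize_hyperparameters",
    "feature_importance_loo",
]


def _derive_seed(*parts: int) -> int:
    """Deterministic child seed below 2**31."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ModelConfig:
    """Forest and ensemble hyperparameters.

    ``neg_pos_ratio`` is the number of sampled negatives per positive;
    ``n_ensemble_iterations`` is the number of independently resampled
    forests whose votes are aggregated into the gene score.
    """

    n_trees: int = 200
    max_features: float | int | str = "sqrt"
    min_samples_split: int = 2
    neg_pos_ratio: float = 1.0
    n_ensemble_iterations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_samples_split < 2:
            raise ValueError("n_trees >= 1 and min_samples_split >= 2 required")
        if self.neg_pos_ratio <= 0:
            raise ValueError("neg_pos_ratio must be positive")
        if self.n_ensemble_iterations < 1:
            raise ValueError("n_ensemble_iterations must be >= 1")


@dataclass
class Ensemble:
    forests: list[RandomForestClassifier]
    feature_names: list[str]
    config: ModelConfig

    def save(self, directory) -> None:
        """Serialize as a directory: config YAML, feature-name
        manifest (order enforced at scoring time), per-iteration
        forests via joblib."""
        import joblib
        import yaml

        d = Path(directory)
        (d / "forests").mkdir(parents=True, exist_ok=True)
        with open(d / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.config), fh)
        with open(d / "feature_names.txt", "w") as fh:
            fh.write("\n".join(self.feature_names) + "\n")
        for i, forest in enumerate(self.forests):
            joblib.dump(forest, d / "forests" / f"iteration_{i:05d}.joblib")

    @classmethod
    def load(cls, directory) -> "Ensemble":
        import joblib
        import yaml

        d = Path(directory)
        with open(d / "config.yaml") as fh:
            config = ModelConfig(**yaml.safe_load(fh))
        feature_names = (d / "feature_names.txt").read_text().split()
        forests = [
            joblib.load(p) for p in sorted((d / "forests").glob("iteration_*.joblib"))
        ]
        if len(forests) != config.n_ensemble_iterations:
            raise ValueError(
                f"bundle holds {len(forests)} forests but config expects "
                f"{config.n_ensemble_iterations}"
            )
        return cls(forests, feature_names, config)


@dataclass
class CVResult:
    """Cross-validation summary: one AUC-ROC per repeat, plus
    classification metrics at a 0.5 vote threshold averaged over
    repeats."""

    auc_values: list[float]
    f1: float
    precision: float
    recall: float

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_values))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.auc_values, ddof=1)) if len(self.auc_values) > 1 else 0.0


def sample_negatives(
    genome_genes: list[str],
    positives: list[str] | set[str],
    neg_pos_ratio: float,
    rng_seed: int,
) -> list[str]:
    """Uniform sample without replacement from the genome minus the
    positives, of size ``round(ratio * n_positives)``."""
    pos = set(positives)
    pool = sorted(set(genome_genes) - pos)
    n = round(neg_pos_ratio * len(pos))
    if len(pool) < n:
        raise ValueError(
            f"negative pool too small: need {n}, have {len(pool)} "
            f"(genome {len(set(genome_genes))}, positives {len(pos)})"
        )
    rng = np.random.default_rng(rng_seed)
    return list(rng.choice(pool, size=n, replace=False))


def _make_forest(config: ModelConfig, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        min_samples_split=config.min_samples_split,
        random_state=seed,
        n_jobs=1,
    )


def train_ensemble(
    features: FeatureTable,
    positives: list[str] | set[str],
    config: ModelConfig,
) -> Ensemble:
    """Fit ``n_ensemble_iterations`` forests, each on all positives plus
    a fresh negative sample."""
    pos = sorted(set(positives))
    missing = set(pos) - set(features.gene_ids)
    if missing:
        raise KeyError(f"positives absent from feature table: {sorted(missing)}")
    X_pos = features.matrix(gene_ids=pos)
    forests = []
    for i in range(config.n_ensemble_iterations):
        neg = sample_negatives(
            features.gene_ids, pos, config.neg_pos_ratio, _derive_seed(config.seed, i, 1)
        )
        X = np.vstack([X_pos, features.matrix(gene_ids=neg)])
        y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        forest = _make_forest(config, _derive_seed(config.seed, i, 2))
        forest.fit(X, y)
        forests.append(forest)
    return Ensemble(forests, features.feature_names, config)


def score_genes(
    ensemble: Ensemble,
    features: FeatureTable,
    gene_ids: list[str],
    aggregation: str = "votes",
) -> dict[str, float]:
    """Ensemble score per gene, in [0, 1].

    ``votes`` (default): fraction of ensemble iterations whose forest
    classifies the gene positive (each forest votes by its own tree
    majority).  ``probability``: mean positive-class probability.
    """
    if aggregation not in ("votes", "probability"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    missing = set(gene_ids) - set(features.gene_ids)
    if missing:
        raise KeyError(f"genes absent from feature table: {sorted(missing)}")
    X = features.matrix(gene_ids=gene_ids, feature_names=ensemble.feature_names)
    acc = np.zeros(len(gene_ids))
    for forest in ensemble.forests:
        proba = forest.predict_proba(X)[:, list(forest.classes_).index(1.0)]
        acc += (proba > 0.5).astype(float) if aggregation == "votes" else proba
    acc /= len(ensemble.forests)
    return {gid: float(s) for gid, s in zip(gene_ids, acc)}


def cross_validate(
    features: FeatureTable,
    positives: list[str] | set[str],
    config: ModelConfig,
    n_folds: int = 5,
    n_repeats: int = 50,
) -> CVResult:
    """Repeated stratified k-fold cross-validation.

    Each repeat draws a fresh negative sample, splits positives and
    negatives into stratified folds (keeping the class ratio equal
    across folds), fits one forest per training fold and pools the
    held-out positive-class probabilities into a single AUC-ROC for the
    repeat.  F1/precision/recall are computed at a 0.5 probability
    threshold on the pooled held-out predictions, averaged over
    repeats.
    """
    pos = sorted(set(positives))
    if len(pos) < n_folds:
        raise ValueError(f"need >= {n_folds} positives, have {len(pos)}")
    aucs, f1s, precisions, recalls = [], [], [], []
    for r in range(n_repeats):
        neg = sample_negatives(
            features.gene_ids, pos, config.neg_pos_ratio, _derive_seed(config.seed, r, 3)
        )
        ids = pos + neg
        X = features.matrix(gene_ids=ids)
        y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=_derive_seed(config.seed, r, 4)
        )
        y_true = np.empty(0)
        y_score = np.empty(0)
        for k, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            forest = _make_forest(config, _derive_seed(config.seed, r, 5, k))
            forest.fit(X[train_idx], y[train_idx])
            proba = forest.predict_proba(X[test_idx])
            proba = proba[:, list(forest.classes_).index(1.0)]
            y_true = np.concatenate([y_true, y[test_idx]])
            y_score = np.concatenate([y_score, proba])
        aucs.append(float(roc_auc_score(y_true, y_score)))
        pred = y_score > 0.5
        tp = float(np.sum(pred & (y_true == 1)))
        fp = float(np.sum(pred & (y_true == 0)))
        fn = float(np.sum(~pred & (y_true == 1)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    return CVResult(
        auc_values=aucs,
        f1=float(np.mean(f1s)),
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
    )


def optimize_hyperparameters(
    features: FeatureTable,
    positives: list[str] | set[str],
    grid: dict[str, list],
    base_config: ModelConfig | None = None,
    n_folds: int = 5,
    n_repeats: int = 10,
) -> tuple[ModelConfig, list[tuple[ModelConfig, float]]]:
    """Exhaustive grid search maximizing mean cross-validation AUC-ROC.

    Ties are broken deterministically toward smaller ``n_trees``, then
    smaller ``neg_pos_ratio``.  Returns the winning config and the full
    (config, mean AUC) surface.
    """
    if not grid or any(not v for v in grid.values()):
        raise ValueError("hyperparameter grid must be non-empty")
    base = base_config or ModelConfig()
    names = sorted(grid)
    surface: list[tuple[ModelConfig, float]] = []
    for combo in product(*(grid[n] for n in names)):
        cfg = replace(base, **dict(zip(names, combo)))
        res = cross_validate(features, positives, cfg, n_folds=n_folds, n_repeats=n_repeats)
        surface.append((cfg, res.mean_auc))
    best = max(
        surface,
        key=lambda cr: (cr[1], -cr[0].n_trees, -cr[0].neg_pos_ratio),
    )
    return best[0], surface


def feature_importance_loo(
    features: FeatureTable,
    positives: list[str] | set[str],
    config: ModelConfig,
    n_folds: int = 5,
    n_repeats: int = 10,
) -> dict[str, float]:
    """Leave-one-out feature importance.

    Importance of feature f = mean CV AUC with all features minus mean
    CV AUC with f removed, using identical seeds for both runs so the
    difference isolates the feature's contribution.
    """
    if len(features.feature_names) < 2:
        raise ValueError("need at least two features")
    baseline = cross_validate(
        features, positives, config, n_folds=n_folds, n_repeats=n_repeats
    ).mean_auc
    importance: dict[str, float] = {}
    for name in features.feature_names:
        reduced = FeatureTable(
            features.values.drop(columns=[name]),
            {k: v for k, v in features.kinds.items() if k != name},
        )
        auc = cross_validate(
            reduced, positives, config, n_folds=n_folds, n_repeats=n_repeats
        ).mean_auc
        importance[name] = baseline - auc
    return importance
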