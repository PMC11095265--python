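"""Gradient-boosted classification of flagellar motility from gene content.

The model is an ensemble of regression trees with a binary logistic
objective over presence/absence features of the panel genes (motile = 1).
Pieces: a stratified 70:30 train/test split, k-fold cross-validation to
pick the boosting-round count, Bayesian hyperparameter optimization with a
Gaussian-process surrogate (random search below a budget floor), training,
gain-based feature importance, and accuracy/sensitivity/specificity
evaluation.

A statsmodels-flavoured facade (:class:`MotilityClassifier` →
:meth:`~MotilityClassifier.fit` → :class:`MotilityClassifierResults` with
``summary()``) wraps the functional pieces for interactive use.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from flagmet.errors import ValidationError
from flagmet.io import GeneContentMatrix, MOTILE, NONMOTILE

logger = logging.getLogger("flagmet")

LABEL_CODES = {NONMOTILE: 0, MOTILE: 1}


def encode_labels(phenotypes: pd.Series) -> np.ndarray:
    """Map motile/nonmotile labels to 1/0."""
    bad = sorted(set(phenotypes) - set(LABEL_CODES))
    if bad:
        raise ValidationError(f"unknown phenotype labels {bad}")
    return phenotypes.map(LABEL_CODES).to_numpy(dtype=int)


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must lie in (0, 1)")


@dataclass
class TrainTestSplit:
    train_ids: list[str]
    test_ids: list[str]
    X_train: pd.DataFrame
    y_train: np.ndarray
    X_test: pd.DataFrame
    y_test: np.ndarray


def split_train_test(
    matrix: GeneContentMatrix, phenotypes: pd.Series, spec: SplitSpec | None = None
) -> TrainTestSplit:
    """Disjoint, exhaustive train/test partition; train size = floor(f·n).

    With stratification each class contributes floor(f·n_class) genomes,
    then remainders (largest fractional part first) top the train set up to
    floor(f·n) — so per-class train fractions stay within one genome of the
    global fraction.  Reproducible under the spec seed.
    """
    spec = spec or SplitSpec()
    ids = matrix.genome_ids
    labels = phenotypes.loc[ids]
    y = encode_labels(labels)
    n = len(ids)
    n_train = math.floor(spec.train_fraction * n)
    rng = np.random.default_rng(spec.seed)
    if spec.stratified:
        train_ids: list[str] = []
        remainders: list[tuple[float, list[str]]] = []
        for cls in sorted(set(y)):
            cls_ids = [g for g, yy in zip(ids, y) if yy == cls]
            if len(cls_ids) < 2:
                raise ValidationError(
                    f"class {cls} has {len(cls_ids)} member(s); stratified split needs >= 2"
                )
            perm = rng.permutation(len(cls_ids))
            shuffled = [cls_ids[i] for i in perm]
            exact = spec.train_fraction * len(cls_ids)
            k = math.floor(exact)
            train_ids.extend(shuffled[:k])
            remainders.append((exact - k, shuffled[k:]))
        remainders.sort(key=lambda t: -t[0])
        deficit = n_train - len(train_ids)
        for _, rest in remainders:
            if deficit <= 0:
                break
            if rest:
                train_ids.append(rest[0])
                deficit -= 1
        train_set = set(train_ids)
        test_ids = [g for g in ids if g not in train_set]
        train_ids = [g for g in ids if g in train_set]  # restore input order
    else:
        perm = rng.permutation(n)
        chosen = set(perm[:n_train].tolist())
        train_ids = [g for i, g in enumerate(ids) if i in chosen]
        test_ids = [g for i, g in enumerate(ids) if i not in chosen]
    X = matrix.data
    return TrainTestSplit(
        train_ids=train_ids,
        test_ids=test_ids,
        X_train=X.loc[train_ids],
        y_train=encode_labels(phenotypes.loc[train_ids]),
        X_test=X.loc[test_ids],
        y_test=encode_labels(phenotypes.loc[test_ids]),
    )


# ---------------------------------------------------------------------------
# Hyperparameters, cross-validation, tuning
# ---------------------------------------------------------------------------

#: search bounds: (low, high, is_integer, log_scale)
DEFAULT_BOUNDS: dict[str, tuple[float, float, bool, bool]] = {
    "learning_rate": (0.01, 0.3, False, True),
    "max_tree_depth": (2, 8, True, False),
    "min_child_weight": (1, 10, True, False),
    "subsample_fraction": (0.5, 1.0, False, False),
    "column_subsample_fraction": (0.5, 1.0, False, False),
    "split_loss_penalty": (0.0, 5.0, False, False),
}


@dataclass
class HyperParams:
    """Boosting hyperparameters (xgboost naming in parentheses)."""

    learning_rate: float = 0.1          # eta
    max_tree_depth: int = 4             # max_depth
    min_child_weight: float = 1.0
    subsample_fraction: float = 1.0     # subsample
    column_subsample_fraction: float = 1.0  # colsample_bytree
    split_loss_penalty: float = 0.0     # gamma
    n_rounds: int = 200

    def __post_init__(self) -> None:
        for name in ("subsample_fraction", "column_subsample_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name}={v} outside (0, 1]")
        if self.max_tree_depth < 1 or self.n_rounds < 1:
            raise ValidationError("depth and n_rounds must be positive integers")

    def to_xgb(self, seed: int = 0) -> dict:
        return {
            "objective": "binary:logistic",
            "eval_metric": "logloss",
            "eta": self.learning_rate,
            "max_depth": int(self.max_tree_depth),
            "min_child_weight": self.min_child_weight,
            "subsample": self.subsample_fraction,
            "colsample_bytree": self.column_subsample_fraction,
            "gamma": self.split_loss_penalty,
            "seed": int(seed) % (2**31),
            "nthread": 1,
        }


def _check_trainable(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class")


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray,
    params: HyperParams | None = None,
    k: int = 5,
    max_rounds: int | None = None,
    seed: int = 0,
    early_stopping_rounds: int = 20,
) -> tuple[int, float]:
    """k-fold CV; returns (optimal boosting rounds, mean held-out logloss)."""
    params = params or HyperParams()
    _check_trainable(y)
    n = len(y)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds n_train={n}")
    dtrain = xgb.DMatrix(X.to_numpy(dtype=float), label=y,
                         feature_names=list(X.columns))
    max_rounds = max_rounds or params.n_rounds
    # leave-one-out folds cannot be stratified
    stratified = k < n
    res = xgb.cv(
        params.to_xgb(seed),
        dtrain,
        num_boost_round=max_rounds,
        nfold=k,
        stratified=stratified,
        seed=int(seed) % (2**31),
        early_stopping_rounds=early_stopping_rounds,
        verbose_eval=False,
        shuffle=True,
    )
    losses = res["test-logloss-mean"].to_numpy()
    best = int(np.argmin(losses))
    return best + 1, float(losses[best])


def _sample_point(rng: np.random.Generator, bounds: dict) -> dict:
    point = {}
    for name, (lo, hi, is_int, log) in bounds.items():
        if log:
            v = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            v = float(rng.uniform(lo, hi))
        if is_int:
            v = int(round(v))
        point[name] = v
    return point


def _to_unit(point: dict, bounds: dict) -> np.ndarray:
    out = []
    for name, (lo, hi, _is_int, log) in bounds.items():
        v = point[name]
        if log:
            out.append((np.log(v) - np.log(lo)) / (np.log(hi) - np.log(lo)))
        else:
            out.append((v - lo) / (hi - lo))
    return np.array(out)


def tune_hyperparameters(
    X: pd.DataFrame,
    y: np.ndarray,
    bounds: dict | None = None,
    budget: int = 30,
    seed: int = 0,
    k: int = 5,
    max_rounds: int = 200,
    random_floor: int = 8,
) -> HyperParams:
    """Pick hyperparameters by CV loss with a GP-surrogate Bayesian search.

    The default parameter point is always evaluated first (so tuning can
    never do worse than the defaults on the same folds).  A third of the
    budget (at least 3 points) is random exploration; the remainder
    maximizes expected improvement under a Matern-5/2 Gaussian process on
    the unit-cube-scaled parameters.  Budgets below ``random_floor`` fall
    back to plain random search.  The returned ``HyperParams`` carries the
    CV-optimal round count for the best point.
    """
    if bounds is None:
        bounds = DEFAULT_BOUNDS
    if not bounds:
        raise ValidationError("empty hyperparameter bounds")
    if budget < 1:
        raise ValidationError("budget must be >= 1 evaluation")
    _check_trainable(y)
    rng = np.random.default_rng(seed)

    evaluated: list[tuple[dict, int, float]] = []

    def score(point: dict) -> None:
        hp = HyperParams(**point)
        rounds, loss = cross_validate(
            X, y, hp, k=k, max_rounds=max_rounds, seed=seed
        )
        evaluated.append((point, rounds, loss))

    default = HyperParams()
    score({name: getattr(default, name) for name in bounds})

    n_init = budget if budget < random_floor else max(3, budget // 3)
    for _ in range(n_init - 1):
        score(_sample_point(rng, bounds))

    if budget > n_init:
        kernel = Matern(nu=2.5, length_scale=np.ones(len(bounds)))
        for _ in range(budget - n_init):
            Xobs = np.array([_to_unit(p, bounds) for p, _, _ in evaluated])
            yobs = np.array([loss for _, _, loss in evaluated])
            gp = GaussianProcessRegressor(
                kernel=kernel, alpha=1e-6, normalize_y=True,
                random_state=int(seed) % (2**31),
            )
            gp.fit(Xobs, yobs)
            candidates = [_sample_point(rng, bounds) for _ in range(256)]
            Xc = np.array([_to_unit(p, bounds) for p in candidates])
            mu, sigma = gp.predict(Xc, return_std=True)
            best_loss = yobs.min()
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (best_loss - mu) / sigma
                ei = (best_loss - mu) * norm.cdf(z) + sigma * norm.pdf(z)
            ei[sigma < 1e-12] = 0.0
            score(candidates[int(np.argmax(ei))])

    best_point, best_rounds, _ = min(evaluated, key=lambda t: t[2])
    return HyperParams(**best_point, n_rounds=best_rounds)


# ---------------------------------------------------------------------------
# Model, training, prediction, evaluation
# ---------------------------------------------------------------------------

class MotilityModel:
    """Trained boosted-tree ensemble over binary panel-gene features.

    Prediction is logistic(sum of leaf scores); the label is motile iff the
    probability exceeds 0.5 (ties go to nonmotile).
    """

    def __init__(self, booster: xgb.Booster, feature_names: list[str],
                 hyperparams: HyperParams, training_history: list[float],
                 metadata: dict | None = None):
        self.booster = booster
        self.feature_names = list(feature_names)
        self.hyperparams = hyperparams
        self.training_history = training_history
        self.metadata = metadata or {}

    def _align(self, X: pd.DataFrame) -> np.ndarray:
        missing = [g for g in self.feature_names if g not in X.columns]
        extra = [g for g in X.columns if g not in self.feature_names]
        if missing:
            logger.warning("missing panel genes treated as absent: %s", missing)
        if extra:
            logger.warning("ignoring features outside the panel: %s", extra)
        aligned = pd.DataFrame(0, index=X.index, columns=self.feature_names)
        present = [g for g in self.feature_names if g in X.columns]
        aligned[present] = X[present]
        return aligned.to_numpy(dtype=float)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        dm = xgb.DMatrix(self._align(X), feature_names=self.feature_names)
        return self.booster.predict(dm)

    def predict(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Return (probabilities, labels); motile iff probability > 0.5."""
        proba = self.predict_proba(X)
        labels = np.where(proba > 0.5, MOTILE, NONMOTILE)
        return proba, labels

    def feature_importance(self) -> list[tuple[str, float]]:
        """Normalized total gain per feature, descending; sums to one."""
        raw = self.booster.get_score(importance_type="total_gain")
        total = sum(raw.values())
        if total == 0:
            return []
        ranked = sorted(raw.items(), key=lambda kv: (-kv[1], kv[0]))
        return [(name, gain / total) for name, gain in ranked]

    def save(self, path) -> None:
        """Serialize as a single JSON document (booster + metadata)."""
        booster_json = json.loads(bytes(self.booster.save_raw(raw_format="json")))
        doc = {
            "format": "flagmet-motility-model",
            "feature_names": self.feature_names,
            "hyperparams": asdict(self.hyperparams),
            "training_history": self.training_history,
            "metadata": self.metadata,
            "booster": booster_json,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "MotilityModel":
        with open(path) as fh:
            doc = json.load(fh)
        booster = xgb.Booster()
        booster.load_model(bytearray(json.dumps(doc["booster"]).encode()))
        return cls(
            booster=booster,
            feature_names=doc["feature_names"],
            hyperparams=HyperParams(**doc["hyperparams"]),
            training_history=doc["training_history"],
            metadata=doc.get("metadata", {}),
        )


def train(
    X: pd.DataFrame, y: np.ndarray, params: HyperParams | None = None,
    seed: int = 0, metadata: dict | None = None,
) -> MotilityModel:
    """Fit the boosted logistic ensemble; training loss is recorded per round."""
    params = params or HyperParams()
    _check_trainable(y)
    dtrain = xgb.DMatrix(X.to_numpy(dtype=float), label=y,
                         feature_names=list(X.columns))
    evals_result: dict = {}
    booster = xgb.train(
        params.to_xgb(seed),
        dtrain,
        num_boost_round=params.n_rounds,
        evals=[(dtrain, "train")],
        evals_result=evals_result,
        verbose_eval=False,
    )
    history = [float(v) for v in evals_result["train"]["logloss"]]
    meta = {"seed": int(seed), "n_train": int(len(y))}
    meta.update(metadata or {})
    return MotilityModel(booster, list(X.columns), params, history, meta)


@dataclass
class EvalReport:
    """Confusion counts and summary metrics on a held-out set."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        """Motile recall."""
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        """Nonmotile recall."""
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


def evaluate(model: MotilityModel, X: pd.DataFrame, y: np.ndarray) -> EvalReport:
    if len(y) == 0:
        raise ValidationError("empty test set")
    proba = model.predict_proba(X)
    pred = (proba > 0.5).astype(int)
    y = np.asarray(y, dtype=int)
    return EvalReport(
        tp=int(((pred == 1) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


# ---------------------------------------------------------------------------
# Model/Results facade
# ---------------------------------------------------------------------------

class MotilityClassifier:
    """Model object built from a gene-content matrix and phenotype labels.

    Restricts features to ``panel_genes`` when given, otherwise uses every
    column.  ``fit`` performs the split, optional hyperparameter tuning,
    CV round selection, training and held-out evaluation, and returns a
    :class:`MotilityClassifierResults`.
    """

    def __init__(self, matrix: GeneContentMatrix, phenotypes: pd.Series,
                 panel_genes: list[str] | None = None):
        if not matrix.is_binary:
            raise ValidationError("MotilityClassifier requires a binarized matrix")
        if panel_genes is not None:
            missing = [g for g in panel_genes if g not in matrix.data.columns]
            if missing:
                raise ValidationError(f"panel genes absent from matrix: {missing}")
            matrix = GeneContentMatrix(matrix.data[panel_genes], is_binary=True)
        self.matrix = matrix
        self.phenotypes = phenotypes

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, phenotypes: pd.Series,
                       panel_genes: list[str] | None = None) -> "MotilityClassifier":
        return cls(GeneContentMatrix(df, is_binary=True), phenotypes, panel_genes)

    def fit(self, split: SplitSpec | None = None, tune: bool = False,
            budget: int = 30, k: int = 5,
            params: HyperParams | None = None) -> "MotilityClassifierResults":
        split = split or SplitSpec()
        parts = split_train_test(self.matrix, self.phenotypes, split)
        if tune:
            params = tune_hyperparameters(
                parts.X_train, parts.y_train, budget=budget, seed=split.seed, k=k
            )
        else:
            base = params or HyperParams()
            rounds, _ = cross_validate(
                parts.X_train, parts.y_train, base, k=k,
                max_rounds=base.n_rounds, seed=split.seed,
            )
            params = HyperParams(**{**asdict(base), "n_rounds": rounds})
        model = train(parts.X_train, parts.y_train, params, seed=split.seed,
                      metadata={"split": asdict(split), "cv_folds": k})
        report = evaluate(model, parts.X_test, parts.y_test)
        return MotilityClassifierResults(model, report, parts, params)


class MotilityClassifierResults:
    """Fit results: trained model, held-out report and feature importances."""

    def __init__(self, model: MotilityModel, report: EvalReport,
                 split: TrainTestSplit, params: HyperParams):
        self.model = model
        self.report = report
        self.split = split
        self.params = params

    @property
    def importance(self) -> pd.DataFrame:
        imp = self.model.feature_importance()
        return pd.DataFrame(imp, columns=["gene_id", "importance"])

    def predict(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        return self.model.predict(X)

    def summary(self) -> str:
        r = self.report
        lines = [
            "Flagellar motility classifier (boosted trees, binary logistic)",
            "=" * 62,
            f"features (panel genes): {len(self.model.feature_names)}",
            f"train / test genomes:   {len(self.split.train_ids)} / {len(self.split.test_ids)}",
            f"boosting rounds:        {self.params.n_rounds}",
            f"learning rate:          {self.params.learning_rate:.4g}",
            f"max tree depth:         {self.params.max_tree_depth}",
            "-" * 62,
            f"held-out accuracy:      {r.accuracy:.4f}",
            f"sensitivity (motile):   {r.sensitivity:.4f}",
            f"specificity (nonmotile):{r.specificity:.4f}",
            f"confusion (tp fp tn fn):{r.tp} {r.fp} {r.tn} {r.fn}",
            "-" * 62,
            "top features by gain:",
        ]
        for gene, imp in self.model.feature_importance()[:10]:
            lines.append(f"  {gene:<24s} {imp:.4f}")
        return "\n".join(lines)
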