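"""Emotion-specific depression classifiers.

For each stimulus condition an extremely-randomized-trees classifier (ERTC)
and a logistic-regression control are trained on standardized per-epoch HRV
features (the calm-state baseline model uses raw calm features, since calm
standardized values are ~N(0,1) by construction and carry no signal).

Protocol: participant-grouped stratified 7:3 train/test split, fivefold
participant-grouped CV for hyperparameter selection (sequential model-based
search with an extra-trees surrogate, or pure random search under a flag),
then accuracy / rank-based AUC / precision on the held-out set with 95%
bootstrap confidence intervals resampled over test participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, ExtraTreesRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    precision_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .cohort import CONDITIONS
from .errors import ConfigurationError, StratificationError, UndefinedMetricError
from .features import FEATURE_NAMES

POSITIVE_LABEL = "IWD"
ALGORITHMS = ("ertc", "logreg")


@dataclass(frozen=True)
class ModelConfig:
    condition: str = "sadness"
    algorithm: str = "ertc"
    test_fraction: float = 0.3
    cv_folds: int = 5
    search_budget: int = 25
    search_strategy: str = "smbo"  # or "random"
    n_bootstrap: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ConfigurationError(f"test_fraction {self.test_fraction} not in (0,1)")
        if self.cv_folds < 2:
            raise ConfigurationError(f"cv_folds {self.cv_folds} < 2")
        if self.search_budget < 1:
            raise ConfigurationError(f"search_budget {self.search_budget} < 1")
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}")
        if self.search_strategy not in ("smbo", "random"):
            raise ConfigurationError(f"unknown search strategy {self.search_strategy!r}")


@dataclass
class FittedModel:
    estimator: object
    config: ModelConfig
    best_params: dict
    cv_scores: list[float]
    feature_columns: list[str]


@dataclass
class ClassifierReport:
    condition: str
    algorithm: str
    accuracy: float
    accuracy_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    precision: float
    precision_ci: tuple[float, float]
    roc: pd.DataFrame  # fpr, tpr, threshold
    confusion: dict[str, int]
    cv_scores: list[float]
    best_params: dict
    n_test_participants: int
    n_test_epochs: int

    def as_row(self) -> dict:
        return {
            "condition": self.condition,
            "algorithm": self.algorithm,
            "accuracy": self.accuracy,
            "accuracy_lo": self.accuracy_ci[0],
            "accuracy_hi": self.accuracy_ci[1],
            "auc": self.auc,
            "auc_lo": self.auc_ci[0],
            "auc_hi": self.auc_ci[1],
            "precision": self.precision,
            "precision_lo": self.precision_ci[0],
            "precision_hi": self.precision_ci[1],
            "n_test_participants": self.n_test_participants,
            "n_test_epochs": self.n_test_epochs,
        }


def _feature_columns(df: pd.DataFrame) -> list[str]:
    std = [f"{n}_std" for n in FEATURE_NAMES if f"{n}_std" in df.columns]
    return std if std else [n for n in FEATURE_NAMES if n in df.columns]


def split_train_test(
    table: pd.DataFrame, config: ModelConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participant-grouped stratified split: the held-out fraction of each
    class's *participants* goes to test, so no participant's epochs straddle
    the boundary."""
    config.validate()
    classes = table["group"].unique()
    if len(classes) < 2:
        raise StratificationError(f"only one class present: {list(classes)}")
    rng = np.random.default_rng(config.seed)
    test_pids: list = []
    for cls in sorted(classes):
        pids = np.sort(table.loc[table["group"] == cls, "participant_id"].unique())
        n_test = max(1, int(round(config.test_fraction * len(pids))))
        if n_test >= len(pids):
            raise StratificationError(
                f"class {cls!r} has too few participants ({len(pids)}) for the split"
            )
        test_pids.extend(rng.choice(pids, size=n_test, replace=False))
    mask = table["participant_id"].isin(test_pids)
    return table[~mask].copy(), table[mask].copy()


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "ertc":
        return ExtraTreesClassifier(
            n_estimators=int(params.get("n_estimators", 300)),
            max_depth=params.get("max_depth"),
            min_samples_leaf=int(params.get("min_samples_leaf", 1)),
            random_state=seed,
            n_jobs=1,
        )
    return Pipeline([
        ("scale", StandardScaler()),
        ("lr", LogisticRegression(C=float(params.get("C", 1.0)), max_iter=2000)),
    ])


def _sample_params(algorithm: str, rng: np.random.Generator) -> dict:
    if algorithm == "ertc":
        depth = rng.choice([None, *range(2, 17)])
        return {
            "n_estimators": int(rng.integers(100, 801)),
            "max_depth": None if depth is None else int(depth),
            "min_samples_leaf": int(rng.integers(1, 9)),
        }
    return {"C": float(10.0 ** rng.uniform(-3, 3))}


def _encode(algorithm: str, params: dict) -> list[float]:
    if algorithm == "ertc":
        return [
            params["n_estimators"],
            -1.0 if params["max_depth"] is None else float(params["max_depth"]),
            params["min_samples_leaf"],
        ]
    return [np.log10(params["C"])]


def _default_params(algorithm: str) -> dict:
    return {"n_estimators": 100, "max_depth": None, "min_samples_leaf": 1} \
        if algorithm == "ertc" else {"C": 1.0}


def _cv_auc(train: pd.DataFrame, cols: list[str], params: dict, config: ModelConfig) -> list[float]:
    X = train[cols].to_numpy()
    y = (train["group"] == POSITIVE_LABEL).to_numpy()
    groups = train["participant_id"].to_numpy()
    n_groups_minor = min(
        train.loc[y, "participant_id"].nunique(),
        train.loc[~y, "participant_id"].nunique(),
    )
    n_splits = min(config.cv_folds, n_groups_minor)
    if n_splits < 2:
        raise StratificationError("too few participants per class for CV")
    cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
    scores = []
    for tr, va in cv.split(X, y, groups):
        if len(np.unique(y[va])) < 2:
            continue
        est = _make_estimator(config.algorithm, params, config.seed)
        est.fit(X[tr], y[tr])
        scores.append(float(roc_auc_score(y[va], est.predict_proba(X[va])[:, 1])))
    if not scores:
        raise StratificationError("no valid CV fold had both classes")
    return scores


def tune_and_train(train: pd.DataFrame, config: ModelConfig) -> FittedModel:
    """Select hyperparameters by mean participant-grouped CV AUC and refit on
    the full training set.

    Budget 1 evaluates the default configuration only.  Otherwise candidates
    are proposed either purely at random or (default) by a lightweight
    sequential model-based search: after a random warm-up, an extra-trees
    surrogate regressor is fitted to (params -> CV AUC) and each next
    candidate is the surrogate-argmax over a fresh random pool.
    """
    config.validate()
    if len(train) == 0:
        raise StratificationError("empty training set")
    cols = _feature_columns(train)
    train = train.dropna(subset=cols)
    rng = np.random.default_rng(config.seed)

    evaluated: list[tuple[dict, list[float]]] = []

    def evaluate_candidate(params: dict) -> float:
        scores = _cv_auc(train, cols, params, config)
        evaluated.append((params, scores))
        return float(np.mean(scores))

    best_params = _default_params(config.algorithm)
    best_score = evaluate_candidate(best_params)

    n_warm = min(max(4, config.search_budget // 4), config.search_budget - 1)
    candidates = [_sample_params(config.algorithm, rng) for _ in range(n_warm)]
    for params in candidates:
        score = evaluate_candidate(params)
        if score > best_score:
            best_score, best_params = score, params

    remaining = config.search_budget - 1 - n_warm
    for _ in range(max(0, remaining)):
        if config.search_strategy == "random" or len(evaluated) < 4:
            params = _sample_params(config.algorithm, rng)
        else:
            Xs = np.array([_encode(config.algorithm, p) for p, _ in evaluated])
            ys = np.array([np.mean(s) for _, s in evaluated])
            surrogate = ExtraTreesRegressor(
                n_estimators=50, random_state=config.seed, n_jobs=1
            ).fit(Xs, ys)
            pool = [_sample_params(config.algorithm, rng) for _ in range(64)]
            preds = surrogate.predict(
                np.array([_encode(config.algorithm, p) for p in pool])
            )
            params = pool[int(np.argmax(preds))]
        score = evaluate_candidate(params)
        if score > best_score:
            best_score, best_params = score, params

    est = _make_estimator(config.algorithm, best_params, config.seed)
    X = train[cols].to_numpy()
    y = (train["group"] == POSITIVE_LABEL).to_numpy()
    est.fit(X, y)
    best_cv = next(s for p, s in evaluated if p == best_params)
    return FittedModel(
        estimator=est, config=config, best_params=best_params,
        cv_scores=best_cv, feature_columns=cols,
    )


def _metrics(y: np.ndarray, scores: np.ndarray) -> tuple[float, float, float]:
    pred = scores >= 0.5
    acc = float(accuracy_score(y, pred))
    auc = float(roc_auc_score(y, scores)) if len(np.unique(y)) == 2 else np.nan
    prec = float(precision_score(y, pred, zero_division=0.0))
    return acc, auc, prec


def evaluate(model: FittedModel, test: pd.DataFrame) -> ClassifierReport:
    """Held-out metrics with 95% participant-bootstrap confidence intervals.

    AUC is the rank-based area (equal to the normalized Mann-Whitney U of the
    scores); accuracy and precision use a 0.5 threshold with IWD positive.
    """
    if len(test) == 0:
        raise StratificationError("empty test set")
    cols = model.feature_columns
    test = test.dropna(subset=cols)
    y = (test["group"] == POSITIVE_LABEL).to_numpy()
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("AUC undefined: test set has a single class")
    scores = model.estimator.predict_proba(test[cols].to_numpy())[:, 1]
    acc, auc, prec = _metrics(y, scores)

    pids = test["participant_id"].to_numpy()
    uniq = np.sort(np.unique(pids))
    rng = np.random.default_rng(model.config.seed + 1)
    boot = {"acc": [], "auc": [], "prec": []}
    idx_by_pid = {p: np.flatnonzero(pids == p) for p in uniq}
    for _ in range(model.config.n_bootstrap):
        sample = rng.choice(uniq, size=len(uniq), replace=True)
        idx = np.concatenate([idx_by_pid[p] for p in sample])
        yb, sb = y[idx], scores[idx]
        if len(np.unique(yb)) < 2:
            continue
        a, u, p = _metrics(yb, sb)
        boot["acc"].append(a)
        boot["auc"].append(u)
        boot["prec"].append(p)

    def ci(vals: Sequence[float], point: float) -> tuple[float, float]:
        if not vals:
            return (point, point)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return (float(min(lo, point)), float(max(hi, point)))

    fpr, tpr, thr = roc_curve(y, scores)
    pred = scores >= 0.5
    confusion = {
        "tp": int(np.sum(pred & y)), "fp": int(np.sum(pred & ~y)),
        "fn": int(np.sum(~pred & y)), "tn": int(np.sum(~pred & ~y)),
    }
    return ClassifierReport(
        condition=model.config.condition, algorithm=model.config.algorithm,
        accuracy=acc, accuracy_ci=ci(boot["acc"], acc),
        auc=auc, auc_ci=ci(boot["auc"], auc),
        precision=prec, precision_ci=ci(boot["prec"], prec),
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        confusion=confusion, cv_scores=model.cv_scores,
        best_params=model.best_params,
        n_test_participants=int(test["participant_id"].nunique()),
        n_test_epochs=len(test),
    )


def run_emotion_battery(
    std_table: pd.DataFrame,
    raw_calm_table: pd.DataFrame,
    groups: pd.DataFrame | dict[str, str],
    base_config: ModelConfig = ModelConfig(),
    algorithms: tuple[str, ...] = ALGORITHMS,
) -> dict[tuple[str, str], ClassifierReport]:
    """Train/evaluate one model per condition x algorithm under an identical
    protocol: emotion models on standardized features, the calm baseline on
    raw calm features.  Missing conditions are skipped with a warning."""
    import warnings
    import dataclasses as _dc

    if isinstance(groups, pd.DataFrame):
        gmap = dict(zip(groups["participant_id"], groups["group"]))
    else:
        gmap = dict(groups)

    reports: dict[tuple[str, str], ClassifierReport] = {}
    for cond in CONDITIONS:
        if cond == "calm":
            data = raw_calm_table[raw_calm_table["condition"] == "calm"].copy()
        else:
            data = std_table[std_table["condition"] == cond].copy()
        if len(data) == 0:
            warnings.warn(f"condition {cond!r} missing: skipped", stacklevel=2)
            continue
        data["group"] = data["participant_id"].map(gmap)
        for algo in algorithms:
            cfg = _dc.replace(base_config, condition=cond, algorithm=algo)
            train, test = split_train_test(data, cfg)
            model = tune_and_train(train, cfg)
            reports[(cond, algo)] = evaluate(model, test)
    return reports


def battery_table(reports: dict[tuple[str, str], ClassifierReport]) -> pd.DataFrame:
    rows = [r.as_row() for r in reports.values()]
    return pd.DataFrame(rows).sort_values(["condition", "algorithm"]).reset_index(drop=True)


def plot_roc(reports: dict[tuple[str, str], ClassifierReport], path) -> None:
    """Optional ROC figure for the ERTC models (one curve per condition)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for (cond, algo), rep in sorted(reports.items()):
        if algo != "ertc":
            continue
        ax.plot(rep.roc["fpr"], rep.roc["tpr"], label=f"{cond} (AUC={rep.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
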