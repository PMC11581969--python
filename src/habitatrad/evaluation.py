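"""Classifier fitting and evaluation: ROC/AUC, calibration, DCA, CV.

Five classifier families are supported (logistic regression, random forest,
extra trees, XGBoost, LightGBM), all behind one ``fit_predict`` call that
returns probability scores. Evaluation covers discrimination (ROC/AUC with
bootstrap CI), calibration (binned reliability + Hosmer-Lemeshow), clinical
utility (decision-curve net benefit), and stratified k-fold
cross-validation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "ALGORITHMS",
    "ModelSpec",
    "EvalReport",
    "fit_predict",
    "roc_auc",
    "hosmer_lemeshow",
    "decision_curve",
    "calibration_bins",
    "evaluate_scores",
    "crossvalidate",
    "compare_models",
    "stratified_split",
]

ALGORITHMS = (
    "logistic_regression",
    "random_forest",
    "extra_trees",
    "xgboost",
    "lightgbm",
)


@dataclasses.dataclass
class ModelSpec:
    algorithm: str = "logistic_regression"
    hyperparameters: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )


@dataclasses.dataclass
class EvalReport:
    """Evaluation of one model on one split."""

    dataset: str
    algorithm: str
    auc: float
    auc_ci: tuple[float, float] | None
    roc_points: pd.DataFrame
    calibration: pd.DataFrame
    hl_statistic: float
    hl_df: int
    hl_pvalue: float
    dca: pd.DataFrame
    confusion_at_half: dict[str, int]


def _build_model(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "logistic_regression":
        hp.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=spec.seed, **hp)
    if spec.algorithm == "random_forest":
        hp.setdefault("n_estimators", 300)
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.algorithm == "extra_trees":
        hp.setdefault("n_estimators", 300)
        return ExtraTreesClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.algorithm == "xgboost":
        from xgboost import XGBClassifier

        hp.setdefault("n_estimators", 200)
        hp.setdefault("eval_metric", "logloss")
        return XGBClassifier(random_state=spec.seed, verbosity=0, n_jobs=1, **hp)
    if spec.algorithm == "lightgbm":
        from lightgbm import LGBMClassifier

        hp.setdefault("n_estimators", 200)
        hp.setdefault("min_child_samples", 5)
        return LGBMClassifier(random_state=spec.seed, verbose=-1, n_jobs=1, **hp)
    raise ValueError(spec.algorithm)  # pragma: no cover


def fit_predict(
    spec: ModelSpec,
    X_train: np.ndarray | pd.DataFrame,
    y_train: np.ndarray,
    X_eval: np.ndarray | pd.DataFrame,
) -> np.ndarray:
    """Fit the classifier and return probability scores on the eval set."""
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("y_train contains a single class; cannot fit")
    model = _build_model(spec)
    model.fit(np.asarray(X_train, dtype=float), y_train)
    return model.predict_proba(np.asarray(X_eval, dtype=float))[:, 1]


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 0,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, tuple[float, float] | None]:
    """AUC (probability of correct ranking, ties ½) with optional bootstrap CI."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    if n_boot <= 0:
        return auc, None
    rng = np.random.default_rng(seed)
    vals = []
    n = len(labels)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if len(np.unique(labels[idx])) < 2:
            continue
        vals.append(roc_auc_score(labels[idx], scores[idx]))
    lo, hi = np.percentile(vals, [(1 - ci) / 2 * 100, (1 + ci) / 2 * 100])
    return auc, (float(lo), float(hi))


def calibration_bins(
    probs: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Deciles-of-risk reliability table (mean predicted vs observed rate)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    order = np.argsort(probs, kind="stable")
    splits = np.array_split(order, n_bins)
    rows = []
    for grp in splits:
        if len(grp) == 0:
            continue
        rows.append(
            {
                "n": len(grp),
                "mean_predicted": float(probs[grp].mean()),
                "observed_rate": float(labels[grp].mean()),
                "observed": float(labels[grp].sum()),
                "expected": float(probs[grp].sum()),
            }
        )
    return pd.DataFrame(rows)


def hosmer_lemeshow(
    probs: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit test on deciles of predicted risk.

    Statistic = Σ_g (O_g − E_g)² / (E_g (1 − E_g/n_g)); df = G − 2. Bins
    whose denominator degenerates (expected 0 or n_g) are merged into the
    neighbor and df adjusted.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(probs) < n_bins:
        raise ValueError("need n >= n_bins observations")
    bins = calibration_bins(probs, labels, n_bins)
    merged = []
    carry = None
    for _, row in bins.iterrows():
        if carry is not None:
            row = row + carry
            carry = None
        denom = row["expected"] * (1.0 - row["expected"] / row["n"])
        if denom <= 0:
            carry = row
            continue
        merged.append(row)
    if carry is not None and merged:
        merged[-1] = merged[-1] + carry
    if len(merged) < 3:
        raise ValueError("too few usable bins for the Hosmer-Lemeshow test")
    stat = 0.0
    for row in merged:
        e, n_g, o = row["expected"], row["n"], row["observed"]
        denom = e * (1.0 - e / n_g)
        stat += (o - e) ** 2 / denom
    df = len(merged) - 2
    p = float(stats.chi2.sf(stat, df))
    return float(stat), int(df), p


def decision_curve(
    probs: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Decision-curve analysis: net benefit across threshold probabilities.

    Net benefit at threshold p_t is TP/n − (FP/n)·p_t/(1−p_t); the
    treat-all and treat-none policies are included as references.
    """
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n = len(labels)
    prevalence = labels.mean()
    rows = []
    for t in thresholds:
        pred = probs >= t
        tp = float((pred & (labels == 1)).sum())
        fp = float((pred & (labels == 0)).sum())
        odds = t / (1.0 - t)
        nb = tp / n - fp / n * odds
        nb_all = prevalence - (1.0 - prevalence) * odds
        rows.append(
            {
                "threshold": float(t),
                "net_benefit": nb,
                "treat_all": nb_all,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    dataset: str = "test",
    algorithm: str = "",
    n_boot: int = 200,
    seed: int = 0,
) -> EvalReport:
    """Bundle ROC/AUC, calibration, Hosmer-Lemeshow and DCA for one split."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    auc, auc_ci = roc_auc(scores, labels, n_boot=n_boot, seed=seed)
    fpr, tpr, thr = roc_curve(labels, scores)
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    calib = calibration_bins(scores, labels)
    try:
        hl_stat, hl_df, hl_p = hosmer_lemeshow(
            np.clip(scores, 1e-9, 1 - 1e-9), labels
        )
    except ValueError:
        hl_stat, hl_df, hl_p = float("nan"), 0, float("nan")
    dca = decision_curve(scores, labels)
    pred = scores >= 0.5
    confusion = {
        "tp": int((pred & (labels == 1)).sum()),
        "fp": int((pred & (labels == 0)).sum()),
        "tn": int((~pred & (labels == 0)).sum()),
        "fn": int((~pred & (labels == 1)).sum()),
    }
    return EvalReport(
        dataset=dataset,
        algorithm=algorithm,
        auc=auc,
        auc_ci=auc_ci,
        roc_points=roc_points,
        calibration=calib,
        hl_statistic=hl_stat,
        hl_df=hl_df,
        hl_pvalue=hl_p,
        dca=dca,
        confusion_at_half=confusion,
    )


def crossvalidate(
    spec: ModelSpec,
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[list[EvalReport], float, float]:
    """Stratified k-fold CV; per-fold reports plus mean ± sd AUC."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < n_folds:
        raise ValueError("stratification impossible: need n_folds per class")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reports = []
    for i, (tr, te) in enumerate(skf.split(X, y)):
        scores = fit_predict(spec, X[tr], y[tr], X[te])
        reports.append(
            evaluate_scores(
                scores, y[te], dataset=f"fold_{i}", algorithm=spec.algorithm,
                n_boot=0, seed=seed,
            )
        )
    aucs = np.array([r.auc for r in reports])
    return reports, float(aucs.mean()), float(aucs.std())


def compare_models(reports: list[EvalReport]) -> pd.DataFrame:
    """Rank models by AUC (descending); ties resolved by algorithm name."""
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    df = pd.DataFrame(
        {
            "algorithm": [r.algorithm for r in reports],
            "dataset": [r.dataset for r in reports],
            "auc": [r.auc for r in reports],
        }
    )
    df = df.sort_values(["auc", "algorithm"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def stratified_split(
    index: np.ndarray, y: np.ndarray, test_size: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split of an index array (default 70/30)."""
    idx_train, idx_test = train_test_split(
        np.asarray(index), test_size=test_size, random_state=seed,
        stratify=np.asarray(y),
    )
    return idx_train, idx_test
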