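"""Staged radiomic feature selection.

The reduction funnel, applied on the training split only:

1. **ICC robustness** — features must reach ICC(2,1) ≥ 0.85 both under
   re-segmentation by the same rater (test-retest) and between two raters;
   skipped for habitat signatures, whose subregions are defined
   algorithmically rather than by a rater.
2. **Distribution screen** — per-feature Shapiro-Wilk normality test;
   features compatible with a parametric (location-family) model survive.
   A literal Student-t goodness-of-fit variant is available via ``mode``.
3. **Pearson pruning** — of any pair with |r| above the threshold, the
   member with the larger mean absolute correlation to everything else is
   dropped, so no surviving pair is near-collinear.
4. **LASSO** — an L1-penalized linear fit along a log-spaced λ grid with
   10-fold cross-validation; λ minimizing mean CV error (λ_min; λ_1se
   optional) and the nonzero-coefficient features are kept.

Stage survivors are strictly nested.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

__all__ = [
    "SelectionReport",
    "icc",
    "icc_filter",
    "distribution_filter",
    "pearson_prune",
    "lasso_select",
    "run_selection",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SelectionReport:
    """Survivors and statistics of every selection stage."""

    stages: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    icc_values: dict[str, tuple[float, float]] = dataclasses.field(default_factory=dict)
    normality_pvalues: dict[str, float] = dataclasses.field(default_factory=dict)
    pruned_pairs: list[tuple[str, str, float]] = dataclasses.field(default_factory=list)
    lambda_grid: np.ndarray | None = None
    cv_mean_error: np.ndarray | None = None
    cv_sd_error: np.ndarray | None = None
    chosen_lambda: float | None = None
    coefficients: dict[str, float] = dataclasses.field(default_factory=dict)

    @property
    def selected(self) -> list[str]:
        if not self.stages:
            return []
        return self.stages[list(self.stages)[-1]]

    def assert_nested(self) -> None:
        names = list(self.stages)
        for prev, cur in zip(names, names[1:]):
            if not set(self.stages[cur]) <= set(self.stages[prev]):
                raise AssertionError(f"stage {cur} not nested in {prev}")


def icc(measurements: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Parameters
    ----------
    measurements : ndarray, shape (n_subjects, n_raters)
        Complete two-way layout (one value per subject × rater/occasion).

    Returns
    -------
    float in [−1, 1], or NaN when total variance is zero (undefined).
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a complete (n_subjects >= 2) x (k >= 2) layout")
    n, k = x.shape
    if np.ptp(x) == 0:
        return float("nan")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_filter(
    retest: dict[str, np.ndarray],
    interrater: dict[str, np.ndarray],
    threshold: float = 0.85,
) -> tuple[list[str], dict[str, tuple[float, float]]]:
    """Keep features whose min(test-retest ICC, inter-rater ICC) ≥ threshold.

    ``retest`` / ``interrater`` map feature name → (n_subjects, 2) layout.
    Features with undefined ICC (zero variance) fail the filter.
    """
    survivors, values = [], {}
    for name in retest:
        icc_rt = icc(retest[name])
        icc_ir = icc(interrater[name])
        values[name] = (icc_rt, icc_ir)
        if np.isnan(icc_rt) or np.isnan(icc_ir):
            logger.info("feature %s: ICC undefined (zero variance); dropped", name)
            continue
        if min(icc_rt, icc_ir) >= threshold:
            survivors.append(name)
    return survivors, values


def distribution_filter(
    table: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "normality",
) -> tuple[list[str], dict[str, float]]:
    """Parametric-suitability screen on each feature's marginal distribution.

    ``mode='normality'`` runs Shapiro-Wilk and keeps features with
    p ≥ alpha; ``mode='t_fit'`` instead tests goodness of fit to a fitted
    Student-t (Kolmogorov-Smirnov). Constant features are degenerate and
    always fail (logged). ``alpha=0`` keeps every non-degenerate feature.
    """
    if len(table) < 8:
        raise ValueError("need at least 8 observations per feature")
    survivors, pvals = [], {}
    for name in table.columns:
        x = table[name].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        if len(x) < 8 or np.ptp(x) == 0:
            logger.info("feature %s: degenerate (constant/missing); dropped", name)
            pvals[name] = 0.0
            continue
        if mode == "normality":
            p = float(stats.shapiro(x).pvalue)
        elif mode == "t_fit":
            params = stats.t.fit(x)
            p = float(stats.kstest(x, "t", args=params).pvalue)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        pvals[name] = p
        if p >= alpha:
            survivors.append(name)
    return survivors, pvals


def pearson_prune(
    table: pd.DataFrame,
    r_threshold: float = 0.9,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop one member of every feature pair with |r| > threshold.

    Repeatedly find the most correlated surviving pair and drop the member
    with the larger mean absolute correlation to the other survivors
    (lexicographic name as the deterministic tie-break). Guarantees no
    surviving pair exceeds the threshold.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 observations")
    cols = sorted(table.columns)
    corr = table[cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    alive = np.ones(len(cols), dtype=bool)
    dropped: list[tuple[str, str, float]] = []
    while True:
        sub = np.where(alive)[0]
        if len(sub) < 2:
            break
        c = corr[np.ix_(sub, sub)]
        mx = c.max()
        if mx <= r_threshold:
            break
        i_loc, j_loc = np.argwhere(c == mx)[0]
        i, j = sub[i_loc], sub[j_loc]
        mean_i = c[i_loc].sum() / (len(sub) - 1)
        mean_j = c[j_loc].sum() / (len(sub) - 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:  # tie: drop the lexicographically larger name
            drop = max(i, j, key=lambda t: cols[t])
        keep = j if drop == i else i
        dropped.append((cols[drop], cols[keep], float(mx)))
        alive[drop] = False
    survivors = [c for c, a in zip(cols, alive) if a]
    return [c for c in table.columns if c in set(survivors)], dropped


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray,
    n_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    rule: str = "min",
) -> SelectionReport:
    """LASSO along a λ grid with k-fold CV; keep nonzero-coefficient features.

    Features are standardized internally; ``rule='min'`` picks λ with the
    lowest mean CV error, ``rule='1se'`` the largest λ within one standard
    error of that minimum.
    """
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    sd = Xv.std(axis=0)
    if (sd == 0).all():
        raise ValueError("all features constant; LASSO cannot select")
    keep = sd > 0
    Xz = (Xv[:, keep] - Xv[:, keep].mean(axis=0)) / sd[keep]
    names = [n for n, k in zip(X.columns, keep) if k]
    if lambda_grid is None:
        lam_max = np.abs(Xz.T @ (yv - yv.mean())).max() / len(yv)
        lam_max = max(lam_max, 1e-6)
        lambda_grid = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-3), 60)
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = LassoCV(alphas=lambda_grid, cv=cv, max_iter=50000)
    model.fit(Xz, yv)
    mean_err = model.mse_path_.mean(axis=1)
    sd_err = model.mse_path_.std(axis=1) / np.sqrt(n_folds)
    alphas = model.alphas_
    i_min = int(np.argmin(mean_err))
    if rule == "min":
        chosen = float(alphas[i_min])
    elif rule == "1se":
        limit = mean_err[i_min] + sd_err[i_min]
        ok = np.where(mean_err <= limit)[0]
        chosen = float(alphas[ok].max())
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if chosen != model.alpha_:
        model = LassoCV(alphas=np.array([chosen]), cv=cv, max_iter=50000)
        model.fit(Xz, yv)
    coefs = {n: float(c) for n, c in zip(names, model.coef_) if c != 0.0}
    report = SelectionReport(
        stages={"lasso": list(coefs)},
        lambda_grid=np.asarray(alphas),
        cv_mean_error=mean_err,
        cv_sd_error=sd_err,
        chosen_lambda=chosen,
        coefficients=coefs,
    )
    return report


def run_selection(
    table: pd.DataFrame,
    y: np.ndarray,
    retest: dict[str, np.ndarray] | None = None,
    interrater: dict[str, np.ndarray] | None = None,
    icc_threshold: float = 0.85,
    use_distribution_filter: bool = True,
    alpha: float = 0.05,
    r_threshold: float = 0.9,
    n_folds: int = 10,
    seed: int = 0,
    lasso_rule: str = "min",
) -> SelectionReport:
    """Full staged pipeline; ICC runs only when rater designs are supplied.

    Returns a :class:`SelectionReport` whose stage survivors are nested.
    """
    report = SelectionReport()
    report.stages["input"] = list(table.columns)
    current = table
    if retest is not None and interrater is not None:
        survivors, values = icc_filter(
            {k: v for k, v in retest.items() if k in current.columns},
            {k: v for k, v in interrater.items() if k in current.columns},
            threshold=icc_threshold,
        )
        report.icc_values = values
        current = current[[c for c in current.columns if c in set(survivors)]]
        report.stages["icc"] = list(current.columns)
    if use_distribution_filter:
        survivors, pvals = distribution_filter(current, alpha=alpha)
        report.normality_pvalues = pvals
        current = current[survivors]
        report.stages["distribution"] = list(current.columns)
    survivors, dropped = pearson_prune(current, r_threshold=r_threshold)
    report.pruned_pairs = dropped
    current = current[survivors]
    report.stages["pearson"] = list(current.columns)
    tail = lasso_select(current, y, n_folds=n_folds, seed=seed, rule=lasso_rule)
    report.stages["lasso"] = tail.stages["lasso"]
    report.lambda_grid = tail.lambda_grid
    report.cv_mean_error = tail.cv_mean_error
    report.cv_sd_error = tail.cv_sd_error
    report.chosen_lambda = tail.chosen_lambda
    report.coefficients = tail.coefficients
    report.assert_nested()
    return report
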