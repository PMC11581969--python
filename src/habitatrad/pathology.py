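"""IHC H-scores, survival-optimal dichotomization, and KM/log-rank tools.

The H-score summarizes an IHC field as ``3·%high-positive + 2·%positive +
1·%low-positive + 0·%negative`` (range 0–300; 300 means every tumor cell is
strongly stained). Expression is dichotomized at a cutoff on the H-score
scale (default 92.3, with the boundary in the low group); an X-tile-style
scan re-derives the survival-optimal cutoff by maximizing the two-group
log-rank statistic under a minimum-group-size constraint. The Kaplan-Meier
estimator and the log-rank test are implemented directly from the risk
table.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats

__all__ = [
    "IhcField",
    "SurvivalRecord",
    "h_score",
    "dichotomize",
    "logrank",
    "km_curve",
    "optimal_cutoff",
    "followup_event_rate",
    "followup_survival_rate",
    "DEFAULT_CUTOFF",
]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 92.3


@dataclasses.dataclass
class IhcField:
    """One IHC field as category percentages (must sum to 100)."""

    percent_high: float
    percent_positive: float
    percent_low: float
    percent_negative: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.percent_high,
                self.percent_positive,
                self.percent_low,
                self.percent_negative,
            ],
            dtype=float,
        )


@dataclasses.dataclass
class SurvivalRecord:
    patient_id: str
    time: float
    event: int
    group: str = ""

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be > 0")


def _validate_field(pct: np.ndarray) -> None:
    if (pct < 0).any() or (pct > 100).any():
        raise ValueError("percentages must lie in [0, 100]")
    if abs(pct.sum() - 100.0) > 1e-6:
        raise ValueError(f"percentages sum to {pct.sum():.6f}, expected 100")


def h_score(fields) -> float:
    """H-score of one or several replicate IHC fields.

    ``3·high + 2·positive + 1·low + 0·negative`` on category percentages;
    replicate fields (e.g. triplicate staining) are averaged after scoring.
    """
    if isinstance(fields, IhcField) or (
        hasattr(fields, "__len__") and len(fields) == 4
        and not isinstance(fields[0], (IhcField, list, tuple, np.ndarray))
    ):
        fields = [fields]
    scores = []
    for f in fields:
        pct = f.as_array() if isinstance(f, IhcField) else np.asarray(f, dtype=float)
        _validate_field(pct)
        scores.append(float(np.array([3.0, 2.0, 1.0, 0.0]) @ pct))
    return float(np.mean(scores))


def dichotomize(score: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """``'low'`` iff score ≤ cutoff (boundary inclusive on low), else ``'high'``."""
    return "low" if score <= cutoff else "high"


def _as_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


def logrank(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank test (df = 1).

    Accepts lists of :class:`SurvivalRecord` or (times, events) tuples.
    Returns (chi-square statistic, p-value); raises when no events occur.
    """
    ta, ea = group_a if isinstance(group_a, tuple) else _as_arrays(group_a)
    tb, eb = group_b if isinstance(group_b, tuple) else _as_arrays(group_b)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    if events.sum() == 0:
        raise ValueError("no events in either group")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & in_a).sum()
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def km_curve(records) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit estimate.

    Returns (times, survival) of the right-continuous step function,
    starting at (0, 1). With no censoring this equals the empirical
    survival function.
    """
    times, events = records if isinstance(records, tuple) else _as_arrays(records)
    if len(times) == 0:
        raise ValueError("need at least one record")
    out_t = [0.0]
    out_s = [1.0]
    s = 1.0
    for t in np.unique(times[events == 1]):
        n = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1.0 - d / n
        out_t.append(float(t))
        out_s.append(float(s))
    return np.array(out_t), np.array(out_s)


def optimal_cutoff(
    scores: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    min_group_frac: float = 0.1,
) -> tuple[float, float, float]:
    """X-tile-style survival-optimal cutoff on a continuous biomarker.

    Scans candidate cutoffs at midpoints between adjacent distinct scores,
    requiring both groups to contain at least ``min_group_frac`` of the
    cohort, and returns the cutoff maximizing the log-rank chi-square along
    with that statistic and its (unadjusted) p-value. The p-value is
    optimism-prone because the cutoff is chosen to maximize separation; it
    is reported unadjusted and flagged here.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(scores)
    if n < 10:
        raise ValueError("need at least 10 patients")
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("all scores identical; no admissible cutoff")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    min_n = max(1, int(np.ceil(min_group_frac * n)))
    best = None
    for c in candidates:
        low = scores <= c
        if low.sum() < min_n or (~low).sum() < min_n:
            continue
        try:
            chi2, p = logrank(
                (times[low], events[low]), (times[~low], events[~low])
            )
        except ValueError:
            continue
        if best is None or chi2 > best[1]:
            best = (float(c), float(chi2), float(p))
    if best is None:
        raise ValueError("no admissible cutoff satisfies the group-size constraint")
    logger.info(
        "optimal cutoff %.3f (chi2=%.3f, unadjusted p=%.4f; p is "
        "optimism-prone due to the cutoff scan)", *best
    )
    return best


def followup_event_rate(n_total: int, n_events: int) -> float:
    """Crude event proportion × 100, rounded to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_events <= n_total:
        raise ValueError("need 0 <= n_events <= n_total")
    return round(100.0 * n_events / n_total, 1)


def followup_survival_rate(n_total: int, n_deaths: int) -> float:
    """Crude survival proportion × 100 (complement of the death rate)."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_deaths <= n_total:
        raise ValueError("need 0 <= n_deaths <= n_total")
    return round(100.0 * (n_total - n_deaths) / n_total, 1)
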