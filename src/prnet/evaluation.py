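"""Discrimination and calibration statistics for scored tables.

Discrimination: AUROC with the mid-rank tie convention, nonparametric
(DeLong) variance for confidence intervals, and the paired DeLong test for
comparing two correlated AUROCs on the same rows.  Calibration: the
Hosmer-Lemeshow chi-square over deciles of risk (equal-count groups, ties
kept together), the expected/observed event ratio, and calibration-in-the-
large (the intercept of a logistic recalibration with slope fixed at 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int).ravel()
    uniq = set(np.unique(labels))
    if uniq - {0, 1}:
        raise ValueError("labels must be coded 0/1")
    if len(uniq) < 2:
        raise ValueError("both outcome classes must be present")
    return labels


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(random positive outscores a random negative), ties counted 1/2."""
    labels = _check_labels(labels)
    scores = np.asarray(scores, float).ravel()
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = stats.rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = np.asarray(scores, float)[labels == 1]
    neg = np.asarray(scores, float)[labels == 0]
    n1, n0 = pos.size, neg.size
    order = np.sort(neg)
    # for each positive: fraction of negatives below, ties at half weight
    below = np.searchsorted(order, pos, side="left")
    upto = np.searchsorted(order, pos, side="right")
    v10 = (below + 0.5 * (upto - below)) / n0
    order1 = np.sort(pos)
    above = n1 - np.searchsorted(order1, neg, side="right")
    upto1 = n1 - np.searchsorted(order1, neg, side="left")
    v01 = (above + 0.5 * (upto1 - above)) / n1
    theta = float(v10.mean())
    return v10, v01, theta


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    labels = _check_labels(labels)
    v10, v01, theta = _delong_components(scores, labels)
    if v10.size < 2 or v01.size < 2:
        raise ValueError("need at least two observations per class")
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    return theta, float(var)


def delong_ci(scores: np.ndarray, labels: np.ndarray,
              level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation interval from the DeLong variance, clipped to
    [0, 1]."""
    theta, var = delong_variance(scores, labels)
    if var <= 0:
        raise ValueError("degenerate DeLong variance (scores tied within class)")
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (max(0.0, theta - half), min(1.0, theta + half))


def delong_compare(scores_a: np.ndarray, scores_b: np.ndarray,
                   labels: np.ndarray) -> float:
    """Two-sided paired test of AUROC(a) = AUROC(b) on the same rows."""
    labels = _check_labels(labels)
    scores_a = np.asarray(scores_a, float).ravel()
    scores_b = np.asarray(scores_b, float).ravel()
    if scores_a.shape != scores_b.shape or scores_a.size != labels.size:
        raise ValueError("both models must score the same rows")
    if np.array_equal(scores_a, scores_b):
        warnings.warn("identical score vectors; p-value 1 by convention")
        return 1.0
    va10, va01, ta = _delong_components(scores_a, labels)
    vb10, vb01, tb = _delong_components(scores_b, labels)
    n1, n0 = va10.size, va01.size
    s10 = np.cov(va10, vb10, ddof=1)
    s01 = np.cov(va01, vb01, ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    if var <= 0:
        warnings.warn("non-positive variance of the AUROC difference; "
                      "p-value 1 by convention")
        return 1.0
    z = (ta - tb) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def _risk_groups(probs: np.ndarray, groups: int) -> np.ndarray:
    """Group assignment by sorted probability, equal counts, ties kept in
    one group (quantile-cutpoint convention)."""
    n = probs.size
    qs = np.quantile(probs, np.arange(1, groups) / groups, method="linear")
    # side='left': every value equal to a cutpoint lands in the lower
    # group, so tied probabilities never straddle a boundary
    return np.searchsorted(qs, probs, side="left")


def hosmer_lemeshow(probs: np.ndarray, labels: np.ndarray,
                    groups: int = 10) -> tuple[float, int, float]:
    """Deciles-of-risk goodness-of-fit chi-square; df = groups - 2."""
    labels = _check_labels(labels)
    probs = np.asarray(probs, float).ravel()
    if groups < 3:
        raise ValueError("need at least 3 groups")
    if np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    g = _risk_groups(probs, groups)
    stat = 0.0
    used = 0
    for k in np.unique(g):
        m = g == k
        ng = int(m.sum())
        e1 = float(probs[m].sum())
        o1 = float(labels[m].sum())
        e0 = ng - e1
        o0 = ng - o1
        if e1 <= 0 or e0 <= 0:
            raise ValueError(
                f"expected count of zero in group {k}; use fewer groups"
            )
        stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        used += 1
    df = used - 2
    return float(stat), int(df), float(stats.chi2.sf(stat, df))


def calibration_summary(probs: np.ndarray, labels: np.ndarray,
                        groups: int = 10) -> dict:
    """E/O ratio, calibration-in-the-large, recalibration slope and a
    per-group observed/expected table with binomial intervals."""
    labels = _check_labels(labels)
    probs = np.asarray(probs, float).ravel()
    if labels.sum() == 0:
        raise ValueError("no observed events; calibration is undefined")
    if np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError("probabilities must lie strictly in (0, 1)")

    eo = float(probs.sum() / labels.sum())
    lp = np.log(probs / (1 - probs))
    # intercept of labels ~ 1 with offset logit(p): slope fixed at 1
    citl_fit = sm.GLM(labels, np.ones((labels.size, 1)), offset=lp,
                      family=sm.families.Binomial()).fit()
    citl = float(citl_fit.params[0])
    if np.ptp(lp) > 0:
        slope_fit = sm.GLM(labels, sm.add_constant(lp),
                           family=sm.families.Binomial()).fit()
        slope = float(slope_fit.params[1])
    else:
        slope = float("nan")  # constant predictions: slope undefined

    g = _risk_groups(probs, groups)
    rows = []
    for k in np.unique(g):
        m = g == k
        ng = int(m.sum())
        obs = float(labels[m].mean())
        exp = float(probs[m].mean())
        half = 1.96 * np.sqrt(max(obs * (1 - obs), 1e-12) / ng)
        rows.append({"group": int(k), "n": ng, "expected": exp,
                     "observed": obs, "obs_lo": max(0.0, obs - half),
                     "obs_hi": min(1.0, obs + half)})
    return {"eo_ratio": eo, "citl": citl, "slope": slope,
            "groups": pd.DataFrame(rows)}


@dataclass
class EvaluationReport:
    """Discrimination + calibration summary for one score vector."""

    auroc: float
    auroc_ci: tuple[float, float]
    hl_stat: float
    hl_df: int
    hl_p: float
    eo_ratio: float
    citl: float
    slope: float
    n: int
    prevalence: float
    delong_p: float | None = None
    group_table: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {
            "auroc": self.auroc, "auroc_lo": self.auroc_ci[0],
            "auroc_hi": self.auroc_ci[1], "hl_stat": self.hl_stat,
            "hl_df": self.hl_df, "hl_p": self.hl_p, "eo_ratio": self.eo_ratio,
            "citl": self.citl, "slope": self.slope, "n": self.n,
            "prevalence": self.prevalence,
        }
        if self.delong_p is not None:
            d["delong_p"] = self.delong_p
        return pd.DataFrame([d])


def evaluate_scores(probs: np.ndarray, labels: np.ndarray, groups: int = 10,
                    level: float = 0.95,
                    baseline: np.ndarray | None = None) -> EvaluationReport:
    """Full report for one model's predicted probabilities; ``baseline``
    adds a paired DeLong comparison against a second score vector."""
    labels = _check_labels(labels)
    probs = np.asarray(probs, float).ravel()
    a = auroc(probs, labels)
    ci = delong_ci(probs, labels, level)
    hl_stat, hl_df, hl_p = hosmer_lemeshow(probs, labels, groups)
    cal = calibration_summary(probs, labels, groups)
    dl = delong_compare(probs, baseline, labels) if baseline is not None else None
    return EvaluationReport(
        auroc=a, auroc_ci=ci, hl_stat=hl_stat, hl_df=hl_df, hl_p=hl_p,
        eo_ratio=cal["eo_ratio"], citl=cal["citl"], slope=cal["slope"],
        n=labels.size, prevalence=float(labels.mean()), delong_p=dl,
        group_table=cal["groups"],
    )
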