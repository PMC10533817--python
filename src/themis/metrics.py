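"""Detection metrics and robustness harnesses.

Covers rank-based AUC with stratified-bootstrap confidence intervals,
sensitivity at a fixed specificity with Wilson intervals, the clinical
limit of detection (logistic fit of detection on log10 mean VAF), a
population screening projection, cross-modality association profiles, and
grouped / repeated train-test split harnesses.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

WILSON_Z = 1.959964


@dataclass
class ScoredCohort:
    """Per-sample detection scores with labels and metadata."""

    ids: list[str]
    labels: list[str]  # "healthy" or a cancer-type label
    scores: np.ndarray  # in [0, 1]
    stages: list[str] = field(default_factory=list)
    sites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("scores must lie in [0, 1]")
        if len(self.ids) != len(self.labels) or len(self.ids) != len(self.scores):
            raise ValueError("ids, labels, scores must align")

    @property
    def is_cancer(self) -> np.ndarray:
        return np.array([lab != "healthy" for lab in self.labels])


def rank_auc(labels01: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC via ranks; ties count one half."""
    y = np.asarray(labels01, bool)
    s = np.asarray(scores, float)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    r = rankdata(s)
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_with_ci(
    cohort: ScoredCohort, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float, float]:
    """AUC with a 95% percentile CI from label-stratified bootstrap
    replicates (2000 by default)."""
    y = cohort.is_cancer
    s = cohort.scores
    auc = rank_auc(y, s)
    rng = np.random.default_rng(seed)
    pos, neg = np.flatnonzero(y), np.flatnonzero(~y)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([bp, bn])
        reps[b] = rank_auc(y[idx], s[idx])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return auc, float(lo), float(hi)


def wilson_interval(k: int, n: int, z: float = WILSON_Z) -> tuple[float, float]:
    """95% Wilson score interval for k successes of n."""
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def sensitivity_at_specificity(
    cohort: ScoredCohort, specificity: float = 0.99
) -> tuple[float, float, tuple[float, float]]:
    """Threshold at the target specificity and the resulting sensitivity.

    The threshold is the smallest held-out healthy score cut achieving at
    least the target specificity; scores at or above the threshold call
    positive. Returns (threshold, sensitivity, 95% Wilson CI).
    """
    y = cohort.is_cancer
    healthy = np.sort(cohort.scores[~y])
    cancer = cohort.scores[y]
    if healthy.size == 0 or cancer.size == 0:
        raise ValueError("need both healthy and cancer samples")
    candidates = np.concatenate([np.unique(cohort.scores), [np.inf]])
    threshold = None
    for t in candidates:
        spec = (healthy < t).mean()
        if spec >= specificity:
            threshold = float(t)
            break
    assert threshold is not None
    k = int((cancer >= threshold).sum())
    n = len(cancer)
    return threshold, k / n, wilson_interval(k, n)


def clod(
    detected: np.ndarray, mean_vaf: np.ndarray
) -> tuple[float, float, float]:
    """Clinical limit of detection from binarized detection outcomes.

    Fits a logistic regression of detection on log10(mean VAF); the LOD is
    the VAF at 50% detection probability, 10^(−intercept/slope), with a
    95% CI from the delta-method (Gaussian) standard error of the crossing
    point on the log10 scale.
    """
    d = np.asarray(detected, int)
    v = np.asarray(mean_vaf, float)
    if (v <= 0).any():
        raise ValueError("mean VAF must be positive")
    if len(np.unique(d)) < 2:
        raise ValueError("both detection outcomes required (no 50% crossing)")
    x = np.log10(v)
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(d, X, family=sm.families.Binomial()).fit()
    b0, b1 = fit.params
    if b1 == 0:
        raise ValueError("flat logistic fit; LOD undefined")
    x50 = -b0 / b1
    cov = fit.cov_params()
    grad = np.array([-1.0 / b1, b0 / b1**2])
    var = float(grad @ np.asarray(cov) @ grad)
    se = np.sqrt(max(var, 0.0))
    if not np.isfinite(se) or se > 10:
        warnings.warn("near-separation: LOD interval is a boundary estimate")
        se = min(se, 10.0) if np.isfinite(se) else 10.0
    return 10**x50, 10 ** (x50 - WILSON_Z * se), 10 ** (x50 + WILSON_Z * se)


def screening_projection(
    sensitivity: float, specificity: float, incidence: float, population: float
) -> tuple[float, float, float]:
    """Expected true positives, false positives and PPV when screening a
    population at a given annual cancer incidence."""
    tp = population * incidence * sensitivity
    fp = population * (1.0 - incidence) * (1.0 - specificity)
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    return tp, fp, ppv


def association_profiles(
    fsi_z: np.ndarray,
    mfr_z: np.ndarray,
    cna_z: np.ndarray,
    z_threshold: float = 2.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Cross-modality associations over aligned per-window z-profiles.

    Inputs are samples x windows z-score matrices of the three modalities.
    Returns per-sample pairwise Pearson correlations among the profiles
    and, per modality, the commonly-altered fraction: windows with
    |z| > 2 in at least half the samples.
    """
    mats = {"fsi": np.asarray(fsi_z, float), "mfr": np.asarray(mfr_z, float), "cna": np.asarray(cna_z, float)}
    shapes = {m.shape for m in mats.values()}
    if len(shapes) != 1:
        raise ValueError("z matrices must be aligned")
    n = next(iter(shapes))[0]
    rows = []
    for i in range(n):
        row = {"sample": i}
        for a, b in itertools.combinations(mats, 2):
            x, y = mats[a][i], mats[b][i]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() >= 2 and x[ok].std() > 0 and y[ok].std() > 0:
                row[f"pcc_{a}_{b}"] = float(np.corrcoef(x[ok], y[ok])[0, 1])
            else:
                row[f"pcc_{a}_{b}"] = np.nan
        rows.append(row)
    fractions = {
        name: float(
            ((np.abs(M) > z_threshold).sum(axis=0) >= np.ceil(M.shape[0] / 2)).mean()
        )
        for name, M in mats.items()
    }
    return pd.DataFrame(rows), fractions


FitScoreFn = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
"""Callable (X_train, y_train, X_test) → test scores; the harnesses treat
model fitting as a black box so any pipeline stage can be plugged in."""


def grouped_split_harness(
    features: np.ndarray,
    labels01: np.ndarray,
    groups: Mapping[str, Sequence],
    fit_score: FitScoreFn,
) -> pd.DataFrame:
    """Hold out one group per stratum, in every combination.

    ``groups`` maps stratum name (e.g. "healthy", "cancer") to a
    per-sample group id (e.g. enrolling site), with NaN/None marking
    samples outside that stratum. The cartesian product of one held-out
    group per stratum defines the combinations (product of the per-stratum
    group counts); per combination the model is refit on the remainder and
    train/test AUC reported.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels01, int)
    strata = list(groups)
    arrays = {s: np.asarray(groups[s], object) for s in strata}
    choices = {
        s: sorted({g for g in arrays[s] if g is not None and g == g}) for s in strata
    }
    rows = []
    for combo in itertools.product(*(choices[s] for s in strata)):
        test_mask = np.zeros(len(y), bool)
        for s, held in zip(strata, combo):
            test_mask |= arrays[s] == held
        train_mask = ~test_mask
        if len(np.unique(y[train_mask])) < 2 or len(np.unique(y[test_mask])) < 2:
            continue
        scores_te = fit_score(X[train_mask], y[train_mask], X[test_mask])
        scores_tr = fit_score(X[train_mask], y[train_mask], X[train_mask])
        rows.append(
            {
                **{f"held_out_{s}": held for s, held in zip(strata, combo)},
                "n_train": int(train_mask.sum()),
                "n_test": int(test_mask.sum()),
                "train_auc": rank_auc(y[train_mask], scores_tr),
                "test_auc": rank_auc(y[test_mask], scores_te),
            }
        )
    return pd.DataFrame(rows)


def repeated_split_harness(
    features: np.ndarray,
    labels01: np.ndarray,
    fit_score: FitScoreFn,
    train_fraction: float = 0.7,
    n_repeats: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified random 7:3 splits, repeated; per-split train/test AUC."""
    from sklearn.model_selection import train_test_split

    X = np.asarray(features, float)
    y = np.asarray(labels01, int)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        rs = int(rng.integers(0, 2**31 - 1))
        tr, te = train_test_split(
            np.arange(len(y)), train_size=train_fraction, stratify=y, random_state=rs
        )
        scores_te = fit_score(X[tr], y[tr], X[te])
        scores_tr = fit_score(X[tr], y[tr], X[tr])
        rows.append(
            {
                "repeat": rep,
                "train_auc": rank_auc(y[tr], scores_tr),
                "test_auc": rank_auc(y[te], scores_te),
            }
        )
    return pd.DataFrame(rows)
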