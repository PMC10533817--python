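"""Detection models: per-modality base classifiers and the logistic ensemble.

Each modality (MFR, FSI, FEM) gets a *base model*: 10 bootstrap
sub-models, each fit on a stratified 70% split after PCA retaining the
smallest number of components that explains the modality's variance
threshold (95% MFR, 90% FSI, 95% FEM), with hyperparameters chosen by
tenfold cross-validation. A sample's base score is the mean probability
over the 10 sub-models. The ensemble is an elastic-net-penalized logistic
regression over the three base scores plus the log10 aneuploidy score; its
published fixed-coefficient form,

    Z = 0.57 + 0.33*MFR + 0.34*FSI + 0.06*CAFF + 0.58*FEM
    Pr(cancer) = exp(Z) / (1 + exp(Z)),

ships as :data:`PUBLISHED_ENSEMBLE`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.decomposition import PCA
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

Modality = Literal["MFR", "FSI", "FEM"]

#: Printed variance thresholds per modality.
VARIANCE_THRESHOLDS: dict[str, float] = {"MFR": 0.95, "FSI": 0.90, "FEM": 0.95}

#: Hyperparameter grids (config-exposed).
SVM_GRID = {
    "clf__estimator__C": [0.1, 1.0, 10.0, 100.0],
    "clf__estimator__kernel": ["rbf", "linear"],
}
LR_GRID = {"clf__C": [0.01, 0.1, 1.0, 10.0, 100.0]}

N_BOOTSTRAPS = 10


@dataclass
class _SubModel:
    pipeline: Pipeline
    train_idx: np.ndarray
    val_idx: np.ndarray
    val_auc: float


@dataclass
class BaseModelBundle:
    """One modality's trained bundle of bootstrap sub-models."""

    modality: str
    variance_threshold: float
    model_family: str  # "max-margin" or "logistic"
    sub_models: list[_SubModel] = field(default_factory=list)
    n_train: int = 0

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Mean sub-model probability per sample (deterministic)."""
        X = np.atleast_2d(np.asarray(features, float))
        probs = np.column_stack(
            [sm.pipeline.predict_proba(X)[:, 1] for sm in self.sub_models]
        )
        return probs.mean(axis=1)

    def oof_scores(self, features: np.ndarray) -> np.ndarray:
        """Out-of-fold training-cohort scores: per sample, the mean over
        the sub-models in whose 30% validation fold it fell (falls back to
        the all-model mean for samples never held out)."""
        X = np.asarray(features, float)
        sums = np.zeros(len(X))
        counts = np.zeros(len(X))
        for sm in self.sub_models:
            p = sm.pipeline.predict_proba(X[sm.val_idx])[:, 1]
            sums[sm.val_idx] += p
            counts[sm.val_idx] += 1
        never = counts == 0
        out = np.empty(len(X))
        out[~never] = sums[~never] / counts[~never]
        if never.any():
            out[never] = self.predict(X[never])
        return out


def _n_components_for(threshold: float, X: np.ndarray) -> int:
    pca = PCA(svd_solver="full")
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def _make_pipeline(modality: str, n_components: int, seed: int) -> tuple[Pipeline, dict]:
    if modality == "FEM":
        clf = LogisticRegression(max_iter=5000, random_state=seed)
        grid = LR_GRID
        family = "logistic"
    else:
        # cross-validated sigmoid (Platt) calibration on out-of-fold
        # decision values; libsvm's built-in probability estimates can
        # invert orientation on small separable folds
        clf = CalibratedClassifierCV(
            SVC(random_state=seed), method="sigmoid", cv=3
        )
        grid = SVM_GRID
        family = "max-margin"
    # PC scores are standardized before the classifier: raw component
    # magnitudes track the (arbitrary) feature scale — motif frequencies
    # are O(1/256) — and an unpenalized direction should not be shrunk to
    # the intercept just because the inputs are numerically tiny.
    pipe = Pipeline(
        [
            ("impute", SimpleImputer(strategy="mean")),
            ("pca", PCA(n_components=n_components, svd_solver="full")),
            ("scale", StandardScaler()),
            ("clf", clf),
        ]
    )
    pipe._family = family  # type: ignore[attr-defined]
    return pipe, grid


def train_base_model(
    features: np.ndarray,
    labels: np.ndarray,
    modality: Modality,
    variance_threshold: float | None = None,
    seed: int = 0,
    n_bootstraps: int = N_BOOTSTRAPS,
    cv_folds: int = 10,
) -> BaseModelBundle:
    """Fit one modality's bootstrap bundle.

    Per bootstrap: a stratified 70/30 split of the training cohort, PCA on
    the 70% fold keeping the smallest component count reaching the variance
    threshold, then the modality's classifier with cross-validated
    hyperparameters; the 30% fold provides the held-out validation AUC.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels, int)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a samples x p feature matrix with p >= 2")
    if X.shape[0] < 20:
        raise ValueError("need >=20 training samples")
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain both classes")
    if variance_threshold is None:
        variance_threshold = VARIANCE_THRESHOLDS[modality]

    rng = np.random.default_rng(seed)
    bundle = BaseModelBundle(
        modality=modality,
        variance_threshold=variance_threshold,
        model_family="logistic" if modality == "FEM" else "max-margin",
        n_train=len(y),
    )
    from sklearn.metrics import roc_auc_score

    idx = np.arange(len(y))
    for b in range(n_bootstraps):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        for attempt in range(10):
            tr, va = train_test_split(
                idx, test_size=0.3, stratify=y, random_state=sub_seed + attempt
            )
            if len(np.unique(y[tr])) == 2 and len(np.unique(y[va])) == 2:
                break
            warnings.warn("single-class fold; resampling split")
        imputed = SimpleImputer(strategy="mean").fit_transform(X[tr])
        n_comp = min(_n_components_for(variance_threshold, imputed), len(tr) - 1)
        pipe, grid = _make_pipeline(modality, n_comp, sub_seed)
        folds = min(cv_folds, int(np.bincount(y[tr]).min()))
        search = GridSearchCV(
            pipe,
            grid,
            cv=StratifiedKFold(folds, shuffle=True, random_state=sub_seed),
            scoring="roc_auc",
            n_jobs=1,
        )
        search.fit(X[tr], y[tr])
        best: Pipeline = search.best_estimator_
        val_auc = roc_auc_score(y[va], best.predict_proba(X[va])[:, 1])
        bundle.sub_models.append(_SubModel(best, tr, va, float(val_auc)))
    return bundle


def predict_base(bundle: BaseModelBundle, features: np.ndarray) -> np.ndarray:
    """Mean of the 10 sub-model probabilities (see
    :meth:`BaseModelBundle.predict`)."""
    return bundle.predict(features)


@dataclass(frozen=True)
class EnsembleModel:
    """Logistic ensemble over (MFR score, FSI score, log10 PA, FEM score)."""

    intercept: float
    coefficients: tuple[float, float, float, float]

    def linear_predictor(self, mfr, fsi, caff_log10, fem) -> np.ndarray:
        c = self.coefficients
        return (
            self.intercept
            + c[0] * np.asarray(mfr, float)
            + c[1] * np.asarray(fsi, float)
            + c[2] * np.asarray(caff_log10, float)
            + c[3] * np.asarray(fem, float)
        )

    def score(self, mfr, fsi, caff_log10, fem) -> np.ndarray:
        z = self.linear_predictor(mfr, fsi, caff_log10, fem)
        return 1.0 / (1.0 + np.exp(-z))


#: The published fixed-coefficient ensemble.
PUBLISHED_ENSEMBLE = EnsembleModel(
    intercept=0.57, coefficients=(0.33, 0.34, 0.06, 0.58)
)


def themis_score(
    model: EnsembleModel, mfr_score, fsi_score, caff_log10, fem_score
) -> np.ndarray:
    """Probability of cancer under a logistic ensemble (strictly in (0,1),
    strictly increasing in every input with a positive coefficient)."""
    return model.score(mfr_score, fsi_score, caff_log10, fem_score)


def train_ensemble(
    base_scores: np.ndarray,
    caff_log10: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_folds: int = 20,
    l1_ratios: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_cs: int = 20,
) -> EnsembleModel:
    """Elastic-net logistic integration of the four modality inputs.

    ``base_scores`` holds the (MFR, FSI, FEM) base-model scores column-wise;
    the log10 PA score is inserted third so the coefficient order matches
    the published formula. Inputs are standardized for the penalized fit
    and coefficients are returned on the original scale. Penalty strength
    and mixing are chosen by k-fold cross-validated deviance; the fold
    count is reduced (with a warning) when the minority class is smaller
    than the requested fold count.
    """
    S = np.asarray(base_scores, float)
    caff = np.asarray(caff_log10, float)
    y = np.asarray(labels, int)
    if S.shape != (len(y), 3):
        raise ValueError("base_scores must be (n_samples, 3): MFR, FSI, FEM")
    X = np.column_stack([S[:, 0], S[:, 1], caff, S[:, 2]])

    mu, sdev = X.mean(axis=0), X.std(axis=0)
    degenerate = sdev == 0
    if degenerate.all():
        # no informative input: prevalence-only model
        prev = y.mean()
        return EnsembleModel(
            intercept=float(np.log(prev / (1 - prev))), coefficients=(0.0,) * 4
        )
    sdev_safe = np.where(degenerate, 1.0, sdev)
    Xs = (X - mu) / sdev_safe

    folds = min(n_folds, int(np.bincount(y).min()))
    if folds < n_folds:
        warnings.warn(f"reducing ensemble CV folds from {n_folds} to {folds}")
    if folds < 2:
        raise ValueError("too few samples per class for cross-validation")

    clf = LogisticRegressionCV(
        Cs=n_cs,
        cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
        penalty="elasticnet",
        solver="saga",
        l1_ratios=list(l1_ratios),
        scoring="neg_log_loss",
        max_iter=20000,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(Xs, y)
    beta_std = clf.coef_.ravel()
    beta = np.where(degenerate, 0.0, beta_std / sdev_safe)
    intercept = float(clf.intercept_[0] - np.sum(beta * mu))
    return EnsembleModel(intercept=intercept, coefficients=tuple(beta))
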