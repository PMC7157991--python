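"""Mondrian aggregated conformal prediction for binary toxicity endpoints.

The statistical core of the package.  A conformal predictor wraps a
probabilistic classifier (here a random forest) with a calibration step so
that, under exchangeability, its set-valued predictions err at most at a
chosen significance level ε.  Three variants are provided, mirroring the
model generations used for endocrine-disruption endpoint modelling:

``original``
    inverse-probability nonconformity (nc = 1 − p̂) with class-conditional
    (mondrian) calibration.
``normalised``
    each nc score is additionally divided by the mean nc score of the
    compound's k nearest neighbours in the proper-training set, making the
    prediction regions locally adaptive in chemical space.
``normalised_balanced``
    as ``normalised``, but each ACP loop additionally draws several
    class-balanced subsamples of the proper-training and calibration sets
    before fitting, countering strong class imbalance.

Aggregation follows the aggregated-conformal-predictor (ACP) scheme:
p-values of the constituent predictors are combined by their median; a
cross-validated ensemble averages fold-level ACP p-values by their mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.utils.validation import check_is_fitted

VARIANTS = ("original", "normalised", "normalised_balanced")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def nonconformity(p_hat: float | np.ndarray) -> float | np.ndarray:
    """Inverse-probability nonconformity score: nc = 1 − p̂.

    ``p_hat`` is the predicted probability of the (true or hypothesised)
    class; an ideal prediction (p̂ = 1) scores 0, the worst possible scores 1.
    """
    arr = np.asarray(p_hat, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = 1.0 - arr
    return float(out) if np.isscalar(p_hat) else out


def knn_norm(X, normaliser: "KNeighborsRegressor", beta: float = 0.01) -> np.ndarray:
    """Norm value for feature vectors: mean nc score of the k nearest
    proper-training compounds (Euclidean distance), plus smoothing ``beta``
    so the divisor of :func:`normalize_nonconformity` is strictly positive."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return normaliser.predict(X) + beta


def normalize_nonconformity(nc: float | np.ndarray, norm_value: float | np.ndarray):
    """Locally-adaptive nonconformity: nc_norm = nc / norm."""
    norm_arr = np.asarray(norm_value, dtype=float)
    if np.any(norm_arr <= 0):
        raise ValueError("norm value must be strictly positive (smoothing beta guards this)")
    return np.asarray(nc, dtype=float) / norm_arr


def p_value(nc_new: float, calibration_scores: Sequence[float]) -> float:
    """Smoothed conformal p-value of one nc score against one mondrian
    calibration list.

    p = (#{α_cal ≥ nc_new} + 1) / (n_cal + 1); ties count as at least as
    nonconforming and the +1 correction includes the query itself, which is
    what makes the validity guarantee hold exactly.
    """
    cal = np.asarray(calibration_scores, dtype=float)
    if cal.size == 0:
        raise ValueError("empty calibration list")
    return (int(np.sum(cal >= nc_new)) + 1) / (cal.size + 1)


def _p_values_sorted(nc_new: np.ndarray, cal_sorted: np.ndarray) -> np.ndarray:
    """Vectorised p-values against an ascending-sorted calibration array."""
    n = cal_sorted.size
    geq = n - np.searchsorted(cal_sorted, nc_new, side="left")
    return (geq + 1) / (n + 1)


def prediction_set(pvals: Sequence[float], epsilon: float) -> set[int]:
    """Labels whose p-value exceeds the significance level ε."""
    if not (0 < epsilon < 1):
        raise ValueError("epsilon must lie in (0, 1)")
    return {c for c, p in enumerate(pvals) if p > epsilon}


def credibility_confidence(pvals: Sequence[float]) -> tuple[float, float]:
    """(credibility, confidence) of a p-value pair.

    Credibility is the largest p-value — the highest significance level at
    which the favoured label is still assigned.  Confidence is 1 minus the
    second-largest p-value — high when no alternative class is plausible.
    """
    srt = sorted(pvals, reverse=True)
    return float(srt[0]), float(1.0 - srt[1])


# ---------------------------------------------------------------------------
# constituent inductive conformal predictor
# ---------------------------------------------------------------------------

@dataclass
class ConstituentPredictor:
    """One inductive conformal predictor of an ACP ensemble: a fitted random
    forest, an optional k-NN nonconformity normaliser, and per-class sorted
    calibration lists (mondrian condition)."""

    classifier: RandomForestClassifier
    normaliser: KNeighborsRegressor | None
    calibration_scores: dict[int, np.ndarray]  # class -> ascending nc scores
    beta: float

    def _norm(self, X: np.ndarray) -> np.ndarray | None:
        if self.normaliser is None:
            return None
        return self.normaliser.predict(X) + self.beta

    def predict_p(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) array of per-class p-values."""
        proba = self.classifier.predict_proba(X)
        cols = {int(c): i for i, c in enumerate(self.classifier.classes_)}
        norm = self._norm(X)
        out = np.empty((X.shape[0], 2))
        for c in (0, 1):
            nc = 1.0 - proba[:, cols[c]]
            if norm is not None:
                nc = normalize_nonconformity(nc, norm)
            out[:, c] = _p_values_sorted(nc, self.calibration_scores[c])
        return out


def train_constituent(
    proper_X: np.ndarray,
    proper_y: np.ndarray,
    cal_X: np.ndarray,
    cal_y: np.ndarray,
    *,
    variant: str = "original",
    rf_n_trees: int = 500,
    knn_k: int = 5,
    beta: float = 0.01,
    oob_normaliser_targets: bool = False,
    random_state: int | None = None,
) -> ConstituentPredictor:
    """Fit one constituent: random forest on the proper-training set, then
    mondrian calibration lists from the calibration set.

    For the normalised variants a k-NN regressor (Euclidean, uniform
    weights) is fitted on the proper-training feature vectors against their
    own true-class nc scores; its prediction is exactly the mean nc score of
    the k nearest proper-training compounds.  ``beta`` is added to every
    norm value so the divisor stays strictly positive.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    for name, y in (("proper training", proper_y), ("calibration", cal_y)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"degenerate split: {name} set contains a single class")

    rf = RandomForestClassifier(
        n_estimators=rf_n_trees,
        random_state=random_state,
        oob_score=oob_normaliser_targets and variant != "original",
    )
    rf.fit(proper_X, proper_y)
    cols = {int(c): i for i, c in enumerate(rf.classes_)}

    normaliser = None
    if variant != "original":
        if knn_k > len(proper_y):
            raise ValueError(f"knn_k={knn_k} exceeds proper-training size {len(proper_y)}")
        if oob_normaliser_targets:
            proba_pt = rf.oob_decision_function_
            bad = ~np.isfinite(proba_pt).all(axis=1)
            if bad.any():  # samples never out-of-bag: fall back to resubstitution
                proba_pt[bad] = rf.predict_proba(proper_X[bad])
        else:
            proba_pt = rf.predict_proba(proper_X)
        idx = np.array([cols[int(c)] for c in proper_y])
        nc_pt = 1.0 - proba_pt[np.arange(len(proper_y)), idx]
        normaliser = KNeighborsRegressor(n_neighbors=knn_k)
        normaliser.fit(proper_X, nc_pt)

    proba_cal = rf.predict_proba(cal_X)
    idx = np.array([cols[int(c)] for c in cal_y])
    nc_cal = 1.0 - proba_cal[np.arange(len(cal_y)), idx]
    if normaliser is not None:
        nc_cal = normalize_nonconformity(nc_cal, normaliser.predict(cal_X) + beta)

    scores = {
        c: np.sort(nc_cal[cal_y == c]) for c in (0, 1)
    }
    return ConstituentPredictor(rf, normaliser, scores, beta)


def _balanced_subsample(X, y, rng: np.random.Generator):
    """Downsample the majority class to the minority count."""
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    n = min(idx0.size, idx1.size)
    take = np.concatenate([
        rng.choice(idx0, size=n, replace=False),
        rng.choice(idx1, size=n, replace=False),
    ])
    rng.shuffle(take)
    return X[take], y[take]


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class MondrianConformalClassifier(BaseEstimator):
    """Aggregated mondrian conformal predictor for binary classification.

    ``fit`` runs ``n_acp_loops`` random stratified proper-training /
    calibration splits (default 70/30) of the training data, fitting one
    constituent per split — or ``n_balance_subsamples`` constituents per
    split for the balanced variant, each on class-balanced subsamples of
    both partitions.  ``predict_p`` aggregates constituent p-values by
    their median.

    Parameters
    ----------
    variant : {"original", "normalised", "normalised_balanced"}
    n_acp_loops : number of random proper-train/calibration splits.
    calibration_fraction : fraction of training data per calibration split.
    rf_n_trees : trees per random forest constituent.
    n_balance_subsamples : balanced subsamples per loop (balanced variant).
    knn_k : neighbours for the nonconformity normaliser.
    norm_smoothing_beta : additive smoothing of the norm divisor.
    oob_normaliser_targets : use out-of-bag probabilities for the
        normaliser's training targets instead of resubstitution ones.
    random_state : root seed; all internal randomness derives from it.
    """

    def __init__(
        self,
        variant: str = "original",
        n_acp_loops: int = 25,
        calibration_fraction: float = 0.3,
        rf_n_trees: int = 500,
        n_balance_subsamples: int = 5,
        knn_k: int = 5,
        norm_smoothing_beta: float = 0.01,
        oob_normaliser_targets: bool = False,
        random_state: int | None = None,
    ):
        self.variant = variant
        self.n_acp_loops = n_acp_loops
        self.calibration_fraction = calibration_fraction
        self.rf_n_trees = rf_n_trees
        self.n_balance_subsamples = n_balance_subsamples
        self.knn_k = knn_k
        self.norm_smoothing_beta = norm_smoothing_beta
        self.oob_normaliser_targets = oob_normaliser_targets
        self.random_state = random_state

    def _check_params(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not (0 < self.calibration_fraction < 1):
            raise ValueError("calibration_fraction must lie in (0, 1)")
        for name in ("n_acp_loops", "rf_n_trees", "n_balance_subsamples", "knn_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def fit(self, X, y) -> "MondrianConformalClassifier":
        self._check_params()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        classes, counts = np.unique(y, return_counts=True)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("y must contain both classes, coded 0/1")
        if counts.min() < 2:
            raise ValueError("need at least 2 compounds per class")
        if self.variant == "normalised_balanced":
            # each balanced partition still needs both classes after the
            # 70/30 split; 4 minority members guarantees >= 1 on each side
            required = max(4, int(np.ceil(2 / min(self.calibration_fraction,
                                                  1 - self.calibration_fraction))))
            if counts.min() < required:
                raise ValueError(
                    f"minority class has {counts.min()} members; balancing needs >= {required}"
                )

        ss = np.random.SeedSequence(self.random_state)
        rng = np.random.Generator(np.random.PCG64(ss))
        constituents: list[ConstituentPredictor] = []
        for _ in range(self.n_acp_loops):
            split_seed = int(rng.integers(2**31))
            pX, cX, py, cy = train_test_split(
                X, y,
                test_size=self.calibration_fraction,
                stratify=y,
                random_state=split_seed,
            )
            if self.variant == "normalised_balanced":
                for _ in range(self.n_balance_subsamples):
                    bpX, bpy = _balanced_subsample(pX, py, rng)
                    bcX, bcy = _balanced_subsample(cX, cy, rng)
                    constituents.append(self._fit_one(bpX, bpy, bcX, bcy, rng))
            else:
                constituents.append(self._fit_one(pX, py, cX, cy, rng))

        self.constituents_ = constituents
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def _fit_one(self, pX, py, cX, cy, rng) -> ConstituentPredictor:
        return train_constituent(
            pX, py, cX, cy,
            variant=self.variant,
            rf_n_trees=self.rf_n_trees,
            knn_k=self.knn_k,
            beta=self.norm_smoothing_beta,
            oob_normaliser_targets=self.oob_normaliser_targets,
            random_state=int(rng.integers(2**31)),
        )

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "constituents_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension mismatch: expected {self.n_features_in_}, got {X.shape}"
            )
        return X

    def predict_p(self, X) -> np.ndarray:
        """Median-aggregated (n, 2) p-values over all constituents."""
        X = self._check_X(X)
        stack = np.stack([c.predict_p(X) for c in self.constituents_])
        return np.median(stack, axis=0)

    def predict_set(self, X, epsilon: float = 0.2) -> list[set[int]]:
        return [prediction_set(p, epsilon) for p in self.predict_p(X)]

    def predict(self, X) -> np.ndarray:
        """Forced-choice label: the class with the larger p-value (ties → 1)."""
        p = self.predict_p(X)
        return (p[:, 1] >= p[:, 0]).astype(int)


class CrossValidatedConformal(BaseEstimator):
    """Cross-validated ensemble of ACPs with an internal held-out test split.

    ``fit`` reserves a stratified ``test_fraction`` of the data for
    reporting, then runs a stratified ``n_cv_folds``-fold cross-validation
    over the remainder; each fold's CV-training portion trains one
    :class:`MondrianConformalClassifier`.  Deployment p-values are the mean
    over fold ACPs of their median-aggregated p-values.
    """

    def __init__(
        self,
        variant: str = "original",
        n_cv_folds: int = 5,
        test_fraction: float = 0.2,
        n_acp_loops: int = 25,
        calibration_fraction: float = 0.3,
        rf_n_trees: int = 500,
        n_balance_subsamples: int = 5,
        knn_k: int = 5,
        norm_smoothing_beta: float = 0.01,
        oob_normaliser_targets: bool = False,
        random_state: int | None = None,
    ):
        self.variant = variant
        self.n_cv_folds = n_cv_folds
        self.test_fraction = test_fraction
        self.n_acp_loops = n_acp_loops
        self.calibration_fraction = calibration_fraction
        self.rf_n_trees = rf_n_trees
        self.n_balance_subsamples = n_balance_subsamples
        self.knn_k = knn_k
        self.norm_smoothing_beta = norm_smoothing_beta
        self.oob_normaliser_targets = oob_normaliser_targets
        self.random_state = random_state

    def _acp(self, seed: int) -> MondrianConformalClassifier:
        return MondrianConformalClassifier(
            variant=self.variant,
            n_acp_loops=self.n_acp_loops,
            calibration_fraction=self.calibration_fraction,
            rf_n_trees=self.rf_n_trees,
            n_balance_subsamples=self.n_balance_subsamples,
            knn_k=self.knn_k,
            norm_smoothing_beta=self.norm_smoothing_beta,
            oob_normaliser_targets=self.oob_normaliser_targets,
            random_state=seed,
        )

    def fit(self, X, y) -> "CrossValidatedConformal":
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must lie in (0, 1)")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        ss = np.random.SeedSequence(self.random_state)
        rng = np.random.Generator(np.random.PCG64(ss))

        idx = np.arange(len(y))
        train_idx, test_idx = train_test_split(
            idx, test_size=self.test_fraction, stratify=y,
            random_state=int(rng.integers(2**31)),
        )
        skf = StratifiedKFold(
            n_splits=self.n_cv_folds, shuffle=True,
            random_state=int(rng.integers(2**31)),
        )
        folds: list[MondrianConformalClassifier] = []
        for fold_train, _ in skf.split(X[train_idx], y[train_idx]):
            sub = train_idx[fold_train]
            acp = self._acp(int(rng.integers(2**31)))
            acp.fit(X[sub], y[sub])
            folds.append(acp)

        self.folds_ = folds
        self.train_indices_ = train_idx
        self.test_indices_ = test_idx
        self.test_p_values_ = np.mean(
            [f.predict_p(X[test_idx]) for f in folds], axis=0
        )
        self.test_y_ = y[test_idx]
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_p(self, X) -> np.ndarray:
        check_is_fitted(self, "folds_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        return np.mean([f.predict_p(X) for f in self.folds_], axis=0)

    def predict_set(self, X, epsilon: float = 0.2) -> list[set[int]]:
        return [prediction_set(p, epsilon) for p in self.predict_p(X)]

    def predict(self, X) -> np.ndarray:
        p = self.predict_p(X)
        return (p[:, 1] >= p[:, 0]).astype(int)
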