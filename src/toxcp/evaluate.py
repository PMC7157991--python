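"""Evaluation of conformal predictors and chemical-space diagnostics.

Validity — fraction of prediction sets containing the true label;
efficiency — fraction of single-class predictions (SCPs); SCP accuracy —
correct singletons over all singletons.  Calibration curves tabulate the
observed error rate against the significance level ε: a well-calibrated
conformal model stays on or below the diagonal.  Chemical-space
diagnostics: a 2-component PCA projection frozen on a reference corpus,
and the mean Tanimoto similarity of each query to its k most similar
reference compounds (a cheap applicability-domain indicator).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .conformal import prediction_set
from .readacross import tanimoto


def _sets(pval_pairs: np.ndarray, epsilon: float) -> list[set[int]]:
    pval_pairs = np.asarray(pval_pairs, dtype=float)
    if pval_pairs.size == 0:
        raise ValueError("empty input")
    return [prediction_set(p, epsilon) for p in pval_pairs]


def validity(
    pval_pairs: np.ndarray,
    true_labels: Sequence[int],
    epsilon: float,
    per_class: bool = False,
):
    """Fraction of prediction sets at ε that contain the true label.

    Empty sets count as errors.  With ``per_class=True`` returns
    ``(overall, {class: validity})`` restricted to compounds of each true
    label.
    """
    y = np.asarray(true_labels).astype(int)
    sets = _sets(pval_pairs, epsilon)
    if len(sets) != len(y):
        raise ValueError("length mismatch")
    hit = np.array([t in s for s, t in zip(sets, y)])
    overall = float(hit.mean())
    if not per_class:
        return overall
    per = {c: float(hit[y == c].mean()) if (y == c).any() else np.nan for c in (0, 1)}
    return overall, per


def efficiency(pval_pairs: np.ndarray, epsilon: float) -> float:
    """Fraction of prediction sets of size exactly one (SCPs)."""
    sets = _sets(pval_pairs, epsilon)
    return float(np.mean([len(s) == 1 for s in sets]))


def scp_accuracy(
    pval_pairs: np.ndarray,
    true_labels: Sequence[int],
    epsilon: float,
    per_class: bool = False,
):
    """Correct single-class predictions over all single-class predictions.

    Undefined (returned as NaN, not 0) when no singleton sets exist at ε.
    ``per_class`` splits by the *predicted* class of the singleton.
    """
    y = np.asarray(true_labels).astype(int)
    sets = _sets(pval_pairs, epsilon)
    singles = [(next(iter(s)), t) for s, t in zip(sets, y) if len(s) == 1]
    overall = (
        float(np.mean([pred == t for pred, t in singles])) if singles else float("nan")
    )
    if not per_class:
        return overall
    per = {}
    for c in (0, 1):
        sub = [pred == t for pred, t in singles if pred == c]
        per[c] = float(np.mean(sub)) if sub else float("nan")
    return overall, per


def set_counts(pval_pairs: np.ndarray, epsilon: float) -> dict[str, int]:
    sets = _sets(pval_pairs, epsilon)
    return {
        "single": sum(len(s) == 1 for s in sets),
        "both": sum(len(s) == 2 for s in sets),
        "empty": sum(len(s) == 0 for s in sets),
    }


DEFAULT_EPSILON_GRID = np.round(np.arange(0.01, 1.0, 0.01), 2)


def calibration_curve(
    pval_pairs: np.ndarray,
    true_labels: Sequence[int],
    epsilon_grid: Sequence[float] = DEFAULT_EPSILON_GRID,
) -> pd.DataFrame:
    """Tabulate error rate (1 − validity) and efficiency over an ε grid."""
    grid = np.asarray(epsilon_grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("epsilon grid must lie strictly inside (0, 1)")
    rows = []
    for eps in grid:
        rows.append({
            "epsilon": eps,
            "error_rate": 1.0 - validity(pval_pairs, true_labels, eps),
            "efficiency": efficiency(pval_pairs, eps),
        })
    return pd.DataFrame(rows)


def is_valid_on_grid(curve: pd.DataFrame, n: int) -> bool:
    """Calibration verdict: error_rate ≤ ε + 3·sqrt(ε(1−ε)/n) everywhere."""
    eps = curve["epsilon"].to_numpy()
    tol = 3 * np.sqrt(eps * (1 - eps) / n)
    return bool(np.all(curve["error_rate"].to_numpy() <= eps + tol))


def pca_project(
    reference_features: np.ndarray,
    query_feature_sets: dict[str, np.ndarray] | Sequence[np.ndarray],
):
    """2-component PCA fitted on the reference set only; every query set is
    projected with the frozen loadings.  Returns ``(reference_coords,
    query_coords)`` where query_coords mirrors the input container."""
    ref = np.asarray(reference_features, dtype=float)
    if ref.shape[0] < 3:
        raise ValueError("reference set must contain at least 3 points")
    pca = PCA(n_components=2)
    ref_coords = pca.fit_transform(ref)

    def _proj(q):
        q = np.asarray(q, dtype=float)
        if q.shape[1] != ref.shape[1]:
            raise ValueError("feature dimension mismatch between query and reference")
        return pca.transform(q)

    if isinstance(query_feature_sets, dict):
        return ref_coords, {k: _proj(v) for k, v in query_feature_sets.items()}
    return ref_coords, [_proj(v) for v in query_feature_sets]


def mean_topk_similarity(
    query_fingerprints: np.ndarray,
    reference_fingerprints: np.ndarray,
    k: int = 10,
) -> tuple[np.ndarray, float]:
    """Per-query mean Tanimoto similarity to the k most similar reference
    compounds, plus the average over the query set.  A low value signals
    that queries sit outside the reference chemical space."""
    ref = np.asarray(reference_fingerprints)
    if k > ref.shape[0]:
        raise ValueError(f"k={k} exceeds reference size {ref.shape[0]}")
    per_query = []
    for q in np.atleast_2d(np.asarray(query_fingerprints)):
        sims = np.sort([tanimoto(q, r) for r in ref])[::-1]
        per_query.append(float(sims[:k].mean()))
    per_query = np.array(per_query)
    return per_query, float(per_query.mean())
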