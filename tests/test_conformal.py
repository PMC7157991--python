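"""The conformal machinery: nc scores, normalisation, p-values, ensembles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.neighbors import KNeighborsRegressor

from toxcp.conformal import (
    ConstituentPredictor,
    CrossValidatedConformal,
    MondrianConformalClassifier,
    _balanced_subsample,
    _p_values_sorted,
    credibility_confidence,
    knn_norm,
    nonconformity,
    normalize_nonconformity,
    p_value,
    prediction_set,
    train_constituent,
)
from toxcp.fixtures import generate_feature_dataset


# -- elementary operations ---------------------------------------------------

@pytest.mark.parametrize("p, nc", [(1.0, 0.0), (0.0, 1.0), (0.75, 0.25), (0.5, 0.5)])
def test_nonconformity_is_inverse_probability(p, nc):
    assert nonconformity(p) == pytest.approx(nc)


def test_nonconformity_rejects_out_of_range():
    with pytest.raises(ValueError):
        nonconformity(1.5)
    with pytest.raises(ValueError):
        nonconformity(np.array([0.2, -0.1]))


def test_knn_norm_hand_cases():
    # exact neighbour, k=1, beta=0
    knn1 = KNeighborsRegressor(n_neighbors=1).fit([[0.0], [10.0]], [0.4, 0.9])
    assert knn_norm([[0.0]], knn1, beta=0.0)[0] == pytest.approx(0.4)
    # neighbours' ncs {0.2, 0.4, 0.6}, k=3 -> mean 0.4, + beta 0.01
    knn3 = KNeighborsRegressor(n_neighbors=3).fit(
        [[0.0], [1.0], [2.0]], [0.2, 0.4, 0.6]
    )
    assert knn_norm([[1.0]], knn3, beta=0.01)[0] == pytest.approx(0.41)
    # all-zero ncs: smoothing keeps the divisor positive
    knn0 = KNeighborsRegressor(n_neighbors=2).fit([[0.0], [1.0]], [0.0, 0.0])
    assert knn_norm([[0.5]], knn0, beta=0.01)[0] == pytest.approx(0.01)


@pytest.mark.parametrize("nc, norm, out", [(0.4, 0.8, 0.5), (0.0, 0.7, 0.0), (0.3, 0.3, 1.0)])
def test_normalize_nonconformity(nc, norm, out):
    assert normalize_nonconformity(nc, norm) == pytest.approx(out)


def test_normalize_nonconformity_rejects_nonpositive_norm():
    with pytest.raises(ValueError):
        normalize_nonconformity(0.4, 0.0)


def test_p_value_examples():
    assert p_value(0.4, [0.9, 0.7, 0.5, 0.3]) == pytest.approx(0.8)
    assert p_value(0.99, [0.1, 0.2, 0.3]) == pytest.approx(1 / 4)  # most nonconforming
    assert p_value(0.0, [0.1, 0.2, 0.3]) == pytest.approx(1.0)     # most conforming
    with pytest.raises(ValueError):
        p_value(0.5, [])


@given(
    cal=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10),
    nc=st.floats(0, 1, allow_nan=False),
    tie=st.booleans(),
)
@settings(max_examples=300, derandomize=True)
def test_p_value_matches_exhaustive_rank_count(cal, nc, tie):
    """Oracle: place nc in the list and count at-least-as-nonconforming
    calibration scores one by one, including exact ties."""
    if tie:
        nc = cal[0]
    count = 0
    for a in cal:
        if a >= nc:
            count += 1
    expected = (count + 1) / (len(cal) + 1)
    assert p_value(nc, cal) == pytest.approx(expected)
    # the vectorised path used by constituents must agree
    vec = _p_values_sorted(np.array([nc]), np.sort(cal))[0]
    assert vec == pytest.approx(expected)


_grid = st.integers(1, 99).map(lambda i: i / 100)  # exact ties, no float near-misses


@given(
    cal=st.lists(_grid, min_size=2, max_size=8),
    nc=_grid,
    scale=st.floats(0.5, 3.0),
)
@settings(max_examples=100, derandomize=True)
def test_p_value_invariant_under_joint_monotone_transform(cal, nc, scale):
    base = p_value(nc, cal)
    f = lambda x: np.exp(scale * np.asarray(x))  # strictly increasing
    assert p_value(float(f(nc)), list(f(cal))) == pytest.approx(base)


# -- prediction sets, credibility, confidence --------------------------------

@pytest.mark.parametrize(
    "p0, p1, eps, labels",
    [
        (0.19, 0.56, 0.2, {1}),
        (0.21, 0.60, 0.2, {0, 1}),
        (0.21, 0.60, 0.25, {1}),
        (0.05, 0.10, 0.2, set()),
    ],
)
def test_prediction_set_cases(p0, p1, eps, labels):
    assert prediction_set((p0, p1), eps) == labels


@given(
    p0=st.floats(0.001, 1), p1=st.floats(0.001, 1),
    e1=st.floats(0.01, 0.98), e2=st.floats(0.01, 0.98),
)
@settings(max_examples=200, derandomize=True)
def test_prediction_sets_are_nested(p0, p1, e1, e2):
    lo, hi = min(e1, e2), max(e1, e2)
    assert prediction_set((p0, p1), hi) <= prediction_set((p0, p1), lo)


@pytest.mark.parametrize(
    "p0, p1, cred, conf",
    [(0.19, 0.56, 0.56, 0.81), (0.5, 0.5, 0.5, 0.5), (1.0, 0.0, 1.0, 1.0)],
)
def test_credibility_confidence(p0, p1, cred, conf):
    c, f = credibility_confidence((p0, p1))
    assert c == pytest.approx(cred)
    assert f == pytest.approx(conf)


# -- constituent training ----------------------------------------------------

def _toy_data(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.normal(size=(n, 4)) + y[:, None] * 2.0
    return X, y


def test_train_constituent_structure():
    X, y = _toy_data()
    con = train_constituent(X[:28], y[:28], X[28:], y[28:],
                            variant="original", rf_n_trees=25, random_state=0)
    assert con.normaliser is None
    assert all(len(con.calibration_scores[c]) > 0 for c in (0, 1))
    # mondrian lists partition the calibration set by true label
    assert sum(len(con.calibration_scores[c]) for c in (0, 1)) == 12
    # calibration scores are exactly 1 - true-class RF probability
    proba = con.classifier.predict_proba(X[28:])
    cols = {int(c): i for i, c in enumerate(con.classifier.classes_)}
    for c in (0, 1):
        expect = np.sort(1.0 - proba[y[28:] == c, cols[c]])
        assert np.allclose(con.calibration_scores[c], expect)


def test_train_constituent_normalised_has_knn():
    X, y = _toy_data()
    con = train_constituent(X[:28], y[:28], X[28:], y[28:],
                            variant="normalised", rf_n_trees=25, random_state=0)
    assert isinstance(con.normaliser, KNeighborsRegressor)
    assert (con.calibration_scores[0] >= 0).all()


def test_train_constituent_degenerate_split():
    X, y = _toy_data()
    with pytest.raises(ValueError, match="degenerate"):
        train_constituent(X[:10], np.zeros(10, dtype=int), X[28:], y[28:])


def test_constituent_symmetric_probabilities_give_equal_pvalues():
    class Stub:
        classes_ = np.array([0, 1])
        def predict_proba(self, X):
            return np.full((len(X), 2), 0.5)

    cal = {0: np.array([0.2, 0.5, 0.8]), 1: np.array([0.2, 0.5, 0.8])}
    con = ConstituentPredictor(Stub(), None, cal, beta=0.01)
    p = con.predict_p(np.zeros((1, 3)))
    assert p[0, 0] == p[0, 1]


# -- ACP ensembles -----------------------------------------------------------

def test_acp_constituent_counts():
    X, y = generate_feature_dataset(80, dim=4, class_separation=2.0, seed=0)
    m = MondrianConformalClassifier(variant="original", n_acp_loops=3,
                                    rf_n_trees=10, random_state=0).fit(X, y)
    assert len(m.constituents_) == 3
    m2 = MondrianConformalClassifier(variant="normalised_balanced", n_acp_loops=2,
                                     n_balance_subsamples=3, rf_n_trees=10,
                                     random_state=0).fit(X, y)
    assert len(m2.constituents_) == 2 * 3


def test_balanced_subsample_equalises_classes():
    rng = np.random.default_rng(0)
    y = np.array([1] * 30 + [0] * 300)
    X = np.zeros((330, 2))
    _, by = _balanced_subsample(X, y, rng)
    assert (by == 1).sum() == (by == 0).sum() == 30


def test_median_aggregation_over_constituents():
    class Fake:
        def __init__(self, val):
            self.val = val
        def predict_p(self, X):
            return np.full((len(X), 2), self.val)

    m = MondrianConformalClassifier()
    m.constituents_ = [Fake(0.1), Fake(0.9), Fake(0.5)]
    m.n_features_in_ = 2
    assert m.predict_p(np.zeros((1, 2)))[0, 0] == pytest.approx(0.5)


def test_mean_aggregation_over_folds():
    class FakeACP:
        def __init__(self, val):
            self.val = val
        def predict_p(self, X):
            return np.full((len(X), 2), self.val)

    cv = CrossValidatedConformal()
    cv.folds_ = [FakeACP(v) for v in (0.2, 0.4, 0.6, 0.3, 0.5)]
    cv.n_features_in_ = 2
    assert cv.predict_p(np.zeros((1, 2)))[0, 1] == pytest.approx(0.4)


def test_acp_determinism_and_dimension_check():
    X, y = generate_feature_dataset(60, dim=4, class_separation=2.0, seed=3)
    kw = dict(variant="normalised", n_acp_loops=2, rf_n_trees=15, random_state=11)
    p1 = MondrianConformalClassifier(**kw).fit(X, y).predict_p(X[:5])
    p2 = MondrianConformalClassifier(**kw).fit(X, y).predict_p(X[:5])
    assert np.array_equal(p1, p2)
    m = MondrianConformalClassifier(**kw).fit(X, y)
    with pytest.raises(ValueError, match="mismatch"):
        m.predict_p(X[:, :3])


def test_acp_pvalues_in_unit_interval_and_positive():
    X, y = generate_feature_dataset(100, dim=4, class_separation=1.0, seed=5)
    m = MondrianConformalClassifier(variant="original", n_acp_loops=3,
                                    rf_n_trees=15, random_state=0).fit(X[:80], y[:80])
    p = m.predict_p(X[80:])
    assert (p > 0).all() and (p <= 1).all()


def test_acp_input_validation():
    X = np.zeros((10, 2))
    with pytest.raises(ValueError, match="both classes"):
        MondrianConformalClassifier().fit(X, np.zeros(10, dtype=int))
    with pytest.raises(ValueError, match="balancing needs"):
        y = np.array([1, 1] + [0] * 38)
        MondrianConformalClassifier(variant="normalised_balanced").fit(np.zeros((40, 2)), y)
    with pytest.raises(ValueError):
        MondrianConformalClassifier(variant="nope").fit(X, np.arange(10) % 2)


def test_cv_model_structure_and_test_split():
    X, y = generate_feature_dataset(200, dim=4, class_separation=2.0, seed=9)
    cv = CrossValidatedConformal(variant="original", n_cv_folds=3, n_acp_loops=2,
                                 rf_n_trees=10, random_state=4).fit(X, y)
    assert len(cv.folds_) == 3
    assert len(cv.test_indices_) == 40
    assert cv.test_p_values_.shape == (40, 2)
    assert set(cv.test_indices_).isdisjoint(cv.train_indices_)
    # deployment path agrees with the stored test predictions
    assert np.allclose(cv.predict_p(X[cv.test_indices_]), cv.test_p_values_)


def test_planted_signal_is_recovered():
    X, y = generate_feature_dataset(300, dim=6, class_separation=4.0, seed=2)
    m = MondrianConformalClassifier(variant="original", n_acp_loops=3,
                                    rf_n_trees=30, random_state=1).fit(X[:250], y[:250])
    # a query deep inside the class-1 region gets p1 > p0
    deep = np.full((1, 6), 4.0 / np.sqrt(6) + 1.0)
    p = m.predict_p(deep)
    assert p[0, 1] > p[0, 0]
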