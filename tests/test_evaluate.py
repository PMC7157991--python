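"""Evaluation metrics against brute-force recounts, plus space diagnostics."""

import numpy as np
import pytest

from toxcp.evaluate import (
    calibration_curve,
    efficiency,
    is_valid_on_grid,
    mean_topk_similarity,
    pca_project,
    scp_accuracy,
    set_counts,
    validity,
)


def _brute_force(pvals, y, eps):
    sets = [{c for c in (0, 1) if p[c] > eps} for p in pvals]
    val = np.mean([t in s for s, t in zip(sets, y)])
    eff = np.mean([len(s) == 1 for s in sets])
    singles = [(next(iter(s)), t) for s, t in zip(sets, y) if len(s) == 1]
    acc = np.mean([p == t for p, t in singles]) if singles else np.nan
    return val, eff, acc


@pytest.mark.parametrize("eps", [0.05, 0.2, 0.5])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_metrics_match_brute_force_recount(eps, seed, rng):
    local = np.random.default_rng(seed)
    p = local.random((50, 2))
    y = local.integers(0, 2, 50)
    val, eff, acc = _brute_force(p, y, eps)
    assert validity(p, y, eps) == pytest.approx(val)
    assert efficiency(p, eps) == pytest.approx(eff)
    got = scp_accuracy(p, y, eps)
    if np.isnan(acc):
        assert np.isnan(got)
    else:
        assert got == pytest.approx(acc)


def test_validity_degenerate_sets():
    both = np.full((10, 2), 0.9)       # all sets {0,1}
    y = np.arange(10) % 2
    assert validity(both, y, 0.2) == 1.0
    empty = np.full((10, 2), 0.01)     # all sets {}
    assert validity(empty, y, 0.2) == 0.0
    counts = set_counts(both, 0.2)
    assert counts == {"single": 0, "both": 10, "empty": 0}


def test_per_class_variants():
    p = np.array([[0.9, 0.1], [0.1, 0.9], [0.9, 0.1], [0.1, 0.9]])
    y = np.array([0, 1, 1, 0])  # two correct singletons, two wrong
    overall, per = validity(p, y, 0.2, per_class=True)
    assert overall == 0.5
    overall, per = scp_accuracy(p, y, 0.2, per_class=True)
    assert overall == 0.5
    assert per[0] == 0.5 and per[1] == 0.5


def test_scp_accuracy_missing_when_no_singletons():
    p = np.full((5, 2), 0.9)
    assert np.isnan(scp_accuracy(p, np.zeros(5, dtype=int), 0.2))


def test_empty_input_raises():
    with pytest.raises(ValueError):
        validity(np.empty((0, 2)), [], 0.2)
    with pytest.raises(ValueError):
        efficiency(np.empty((0, 2)), 0.2)


def test_calibration_curve_well_calibrated_predictor(rng):
    # ideal mondrian p-values: true-class p ~ U(0,1), other class conforming
    n = 4000
    y = rng.integers(0, 2, n)
    p = rng.random((n, 2)) * 0.15
    p[np.arange(n), y] = rng.random(n)
    curve = calibration_curve(p, y, np.round(np.arange(0.05, 1.0, 0.05), 2))
    assert np.all(np.abs(curve["error_rate"] - curve["epsilon"]) < 0.03)
    assert is_valid_on_grid(curve, n)
    # error rate vanishes as epsilon -> 0 (sets grow to {0,1})
    tiny = calibration_curve(p, y, [0.001])
    assert tiny["error_rate"].iloc[0] < 0.01


def test_calibration_curve_rejects_bad_grid():
    with pytest.raises(ValueError):
        calibration_curve(np.full((5, 2), 0.5), np.zeros(5, dtype=int), [0.0, 0.5])


def test_validity_nonincreasing_in_epsilon(rng):
    p = rng.random((200, 2))
    y = rng.integers(0, 2, 200)
    vals = [validity(p, y, e) for e in (0.1, 0.3, 0.5, 0.7, 0.9)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))


def test_pca_projection_properties(rng):
    ref = rng.normal(size=(30, 8))
    ref_coords, (q_coords,) = pca_project(ref, [ref[:3]])
    assert ref_coords.shape == (30, 2)
    assert np.var(ref_coords[:, 0]) >= np.var(ref_coords[:, 1])
    # query identical to a reference point projects onto identical coords
    assert np.allclose(q_coords, ref_coords[:3])
    with pytest.raises(ValueError, match="mismatch"):
        pca_project(ref, [rng.normal(size=(2, 5))])
    with pytest.raises(ValueError):
        pca_project(ref[:2], [])


def test_pca_separates_planted_clusters(rng):
    a = rng.normal(size=(40, 5))
    b = rng.normal(size=(40, 5)) + np.array([8, 0, 0, 0, 0])
    ref = np.vstack([a, b])
    coords, _ = pca_project(ref, [])
    c1 = coords[:40, 0], coords[40:, 0]
    assert abs(c1[0].mean() - c1[1].mean()) > 4


def test_mean_topk_similarity():
    ref = np.array([[1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 0, 1]], dtype=np.uint8)
    per, avg = mean_topk_similarity(ref[:1], ref, k=1)
    assert per[0] == 1.0  # self-match
    # hand-computed: query [1,1,0,0] vs rows: 1.0, 1/3, 0.0 -> top-2 mean
    per, avg = mean_topk_similarity(ref[:1], ref, k=2)
    assert per[0] == pytest.approx((1.0 + 1 / 3) / 2)
    disjoint = np.array([[0, 0, 1, 0]], dtype=np.uint8)
    per, _ = mean_topk_similarity(disjoint, ref[:1], k=1)
    assert per[0] == 0.0
    with pytest.raises(ValueError):
        mean_topk_similarity(ref[:1], ref, k=10)
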