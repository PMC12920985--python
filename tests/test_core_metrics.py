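"""Unit and property tests for the overlap metrics.

The independent oracles used here deliberately avoid the code paths under
test: set-counting DSC enumerates coordinate tuples in Python sets, and the
weight-map oracle derives environment membership from a taxicab distance
transform instead of iterated dilation.
"""

import numpy as np
import pytest
from scipy import ndimage

from envdice.core_metrics import (
    Connectivity,
    DegenerateCase,
    MetricConfig,
    build_environments,
    dsc,
    hybrid_wdc,
    ldc,
    wdc_fast,
    wdc_setform,
)

DEFAULT = MetricConfig()


# ---------------------------------------------------------------------------
# independent oracles


def oracle_dsc(x, y):
    X = set(map(tuple, np.argwhere(x)))
    Y = set(map(tuple, np.argwhere(y)))
    if not X and not Y:
        return 1.0
    return 2 * len(X & Y) / (len(X) + len(Y))


def oracle_weight_map(x, config=DEFAULT):
    """Weights from a taxicab/Chebyshev distance transform, not dilation."""
    metric = "taxicab" if config.connectivity is Connectivity.EDGE else "chessboard"
    if not x.any():
        return np.zeros(x.shape)
    dist = ndimage.distance_transform_cdt(~x, metric=metric)
    wmap = np.zeros(x.shape)
    wmap[dist == 0] = 1.0
    for i, nu in enumerate(config.weights, start=1):
        wmap[dist == i] = nu
    return wmap


def oracle_wdc(x, y, config=DEFAULT):
    wx, wy = oracle_weight_map(x, config), oracle_weight_map(y, config)
    if not x.any() and not y.any():
        return 1.0
    return 2 * np.minimum(wx, wy).sum() / (wx.sum() + wy.sum())


# ---------------------------------------------------------------------------
# DSC


def test_dsc_two_squares_overlap_two_pixels():
    x = np.zeros((10, 10), bool)
    y = np.zeros((10, 10), bool)
    x[1:4, 1:4] = True
    y[2:5, 3:6] = True
    assert int((x & y).sum()) == 2
    assert dsc(x, y).value == pytest.approx(0.222, abs=5e-4)


def test_dsc_identity_is_one():
    x = np.zeros((7, 7), bool)
    x[2:5, 2:5] = True
    r = dsc(x, x)
    assert r.value == 1.0
    assert r.degenerate is DegenerateCase.NONE


def test_dsc_matches_set_counting_oracle(random_pairs_2d):
    for x, y in random_pairs_2d:
        assert dsc(x, y).value == oracle_dsc(x, y)


@pytest.mark.parametrize(
    "x_empty, y_empty, expected, flag",
    [
        (True, True, 1.0, DegenerateCase.BOTH_EMPTY),
        (True, False, 0.0, DegenerateCase.ONE_EMPTY),
        (False, True, 0.0, DegenerateCase.ONE_EMPTY),
    ],
)
def test_empty_mask_semantics(x_empty, y_empty, expected, flag):
    x = np.zeros((6, 6), bool)
    y = np.zeros((6, 6), bool)
    if not x_empty:
        x[2, 2] = True
    if not y_empty:
        y[3, 3] = True
    for metric in (dsc, wdc_fast, wdc_setform, ldc, hybrid_wdc):
        r = metric(x, y)
        assert r.value == expected, metric.__name__
        assert r.degenerate is flag, metric.__name__


def test_shape_mismatch_error_names_both_shapes():
    with pytest.raises(ValueError, match=r"\(4, 4\).*\(5, 5\)"):
        dsc(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


def test_non_binary_input_rejected():
    with pytest.raises(ValueError, match="binary"):
        dsc(np.full((4, 4), 0.5), np.zeros((4, 4), bool))


# ---------------------------------------------------------------------------
# environments


def test_center_pixel_environment_shells():
    # L1 shells around an interior pixel have sizes 4, 8, 12; the weighted
    # total is 1 + 4*0.7 + 8*0.5 + 12*0.3 = 11.4
    x = np.zeros((9, 9), bool)
    x[4, 4] = True
    stack = build_environments(x, DEFAULT)
    assert [int(r.sum()) for r in stack.rings] == [1, 4, 8, 12]
    assert stack.weight_sum == pytest.approx(11.4, abs=1e-12)
    np.testing.assert_allclose(stack.weight_map, oracle_weight_map(x))


def test_zero_environments_stack_is_mask_only():
    x = np.zeros((5, 5), bool)
    x[1:3, 1:3] = True
    stack = build_environments(x, MetricConfig(n_env=0, weights=(), ldc_env_index=0))
    assert len(stack.rings) == 1
    assert stack.weight_sum == 4.0


def test_corner_pixel_environment_is_clipped():
    x = np.zeros((8, 8), bool)
    x[0, 0] = True
    stack = build_environments(x, MetricConfig(n_env=1, weights=(0.7,), ldc_env_index=1))
    assert int(stack.rings[1].sum()) == 2


def test_rings_disjoint_and_weights_from_palette(random_pairs_2d):
    x, _ = random_pairs_2d[0]
    stack = build_environments(x, DEFAULT)
    total = sum(int(r.sum()) for r in stack.rings)
    union = np.zeros_like(x)
    for r in stack.rings:
        union |= r
    assert total == int(union.sum())  # pairwise disjoint
    palette = {0.0, 1.0, *DEFAULT.weights}
    assert set(np.unique(stack.weight_map)) <= palette


# ---------------------------------------------------------------------------
# WDC


def test_wdc_adjacent_single_pixels():
    x = np.zeros((11, 11), bool)
    y = np.zeros((11, 11), bool)
    x[5, 5], y[5, 6] = True, True
    r = wdc_fast(x, y)
    assert r.value == pytest.approx(14.8 / 22.8, abs=1e-12)
    assert r.value == pytest.approx(oracle_wdc(x, y), abs=1e-12)
    assert dsc(x, y).value == 0.0
    assert hybrid_wdc(x, y).value == 0.0


def test_wdc_identity_is_one():
    x = np.zeros((9, 9), bool)
    x[3:6, 3:6] = True
    assert wdc_fast(x, x).value == 1.0
    assert wdc_setform(x, x).value == 1.0


def test_wdc_disjoint_environments_give_zero():
    x = np.zeros((20, 20), bool)
    y = np.zeros((20, 20), bool)
    x[3, 3], y[16, 16] = True, True
    assert wdc_fast(x, y).value == 0.0


@pytest.mark.parametrize("pairs_fixture", ["random_pairs_2d", "random_pairs_3d"])
def test_setform_and_fast_wdc_agree(pairs_fixture, request):
    """The set and minimum-matrix formulations are the same quantity."""
    for x, y in request.getfixturevalue(pairs_fixture):
        a = wdc_fast(x, y).value
        b = wdc_setform(x, y).value
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(oracle_wdc(x, y), abs=1e-12)


def test_wdc_matches_oracle_with_full_connectivity(random_pairs_2d):
    config = MetricConfig(connectivity=Connectivity.FULL)
    for x, y in random_pairs_2d[:10]:
        assert wdc_fast(x, y, config).value == pytest.approx(
            oracle_wdc(x, y, config), abs=1e-12
        )


# ---------------------------------------------------------------------------
# LDC


def test_ldc_penalizes_distant_extra_pixel():
    x = np.zeros((20, 20), bool)
    x[5:8, 5:8] = True
    y = x.copy()
    y[15, 15] = True  # farther than 3 dilation steps from X
    assert ldc(x, y).value == pytest.approx(0.9, abs=1e-12)
    assert dsc(x, y).value == pytest.approx(18 / 19, abs=1e-12)


def test_ldc_identity_is_one():
    x = np.zeros((9, 9), bool)
    x[4, 4] = True
    assert ldc(x, x).value == 1.0


def test_ldc_equals_dsc_when_masks_inside_each_others_environments():
    x = np.zeros((12, 12), bool)
    x[4:7, 4:7] = True
    y = np.zeros((12, 12), bool)
    y[5:8, 4:7] = True  # one step off: well inside the 3-step environments
    assert ldc(x, y).value == pytest.approx(dsc(x, y).value, abs=1e-12)


def test_ldc_dominated_by_dsc(random_pairs_2d, random_pairs_3d):
    for x, y in random_pairs_2d + random_pairs_3d:
        assert ldc(x, y).value <= dsc(x, y).value + 1e-12


# ---------------------------------------------------------------------------
# hybrid WDC


def test_hybrid_passes_through_on_overlap(random_pairs_2d):
    for x, y in random_pairs_2d:
        h = hybrid_wdc(x, y).value
        if dsc(x, y).value > 0:
            assert h == wdc_fast(x, y).value
        else:
            assert h == 0.0


# ---------------------------------------------------------------------------
# shared properties


def test_metrics_symmetric_and_in_range(random_pairs_2d, random_pairs_3d):
    for x, y in random_pairs_2d[:20] + random_pairs_3d[:20]:
        for metric in (dsc, wdc_fast, wdc_setform, ldc, hybrid_wdc):
            a, b = metric(x, y).value, metric(y, x).value
            assert a == b, metric.__name__
            assert 0.0 <= a <= 1.0


def test_zero_environment_degeneration(random_pairs_2d):
    config = MetricConfig(n_env=0, weights=(), ldc_env_index=0)
    for x, y in random_pairs_2d[:20]:
        d = dsc(x, y).value
        assert wdc_fast(x, y, config).value == pytest.approx(d, abs=1e-12)
        assert wdc_setform(x, y, config).value == pytest.approx(d, abs=1e-12)
        nx, ny = int(x.sum()), int(y.sum())
        inter = int((x & y).sum())
        closed = 2 * inter / (nx + ny + (nx - inter) + (ny - inter))
        assert ldc(x, y, config).value == pytest.approx(closed, abs=1e-12)


def test_locality_ranking_equal_dsc_ordered_wdc():
    """Same error count near vs far: DSC ties, WDC prefers the near errors."""
    x = np.zeros((30, 30), bool)
    x[12:17, 12:17] = True  # 5x5 reference
    core = np.zeros_like(x)
    core[12:17, 12:15] = True  # 15 true positives shared by both predictions
    near = core.copy()
    near[12:17, 17] = True  # 5 false positives hugging the boundary (inside X_1)
    far = core.copy()
    far[12:17, 25] = True  # 5 false positives > 3 dilation steps away
    assert dsc(x, near).value == dsc(x, far).value
    assert wdc_fast(x, near).value > wdc_fast(x, far).value


def test_near_miss_increases_low_wdc():
    # flipping one negative inside the reference's weighted environment (but
    # outside the prediction's support) raises a small WDC
    x = np.zeros((20, 20), bool)
    x[8:11, 8:11] = True
    y = np.zeros((20, 20), bool)
    y[8, 13] = True  # inside X_2, disjoint from X
    before = wdc_fast(x, y).value
    y2 = y.copy()
    y2[9, 12] = True  # another point inside X's environment
    assert wdc_fast(x, y2).value > before


def test_translation_invariance():
    rng = np.random.default_rng(7)
    x = np.zeros((24, 24), bool)
    y = np.zeros((24, 24), bool)
    x[8:12, 8:12] = rng.random((4, 4)) < 0.7
    y[8:12, 8:12] = rng.random((4, 4)) < 0.7
    shifted_x = np.roll(x, (3, -2), axis=(0, 1))
    shifted_y = np.roll(y, (3, -2), axis=(0, 1))
    for metric in (dsc, wdc_fast, ldc, hybrid_wdc):
        assert metric(x, y).value == metric(shifted_x, shifted_y).value


# ---------------------------------------------------------------------------
# config validation


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(weights=(0.3, 0.5, 0.7)),          # increasing
        dict(weights=(0.7, 0.7, 0.3)),          # not strictly decreasing
        dict(weights=(1.0, 0.5, 0.3)),          # nu_1 not < 1
        dict(weights=(0.7, 0.5, 0.0)),          # nu_n not > 0
        dict(weights=(0.7, 0.5), n_env=3),      # wrong count
        dict(ldc_env_index=4),                  # index > n
        dict(n_env=-1, weights=()),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        MetricConfig(**kwargs)


def test_environment_accessor_reconstructs_nested_sets():
    x = np.zeros((9, 9), bool)
    x[4, 4] = True
    stack = build_environments(x, DEFAULT)
    env1 = stack.environment(1)
    assert int(env1.sum()) == 5
    assert (stack.environment(3) == (stack.weight_map > 0)).all()
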