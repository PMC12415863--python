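import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fishann as fa
from fishann import MapeBand, classify_mape, evaluate, mape, r2_conventional, r2_prednorm, rmse


def loop_rmse(a, p):
    s = 0.0
    for x, y in zip(a, p):
        s += (x - y) ** 2
    return math.sqrt(s / len(a))


def loop_r2_prednorm(a, p):
    num = sum((x - y) ** 2 for x, y in zip(a, p))
    den = sum(y**2 for y in p)
    return 1 - num / den


def loop_r2_conventional(a, p):
    mean = sum(a) / len(a)
    num = sum((x - y) ** 2 for x, y in zip(a, p))
    den = sum((x - mean) ** 2 for x in a)
    return 1 - num / den


@pytest.mark.parametrize(
    "fn,a,p,expected",
    [
        (rmse, [0.0, 0.0], [3.0, 4.0], math.sqrt(25 / 2)),
        (mape, [100.0, 200.0], [110.0, 180.0], 10.0),
        (r2_prednorm, [1.0, 2.0], [1.0, 1.0], 0.5),
    ],
)
def test_forced_arithmetic(fn, a, p, expected):
    assert fn(a, p) == pytest.approx(expected, abs=1e-9)


def test_perfect_predictions():
    a = np.array([3.0, 1.0, 4.0])
    assert rmse(a, a) == 0.0
    assert mape(a, a) == 0.0
    assert r2_prednorm(a, a) == 1.0
    assert r2_conventional(a, a) == 1.0


def test_against_independent_loop_oracles():
    rng = np.random.default_rng(5)
    for _ in range(50):
        n = int(rng.integers(2, 40))
        a = rng.uniform(0.5, 10, n)
        p = rng.uniform(0.5, 10, n)
        assert rmse(a, p) == pytest.approx(loop_rmse(a, p), abs=1e-12)
        assert r2_prednorm(a, p) == pytest.approx(loop_r2_prednorm(a, p), abs=1e-12)
        assert r2_conventional(a, p) == pytest.approx(
            loop_r2_conventional(a, p), abs=1e-12
        )


def test_r2_oracle_sklearn():
    from sklearn.metrics import r2_score

    rng = np.random.default_rng(9)
    a = rng.uniform(1, 5, 25)
    p = a + rng.normal(0, 0.3, 25)
    assert r2_conventional(a, p) == pytest.approx(r2_score(a, p), abs=1e-12)


@given(k=st.floats(min_value=0.1, max_value=100))
@settings(max_examples=50, deadline=None)
def test_mape_scale_invariance(k):
    a = np.array([1.0, 2.0, 3.0])
    p = np.array([1.1, 1.9, 3.3])
    assert mape(k * a, k * p) == pytest.approx(mape(a, p), rel=1e-9)


def test_mape_rejects_zero_actual():
    with pytest.raises(ValueError):
        mape([0.0, 1.0], [1.0, 1.0])


def test_null_model_has_zero_conventional_r2():
    a = np.array([1.0, 2.0, 3.0])
    p = np.full(3, a.mean())
    assert r2_conventional(a, p) == pytest.approx(0.0, abs=1e-12)


def test_degenerate_inputs_raise():
    with pytest.raises(ValueError):
        r2_conventional([2.0, 2.0], [1.0, 2.0])  # constant actual
    with pytest.raises(ValueError):
        r2_prednorm([1.0], [0.0])  # all-zero predictions
    with pytest.raises(ValueError):
        rmse([1.0], [1.0, 2.0])  # length mismatch
    with pytest.raises(ValueError):
        rmse([], [])


@pytest.mark.parametrize(
    "m,band",
    [
        (0.0, MapeBand.HIGH_ACCURACY),
        (3.58, MapeBand.HIGH_ACCURACY),
        (10.0, MapeBand.HIGH_ACCURACY),
        (10.0001, MapeBand.GOOD),
        (20.0, MapeBand.GOOD),
        (20.0001, MapeBand.ACCEPTABLE),
        (49.999, MapeBand.ACCEPTABLE),
        (50.0, MapeBand.MISLEADING),
        (60.0, MapeBand.MISLEADING),
    ],
)
def test_mape_bands(m, band):
    assert classify_mape(m) is band


@given(m=st.floats(min_value=0, max_value=1000))
@settings(max_examples=200, deadline=None)
def test_bands_partition_nonnegative_reals(m):
    assert classify_mape(m) in MapeBand


def test_negative_mape_rejected():
    with pytest.raises(ValueError):
        classify_mape(-0.1)


def test_both_r2_equal_one_iff_zero_residuals():
    a = np.array([1.0, 2.0, 4.0])
    assert r2_prednorm(a, a) == 1.0 and r2_conventional(a, a) == 1.0
    p = a.copy()
    p[0] += 1e-3
    assert r2_prednorm(a, p) < 1.0 and r2_conventional(a, p) < 1.0


def test_evaluate_bundles_all_metrics():
    a = np.array([100.0, 120.0, 140.0])
    p = np.array([101.0, 118.0, 143.0])
    m = evaluate(a, p)
    assert m.n == 3
    assert m.rmse == pytest.approx(rmse(a, p))
    assert m.mape_band is classify_mape(m.mape)
    assert m.r2_conventional <= 1.0 and m.r2_prednorm <= 1.0
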