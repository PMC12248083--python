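"""Scaling curves, fits, Knight-Ruiz balancing and compartment diagnostics."""
import numpy as np
import pytest

import virtualhic as vh
from virtualhic.analysis import half_plateau_distance
from virtualhic.maps import DataError
from virtualhic.model import SIGMA_NM
from virtualhic.protocol import ExperimentResult, FragmentSet, LigationEvent, \
    ProtocolParams


# ------------------------------------------------------------- P(s) ------

def test_ps_curve_localisation_and_flatness():
    n = 30
    band = np.zeros((n, n))
    idx = np.arange(n - 1)
    band[idx, idx + 1] = band[idx + 1, idx] = 1.0
    curve = vh.ps_curve(band)
    assert curve.y[0] == pytest.approx(1.0)            # all mass at s = 1
    assert np.all(curve.y[1:] == 0)
    flat = vh.ps_curve(np.ones((n, n)))
    assert np.allclose(flat.y, flat.y[0])


def planted_power_matrix(n, exponent, noise=0.0, seed=0):
    s = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    with np.errstate(divide="ignore"):
        m = np.where(s > 0, s ** exponent, 1.0)
    if noise:
        rng = np.random.default_rng(seed)
        fac = np.exp(rng.normal(scale=noise, size=(n, n)))
        fac = np.sqrt(fac * fac.T)
        m = m * fac
    return m


@pytest.mark.parametrize("exponent", [-1.0, -1.5])
def test_power_exponent_recovered_exactly_on_clean_data(exponent):
    curve = vh.ps_curve(planted_power_matrix(200, exponent))
    est, _ = vh.fit_power_exponent(curve, (3, 20))
    assert est == pytest.approx(exponent, abs=1e-9)


def test_power_exponent_recovered_under_noise():
    curve = vh.ps_curve(planted_power_matrix(400, -1.2, noise=0.05, seed=3))
    est, se = vh.fit_power_exponent(curve, (3, 40))
    assert est == pytest.approx(-1.2, abs=0.05)
    assert abs(est + 1.2) < max(3 * se, 0.05)


def test_power_fit_excludes_nonpositive_with_warning():
    m = planted_power_matrix(60, -1.0)
    curve = vh.ps_curve(m)
    curve.y[4] = 0.0
    with pytest.warns(UserWarning):
        est, _ = vh.fit_power_exponent(curve, (3, 20))
    assert np.isfinite(est)
    with pytest.raises(DataError):
        vh.fit_power_exponent(vh.ps_curve(np.ones((5, 5))), (30, 40))


def test_log_binned_curve_tracks_raw_curve():
    m = planted_power_matrix(300, -1.3)
    logc = vh.ps_curve(m, log_bins=True)
    est, _ = vh.fit_power_exponent(logc, (3, 30))
    assert est == pytest.approx(-1.3, abs=0.02)


# ------------------------------------------------- Euclidean curves ------

def fake_experiment(end_positions, ligated_pairs):
    """Minimal ExperimentResult carrying only curve-relevant fields."""
    end_positions = np.asarray(end_positions, dtype=float)
    k = end_positions.shape[0]
    events = [LigationEvent(a, b, 0, a, b) for a, b in ligated_pairs]
    return ExperimentResult(
        events=events, end_beads=np.arange(k) * 3,
        end_native_positions=end_positions, n_beads=3 * k + 3,
        frozen=np.zeros(3 * k + 3, dtype=bool),
        fragments=FragmentSet([(0, 3 * k + 3)]), free_ends=[],
        proto=ProtocolParams(), sweeps_run=0)


def test_euclidean_curve_frequencies_and_masking():
    # ends at 0, 1, 3 sigma along x: pair distances 10, 20, 30 nm
    exp = fake_experiment([[0, 0, 0], [1, 0, 0], [3, 0, 0]], [(0, 1)])
    curve = vh.euclidean_ligation_curve([exp], bin_width_nm=2.0)
    bin_of = lambda d: int(d // 2.0)
    assert curve.y[bin_of(10)] == pytest.approx(1.0)   # 1 of 1 ligated
    assert curve.y[bin_of(20)] == 0.0
    assert curve.y[bin_of(30)] == 0.0
    assert np.isnan(curve.y[0])                        # no candidates there
    assert curve.counts.sum() == 3


def test_euclidean_curve_zero_rate_is_identically_zero():
    exp = fake_experiment([[0, 0, 0], [1, 0, 0], [3, 0, 0]], [])
    curve = vh.euclidean_ligation_curve([exp])
    defined = ~np.isnan(curve.y)
    assert defined.any() and np.all(curve.y[defined] == 0)


def test_frozen_geometry_restricts_curve_to_capture_radius():
    conf = vh.Conformation(np.random.default_rng(3).uniform(
        -4, 4, size=(150, 3)))
    topo = vh.Topology(150, np.ones(149, dtype=bool))
    proto = vh.ProtocolParams(n_crosslinks=150, n_cuts=60, ligation_rate=1.0,
                              duration=200000, seed=2)
    res = vh.run_experiment(conf, topo, proto=proto)
    curve = vh.euclidean_ligation_curve([res], bin_width_nm=2.0)
    beyond = curve.x - 1.0 > 1.5 * SIGMA_NM    # bins fully above 15 nm
    defined = ~np.isnan(curve.y)
    assert np.all(curve.y[beyond & defined] == 0)
    assert np.nansum(curve.y[~beyond]) > 0


# ------------------------------------------------------ sigmoid fit ------

def test_sigmoid_fit_self_consistency():
    x = np.arange(1.0, 60.0, 2.0)
    y = 0.8 / (1.0 + np.exp((x - 20.0) / 3.0))
    curve = vh.ScalingCurve(x, y, np.full_like(x, 100), "euclidean")
    fit = vh.fit_sigmoid(curve)
    assert fit.success
    assert fit.midpoint == pytest.approx(20.0, rel=0.01)
    assert fit.width == pytest.approx(3.0, rel=0.01)
    assert fit.amplitude == pytest.approx(0.8, rel=0.01)


def test_sigmoid_fit_limiting_step():
    x = np.arange(1.0, 40.0, 2.0)
    y = np.where(x < 15.0, 0.5, 0.0)
    curve = vh.ScalingCurve(x, y, np.full_like(x, 50), "euclidean")
    fit = vh.fit_sigmoid(curve)
    assert fit.success
    assert 13.0 < fit.midpoint < 15.5
    assert fit.width < 1.0


def test_sigmoid_fit_rejects_increasing_input():
    x = np.arange(1.0, 40.0, 2.0)
    curve = vh.ScalingCurve(x, x / 40.0, np.full_like(x, 50), "euclidean")
    assert not vh.fit_sigmoid(curve).success


def test_half_plateau_crossing_interpolation():
    x = np.arange(1.0, 30.0, 2.0)
    y = np.where(x < 15, 0.4, 0.0)
    y = y.astype(float)
    curve = vh.ScalingCurve(x, y, np.full_like(x, 10), "euclidean")
    d = half_plateau_distance(curve)
    assert 13.0 <= d <= 15.0


# ------------------------------------------------------ KR balance ------

def test_kr_identity_is_fixed_point():
    bal = vh.kr_balance(np.eye(4))
    assert np.allclose(bal.matrix, np.eye(4))
    assert np.allclose(bal.scaling, 1.0)


def test_kr_rank_one_closed_form():
    bal = vh.kr_balance(np.array([[1.0, 2.0], [2.0, 4.0]]))
    assert np.allclose(bal.matrix, 0.5, atol=1e-8)
    assert bal.scaling[0] == pytest.approx(2 ** -0.5, abs=1e-6)
    assert bal.scaling[1] == pytest.approx(2 ** -1.5, abs=1e-6)


def test_kr_doubly_stochastic_and_idempotent():
    rng = np.random.default_rng(0)
    a = rng.uniform(0.0, 1.0, size=(80, 80))
    a = a + a.T
    bal = vh.kr_balance(a, tol=1e-8)
    sums = bal.matrix.sum(axis=1)
    assert np.abs(sums - 1).max() < 1e-8
    again = vh.kr_balance(bal.matrix, tol=1e-8)
    assert np.allclose(again.scaling, 1.0, atol=1e-6)


def test_kr_masks_empty_rows_and_flags_bad_support():
    a = np.array([[1.0, 2.0, 0.0], [2.0, 4.0, 0.0], [0.0, 0.0, 0.0]])
    bal = vh.kr_balance(a)
    assert not bal.mask[2] and np.all(bal.matrix[2] == 0)
    assert np.isnan(bal.scaling[2])
    bad = np.array([[0.0, 0, 1], [0, 0, 1], [1, 1, 0.0]])
    with pytest.raises(vh.BalanceError):
        vh.kr_balance(bad, max_iter=50)
    with pytest.raises(DataError):
        vh.kr_balance(np.array([[1.0, -1], [-1, 1]]))


# --------------------------------------------- PCM / FPC / SVD / sums ----

def checkerboard_map(n=60, block=15, contrast=0.6):
    s = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    base = np.where(s > 0, (s + 1.0) ** -1.0, 1.0)
    par = (np.arange(n) // block) % 2
    same = np.equal.outer(par, par)
    return base * np.where(same, 1 + contrast, 1 - contrast), par


def test_pcm_checkerboard_signs_and_diagonal():
    m, par = checkerboard_map()
    res = vh.pearson_correlation_matrix(m)
    same = np.equal.outer(par, par)
    off = ~np.eye(len(par), dtype=bool)
    assert res.pcm[same & off].mean() > 0.5
    assert res.pcm[~same].mean() < -0.5
    assert np.allclose(np.diag(res.pcm), 1.0)
    assert np.allclose(res.pcm, res.pcm.T, equal_nan=True)


def test_pcm_masks_degenerate_rows():
    with pytest.warns(UserWarning):
        res = vh.pearson_correlation_matrix(np.ones((6, 6)))
    assert not res.mask.any()


def test_fpc_tracks_block_boundaries_and_is_unit_norm():
    m, par = checkerboard_map()
    res = vh.pearson_correlation_matrix(m)
    ref = np.where(par == 0, 1.0, -1.0)
    fpc = vh.first_principal_component(res, reference=ref)
    assert np.linalg.norm(fpc) == pytest.approx(1.0)
    assert np.array_equal(np.sign(fpc), ref)           # exact sign pattern
    r = np.corrcoef(fpc, ref)[0, 1]
    assert r > 0


def test_svd_spectrum_limits():
    assert np.allclose(vh.svd_spectrum(np.eye(7)), 1.0)
    v = np.ones((5, 1))
    spec = vh.svd_spectrum(v @ v.T)
    assert spec[0] == pytest.approx(5.0)
    assert np.all(spec[1:] < 1e-10)
    assert np.all(np.diff(spec) <= 1e-12)


def test_column_sums_and_moving_average():
    sums, ma = vh.column_sums(np.ones((8, 8)), window=3)
    assert np.allclose(sums, 8.0) and np.allclose(ma, 8.0)
    m = np.diag(np.arange(1.0, 5.0))
    sums, _ = vh.column_sums(m)
    assert sums.sum() == pytest.approx(m.sum())
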