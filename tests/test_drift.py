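import numpy as np
import pytest
from scipy.interpolate import make_smoothing_spline

from urimet.drift import (
    DriftOptions,
    apply_correction,
    correct_drift,
    fit_all,
    fit_drift,
    loo_cv_scores,
    smoothing_hat_matrix,
)
from urimet.synth import SimulationSpec, simulate_feature_table


def brute_force_loo(x, y, lambdas):
    """Independent leave-one-out grid search: refit on n-1 points per fold.

    The natural smoothing spline is linear beyond its boundary knots, so
    a removed endpoint is predicted by linear extension of the edge fit.
    """
    scores = []
    for lam in lambdas:
        total = 0.0
        for i in range(len(x)):
            xm, ym = np.delete(x, i), np.delete(y, i)
            sp = make_smoothing_spline(xm, ym, lam=lam)
            if x[i] < xm[0]:
                pred = sp(xm[0]) + sp(xm[0], 1) * (x[i] - xm[0])
            elif x[i] > xm[-1]:
                pred = sp(xm[-1]) + sp(xm[-1], 1) * (x[i] - xm[-1])
            else:
                pred = sp(x[i])
            total += float(y[i] - pred) ** 2
        scores.append(total)
    return np.asarray(scores)


def test_hat_matrix_matches_reference_spline(rng):
    x = np.sort(rng.uniform(0, 1, 15))
    y = np.sin(6 * x) + rng.normal(0, 0.1, 15)
    for lam in (1e-4, 1e-2, 1.0):
        fitted = smoothing_hat_matrix(x, lam) @ y
        assert np.allclose(fitted, make_smoothing_spline(x, y, lam=lam)(x), atol=1e-10)


def test_loo_selection_equals_brute_force_grid_search(rng):
    x = np.sort(rng.uniform(0, 1, 10))
    y = np.log(1.0 + 0.3 * x) + rng.normal(0, 0.05, 10)
    grid = np.geomspace(1e-5, 10, 12)
    fast = loo_cv_scores(x, y, grid)
    slow = brute_force_loo(x, y, grid)
    assert np.allclose(fast, slow, rtol=1e-8)
    assert np.argmin(fast) == np.argmin(slow)


def _qc_table(make, qc_values, n_samples=4):
    """Single-feature, single-batch table with given SQC intensities."""
    qs = list(qc_values)
    klasses = ["SQC"] * len(qs) + ["sample"] * n_samples + ["blank"]
    row = qs + [1000.0] * n_samples + [5.0]
    return make([row], klasses)


def test_constant_qcs_give_constant_fit(table_factory):
    table = _qc_table(table_factory, [500.0] * 8)
    fit = fit_drift(table, "F1", "B1")
    orders = np.arange(1, 14, dtype=float)
    assert np.allclose(fit.predict(orders), 500.0, rtol=1e-9)
    assert fit.fallback == "spline"


def test_noiseless_linear_drift_reproduced(table_factory):
    # 30% linear drift across the batch, sampled at the QC injections
    n_inj = 30
    klasses = ["SQC" if i % 3 == 0 else "sample" for i in range(n_inj)]
    orders = np.arange(1, n_inj + 1, dtype=float)
    drift = 1.0 + 0.3 * (orders - 1) / (n_inj - 1)
    row = 1000.0 * drift
    table = table_factory([row], klasses)
    fit = fit_drift(table, "F1", "B1")
    qc_orders = orders[np.array([k == "SQC" for k in klasses])]
    expected = 1000.0 * (1.0 + 0.3 * (qc_orders - 1) / (n_inj - 1))
    assert np.allclose(fit.predict(qc_orders), expected, rtol=1e-6)
    # between QC knots the natural-spline interpolant stays close to the
    # trend (the zero-curvature boundary condition costs ~1e-4 at the edges)
    interior = orders[(orders >= qc_orders[0]) & (orders <= qc_orders[-1])]
    exp_int = 1000.0 * (1.0 + 0.3 * (interior - 1) / (n_inj - 1))
    assert np.allclose(fit.predict(interior), exp_int, rtol=1e-3)


def test_linear_fallback_below_five_qcs(table_factory):
    table = _qc_table(table_factory, [100.0, 110.0, 120.0, 130.0])
    fit = fit_drift(table, "F1", "B1")
    assert fit.fallback == "linear"
    assert fit.n_qc == 4


def test_skip_below_min_qc_is_not_an_exception(table_factory):
    table = _qc_table(table_factory, [100.0, np.nan, np.nan, np.nan])
    fit = fit_drift(table, "F1", "B1")
    assert fit.skipped
    assert "usable QC" in fit.skip_reason


def test_clamped_extrapolation_beyond_qc_span(table_factory):
    n_inj = 20
    klasses = ["sample"] + ["SQC" if 1 <= i - 1 < 8 else "sample" for i in range(1, n_inj)]
    orders = np.arange(1, n_inj + 1, dtype=float)
    row = 1000.0 * (1.0 + 0.02 * orders)
    table = table_factory([row], klasses)
    fit = fit_drift(table, "F1", "B1")
    lo, hi = fit.qc_span
    assert fit.predict(np.array([lo - 5]))[0] == pytest.approx(fit.predict(np.array([lo]))[0])
    assert fit.predict(np.array([hi + 50]))[0] == pytest.approx(fit.predict(np.array([hi]))[0])


def test_identity_on_driftfree_noiseless_table():
    spec = SimulationSpec(n_features=12, n_samples_per_batch=10, drift_model="none", noise_cv=0.0, seed=4)
    table, _ = simulate_feature_table(spec)
    corrected, report = correct_drift(table)
    assert np.allclose(corrected.intensities.to_numpy(), table.intensities.to_numpy(), rtol=1e-9)
    assert report.n_skipped == 0


def test_scale_equivariance():
    spec = SimulationSpec(n_features=6, n_samples_per_batch=15, seed=8)
    table, _ = simulate_feature_table(spec)
    corrected1, _ = correct_drift(table)
    scaled = table.copy()
    scaled.intensities.iloc[2] *= 7.5
    corrected2, _ = correct_drift(scaled)
    assert np.allclose(
        corrected2.intensities.iloc[2].to_numpy(),
        7.5 * corrected1.intensities.iloc[2].to_numpy(),
        rtol=1e-9,
    )
    others = [0, 1, 3, 4, 5]
    assert np.allclose(
        corrected2.intensities.iloc[others].to_numpy(),
        corrected1.intensities.iloc[others].to_numpy(),
        rtol=1e-12,
    )


def test_batchwise_qc_median_preserved_single_batch():
    spec = SimulationSpec(n_features=10, n_samples_per_batch=20, seed=5)
    table, _ = simulate_feature_table(spec)
    corrected, _ = correct_drift(table)
    qc = table.injection_ids(klass="SQC")
    pre = table.intensities[qc].median(axis=1)
    post = corrected.intensities[qc].median(axis=1)
    assert np.allclose(post, pre, rtol=1e-9)


def test_batches_never_share_a_fit():
    spec = SimulationSpec(n_features=5, n_samples_per_batch=12, n_batches=2, seed=6)
    table, _ = simulate_feature_table(spec)
    fits = fit_all(table)
    by_batch = {(f.feature_id, f.batch_id) for f in fits}
    assert len(by_batch) == table.shape[0] * 2  # every feature row, incl. tIS panels
    # corrupting batch B02's QCs leaves batch B01's correction unchanged
    options = DriftOptions(align_batches=False)
    corrected1, _ = apply_correction(table, fit_all(table, options), options)
    tampered = table.copy()
    b2_qcs = tampered.injection_ids(klass="SQC", batch_id="B02")
    tampered.intensities.loc[:, b2_qcs] *= 3.0
    corrected2, _ = apply_correction(tampered, fit_all(tampered, options), options)
    b1 = table.injection_ids(batch_id="B01")
    assert np.allclose(
        corrected1.intensities[b1].to_numpy(), corrected2.intensities[b1].to_numpy(), rtol=1e-12
    )


def test_multibatch_alignment_equalizes_qc_medians():
    spec = SimulationSpec(n_features=8, n_samples_per_batch=15, n_batches=3, seed=9)
    table, _ = simulate_feature_table(spec)
    corrected, _ = correct_drift(table, DriftOptions(align_batches=True))
    medians = []
    for batch in table.batches():
        qc = table.injection_ids(klass="SQC", batch_id=batch)
        medians.append(corrected.intensities[qc].median(axis=1).to_numpy())
    assert np.allclose(medians[0], medians[1], rtol=1e-9)
    assert np.allclose(medians[0], medians[2], rtol=1e-9)


def test_simulated_drift_removed():
    """Sinusoidal 20% drift with 3% injection noise: the corrected pooled-QC
    CVs collapse to the noise floor while raw CVs reflect the drift."""
    spec = SimulationSpec(n_features=60, n_batches=2, seed=13)
    table, truth = simulate_feature_table(spec)
    corrected, report = correct_drift(table)
    pf = report.per_feature.loc[truth.feature_ids]
    assert pf["cv_qc_pre"].median() > 15.0
    assert pf["cv_qc_post"].median() < 5.0
    assert (pf["cv_qc_post"] <= pf["cv_qc_pre"]).mean() >= 0.95


def test_fit_all_matches_per_feature_fit():
    spec = SimulationSpec(n_features=4, n_samples_per_batch=25, seed=21)
    table, _ = simulate_feature_table(spec)
    fits_fast = {(f.feature_id, f.batch_id): f for f in fit_all(table)}
    orders = np.linspace(3, 90, 40)
    for fid in table.intensities.index:
        slow = fit_drift(table, fid, "B01")
        fast = fits_fast[(fid, "B01")]
        assert slow.lam == fast.lam
        assert np.allclose(slow.predict(orders), fast.predict(orders), rtol=1e-10)
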