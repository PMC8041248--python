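import math

import numpy as np
import pytest

from urimet.qcmetrics import (
    FeatureQCRecord,
    FilterCriteria,
    PRESET_NONZERO_IQR,
    PRESET_STRICT,
    compute_metrics,
    evaluate_tis,
    filter_features,
    metrics_frame,
)
from urimet.synth import SimulationSpec, simulate_feature_table


# ---------------------------------------------------------------------------
# independent naive oracle (plain Python, no numpy statistics)
# ---------------------------------------------------------------------------

def _mean(v):
    return sum(v) / len(v)


def _sd(v):
    m = _mean(v)
    return math.sqrt(sum((x - m) ** 2 for x in v) / (len(v) - 1))


def _percentile_linear(v, q):
    s = sorted(v)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def _skew_adjusted(v):
    n = len(v)
    m = _mean(v)
    m2 = sum((x - m) ** 2 for x in v) / n
    m3 = sum((x - m) ** 3 for x in v) / n
    g1 = m3 / m2**1.5
    return g1 * math.sqrt(n * (n - 1)) / (n - 2)


def naive_metrics(table, blank_factor=5.0):
    inj = table.injections
    out = {}
    batches = sorted(inj["batch_id"].unique())
    blank_ids_all = [i for i in inj.index if inj.loc[i, "klass"] == "blank"]
    for fid in table.intensities.index:
        row = table.intensities.loc[fid]
        qc = [row[i] for i in inj.index if inj.loc[i, "klass"] == "SQC" and not math.isnan(row[i])]
        smp_ids = [i for i in inj.index if inj.loc[i, "klass"] == "sample"]
        smp = [row[i] for i in smp_ids if not math.isnan(row[i])]
        overall_blank = _mean([row[i] for i in blank_ids_all if not math.isnan(row[i])])
        blank_by_batch = {}
        for b in batches:
            ids = [i for i in blank_ids_all if inj.loc[i, "batch_id"] == b]
            vals = [row[i] for i in ids if not math.isnan(row[i])]
            blank_by_batch[b] = _mean(vals) if vals else overall_blank
        below = 0
        for i in smp_ids:
            thr = blank_factor * blank_by_batch[inj.loc[i, "batch_id"]]
            if math.isnan(row[i]) or row[i] < thr:
                below += 1
        out[fid] = dict(
            mean_intensity_qc=_mean(qc),
            cv_qc=100.0 * _sd(qc) / _mean(qc),
            cv_sample=100.0 * _sd(smp) / _mean(smp),
            d_ratio=100.0 * _sd(qc) / _sd(smp),
            missingness=100.0 * below / len(smp_ids),
            iqr=_percentile_linear(smp, 0.75) - _percentile_linear(smp, 0.25),
            skewness=_skew_adjusted(smp),
        )
    return out


def test_metrics_match_naive_oracle_to_1e12():
    spec = SimulationSpec(
        n_features=50, n_samples_per_batch=20, n_batches=2, missing_rate=0.05, seed=17
    )
    table, _ = simulate_feature_table(spec)
    records = {r.feature_id: r for r in compute_metrics(table)}
    oracle = naive_metrics(table)
    for fid, expect in oracle.items():
        got = records[fid]
        for key, val in expect.items():
            assert getattr(got, key) == pytest.approx(val, rel=1e-12, abs=1e-12), (fid, key)


def test_constant_qc_feature_has_zero_cv(table_factory):
    table = table_factory(
        [[50.0, 50.0, 50.0, 40.0, 60.0, 1.0]],
        ["SQC", "SQC", "SQC", "sample", "sample", "blank"],
    )
    (rec,) = compute_metrics(table)
    assert rec.cv_qc == 0.0


def test_equal_sds_give_d_ratio_100(table_factory):
    table = table_factory(
        [[10.0, 20.0, 110.0, 120.0, 1.0]],
        ["SQC", "SQC", "sample", "sample", "blank"],
    )
    (rec,) = compute_metrics(table)
    assert rec.d_ratio == pytest.approx(100.0)


def test_undefined_statistics_flagged_not_infinite(table_factory):
    # zero QC mean and zero sample SD
    table = table_factory(
        [[0.0, 0.0, 77.0, 77.0, 77.0, 1.0]],
        ["SQC", "SQC", "sample", "sample", "sample", "blank"],
    )
    (rec,) = compute_metrics(table)
    assert math.isnan(rec.cv_qc) and "cv_qc" in rec.undefined
    assert math.isnan(rec.d_ratio) and "d_ratio" in rec.undefined
    report = filter_features([rec])
    assert rec.feature_id in report.fails["cv_qc"]
    assert rec.feature_id in report.fails["d_ratio"]


def _record(fid, **kw):
    base = dict(
        feature_id=fid, mean_intensity_qc=1e4, cv_qc=10.0, cv_sample=40.0,
        d_ratio=25.0, missingness=5.0, iqr=500.0, skewness=0.5, in_dynamic_range=True,
    )
    base.update(kw)
    return FeatureQCRecord(**base)


def test_cv_exactly_at_threshold_fails_strictly():
    report = filter_features([_record("F1", cv_qc=35.0)])
    assert "F1" in report.fails["cv_qc"]
    report = filter_features([_record("F2", cv_qc=34.999999)])
    assert report.survivors == ("F2",)


def test_constructed_violations_and_survivor_count():
    records = (
        [_record(f"cv{i}", cv_qc=40.0 + i) for i in range(3)]
        + [_record(f"dr{i}", d_ratio=60.0 + i) for i in range(2)]
        + [_record("rng0", mean_intensity_qc=4.2e6)]
        + [_record(f"ok{i}") for i in range(4)]
    )
    report = filter_features(records)
    assert len(report.survivors) == 4
    assert report.fail_counts == {
        "cv_qc": 3, "d_ratio": 2, "dynamic_range": 1, "missingness": 0, "iqr": 0,
    }


def test_all_passing_records_survive():
    records = [_record(f"F{i}") for i in range(10)]
    report = filter_features(records)
    assert report.survivors == tuple(f"F{i}" for i in range(10))
    assert all(len(v) == 0 for v in report.fails.values())


def test_vacuous_filter_keeps_everything():
    crit = FilterCriteria(
        cv_qc_max=np.inf, dynamic_min=-np.inf, dynamic_max=np.inf,
        missingness_max=np.inf, d_ratio_max=np.inf, iqr_min=-np.inf,
    )
    records = [
        _record("A", cv_qc=500.0, d_ratio=300.0, missingness=99.0, iqr=0.0, mean_intensity_qc=1.0),
        _record("B"),
    ]
    report = filter_features(records, crit)
    assert report.survivors == ("A", "B")


def test_strict_vs_nonzero_iqr_presets():
    rec = _record("F1", iqr=50.0)
    assert "F1" in filter_features([rec], PRESET_STRICT).fails["iqr"]  # IQR > 80
    assert filter_features([rec], PRESET_NONZERO_IQR).survivors == ("F1",)  # IQR > 0


def test_metrics_invariant_to_injection_reordering(table_factory, rng):
    mat = rng.uniform(1e3, 1e5, (3, 12))
    klasses = ["SQC", "sample", "blank", "sample", "SQC", "sample", "SQC", "sample", "blank", "SQC", "sample", "sample"]
    t1 = table_factory(mat, klasses)
    perm = rng.permutation(12)
    t2 = table_factory(mat[:, perm], [klasses[p] for p in perm])
    f1, f2 = metrics_frame(compute_metrics(t1)), metrics_frame(compute_metrics(t2))
    assert np.allclose(f1.drop(columns="in_dynamic_range"), f2.drop(columns="in_dynamic_range"))


def test_d_ratio_scale_invariant(table_factory, rng):
    mat = rng.uniform(1e3, 1e5, (1, 10))
    klasses = ["SQC"] * 3 + ["sample"] * 6 + ["blank"]
    (r1,) = compute_metrics(table_factory(mat, klasses))
    (r2,) = compute_metrics(table_factory(mat * 13.0, klasses))
    assert r1.d_ratio == pytest.approx(r2.d_ratio, rel=1e-12)
    assert r1.cv_qc == pytest.approx(r2.cv_qc, rel=1e-12)


# ---------------------------------------------------------------------------
# technical internal standards
# ---------------------------------------------------------------------------

def test_tis_constant_within_batch_passes(table_factory):
    table = table_factory(
        [[100.0] * 6],
        ["SQC", "SQC", "sample", "sample", "sample", "blank"],
        feature_ids=["tIS_CHES"],
    )
    report = evaluate_tis(table, ["tIS_CHES"])
    assert report.passed


def test_tis_cv_exactly_at_threshold_fails(table_factory):
    # two QC values with mean 100 and CV exactly 10%
    sd_target = 10.0
    a, b = 100 + sd_target / math.sqrt(2), 100 - sd_target / math.sqrt(2)
    table = table_factory(
        [[a, b, 100.0, 100.0, 1.0]],
        ["SQC", "SQC", "sample", "sample", "blank"],
        feature_ids=["tIS_PIPES"],
    )
    report = evaluate_tis(table, ["tIS_PIPES"])
    cv = next(r.cv_qc for r in report.results)
    assert cv == pytest.approx(10.0)
    assert not report.passed


def test_missing_tis_id_is_named():
    table, _ = simulate_feature_table(SimulationSpec(n_features=3, n_samples_per_batch=6, seed=2))
    with pytest.raises(ValueError, match="tIS_ghost"):
        evaluate_tis(table, ["tIS_ghost"])


@pytest.mark.parametrize("noise, expect_pass", [(0.03, True), (0.12, False)])
def test_tis_acceptance_across_24_batches(noise, expect_pass):
    spec = SimulationSpec(
        n_features=1, n_samples_per_batch=70, n_batches=24,
        drift_model="none", noise_cv=noise, seed=33,
    )
    table, truth = simulate_feature_table(spec)
    report = evaluate_tis(table, truth.tis_ids)
    assert report.passed is expect_pass
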