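"""Per-feature quality statistics, filter criteria, and tIS run acceptance.

For every feature the module computes, on raw intensities:

* ``cv_qc`` / ``cv_sample`` — 100 * SD/mean over pooled-QC (SQC) and study
  sample injections (SD with the n-1 denominator);
* ``d_ratio`` — 100 * SD_SQC / SD_sample, the share of technical in total
  variation; low values mean biology dominates;
* ``missingness`` — percentage of sample injections whose intensity falls
  below five times the blank signal (missing values count as below);
  the blank reference is the mean blank intensity of the injection's own
  batch, falling back to the whole-run mean when a batch has no usable
  blank;
* ``iqr`` — interquartile range of sample intensities
  (linear-interpolation quantiles);
* ``skewness`` — adjusted Fisher-Pearson skewness of sample intensities;
* ``in_dynamic_range`` — mean SQC intensity within the instrument's
  dynamic range.

Statistics whose denominator vanishes are reported as NaN with an
``undefined`` flag and fail the corresponding filter conservatively.
Filters use the strict inequalities exactly as printed in their
definitions (a CV of exactly 35.0 fails "CV < 35%").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable

#: technical internal standards used in the positive-ionization method
TIS_PANEL_POSITIVE = ("pyrantel", "CHES", "fluorocytosine", "PIPES", "HEPES")
#: technical internal standards used in the negative-ionization method
TIS_PANEL_NEGATIVE = ("fluorocinnamic acid", "tricarballylic acid", "CHES", "PIPES", "HEPES")


@dataclass(frozen=True)
class FeatureQCRecord:
    feature_id: str
    mean_intensity_qc: float
    cv_qc: float  # %
    cv_sample: float  # %
    d_ratio: float  # %
    missingness: float  # % of sample injections below 5x blank
    iqr: float
    skewness: float
    in_dynamic_range: bool
    undefined: tuple[str, ...] = ()  # statistics with vanishing denominators


@dataclass(frozen=True)
class FilterCriteria:
    """Feature-retention thresholds; comparisons are strict as printed."""

    cv_qc_max: float = 35.0  # keep if cv_qc < 35
    dynamic_min: float = 1.5e3  # keep if dynamic_min <= mean QC <= dynamic_max
    dynamic_max: float = 3.5e6
    missingness_max: float = 90.0  # keep if missingness < 90
    d_ratio_max: float = 55.0  # keep if d_ratio < 55
    iqr_min: float = 80.0  # keep if iqr > 80

    def __post_init__(self) -> None:
        if self.dynamic_min >= self.dynamic_max:
            raise ValueError("dynamic_min must be < dynamic_max")


#: the full published-threshold set (IQR > 80)
PRESET_STRICT = FilterCriteria()
#: alternative preset with IQR > 0 (drop only no-variability features)
PRESET_NONZERO_IQR = FilterCriteria(iqr_min=0.0)
PRESETS: Mapping[str, FilterCriteria] = {
    "strict": PRESET_STRICT,
    "nonzero-iqr": PRESET_NONZERO_IQR,
}


def _sd(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1)) if len(v) >= 2 else float("nan")


def _cv_pct(v: np.ndarray) -> tuple[float, bool]:
    """CV% and an undefined flag (zero/invalid mean)."""
    v = v[np.isfinite(v)]
    if len(v) < 2:
        return float("nan"), True
    m = v.mean()
    if m == 0:
        return float("nan"), True
    return float(100.0 * _sd(v) / m), False


def blank_reference(table: FeatureTable) -> pd.DataFrame:
    """Mean blank intensity per feature and batch (whole-run fallback)."""
    blanks = table.injections.index[table.injections["klass"] == "blank"]
    if len(blanks) == 0:
        raise ValueError("table has no blank injections")
    overall = table.intensities[blanks].mean(axis=1)
    cols = {}
    for batch in table.batches():
        bb = table.injection_ids(klass="blank", batch_id=batch)
        if len(bb):
            ref = table.intensities[bb].mean(axis=1)
            cols[batch] = ref.fillna(overall)
        else:
            cols[batch] = overall
    return pd.DataFrame(cols)


def compute_metrics(
    table: FeatureTable,
    criteria: FilterCriteria = FilterCriteria(),
    blank_factor: float = 5.0,
) -> list[FeatureQCRecord]:
    """Quality statistics for every feature in the table.

    Requires at least 2 SQC, 2 sample and 1 blank injections.  Statistics
    are computed on raw intensities, missing values excluded except in
    missingness where a missing sample intensity counts as below the
    5x-blank threshold.
    """
    qc_ids = table.injection_ids(klass="SQC")
    smp_ids = table.injection_ids(klass="sample")
    if len(qc_ids) < 2 or len(smp_ids) < 2:
        raise ValueError(f"need >= 2 SQC and >= 2 sample injections, got {len(qc_ids)}/{len(smp_ids)}")
    bref = blank_reference(table)  # raises without blanks
    smp_batches = table.injections.loc[smp_ids, "batch_id"]

    records = []
    for fid in table.intensities.index:
        undefined: list[str] = []
        qc = table.intensities.loc[fid, qc_ids].to_numpy(dtype=float)
        smp = table.intensities.loc[fid, smp_ids].to_numpy(dtype=float)
        qc_f = qc[np.isfinite(qc)]
        smp_f = smp[np.isfinite(smp)]

        mean_qc = float(qc_f.mean()) if len(qc_f) else float("nan")
        cv_qc, undef = _cv_pct(qc)
        if undef:
            undefined.append("cv_qc")
        cv_smp, undef = _cv_pct(smp)
        if undef:
            undefined.append("cv_sample")
        sd_qc, sd_smp = _sd(qc_f), _sd(smp_f)
        if not np.isfinite(sd_smp) or sd_smp == 0:
            d_ratio = float("nan")
            undefined.append("d_ratio")
        else:
            d_ratio = 100.0 * sd_qc / sd_smp

        thresholds = (blank_factor * bref.loc[fid, smp_batches]).to_numpy(dtype=float)
        below = ~np.isfinite(smp) | (smp < thresholds)
        missingness = float(100.0 * below.mean())

        if len(smp_f) >= 2:
            q1, q3 = np.percentile(smp_f, [25, 75], method="linear")
            iqr = float(q3 - q1)
        else:
            iqr = float("nan")
            undefined.append("iqr")
        skew = float(stats.skew(smp_f, bias=False)) if len(smp_f) >= 3 else float("nan")

        records.append(
            FeatureQCRecord(
                feature_id=fid,
                mean_intensity_qc=mean_qc,
                cv_qc=cv_qc,
                cv_sample=cv_smp,
                d_ratio=d_ratio,
                missingness=missingness,
                iqr=iqr,
                skewness=skew,
                in_dynamic_range=bool(
                    np.isfinite(mean_qc) and criteria.dynamic_min <= mean_qc <= criteria.dynamic_max
                ),
                undefined=tuple(undefined),
            )
        )
    return records


def metrics_frame(records: Sequence[FeatureQCRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mean_intensity_qc": [r.mean_intensity_qc for r in records],
            "cv_qc": [r.cv_qc for r in records],
            "cv_sample": [r.cv_sample for r in records],
            "d_ratio": [r.d_ratio for r in records],
            "missingness": [r.missingness for r in records],
            "iqr": [r.iqr for r in records],
            "skewness": [r.skewness for r in records],
            "in_dynamic_range": [r.in_dynamic_range for r in records],
        },
        index=pd.Index([r.feature_id for r in records], name="feature_id"),
    )


@dataclass(frozen=True)
class FilterReport:
    survivors: tuple[str, ...]
    fails: Mapping[str, tuple[str, ...]]  # criterion -> feature ids (may overlap)
    criteria: FilterCriteria

    @property
    def fail_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.fails.items()}


def filter_features(records: Sequence[FeatureQCRecord], criteria: FilterCriteria = FilterCriteria()) -> FilterReport:
    """Apply the retention criteria; a feature may fail several at once.

    Keep iff cv_qc < cv_qc_max, mean QC intensity within the dynamic
    range, missingness < missingness_max, d_ratio < d_ratio_max and
    iqr > iqr_min.  NaN (undefined) statistics fail their criterion.
    """
    fails: dict[str, list[str]] = {k: [] for k in ("cv_qc", "dynamic_range", "missingness", "d_ratio", "iqr")}
    survivors = []
    for r in records:
        ok = True
        if not (np.isfinite(r.cv_qc) and r.cv_qc < criteria.cv_qc_max):
            fails["cv_qc"].append(r.feature_id)
            ok = False
        in_range = np.isfinite(r.mean_intensity_qc) and (
            criteria.dynamic_min <= r.mean_intensity_qc <= criteria.dynamic_max
        )
        if not in_range:
            fails["dynamic_range"].append(r.feature_id)
            ok = False
        if not (np.isfinite(r.missingness) and r.missingness < criteria.missingness_max):
            fails["missingness"].append(r.feature_id)
            ok = False
        if not (np.isfinite(r.d_ratio) and r.d_ratio < criteria.d_ratio_max):
            fails["d_ratio"].append(r.feature_id)
            ok = False
        if not (np.isfinite(r.iqr) and r.iqr > criteria.iqr_min):
            fails["iqr"].append(r.feature_id)
            ok = False
        if ok:
            survivors.append(r.feature_id)
    return FilterReport(
        survivors=tuple(survivors),
        fails={k: tuple(v) for k, v in fails.items()},
        criteria=criteria,
    )


# ---------------------------------------------------------------------------
# technical-internal-standard run acceptance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TISBatchResult:
    feature_id: str
    batch_id: str  # "" for the whole run
    cv_qc: float
    cv_sample: float
    pass_qc: bool
    pass_sample: bool

    @property
    def passed(self) -> bool:
        return self.pass_qc and self.pass_sample


@dataclass(frozen=True)
class TISReport:
    results: tuple[TISBatchResult, ...]
    cv_qc_max: float
    cv_sample_max: float

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.results)

    def per_batch(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": [r.feature_id for r in self.results],
                "batch_id": [r.batch_id for r in self.results],
                "cv_qc": [r.cv_qc for r in self.results],
                "cv_sample": [r.cv_sample for r in self.results],
                "pass": [r.passed for r in self.results],
            }
        )


def evaluate_tis(
    table: FeatureTable,
    tis_ids: Sequence[str],
    cv_qc_max: float = 10.0,
    cv_sample_max: float = 20.0,
) -> TISReport:
    """Run acceptance on the technical internal standards.

    Per batch and for the whole run, a tIS passes when its SQC CV is
    strictly below ``cv_qc_max`` and its sample CV strictly below
    ``cv_sample_max`` (undefined CVs fail).
    """
    missing = [t for t in tis_ids if t not in table.intensities.index]
    if missing:
        raise ValueError(f"tIS features not found in table: {missing}")
    results = []
    scopes: list[str | None] = list(table.batches()) + [None]
    for fid in tis_ids:
        for batch in scopes:
            qc = table.intensities.loc[fid, table.injection_ids("SQC", batch)].to_numpy(dtype=float)
            smp = table.intensities.loc[fid, table.injection_ids("sample", batch)].to_numpy(dtype=float)
            cv_qc, _ = _cv_pct(qc)
            cv_smp, _ = _cv_pct(smp)
            results.append(
                TISBatchResult(
                    feature_id=fid,
                    batch_id=batch or "",
                    cv_qc=cv_qc,
                    cv_sample=cv_smp,
                    pass_qc=bool(np.isfinite(cv_qc) and cv_qc < cv_qc_max),
                    pass_sample=bool(np.isfinite(cv_smp) and cv_smp < cv_sample_max),
                )
            )
    return TISReport(results=tuple(results), cv_qc_max=cv_qc_max, cv_sample_max=cv_sample_max)
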