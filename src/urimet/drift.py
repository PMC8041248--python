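"""Pooled-QC signal-drift correction across injection order.

LC-MS intensities drift with injection order (source fouling, temperature,
mobile-phase ageing).  Because the pooled study QC (SQC) is chemically
identical in every injection, any trend in its intensities is purely
technical and can be divided out.  Per feature and per batch this module:

1. fits a natural cubic smoothing spline to log SQC intensity versus
   injection order, choosing the smoothing parameter on a geometric grid
   by exact leave-one-out cross-validation (the Craven-Wahba identity for
   linear smoothers, computed from the hat matrix (I + lam*K)^-1 in
   Reinsch form);
2. falls back to a straight line when fewer than five usable QCs exist,
   and skips the feature (passing it through unchanged) below ``min_qc``;
3. divides every intensity in the batch by the fitted curve (clamped to a
   constant beyond the first/last QC) and rescales so the batch's
   corrected SQC median equals a reference level.

Fitting on the log scale makes the correction multiplicative — LC-MS
drift predominantly scales signals — and guarantees a strictly positive
fitted curve.  With ``align_batches=True`` (default) the reference level
is the whole-run SQC median, aligning batches to a common level; with
``False`` each batch keeps its own raw SQC median exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .io import FeatureTable


@dataclass(frozen=True)
class DriftOptions:
    min_qc: int = 4  # skip correction below this many usable QCs
    linear_below: int = 5  # straight-line fit below this many QCs
    grid_size: int = 25
    lambda_min: float = 1e-8  # smoothing grid on order rescaled to [0, 1]
    lambda_max: float = 1e2
    align_batches: bool = True

    def lambda_grid(self) -> np.ndarray:
        return np.geomspace(self.lambda_min, self.lambda_max, self.grid_size)


@dataclass
class DriftFit:
    """Fitted drift curve for one (feature, batch) pair."""

    feature_id: str
    batch_id: str
    predict: Callable[[np.ndarray], np.ndarray]  # order -> positive drift factor
    reference_level: float  # target corrected SQC median (raw scale)
    n_qc: int
    fallback: str  # "spline" | "linear" | "skipped"
    lam: float | None = None
    skip_reason: str | None = None
    qc_span: tuple[float, float] | None = None

    @property
    def skipped(self) -> bool:
        return self.fallback == "skipped"


# ---------------------------------------------------------------------------
# natural cubic smoothing spline in Reinsch form
# ---------------------------------------------------------------------------

def smoothing_hat_matrix(x: np.ndarray, lam: float) -> np.ndarray:
    """Hat matrix A with fitted = A @ y for the natural cubic smoothing spline.

    Minimizes sum (y - f(x))^2 + lam * integral f''(t)^2 dt; A =
    (I + lam*K)^-1 with K = D' R^-1 D built from the second-difference
    operator D and the tridiagonal Gram matrix R of the natural-spline
    basis (Reinsch algorithm).  Requires >= 3 strictly increasing x.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"smoothing spline needs >= 3 points, got {n}")
    h = np.diff(x)
    if (h <= 0).any():
        raise ValueError("x must be strictly increasing")
    D = np.zeros((n - 2, n))
    R = np.zeros((n - 2, n - 2))
    idx = np.arange(n - 2)
    D[idx, idx] = 1.0 / h[:-1]
    D[idx, idx + 1] = -1.0 / h[:-1] - 1.0 / h[1:]
    D[idx, idx + 2] = 1.0 / h[1:]
    R[idx, idx] = (h[:-1] + h[1:]) / 3.0
    R[idx[:-1], idx[:-1] + 1] = h[1:-1] / 6.0
    R[idx[:-1] + 1, idx[:-1]] = h[1:-1] / 6.0
    K = D.T @ np.linalg.solve(R, D)
    return np.linalg.inv(np.eye(n) + lam * K)


def loo_cv_scores(x: np.ndarray, y: np.ndarray, lambdas: Iterable[float]) -> np.ndarray:
    """Exact leave-one-out CV score per smoothing value.

    Uses the linear-smoother identity: the LOO residual at point i equals
    (y_i - fitted_i) / (1 - A_ii), so no refits are needed.
    """
    y = np.asarray(y, dtype=float)
    scores = []
    for lam in lambdas:
        A = smoothing_hat_matrix(x, lam)
        resid = (y - A @ y) / (1.0 - np.diag(A))
        scores.append(float(np.sum(resid**2)))
    return np.asarray(scores)


def _clamped(curve: Callable[[np.ndarray], np.ndarray], lo: float, hi: float) -> Callable[[np.ndarray], np.ndarray]:
    def predict(order: np.ndarray) -> np.ndarray:
        return np.asarray(curve(np.clip(np.asarray(order, dtype=float), lo, hi)))

    return predict


def fit_drift(
    table: FeatureTable,
    feature_id: str,
    batch_id: str,
    options: DriftOptions = DriftOptions(),
) -> DriftFit:
    """Fit the drift curve of one feature in one batch from its SQC signals.

    QC points with missing or non-positive intensity are dropped; if fewer
    than ``options.min_qc`` remain the feature is flagged skipped (never an
    exception).  The returned ``predict`` maps injection order to the
    multiplicative drift factor, constant beyond the QC span.
    """
    qc_ids = table.injection_ids(klass="SQC", batch_id=batch_id)
    orders = table.injections.loc[qc_ids, "order"].to_numpy(dtype=float)
    y = table.intensities.loc[feature_id, qc_ids].to_numpy(dtype=float)
    usable = np.isfinite(y) & (y > 0)
    x, y = orders[usable], y[usable]
    srt = np.argsort(x)
    x, y = x[srt], y[srt]
    ref = float(np.median(y)) if len(y) else float("nan")

    def skipped(reason: str) -> DriftFit:
        return DriftFit(
            feature_id=feature_id, batch_id=batch_id, predict=lambda o: np.ones_like(np.asarray(o, float)),
            reference_level=ref, n_qc=int(len(y)), fallback="skipped", skip_reason=reason,
        )

    if len(y) < max(2, options.min_qc):
        return skipped(f"only {len(y)} usable QC intensities (min_qc={options.min_qc})")
    if len(np.unique(x)) < 2:
        return skipped("QC injections share a single order value")

    logy = np.log(y)
    span = (float(x[0]), float(x[-1]))
    if len(y) < options.linear_below:
        coef = np.polyfit(x, logy, 1)
        curve = lambda o: np.exp(np.polyval(coef, o))  # noqa: E731
        return DriftFit(
            feature_id=feature_id, batch_id=batch_id, predict=_clamped(curve, *span),
            reference_level=ref, n_qc=len(y), fallback="linear", qc_span=span,
        )

    # rescale order to [0, 1] so the smoothing grid is span-independent
    u = (x - x[0]) / (x[-1] - x[0])
    grid = options.lambda_grid()
    scores = loo_cv_scores(u, logy, grid)
    lam = float(grid[int(np.argmin(scores))])
    fitted = smoothing_hat_matrix(u, lam) @ logy
    spline = CubicSpline(x, fitted, bc_type="natural")
    curve = lambda o: np.exp(spline(o))  # noqa: E731
    if not np.all(np.isfinite(curve(np.linspace(*span, 64)))):
        return skipped("non-finite fitted drift curve")
    return DriftFit(
        feature_id=feature_id, batch_id=batch_id, predict=_clamped(curve, *span),
        reference_level=ref, n_qc=len(y), fallback="spline", lam=lam, qc_span=span,
    )


def fit_all(table: FeatureTable, options: DriftOptions = DriftOptions()) -> list[DriftFit]:
    """Fit drift curves for every (feature, batch) pair.

    Exploits that the leave-one-out hat matrices depend only on the QC
    order positions, not on the intensities, so the smoothing-parameter
    search is shared across all features with the same usable-QC pattern
    within a batch.
    """
    fits: list[DriftFit] = []
    grid = options.lambda_grid()
    for batch in table.batches():
        qc_ids = table.injection_ids(klass="SQC", batch_id=batch)
        orders = table.injections.loc[qc_ids, "order"].to_numpy(dtype=float)
        srt = np.argsort(orders)
        orders, qc_ids = orders[srt], qc_ids[srt]
        Y = table.intensities.loc[:, qc_ids].to_numpy(dtype=float)
        usable = np.isfinite(Y) & (Y > 0)
        # group features by usable-QC mask: the hat matrices are shared
        cache: dict[bytes, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for i, fid in enumerate(table.intensities.index):
            mask = usable[i]
            n_use = int(mask.sum())
            if n_use < max(2, options.min_qc) or len(np.unique(orders[mask])) < 2 or n_use < options.linear_below:
                fits.append(fit_drift(table, fid, batch, options))
                continue
            key = mask.tobytes()
            if key not in cache:
                x = orders[mask]
                u = (x - x[0]) / (x[-1] - x[0])
                hats = np.stack([smoothing_hat_matrix(u, lam) for lam in grid])
                diags = np.stack([np.diag(h) for h in hats])
                cache[key] = (x, hats, diags)
            x, hats, diags = cache[key]
            logy = np.log(Y[i, mask])
            fitted_all = hats @ logy  # (grid, n_qc)
            resid = (logy[None, :] - fitted_all) / (1.0 - diags)
            k = int(np.argmin(np.sum(resid**2, axis=1)))
            spline = CubicSpline(x, fitted_all[k], bc_type="natural")
            span = (float(x[0]), float(x[-1]))
            curve = (lambda sp: (lambda o: np.exp(sp(o))))(spline)
            fits.append(
                DriftFit(
                    feature_id=fid, batch_id=batch, predict=_clamped(curve, *span),
                    reference_level=float(np.median(Y[i, mask])), n_qc=int(mask.sum()),
                    fallback="spline", lam=float(grid[k]), qc_span=span,
                )
            )
    return fits


# ---------------------------------------------------------------------------
# applying the correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrectionReport:
    per_feature: pd.DataFrame  # cv_qc_pre/post, cv_sample_pre/post (%)
    skipped: tuple[tuple[str, str, str], ...]  # (feature, batch, reason)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)

    def medians(self) -> dict[str, float]:
        return {c: float(self.per_feature[c].median()) for c in self.per_feature.columns}


def _cv_pct(values: np.ndarray) -> float:
    v = values[np.isfinite(values)]
    if len(v) < 2 or v.mean() == 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / v.mean())


def apply_correction(
    table: FeatureTable,
    fits: Sequence[DriftFit],
    options: DriftOptions = DriftOptions(),
) -> tuple[FeatureTable, CorrectionReport]:
    """Divide out the fitted drift curves and rescale to the reference level.

    corrected = raw * c / fitted(order), with c chosen per (feature, batch)
    so that the corrected SQC median equals the reference level exactly
    (the whole-run SQC median when ``options.align_batches``, else the
    batch's own).  Skipped (feature, batch) pairs pass through unchanged
    and are listed in the report; a fit whose curve is non-positive
    anywhere in the batch is skipped likewise.
    """
    fit_map = {(f.feature_id, f.batch_id): f for f in fits}
    corrected = table.intensities.to_numpy(dtype=float).copy()
    raw = table.intensities
    skipped: list[tuple[str, str, str]] = []

    qc_all = table.injection_ids(klass="SQC")
    global_median = raw[qc_all].median(axis=1)  # per feature, ignores NaN

    fid_pos = {fid: i for i, fid in enumerate(raw.index)}
    col_pos = {iid: j for j, iid in enumerate(raw.columns)}

    for batch in table.batches():
        batch_ids = table.injection_ids(batch_id=batch)
        orders = table.injections.loc[batch_ids, "order"].to_numpy(dtype=float)
        qc_ids = table.injection_ids(klass="SQC", batch_id=batch)
        cols = np.array([col_pos[i] for i in batch_ids])
        qc_cols = np.array([col_pos[i] for i in qc_ids])
        qc_orders = table.injections.loc[qc_ids, "order"].to_numpy(dtype=float)
        for fid in raw.index:
            fit = fit_map.get((fid, batch))
            i = fid_pos[fid]
            if fit is None or fit.skipped:
                skipped.append((fid, batch, fit.skip_reason if fit else "no fit provided"))
                continue
            factors = fit.predict(orders)
            if not np.all(np.isfinite(factors)) or np.any(factors <= 0):
                skipped.append((fid, batch, "fitted drift curve non-positive in batch"))
                continue
            target = float(global_median.loc[fid]) if options.align_batches else fit.reference_level
            qc_factors = fit.predict(qc_orders)
            qc_raw = raw.iloc[i, qc_cols].to_numpy(dtype=float)
            ratio_median = np.nanmedian(qc_raw / qc_factors)
            if not np.isfinite(ratio_median) or ratio_median <= 0 or not np.isfinite(target):
                skipped.append((fid, batch, "cannot anchor corrected QC median"))
                continue
            scale = target / ratio_median
            corrected[i, cols] = raw.iloc[i, cols].to_numpy(dtype=float) / factors * scale

    out = table.copy()
    out.intensities = pd.DataFrame(corrected, index=raw.index, columns=raw.columns)

    qc_idx = [col_pos[i] for i in table.injection_ids(klass="SQC")]
    smp_idx = [col_pos[i] for i in table.injection_ids(klass="sample")]
    pre = raw.to_numpy(dtype=float)
    rows = {
        "cv_qc_pre": [_cv_pct(pre[i, qc_idx]) for i in range(pre.shape[0])],
        "cv_qc_post": [_cv_pct(corrected[i, qc_idx]) for i in range(pre.shape[0])],
        "cv_sample_pre": [_cv_pct(pre[i, smp_idx]) for i in range(pre.shape[0])],
        "cv_sample_post": [_cv_pct(corrected[i, smp_idx]) for i in range(pre.shape[0])],
    }
    report = CorrectionReport(
        per_feature=pd.DataFrame(rows, index=raw.index),
        skipped=tuple(skipped),
    )
    return out, report


def correct_drift(
    table: FeatureTable, options: DriftOptions = DriftOptions()
) -> tuple[FeatureTable, CorrectionReport]:
    """Convenience: fit every (feature, batch) drift curve and apply it."""
    return apply_correction(table, fit_all(table, options), options)
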