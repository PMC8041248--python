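"""Synthetic inputs with the statistical structure the workflow assumes.

The generator emulates a multi-plate urinary LC-MS study so every stage of
the toolkit is testable without instrument data:

* each batch is a full 96-well plate (70 samples, 20 SQCs, 2 RQCs, 4
  blanks) injected in a QC-interspaced sequence;
* feature base intensities are log-normal (log10 SD 0.8 by default),
  spanning the instrument's quantitative range of roughly 1.5e3-3.5e6
  counts;
* pooled QCs share a single latent sample per feature, study samples add
  biological log-normal variation, blanks sit at a small fraction of the
  feature mean;
* a smooth multiplicative drift multiplies every injection.  The drift
  ``amplitude`` is defined as the RMS fractional deviation of the drift
  factor over a batch, so an amplitude of 0.20 contributes ~20
  percentage points to the pre-correction QC CV (a sinusoid therefore
  uses a peak deviation of amplitude * sqrt(2));
* injection noise is multiplicative log-normal scaled so its CV equals
  the requested fraction exactly;
* the technical-internal-standard panel is spiked at a constant level in
  every sample (no biological variation) and is drift-affected by
  default; a drift-free control panel is emitted alongside.

Everything is driven by one integer seed; identical specs give
bit-identical tables.  Ground truth (true drift curves, noise CV, latent
levels) is returned for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import FeatureRecord, FeatureTable, InjectionRecord
from .plates import build_layout, build_sequence
from .refractometry import CalibrationModel, CalibrationPoint

DRIFT_MODELS = ("none", "linear", "sinusoidal", "spline-random")


@dataclass(frozen=True)
class SimulationSpec:
    n_features: int = 200
    n_samples_per_batch: int = 70  # full plate
    n_batches: int = 1
    drift_model: str = "sinusoidal"
    drift_amplitude: float = 0.20  # RMS fractional deviation of the drift factor
    noise_cv: float = 0.03  # injection-to-injection CV
    bio_log10_sd: float = 0.25  # biological spread of study samples
    blank_level: float = 0.005  # blank signal as fraction of feature mean
    missing_rate: float = 0.0  # sample intensities set missing at random
    base_log10_mean: float = 4.6
    base_log10_sd: float = 0.8
    tis_panel: Sequence[str] = ("pyrantel", "CHES", "fluorocytosine", "PIPES", "HEPES")
    tis_drift_free: bool = False  # if True, the panel is exempt from drift
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("drift_amplitude", "noise_cv", "blank_level", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.drift_model not in DRIFT_MODELS:
            raise ValueError(f"unknown drift model {self.drift_model!r} (expected one of {DRIFT_MODELS})")
        if self.n_features < 1 or self.n_batches < 1:
            raise ValueError("n_features and n_batches must be >= 1")


@dataclass
class GroundTruth:
    spec: SimulationSpec
    base_level: np.ndarray  # latent QC-pool level per feature (incl. tIS rows)
    drift_factors: dict[str, np.ndarray]  # batch -> (n_all_features, n_injections)
    feature_ids: list[str]
    tis_ids: list[str]
    tis_control_ids: list[str]
    seed: int = 0


def _drift_curve(model: str, amplitude: float, u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative drift factor over batch position u in [0, 1].

    Curves are normalized so their RMS deviation from 1 equals
    ``amplitude`` (exactly for linear/sinusoidal, by construction for the
    random smooth curve).
    """
    if model == "none" or amplitude == 0:
        return np.ones_like(u)
    if model == "linear":
        # slope sign random; RMS of sqrt(12)*(u-1/2) over [0,1] is 1
        sign = rng.choice([-1.0, 1.0])
        return 1.0 + amplitude * math.sqrt(12.0) * sign * (u - 0.5)
    if model == "sinusoidal":
        phase = rng.uniform(0.0, 2.0 * math.pi)
        return 1.0 + amplitude * math.sqrt(2.0) * np.sin(2.0 * math.pi * u + phase)
    # spline-random: sum of the first three Fourier modes with random
    # coefficients, rescaled to the requested RMS deviation
    dev = np.zeros_like(u)
    for k in range(1, 4):
        a, b = rng.normal(size=2)
        dev += a * np.sin(2 * math.pi * k * u) + b * np.cos(2 * math.pi * k * u)
    rms = math.sqrt(float(np.mean(dev**2)))
    if rms == 0:
        return np.ones_like(u)
    return 1.0 + amplitude * dev / rms


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and CV exactly ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return np.exp(rng.normal(0.0, sigma, size)) / math.exp(sigma**2 / 2.0)


def simulate_feature_table(spec: SimulationSpec) -> tuple[FeatureTable, GroundTruth]:
    """Generate a drift-affected multi-batch feature table plus ground truth.

    Rows are ``spec.n_features`` anonymous features, then the tIS panel,
    then a drift-free tIS control panel (ids suffixed ``_nodrift``).
    """
    rng = np.random.default_rng(spec.seed)
    layout = build_layout(spec.n_samples_per_batch)
    sequence = build_sequence(layout)
    well_sample = {w.well: w.sample_id for w in layout.wells}

    injections: list[InjectionRecord] = []
    for b in range(spec.n_batches):
        batch_id = f"B{b + 1:02d}"
        for pos, well, klass in sequence.entries:
            injections.append(
                InjectionRecord(
                    injection_id=f"{batch_id}_{pos:03d}",
                    order=pos,
                    batch_id=batch_id,
                    klass=klass,
                    well=well,
                )
            )

    n_tis = len(spec.tis_panel)
    feature_ids = [f"F{i + 1:04d}" for i in range(spec.n_features)]
    tis_ids = [f"tIS_{name}" for name in spec.tis_panel]
    tis_control_ids = [f"tIS_{name}_nodrift" for name in spec.tis_panel]
    all_ids = feature_ids + tis_ids + tis_control_ids
    n_all = len(all_ids)

    features = [
        FeatureRecord(
            feature_id=fid,
            mz=float(rng.uniform(60.0, 1200.0)),
            rt=float(rng.uniform(0.5, 12.0)),
            annotation=fid if fid.startswith("tIS_") else None,
        )
        for fid in all_ids
    ]

    base = 10.0 ** rng.normal(spec.base_log10_mean, spec.base_log10_sd, n_all)
    # tIS spiked at mid-range constant concentration
    base[spec.n_features:] = 10.0 ** rng.normal(5.0, 0.1, 2 * n_tis)
    rqc_offset = np.exp(rng.normal(0.0, 0.1, n_all))  # RQC pool differs a little from SQC pool
    rqc_offset[spec.n_features:] = 1.0  # tIS identical everywhere

    n_inj = len(sequence.entries)
    orders = np.array([pos for pos, _, _ in sequence.entries], dtype=float)
    u = (orders - orders.min()) / (orders.max() - orders.min())
    klasses = np.array([klass for _, _, klass in sequence.entries])
    wells = [well for _, well, _ in sequence.entries]

    intensities = np.empty((n_all, n_inj * spec.n_batches))
    drift_truth: dict[str, np.ndarray] = {}
    # biological factor per (feature, study sample): shared across batches
    # of the same plate position? each batch has its own 70 samples.
    col = 0
    drift_free = np.zeros(n_all, dtype=bool)
    if spec.tis_drift_free:
        drift_free[spec.n_features : spec.n_features + n_tis] = True
    drift_free[spec.n_features + n_tis :] = True  # control panel always drift-free

    for b in range(spec.n_batches):
        batch_id = f"B{b + 1:02d}"
        factors = np.ones((n_all, n_inj))
        for i in range(n_all):
            if not drift_free[i]:
                factors[i] = _drift_curve(spec.drift_model, spec.drift_amplitude, u, rng)
        drift_truth[batch_id] = factors

        level = np.empty((n_all, n_inj))
        for j in range(n_inj):
            if klasses[j] == "SQC":
                level[:, j] = base
            elif klasses[j] == "RQC":
                level[:, j] = base * rqc_offset
            elif klasses[j] == "blank":
                level[:, j] = base * spec.blank_level
            else:  # sample: biological variation, none for tIS rows
                bio = np.exp(rng.normal(0.0, spec.bio_log10_sd * math.log(10.0), n_all))
                bio[spec.n_features:] = 1.0
                level[:, j] = base * bio
        noise = _lognormal_noise(rng, spec.noise_cv, (n_all, n_inj))
        block = level * factors * noise
        if spec.missing_rate > 0:
            smp_cols = np.flatnonzero(klasses == "sample")
            mask = rng.random((n_all, len(smp_cols))) < spec.missing_rate
            blk = block[:, smp_cols]
            blk[mask] = np.nan
            block[:, smp_cols] = blk
        intensities[:, col : col + n_inj] = block
        col += n_inj

    table = FeatureTable.from_records(features, injections, intensities)
    truth = GroundTruth(
        spec=spec,
        base_level=base,
        drift_factors=drift_truth,
        feature_ids=feature_ids,
        tis_ids=tis_ids,
        tis_control_ids=tis_control_ids,
        seed=spec.seed,
    )
    return table, truth


def simulate_rid_run(
    sg_values: Sequence[float],
    model: CalibrationModel,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> list[CalibrationPoint]:
    """RID peak areas for known SG values under a calibration model.

    areas = slope*(sg-1) + intercept, perturbed multiplicatively by
    ``noise_rel`` (relative Gaussian noise).
    """
    rng = np.random.default_rng(seed)
    points = []
    for sg in sg_values:
        area = model.sg_to_area(sg)
        if noise_rel > 0:
            area *= 1.0 + rng.normal(0.0, noise_rel)
        points.append(CalibrationPoint(sg_ref=float(sg), area=float(max(area, 0.0))))
    return points


def simulate_sg_cohort(
    n: int,
    median_excess: float = 0.012,
    log_sd: float = 0.7,
    seed: int = 0,
) -> list[float]:
    """Cohort of urinary SG values with a physiologically wide solute spread.

    SG - 1 is log-normal (median ``median_excess``, log-SD ``log_sd``);
    the defaults span well over the 15-fold solute range seen across
    hydration states.  Values are clipped to (1.000, 1.060].
    """
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    rng = np.random.default_rng(seed)
    excess = median_excess * np.exp(rng.normal(0.0, log_sd, n))
    sg = 1.0 + np.clip(excess, 1e-4, 0.060)
    return [float(v) for v in sg]
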