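"""MS2 spectral matching and annotation curation.

The spectral similarity used here is the unweighted dot product on a
0-1000 scale, as printed by common annotation software:

    score = 1000 * (sum_pairs Iq*Ir)^2 / (sum Iq^2 * sum Ir^2)

where the sum in the numerator runs over a one-to-one pairing of query and
reference peaks whose m/z values agree within ``mz_tol``.  Peaks are paired
by an optimal assignment that maximizes the matched intensity-product sum
(ties broken in favour of more matched pairs), so the score equals the
exhaustive maximum over all one-to-one pairings.  No m/z weighting and no
square-root intensity transform is applied ("without weighting"); a
weighted variant is available but off by default.

Curation applies the strict acceptance thresholds used for library
annotations: retention-time shift < 0.5 min, mass shift < 10 mDa, and for
spectral matches a score strictly above 700 with at least three matched
peaks (guarding against spuriously high scores from sparse spectra).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

LEVELS = ("AMRT-MS/MS", "AMRT", "AM")
DECISIONS = ("accept", "reject", "accept_with_comment")


class SpectrumError(ValueError):
    pass


@dataclass
class Spectrum:
    """A peak list (m/z ascending).  Intensities must be non-negative.

    Peaks closer than ``merge_tol`` (Da) are merged by summing intensities
    at their intensity-weighted mean m/z, so the stored m/z values are
    strictly increasing.
    """

    peaks: Sequence[tuple[float, float]]
    name: Optional[str] = None
    precursor_mz: Optional[float] = None
    merge_tol: float = 0.0

    mz: np.ndarray = field(init=False, repr=False)
    intensity: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.peaks, dtype=float)
        if arr.size == 0:
            raise SpectrumError(f"spectrum {self.name!r}: empty peak list")
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise SpectrumError(f"spectrum {self.name!r}: peaks must be (mz, intensity) pairs")
        if (arr[:, 1] < 0).any():
            raise SpectrumError(f"spectrum {self.name!r}: negative intensity")
        if not np.isfinite(arr).all():
            raise SpectrumError(f"spectrum {self.name!r}: non-finite peak values")
        order = np.argsort(arr[:, 0], kind="stable")
        arr = arr[order]
        if self.merge_tol > 0 or (np.diff(arr[:, 0]) == 0).any():
            arr = _merge_close(arr, self.merge_tol)
        self.mz = arr[:, 0]
        self.intensity = arr[:, 1]
        self.peaks = [tuple(p) for p in arr]

    def __len__(self) -> int:
        return len(self.mz)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(
            peaks=list(zip(self.mz, self.intensity * factor)),
            name=self.name,
            precursor_mz=self.precursor_mz,
        )


def _merge_close(arr: np.ndarray, tol: float) -> np.ndarray:
    out: list[list[float]] = []
    for m, i in arr:
        if out and m - out[-1][0] <= tol:
            tot = out[-1][1] + i
            if tot > 0:
                out[-1][0] = (out[-1][0] * out[-1][1] + m * i) / tot
            out[-1][1] = tot
        else:
            out.append([m, i])
    return np.asarray(out)


@dataclass(frozen=True)
class SpectralMatchResult:
    """Unweighted dot-product score on the 0-1000 scale and matched-peak count."""

    score: float
    n_matched: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1000.0 + 1e-9):
            raise ValueError(f"score {self.score} outside [0, 1000]")


def _pair_weights(query: Spectrum, ref: Spectrum, mz_tol: float, weighted: bool) -> np.ndarray:
    iq = query.intensity * (query.mz if weighted else 1.0)
    ir = ref.intensity * (ref.mz if weighted else 1.0)
    feasible = np.abs(query.mz[:, None] - ref.mz[None, :]) <= mz_tol
    w = np.where(feasible, iq[:, None] * ir[None, :], -1.0)
    return w


def dot_product(query: Spectrum, ref: Spectrum, mz_tol: float = 0.01, weighted: bool = False) -> SpectralMatchResult:
    """Score two spectra with the unweighted dot product (0-1000 scale).

    Peaks are paired one-to-one within ``mz_tol`` by an assignment that
    maximizes the matched intensity-product sum; among equal-sum pairings
    the one with more matched pairs is preferred.  ``weighted=True``
    applies m/z weighting (intensity * m/z) instead of raw intensities.
    """
    if mz_tol <= 0:
        raise ValueError(f"mz_tol must be > 0, got {mz_tol}")
    w = _pair_weights(query, ref, mz_tol, weighted)
    feasible = w >= 0
    if not feasible.any():
        return SpectralMatchResult(score=0.0, n_matched=0)
    # tiny per-pair bonus: prefers more matches among equal product sums
    scale = max(w.max(), 1.0)
    bonus = 1e-12 * scale
    benefit = np.where(feasible, w + bonus, 0.0)
    rows, cols = linear_sum_assignment(benefit, maximize=True)
    keep = feasible[rows, cols]
    rows, cols = rows[keep], cols[keep]

    iq = query.intensity * (query.mz if weighted else 1.0)
    ir = ref.intensity * (ref.mz if weighted else 1.0)
    num = float(np.sum(iq[rows] * ir[cols]))
    denom = float(np.sum(iq**2)) * float(np.sum(ir**2))
    score = 0.0 if denom == 0 else 1000.0 * num**2 / denom
    return SpectralMatchResult(score=min(score, 1000.0), n_matched=int(len(rows)))


@dataclass(frozen=True)
class CurationCriteria:
    """Strict annotation-acceptance thresholds."""

    rt_shift_max_min: float = 0.5
    mass_shift_max_mda: float = 10.0
    score_min: float = 700.0  # accepted only when strictly above
    n_matched_min: int = 3


@dataclass
class AnnotationRecord:
    """A candidate library annotation for one feature.

    ``rt_shift`` (minutes) and ``mass_shift`` (mDa) are absolute deviations
    from the library entry; ``match`` carries the spectral comparison when
    MS2 evidence exists.  ``level`` is the annotation confidence tier:
    AMRT-MS/MS (accurate mass + RT + spectral match), AMRT, or AM.
    """

    feature_id: str
    compound_id: str
    rt_shift: float
    mass_shift: float
    level: str = "AMRT-MS/MS"
    match: Optional[SpectralMatchResult] = None
    decision: Optional[str] = None
    comment: str = ""

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown annotation level {self.level!r} (expected one of {LEVELS})")
        if self.rt_shift < 0 or self.mass_shift < 0:
            raise ValueError("rt_shift and mass_shift are absolute values and must be >= 0")


def curate(
    record: AnnotationRecord,
    criteria: CurationCriteria = CurationCriteria(),
    override: bool = False,
    comment: str = "",
) -> str:
    """Apply the curation rules to one annotation record; returns the decision.

    Acceptance requires (per level): mass shift < 10 mDa; additionally RT
    shift < 0.5 min for AMRT and AMRT-MS/MS; additionally a spectral match
    with score > 700 and >= 3 matched peaks for AMRT-MS/MS.  ``override``
    marks an annotation that fails a criterion but was judged accurate; it
    requires a non-empty explanatory comment and yields
    ``accept_with_comment``.
    """
    if override:
        if not comment.strip():
            raise ValueError("manual override requires a non-empty explanatory comment")
        record.decision = "accept_with_comment"
        record.comment = comment
        return record.decision

    ok = record.mass_shift < criteria.mass_shift_max_mda
    if record.level in ("AMRT", "AMRT-MS/MS"):
        ok = ok and record.rt_shift < criteria.rt_shift_max_min
    if record.level == "AMRT-MS/MS":
        if record.match is None:
            raise ValueError(f"record {record.feature_id!r}: level AMRT-MS/MS requires a spectral match")
        ok = ok and record.match.score > criteria.score_min
        ok = ok and record.match.n_matched >= criteria.n_matched_min
    record.decision = "accept" if ok else "reject"
    return record.decision


def curate_all(
    records: Sequence[AnnotationRecord],
    criteria: CurationCriteria = CurationCriteria(),
) -> list[AnnotationRecord]:
    for rec in records:
        curate(rec, criteria)
    return list(records)
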