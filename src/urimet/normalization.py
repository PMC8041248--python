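"""Specific-gravity dilution planning: normalize urines to a common target SG.

Urinary solute concentration is proportional to SG - 1 (the linear solute
model), so diluting V_urine of a urine at SG_sample into a total volume
V_total of water yields

    SG_post = 1 + (SG_sample - 1) * V_urine / V_total

and the Levine-Fahys volume that lands exactly on a target SG is

    V_urine = V_total * (SG_target - 1) / (SG_sample - 1).

The default target SG of 1.002 is the lowest normal physiological value,
chosen so that essentially every urine is diluted rather than
concentrated; samples already at or below the target are used undiluted
and flagged.  Water volume is computed as total minus the *rounded* urine
volume so the dispensed total is exact on the pipetting grid.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

FLAG_OK = "ok"
FLAG_UNDILUTED = "undiluted_below_target"
FLAG_BELOW_MIN = "volume_below_min"


@dataclass(frozen=True)
class NormalizationParams:
    sg_target: float = 1.002
    total_volume: float = 340.0  # uL
    min_pipette: float = 1.0  # uL
    volume_digits: int = 1  # 0.1 uL pipetting grid

    def __post_init__(self) -> None:
        if self.sg_target <= 1.0:
            raise ValueError(f"sg_target must be > 1.000, got {self.sg_target}")
        if self.total_volume <= 0:
            raise ValueError(f"total_volume must be > 0, got {self.total_volume}")


def dilution_volumes(sg_sample: float, params: NormalizationParams = NormalizationParams()) -> tuple[float, float, str]:
    """Urine and water volumes (uL) normalizing one sample to the target SG.

    Returns ``(urine, water, flag)``.  Samples at the target get the full
    volume of urine and no water (flag ``ok``); below the target they are
    used undiluted and flagged; an ok-row urine volume below
    ``min_pipette`` is flagged ``volume_below_min`` for review.
    """
    if sg_sample <= 1.0:
        raise ValueError(f"sg_sample must be > 1.000, got {sg_sample} (non-physical)")
    total = params.total_volume
    if sg_sample < params.sg_target:
        return total, 0.0, FLAG_UNDILUTED
    urine = total * (params.sg_target - 1.0) / (sg_sample - 1.0)
    urine = round(urine, params.volume_digits)
    water = round(total - urine, params.volume_digits)
    if sg_sample == params.sg_target:
        return total, 0.0, FLAG_OK
    if urine < params.min_pipette:
        return urine, water, FLAG_BELOW_MIN
    return urine, water, FLAG_OK


@dataclass(frozen=True)
class PlanRow:
    well: str
    sample_id: str
    sg_sample: float
    urine_volume: float
    water_volume: float
    flag: str


@dataclass(frozen=True)
class DilutionPlan:
    rows: tuple[PlanRow, ...]
    params: NormalizationParams

    @property
    def flag_counts(self) -> dict[str, int]:
        return dict(Counter(r.flag for r in self.rows))

    def to_csv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        """Export as a liquid-handler worklist: well,sample_id,urine_uL,water_uL,flag."""
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("well,sample_id,urine_uL,water_uL,flag\n")
            for r in self.rows:
                fh.write(f"{r.well},{r.sample_id},{r.urine_volume},{r.water_volume},{r.flag}\n")


def plan_plate(
    sg_map: Mapping[str, tuple[str, float]],
    params: NormalizationParams = NormalizationParams(),
) -> DilutionPlan:
    """Dilution plan for a plate: well -> (sample_id, sg_sample)."""
    wells = list(sg_map)
    if len(set(wells)) != len(wells):
        dup = [w for w, c in Counter(wells).items() if c > 1]
        raise ValueError(f"duplicate wells: {dup}")
    rows = []
    for well, (sample_id, sg) in sg_map.items():
        urine, water, flag = dilution_volumes(sg, params)
        rows.append(PlanRow(well, sample_id, sg, urine, water, flag))
    return DilutionPlan(rows=tuple(rows), params=params)


def predicted_sg(sg_sample: float, urine_volume: float, total_volume: float) -> float:
    """Post-dilution SG under the linear solute model."""
    return 1.0 + (sg_sample - 1.0) * urine_volume / total_volume


def dilute_sg(sg_stock: float, factor: float) -> float:
    """SG of a stock diluted ``factor``-fold in water (linear solute model)."""
    if factor < 1:
        raise ValueError(f"dilution factor must be >= 1, got {factor}")
    return 1.0 + (sg_stock - 1.0) / factor
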