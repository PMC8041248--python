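"""96-well batch layouts and QC-embedded injection sequences.

An analytical batch is a 96-well plate carrying 70 study samples, 20
pooled study QCs (SQC), 2 laboratory reference QCs (RQC) and 4 blanks.
The injection sequence interleaves pooled QCs so that no more than five
study samples ever run back to back: a configurable block of conditioning
SQC injections opens the run, an SQC follows every fifth sample, the RQCs
sit mid-sequence, and blank pairs bracket the run.  Every assigned well
is injected exactly once.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

FULL_PLATE_COUNTS = {"sample": 70, "SQC": 20, "RQC": 2, "blank": 4}
ROWS = "ABCDEFGH"
WELLS_96 = [f"{r}{c}" for r in ROWS for c in range(1, 13)]  # row-major A1..H12


@dataclass(frozen=True)
class WellAssignment:
    well: str
    klass: str  # sample | SQC | RQC | blank | empty
    sample_id: str | None = None


@dataclass(frozen=True)
class PlateLayout:
    wells: tuple[WellAssignment, ...]

    def __post_init__(self) -> None:
        if len(self.wells) != 96:
            raise ValueError(f"a plate layout must assign all 96 wells, got {len(self.wells)}")
        names = [w.well for w in self.wells]
        if len(set(names)) != 96:
            raise ValueError("duplicate well names in layout")
        counts = self.counts
        for klass in ("SQC", "RQC", "blank"):
            if counts.get(klass, 0) != FULL_PLATE_COUNTS[klass]:
                raise ValueError(
                    f"layout must carry the full QC complement "
                    f"({FULL_PLATE_COUNTS[klass]} {klass}), got {counts.get(klass, 0)}"
                )

    @property
    def counts(self) -> dict[str, int]:
        return dict(Counter(w.klass for w in self.wells))

    def wells_of(self, klass: str) -> list[WellAssignment]:
        return [w for w in self.wells if w.klass == klass]

    def to_csv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("well,klass,sample_id\n")
            for w in self.wells:
                fh.write(f"{w.well},{w.klass},{w.sample_id or ''}\n")


@dataclass(frozen=True)
class InjectionSequence:
    entries: tuple[tuple[int, str, str], ...]  # (position, well, klass)

    def max_consecutive_samples(self) -> int:
        longest = run = 0
        for _, _, klass in self.entries:
            run = run + 1 if klass == "sample" else 0
            longest = max(longest, run)
        return longest

    def to_csv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("position,well,klass\n")
            for pos, well, klass in self.entries:
                fh.write(f"{pos},{well},{klass}\n")


def build_layout(n_samples: int) -> PlateLayout:
    """Assign a 96-well plate: n_samples sample wells plus the fixed QC set.

    Blanks occupy the plate corners (A1, A2, H11, H12), RQCs the plate
    centre (D6, E6), SQC wells are spread evenly over the remaining
    positions, and samples fill the rest row-major; unused sample wells
    are marked ``empty``.
    """
    if not (1 <= n_samples <= FULL_PLATE_COUNTS["sample"]):
        raise ValueError(f"n_samples must be in 1..{FULL_PLATE_COUNTS['sample']}, got {n_samples}")
    blanks = ["A1", "A2", "H11", "H12"]
    rqcs = ["D6", "E6"]
    rest = [w for w in WELLS_96 if w not in blanks + rqcs]
    # 20 SQC wells spread evenly across the remaining 90 positions
    sqc_wells = {rest[round(i * (len(rest) - 1) / 19)] for i in range(20)}
    assert len(sqc_wells) == 20
    assignments: list[WellAssignment] = []
    sample_no = 0
    for well in WELLS_96:
        if well in blanks:
            assignments.append(WellAssignment(well, "blank"))
        elif well in rqcs:
            assignments.append(WellAssignment(well, "RQC"))
        elif well in sqc_wells:
            assignments.append(WellAssignment(well, "SQC"))
        elif sample_no < n_samples:
            sample_no += 1
            assignments.append(WellAssignment(well, "sample", f"S{sample_no:03d}"))
        else:
            assignments.append(WellAssignment(well, "empty"))
    return PlateLayout(wells=tuple(assignments))


def build_sequence(
    layout: PlateLayout,
    n_conditioning: int = 5,
    samples_per_block: int = 5,
) -> InjectionSequence:
    """Injection order for one plate, pooled QCs after every sample block.

    Structure: leading blank pair, ``n_conditioning`` SQC conditioning
    injections, then blocks of at most ``samples_per_block`` samples each
    followed by an SQC (while SQC wells remain), RQCs at the middle of the
    sample blocks, leftover SQCs before the trailing blank pair.
    """
    sqcs = [w.well for w in layout.wells_of("SQC")]
    if not sqcs:
        raise ValueError("layout has no SQC wells")
    if n_conditioning >= len(sqcs):
        raise ValueError(f"n_conditioning {n_conditioning} leaves no SQCs for interspacing")
    samples = [w.well for w in layout.wells_of("sample")]
    rqcs = [w.well for w in layout.wells_of("RQC")]
    blanks = [w.well for w in layout.wells_of("blank")]
    lead_blanks, tail_blanks = blanks[: len(blanks) // 2], blanks[len(blanks) // 2 :]

    seq: list[tuple[str, str]] = [(w, "blank") for w in lead_blanks]
    sqc_iter = iter(sqcs)
    for _ in range(n_conditioning):
        seq.append((next(sqc_iter), "SQC"))

    blocks = [samples[i : i + samples_per_block] for i in range(0, len(samples), samples_per_block)]
    mid = len(blocks) // 2
    remaining_sqcs = list(sqc_iter)
    for b, block in enumerate(blocks):
        if b == mid:
            seq += [(w, "RQC") for w in rqcs]
        seq += [(w, "sample") for w in block]
        if remaining_sqcs:
            seq.append((remaining_sqcs.pop(0), "SQC"))
    if not blocks:
        seq += [(w, "RQC") for w in rqcs]
    seq += [(w, "SQC") for w in remaining_sqcs]
    seq += [(w, "blank") for w in tail_blanks]

    return InjectionSequence(entries=tuple((i + 1, well, klass) for i, (well, klass) in enumerate(seq)))
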