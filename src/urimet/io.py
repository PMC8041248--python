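"""Tabular and spectral I/O with validation into the workflow's domain types.

Feature tables follow the layout of peak-picking exports (MS-DIAL / MZmine
style): leading columns ``feature_id``, ``mz``, ``rt`` (optionally
``annotation``), then one intensity column per injection.  Injection
metadata (acquisition order, batch, class, well) always comes from a
separate metadata table — never from column order, which is not
trustworthy after manual edits.

Missing intensities are accepted as empty cells, ``NA`` or ``NaN`` on
input and written back as empty cells; internally they are ``numpy.nan``,
kept distinct from true zeros.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .annotation import Spectrum

#: closed vocabulary of injection classes
KLASSES = ("sample", "SQC", "RQC", "blank")

_MISSING_TOKENS = {"", "na", "nan", "n/a"}


class ValidationError(ValueError):
    """Raised when an input table violates a domain-type invariant."""


@dataclass(frozen=True)
class InjectionRecord:
    """One injection in the acquisition sequence."""

    injection_id: str
    order: int
    batch_id: str
    klass: str
    well: str | None = None

    def __post_init__(self) -> None:
        if self.klass not in KLASSES:
            raise ValidationError(
                f"injection {self.injection_id!r}: unknown class {self.klass!r} "
                f"(expected one of {KLASSES})"
            )
        if self.order < 1:
            raise ValidationError(
                f"injection {self.injection_id!r}: order must be a positive integer, got {self.order}"
            )


@dataclass(frozen=True)
class FeatureRecord:
    """An LC-MS feature: an (m/z, retention time) pair."""

    feature_id: str
    mz: float
    rt: float
    annotation: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.mz) or self.mz <= 0:
            raise ValidationError(f"feature {self.feature_id!r}: m/z must be finite and > 0, got {self.mz}")
        if not np.isfinite(self.rt) or self.rt < 0:
            raise ValidationError(f"feature {self.feature_id!r}: rt must be finite and >= 0, got {self.rt}")


@dataclass
class FeatureTable:
    """Feature x injection intensity matrix plus injection metadata.

    ``intensities`` is a float DataFrame indexed by ``feature_id`` with one
    column per ``injection_id`` (NaN = missing).  ``features`` and
    ``injections`` are metadata DataFrames indexed by the same ids;
    injections are kept sorted by (batch_id, order).
    """

    features: pd.DataFrame
    injections: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        features: Sequence[FeatureRecord],
        injections: Sequence[InjectionRecord],
        intensities: np.ndarray,
    ) -> "FeatureTable":
        intensities = np.asarray(intensities, dtype=float)
        if intensities.shape != (len(features), len(injections)):
            raise ValidationError(
                f"intensity matrix shape {intensities.shape} does not match "
                f"{len(features)} features x {len(injections)} injections"
            )
        fdf = pd.DataFrame(
            {
                "mz": [f.mz for f in features],
                "rt": [f.rt for f in features],
                "annotation": [f.annotation for f in features],
            },
            index=pd.Index([f.feature_id for f in features], name="feature_id"),
        )
        idf = pd.DataFrame(
            {
                "order": [i.order for i in injections],
                "batch_id": [i.batch_id for i in injections],
                "klass": [i.klass for i in injections],
                "well": [i.well for i in injections],
            },
            index=pd.Index([i.injection_id for i in injections], name="injection_id"),
        )
        mat = pd.DataFrame(np.asarray(intensities, dtype=float), index=fdf.index, columns=idf.index)
        return cls(fdf, idf, mat)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        fid = self.features.index
        iid = self.injections.index
        if fid.has_duplicates:
            dup = fid[fid.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dup}")
        if iid.has_duplicates:
            dup = iid[iid.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate injection ids: {dup}")
        if self.intensities.shape != (len(fid), len(iid)):
            raise ValidationError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{len(fid)} features x {len(iid)} injections"
            )
        missing_cols = [c for c in iid if c not in self.intensities.columns]
        if missing_cols:
            raise ValidationError(f"injections missing from the intensity matrix: {missing_cols}")
        missing_rows = [r for r in fid if r not in self.intensities.index]
        if missing_rows:
            raise ValidationError(f"features missing from the intensity matrix: {missing_rows}")
        bad_klass = sorted(set(self.injections["klass"]) - set(KLASSES))
        if bad_klass:
            raise ValidationError(f"unknown injection classes {bad_klass} (expected one of {KLASSES})")
        orders = self.injections["order"]
        if (orders < 1).any():
            bad = self.injections.index[orders < 1].tolist()
            raise ValidationError(f"non-positive injection order for: {bad}")
        for batch, grp in self.injections.groupby("batch_id"):
            if grp["order"].duplicated().any():
                dup = grp.loc[grp["order"].duplicated(), "order"].tolist()
                raise ValidationError(f"batch {batch!r}: duplicate injection orders {dup}")
        neg = self.intensities.lt(0)
        if neg.any().any():
            r = self.intensities.index[neg.any(axis=1)][0]
            c = self.intensities.columns[neg.any(axis=0)][0]
            raise ValidationError(f"negative intensity at feature {r!r}, injection {c!r}")
        # canonical ordering: (batch, order), matrix columns follow
        self.injections = self.injections.sort_values(["batch_id", "order"], kind="stable")
        self.intensities = self.intensities.loc[fid, self.injections.index]

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def injection_ids(self, klass: str | None = None, batch_id: str | None = None) -> pd.Index:
        sel = pd.Series(True, index=self.injections.index)
        if klass is not None:
            sel &= self.injections["klass"] == klass
        if batch_id is not None:
            sel &= self.injections["batch_id"] == batch_id
        return self.injections.index[sel]

    def batches(self) -> list[str]:
        return sorted(self.injections["batch_id"].unique())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.injections.copy(), self.intensities.copy())


# ---------------------------------------------------------------------------
# delimited-table helpers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path, override: str | None) -> str:
    if override is not None:
        return override
    with open(path, "r", newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if line.count("\t") >= line.count(",") else ","
    return ","


def _read_delim(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_sep(path, sep)
    return pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)


def _parse_intensity(token: str, where: str) -> float:
    if token.strip().lower() in _MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ValidationError(f"non-numeric intensity {token!r} at {where}") from None


def read_feature_table(
    path: str | Path,
    metadata_path: str | Path,
    sep: str | None = None,
) -> FeatureTable:
    """Read a peak-picking export plus its injection metadata table.

    The export must start with ``feature_id``, ``mz``, ``rt`` (and an
    optional ``annotation``) columns; every remaining column is matched
    against the ``injection_id`` column of the metadata file.  The
    delimiter is sniffed (tab vs comma) unless ``sep`` is given.
    """
    raw = _read_delim(path, sep)
    meta = _read_delim(metadata_path, sep)

    for col in ("feature_id", "mz", "rt"):
        if col not in raw.columns:
            raise ValidationError(f"feature table {path}: missing required column {col!r}")
    for col in ("injection_id", "order", "batch_id", "klass"):
        if col not in meta.columns:
            raise ValidationError(f"metadata table {metadata_path}: missing required column {col!r}")

    lead = ["feature_id", "mz", "rt"] + (["annotation"] if "annotation" in raw.columns else [])
    inj_cols = [c for c in raw.columns if c not in lead]

    meta_ids = meta["injection_id"].tolist()
    absent = [i for i in meta_ids if i not in inj_cols]
    if absent:
        raise ValidationError(f"metadata lists injections absent from the intensity matrix: {absent}")
    extra = [c for c in inj_cols if c not in set(meta_ids)]
    if extra:
        raise ValidationError(f"intensity columns without metadata: {extra}")

    features = [
        FeatureRecord(
            feature_id=row["feature_id"],
            mz=float(row["mz"]),
            rt=float(row["rt"]),
            annotation=(row.get("annotation") or None) if "annotation" in raw.columns else None,
        )
        for _, row in raw.iterrows()
    ]
    injections = [
        InjectionRecord(
            injection_id=row["injection_id"],
            order=int(row["order"]),
            batch_id=row["batch_id"],
            klass=row["klass"],
            well=(row.get("well") or None) if "well" in meta.columns else None,
        )
        for _, row in meta.iterrows()
    ]
    mat = np.empty((len(features), len(meta_ids)), dtype=float)
    for j, iid in enumerate(meta_ids):
        col = raw[iid]
        for i, token in enumerate(col):
            mat[i, j] = _parse_intensity(token, f"feature {features[i].feature_id!r}, injection {iid!r}")
    return FeatureTable.from_records(features, injections, mat)


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    metadata_path: str | Path,
    sep: str = "\t",
    header_lines: Iterable[str] = (),
) -> None:
    """Write a feature table and its metadata in the dialect the reader consumes.

    Intensities are written with ``repr``-level precision so a write/read
    round trip is bit-exact; missing values become empty cells.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter=sep)
        has_ann = table.features["annotation"].notna().any()
        lead = ["feature_id", "mz", "rt"] + (["annotation"] if has_ann else [])
        w.writerow(lead + list(table.intensities.columns))
        for fid, meta in table.features.iterrows():
            row = [fid, repr(float(meta["mz"])), repr(float(meta["rt"]))]
            if has_ann:
                row.append(meta["annotation"] if pd.notna(meta["annotation"]) else "")
            vals = table.intensities.loc[fid]
            row += ["" if pd.isna(v) else repr(float(v)) for v in vals]
            w.writerow(row)
    with open(metadata_path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["injection_id", "order", "batch_id", "klass", "well"])
        for iid, meta in table.injections.iterrows():
            w.writerow([iid, int(meta["order"]), meta["batch_id"], meta["klass"], meta["well"] or ""])


# ---------------------------------------------------------------------------
# plate maps and RID exports
# ---------------------------------------------------------------------------

def read_plate_map(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Plate map CSV: columns well, sample_id, klass."""
    df = _read_delim(path, sep)
    for col in ("well", "sample_id", "klass"):
        if col not in df.columns:
            raise ValidationError(f"plate map {path}: missing required column {col!r}")
    if df["well"].duplicated().any():
        dup = df.loc[df["well"].duplicated(), "well"].tolist()
        raise ValidationError(f"plate map {path}: duplicate wells {dup}")
    return df


def read_rid_export(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """RID export CSV: columns sample_id, area_nRIU (peak areas in nRIU)."""
    df = _read_delim(path, sep)
    for col in ("sample_id", "area_nRIU"):
        if col not in df.columns:
            raise ValidationError(f"RID export {path}: missing required column {col!r}")
    out = df[["sample_id"]].copy()
    out["area_nRIU"] = pd.to_numeric(df["area_nRIU"], errors="raise")
    if (out["area_nRIU"] < 0).any():
        bad = out.loc[out["area_nRIU"] < 0, "sample_id"].tolist()
        raise ValidationError(f"RID export {path}: negative peak area for {bad}")
    return out


# ---------------------------------------------------------------------------
# spectra: MSP and MGF
# ---------------------------------------------------------------------------

def read_spectra(path: str | Path, fmt: str | None = None) -> list[Spectrum]:
    """Read MSP- or MGF-style peak lists into :class:`Spectrum` objects.

    Peak lists are sorted m/z-ascending on construction; an empty spectrum
    raises.  The format is taken from the extension unless ``fmt`` is given.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "msp":
        return _read_msp(path)
    if fmt == "mgf":
        return _read_mgf(path)
    raise ValidationError(f"unsupported spectrum format {fmt!r} (expected msp or mgf)")


def write_spectra(spectra: Sequence[Spectrum], path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "msp":
        _write_msp(spectra, path)
    elif fmt == "mgf":
        _write_mgf(spectra, path)
    else:
        raise ValidationError(f"unsupported spectrum format {fmt!r} (expected msp or mgf)")


def _read_msp(path: Path) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    name: str | None = None
    precursor: float | None = None
    peaks: list[tuple[float, float]] = []
    n_expected: int | None = None

    def flush() -> None:
        nonlocal name, precursor, peaks, n_expected
        if name is None and not peaks:
            return
        if n_expected is not None and n_expected != len(peaks):
            raise ValidationError(
                f"{path}: spectrum {name!r} declares {n_expected} peaks but lists {len(peaks)}"
            )
        spectra.append(Spectrum(peaks=peaks, name=name, precursor_mz=precursor))
        name, precursor, peaks, n_expected = None, None, [], None

    with open(path) as fh:
        for raw_line in fh:
            line = raw_line.strip()
            if not line:
                flush()
                continue
            if ":" in line and not line[0].isdigit():
                key, _, val = line.partition(":")
                key = key.strip().lower()
                val = val.strip()
                if key == "name":
                    name = val
                elif key in ("precursormz", "precursor_mz"):
                    precursor = float(val)
                elif key == "num peaks":
                    n_expected = int(val)
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValidationError(f"{path}: malformed peak line {line!r}")
            peaks.append((float(parts[0]), float(parts[1])))
    flush()
    if not spectra:
        raise ValidationError(f"{path}: no spectra found")
    return spectra


def _write_msp(spectra: Sequence[Spectrum], path: Path) -> None:
    with open(path, "w") as fh:
        for k, sp in enumerate(spectra):
            fh.write(f"Name: {sp.name or f'spectrum_{k}'}\n")
            if sp.precursor_mz is not None:
                fh.write(f"PrecursorMZ: {float(sp.precursor_mz)!r}\n")
            fh.write(f"Num Peaks: {len(sp.mz)}\n")
            for m, i in zip(sp.mz, sp.intensity):
                fh.write(f"{float(m)!r} {float(i)!r}\n")
            fh.write("\n")


def _read_mgf(path: Path) -> list[Spectrum]:
    spectra = []
    with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
        for entry in reader:
            mz = np.asarray(entry["m/z array"], dtype=float)
            inten = np.asarray(entry["intensity array"], dtype=float)
            params = entry.get("params", {})
            pep = params.get("pepmass")
            precursor = float(pep[0]) if pep is not None else None
            spectra.append(
                Spectrum(
                    peaks=list(zip(mz, inten)),
                    name=params.get("title"),
                    precursor_mz=precursor,
                )
            )
    if not spectra:
        raise ValidationError(f"{path}: no spectra found")
    return spectra


def _write_mgf(spectra: Sequence[Spectrum], path: Path) -> None:
    entries = []
    for k, sp in enumerate(spectra):
        params: dict = {"title": sp.name or f"spectrum_{k}"}
        if sp.precursor_mz is not None:
            params["pepmass"] = sp.precursor_mz
        entries.append(
            {
                "m/z array": np.asarray(sp.mz),
                "intensity array": np.asarray(sp.intensity),
                "params": params,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")
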