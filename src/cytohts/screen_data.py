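"""Domain types and CSV I/O for 384-well screening datasets.

A screen is represented by three long-format tables held in a
:class:`ScreenDataset`:

* ``annotations`` — one row per (plate, well): role, compound, dose, cell line;
* ``imaging`` — one row per (plate, well, field, timepoint): live-stain
  (cell tracker) and dead-stain (DRAQ7) object counts;
* ``luminescence`` — optional, one row per (plate, well): CellTiter-Glo RLU.

Object counts are inputs; image segmentation happens upstream on the
instrument.  Concentrations are stored in nM throughout.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

ROLES = ("library", "vehicle", "positive_control", "empty")
DEFAULT_TIMEPOINTS = (0.0, 24.0, 48.0, 72.0)

ANNOTATION_COLUMNS = ["plate_id", "well", "role", "compound_id",
                      "concentration_nM", "cell_line"]
IMAGING_COLUMNS = ["plate_id", "well", "field", "timepoint_h",
                   "tracker_count", "draq7_count"]
LUMINESCENCE_COLUMNS = ["plate_id", "well", "rlu"]

_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


class ScreenDataError(ValueError):
    """Raised on malformed or inconsistent screen data."""


@dataclass(frozen=True, order=True)
class WellAddress:
    """A well in 384-well geometry: rows A–P, columns 1–24.

    The canonical string form is unpadded (``A1`` .. ``P24``); zero-padded
    dialects (``A01``) are accepted by :meth:`parse` and normalized.
    """

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in "ABCDEFGHIJKLMNOP" or len(self.row) != 1:
            raise ScreenDataError(f"row {self.row!r} outside A-P")
        if not 1 <= self.column <= 24:
            raise ScreenDataError(f"column {self.column} outside 1-24")

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        m = _WELL_RE.match(str(text).strip())
        if not m:
            raise ScreenDataError(f"malformed well address {text!r}")
        return cls(m.group(1).upper(), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.column}"


@dataclass
class ScreenDataset:
    """Annotated measurements of one or more screening plates.

    Invariants (enforced by :func:`validate_dataset` and on assembly):
    every measurement references an annotated (plate_id, well), and imaging
    records are unique per (plate_id, well, field, timepoint).
    """

    annotations: pd.DataFrame
    imaging: pd.DataFrame
    luminescence: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def annotated_wells(self) -> set[tuple[str, str]]:
        return set(zip(self.annotations.plate_id, self.annotations.well))

    def write(self, directory: str | Path) -> None:
        """Write plate map, measurement and luminescence CSVs plus a JSON
        metadata sidecar into *directory*."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.annotations.to_csv(d / "plate_map.csv", index=False)
        self.imaging.to_csv(d / "imaging.csv", index=False)
        if self.luminescence is not None:
            self.luminescence.to_csv(d / "luminescence.csv", index=False)
        (d / "metadata.json").write_text(json.dumps(self.metadata, indent=2,
                                                   default=str))

    @classmethod
    def read(cls, directory: str | Path, strict: bool = True,
             timepoints: Iterable[float] = DEFAULT_TIMEPOINTS) -> "ScreenDataset":
        d = Path(directory)
        lum = None
        if (d / "luminescence.csv").exists():
            lum = read_luminescence(d / "luminescence.csv")
        meta = {}
        if (d / "metadata.json").exists():
            meta = json.loads((d / "metadata.json").read_text())
        ds = cls(
            annotations=read_plate_map(d / "plate_map.csv"),
            imaging=read_measurements(d / "imaging.csv", strict=strict,
                                      timepoints=timepoints),
            luminescence=lum,
            metadata=meta,
        )
        _check_references(ds)
        return ds


def _normalize_wells(series: pd.Series) -> pd.Series:
    return series.map(lambda w: str(WellAddress.parse(w)))


def read_plate_map(path: str | Path) -> pd.DataFrame:
    """Read a plate-map CSV into an annotation table.

    Expected header: ``plate_id, well, role, compound_id, concentration_nM,
    cell_line``.  Roles are validated; well addresses normalized to the
    canonical unpadded form; concentrations parsed as nM.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "role": str,
                                  "compound_id": str, "cell_line": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ScreenDataError(f"plate map missing columns {sorted(missing)}")
    df = df[ANNOTATION_COLUMNS].copy()
    bad_roles = set(df.role) - set(ROLES)
    if bad_roles:
        raise ScreenDataError(f"unknown role token(s) {sorted(bad_roles)}")
    df["well"] = _normalize_wells(df.well)
    df["concentration_nM"] = pd.to_numeric(df.concentration_nM, errors="raise")
    dup = df.duplicated(["plate_id", "well"])
    if dup.any():
        raise ScreenDataError(
            f"duplicate (plate_id, well) annotations: "
            f"{df.loc[dup, ['plate_id', 'well']].values.tolist()}")
    lib = df.role == "library"
    if (lib & (df.compound_id.isna() | ~(df.concentration_nM > 0))).any():
        raise ScreenDataError(
            "library wells require compound_id and concentration_nM > 0")
    if (df.role.isin(["vehicle", "empty"]) & df.compound_id.notna()).any():
        raise ScreenDataError("vehicle/empty wells must not carry a compound_id")
    return df


def read_measurements(path: str | Path, strict: bool = True,
                      timepoints: Iterable[float] = DEFAULT_TIMEPOINTS,
                      ) -> pd.DataFrame:
    """Read a long-format imaging CSV (one row per plate/well/field/timepoint).

    With ``strict=True`` (default) a timepoint outside the configured
    schedule is an error; otherwise it only produces a warning column in the
    validation report later.  Counts must be non-negative integers.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str})
    missing = set(IMAGING_COLUMNS) - set(df.columns)
    if missing:
        raise ScreenDataError(f"measurement CSV missing columns {sorted(missing)}")
    df = df[IMAGING_COLUMNS].copy()
    df["well"] = _normalize_wells(df.well)
    for col in ("tracker_count", "draq7_count"):
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals < 0).any():
            raise ScreenDataError(f"negative counts in {col}")
        if not (vals == vals.round()).all():
            raise ScreenDataError(f"non-integer counts in {col}")
        df[col] = vals.astype(int)
    df["field"] = df.field.astype(int)
    df["timepoint_h"] = pd.to_numeric(df.timepoint_h, errors="raise").astype(float)
    schedule = set(float(t) for t in timepoints)
    off = ~df.timepoint_h.isin(schedule)
    if off.any() and strict:
        raise ScreenDataError(
            f"timepoints outside schedule {sorted(schedule)}: "
            f"{sorted(df.loc[off, 'timepoint_h'].unique().tolist())}")
    dup = df.duplicated(["plate_id", "well", "field", "timepoint_h"])
    if dup.any():
        raise ScreenDataError(
            "duplicate (plate_id, well, field, timepoint) imaging records")
    return df


def read_luminescence(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str})
    missing = set(LUMINESCENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ScreenDataError(f"luminescence CSV missing columns {sorted(missing)}")
    df = df[LUMINESCENCE_COLUMNS].copy()
    df["well"] = _normalize_wells(df.well)
    df["rlu"] = pd.to_numeric(df.rlu, errors="raise")
    if (df.rlu < 0).any():
        raise ScreenDataError("negative RLU values")
    if df.duplicated(["plate_id", "well"]).any():
        raise ScreenDataError("duplicate (plate_id, well) luminescence records")
    return df


def _check_references(ds: ScreenDataset) -> None:
    wells = ds.annotated_wells()
    for name, table in (("imaging", ds.imaging),
                        ("luminescence", ds.luminescence)):
        if table is None:
            continue
        orphan = [t for t in zip(table.plate_id, table.well) if t not in wells]
        if orphan:
            raise ScreenDataError(
                f"{name} measurements reference unannotated wells: "
                f"{sorted(set(orphan))[:5]}")


def validate_dataset(ds: ScreenDataset,
                     timepoints: Iterable[float] = DEFAULT_TIMEPOINTS,
                     ) -> pd.DataFrame:
    """Produce a QC report; never raises on syntactically valid input.

    Issue classes: ``orphan_measurement`` (measurement without annotation),
    ``incomplete_series`` (well missing scheduled timepoints),
    ``zero_tracker`` (pooled live-stain count of zero at some timepoint,
    which would make the death fraction undefined).
    """
    issues: list[dict] = []
    wells = ds.annotated_wells()
    for name, table in (("imaging", ds.imaging),
                        ("luminescence", ds.luminescence)):
        if table is None:
            continue
        for plate, well in sorted({t for t in zip(table.plate_id, table.well)
                                   if t not in wells}):
            issues.append({"issue": "orphan_measurement", "plate_id": plate,
                           "well": well, "detail": name})
    schedule = sorted(float(t) for t in timepoints)
    pooled = (ds.imaging.groupby(["plate_id", "well", "timepoint_h"],
                                 as_index=False)
              .agg(tracker=("tracker_count", "sum")))
    for (plate, well), grp in pooled.groupby(["plate_id", "well"]):
        present = set(grp.timepoint_h)
        missing = [t for t in schedule if t not in present]
        if missing:
            issues.append({"issue": "incomplete_series", "plate_id": plate,
                           "well": well, "detail": f"missing t={missing}"})
        for _, r in grp[grp.tracker == 0].iterrows():
            issues.append({"issue": "zero_tracker", "plate_id": plate,
                           "well": well, "detail": f"t={r.timepoint_h}"})
    return pd.DataFrame(issues, columns=["issue", "plate_id", "well", "detail"])
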