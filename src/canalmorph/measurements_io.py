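"""Data model and CSV I/O for semicircular-canal measurement tables.

Three table layouts are supported, mirroring how such data are published:

* ``diameters`` — one row per specimen with major/minor axis diameters of the
  anterior, posterior and horizontal canals (mm) plus log10 body mass (grams)
  and a flag marking masses that were themselves regression estimates.
* ``lumen`` — replicated lumen-diameter panels (mm), five repeats per canal.
* ``angles`` — replicated inter-canal angle panels (degrees), five repeats per
  angle pair.

The packaged fixtures (``fixture("table1")`` etc.) hold the published
*Endothiodon* cf. *bathystoma* / extant-mammal measurement tables so every
downstream statistic can be recomputed without downloads.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from .exceptions import SchemaError, ValidationError

CanalId = Literal["anterior", "posterior", "horizontal"]
CANAL_IDS: tuple[CanalId, ...] = ("anterior", "posterior", "horizontal")

#: replicate-panel variables: lumen diameters (mm) and inter-canal angles (deg)
LUMEN_VARIABLES = ("LDASC", "LDPSC", "LDHSC")
ANGLE_VARIABLES = ("AAHSC", "APHSC", "AAPSC")
PANEL_VARIABLES = LUMEN_VARIABLES + ANGLE_VARIABLES

N_REPLICATES = 5

_DIAMETER_COLUMNS = (
    "AMaSCD", "AMiSCD", "PMaSCD", "PMiSCD", "HMaSCD", "HMiSCD",
)
_DIAMETER_HEADER = ("taxon", "specimen") + _DIAMETER_COLUMNS + (
    "log10_bm_grams", "bm_estimated",
)
_PANEL_HEADER = ("specimen", "variable", "rep1", "rep2", "rep3", "rep4", "rep5")

#: (major column, minor column) per canal in the diameters layout
_CANAL_COLUMNS: dict[CanalId, tuple[str, str]] = {
    "anterior": ("AMaSCD", "AMiSCD"),
    "posterior": ("PMaSCD", "PMiSCD"),
    "horizontal": ("HMaSCD", "HMiSCD"),
}

TableKind = Literal["diameters", "lumen", "angles"]


@dataclass(frozen=True)
class CanalEllipse:
    """Planar outline of one semicircular canal as a major/minor axis pair."""

    canal_id: CanalId
    major_d: float  # mm
    minor_d: float  # mm

    def __post_init__(self) -> None:
        if self.canal_id not in CANAL_IDS:
            raise ValidationError(f"unknown canal_id {self.canal_id!r}")
        if not (self.minor_d > 0):
            raise ValidationError(
                f"{self.canal_id} minor diameter must be positive, got {self.minor_d}"
            )
        if self.major_d < self.minor_d:
            raise ValidationError(
                f"{self.canal_id} major diameter {self.major_d} < minor {self.minor_d}"
            )


@dataclass(frozen=True)
class ReplicatePanel:
    """Five repeated measurements of one variable on one specimen."""

    variable_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.variable_id not in PANEL_VARIABLES:
            raise ValidationError(f"unknown panel variable {self.variable_id!r}")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.values) != N_REPLICATES:
            raise ValidationError(
                f"panel {self.variable_id} needs {N_REPLICATES} values, "
                f"got {len(self.values)}"
            )
        for i, v in enumerate(self.values, start=1):
            if self.variable_id in ANGLE_VARIABLES and not (0.0 < v < 180.0):
                raise ValidationError(
                    f"{self.variable_id} rep{i}: angle {v} outside (0, 180) degrees"
                )
            if self.variable_id in LUMEN_VARIABLES and not (v > 0.0):
                raise ValidationError(
                    f"{self.variable_id} rep{i}: lumen diameter {v} not positive"
                )

    @property
    def is_angle(self) -> bool:
        return self.variable_id in ANGLE_VARIABLES


@dataclass
class SpecimenRecord:
    """One specimen: canal ellipses, replicate panels and optional body mass.

    ``log10_bm_grams`` is the log10 of body mass in grams; ``bm_estimated``
    marks masses that were produced by a regression rather than weighed, and
    such records are excluded from calibration sets.
    """

    specimen_id: str
    taxon: str = ""
    canals: dict[CanalId, CanalEllipse] = field(default_factory=dict)
    panels: dict[str, ReplicatePanel] = field(default_factory=dict)
    log10_bm_grams: Optional[float] = None
    bm_estimated: bool = False

    def __post_init__(self) -> None:
        for cid, canal in self.canals.items():
            if canal.canal_id != cid:
                raise ValidationError(
                    f"{self.specimen_id}: canal keyed {cid} has id {canal.canal_id}"
                )
        for vid, panel in self.panels.items():
            if panel.variable_id != vid:
                raise ValidationError(
                    f"{self.specimen_id}: panel keyed {vid} has id {panel.variable_id}"
                )

    def canal(self, canal_id: CanalId) -> CanalEllipse:
        from .exceptions import MissingDataError

        try:
            return self.canals[canal_id]
        except KeyError:
            raise MissingDataError(
                f"{self.specimen_id}: no {canal_id} canal measured"
            ) from None

    def panel(self, variable_id: str) -> ReplicatePanel:
        from .exceptions import MissingDataError

        try:
            return self.panels[variable_id]
        except KeyError:
            raise MissingDataError(
                f"{self.specimen_id}: no {variable_id} panel measured"
            ) from None

    @property
    def has_all_canals(self) -> bool:
        return all(c in self.canals for c in CANAL_IDS)


@dataclass
class CalibrationTable:
    """Extant-taxon records used to fit the allometric body-mass model.

    Every record must carry a non-estimated body mass and all three canal
    ellipses; (taxon, specimen_id) pairs must be unique (published voucher
    numbers alone are reused across taxa).
    """

    records: list[SpecimenRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 3:
            raise ValidationError(
                f"calibration needs >= 3 records, got {len(self.records)}"
            )
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.taxon, rec.specimen_id)
            if key in seen:
                raise ValidationError(f"duplicated calibration record {key}")
            seen.add(key)
            if rec.log10_bm_grams is None:
                raise ValidationError(f"{rec.specimen_id}: body mass missing")
            if not rec.has_all_canals:
                raise ValidationError(f"{rec.specimen_id}: incomplete canal set")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_records(cls, records: Iterable[SpecimenRecord]) -> "CalibrationTable":
        """Keep records with a measured (not regression-estimated) body mass."""
        usable = [
            r for r in records
            if r.log10_bm_grams is not None and not r.bm_estimated and r.has_all_canals
        ]
        return cls(records=usable)


def _parse_float(raw: str, row: int, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ValidationError(
            f"row {row}, column {column}: cannot parse {raw!r} as a number"
        ) from None


def _parse_bool(raw: str, row: int, column: str) -> bool:
    low = raw.strip().lower()
    if low in {"true", "1", "yes"}:
        return True
    if low in {"false", "0", "no", ""}:
        return False
    raise ValidationError(f"row {row}, column {column}: cannot parse {raw!r} as a flag")


def _check_header(header: Sequence[str], expected: Sequence[str], kind: str) -> None:
    missing = [c for c in expected if c not in header]
    if missing:
        raise SchemaError(
            f"{kind} table is missing column(s) {missing}; header was {list(header)}"
        )


def _read_diameter_rows(reader: csv.DictReader, kind: str) -> list[SpecimenRecord]:
    records = []
    for i, row in enumerate(reader, start=2):  # header is line 1
        canals = {}
        for cid, (maj_col, min_col) in _CANAL_COLUMNS.items():
            maj = _parse_float(row[maj_col], i, maj_col)
            mnr = _parse_float(row[min_col], i, min_col)
            if maj <= 0 or mnr <= 0:
                raise ValidationError(
                    f"row {i}, columns {maj_col}/{min_col}: non-positive diameter"
                )
            if maj < mnr:  # axes swapped at data entry; reorder
                maj, mnr = mnr, maj
            canals[cid] = CanalEllipse(canal_id=cid, major_d=maj, minor_d=mnr)
        bm_raw = row.get("log10_bm_grams", "").strip()
        records.append(
            SpecimenRecord(
                specimen_id=row["specimen"].strip(),
                taxon=row["taxon"].strip(),
                canals=canals,
                log10_bm_grams=(
                    _parse_float(bm_raw, i, "log10_bm_grams") if bm_raw else None
                ),
                bm_estimated=_parse_bool(row.get("bm_estimated", ""), i, "bm_estimated"),
            )
        )
    return records


def _read_panel_rows(
    reader: csv.DictReader, kind: str, allowed: Sequence[str]
) -> list[SpecimenRecord]:
    by_specimen: dict[str, SpecimenRecord] = {}
    for i, row in enumerate(reader, start=2):
        vid = row["variable"].strip()
        if vid not in allowed:
            raise ValidationError(
                f"row {i}, column variable: {vid!r} is not a {kind} variable "
                f"(expected one of {list(allowed)})"
            )
        values = tuple(
            _parse_float(row[f"rep{j}"], i, f"rep{j}")
            for j in range(1, N_REPLICATES + 1)
        )
        sid = row["specimen"].strip()
        rec = by_specimen.setdefault(sid, SpecimenRecord(specimen_id=sid))
        if vid in rec.panels:
            raise ValidationError(f"row {i}: duplicate panel {vid} for {sid}")
        rec.panels[vid] = ReplicatePanel(variable_id=vid, values=values)
    return list(by_specimen.values())  # insertion order == row order


def load_measurement_table(path: str | Path, table_kind: TableKind) -> list[SpecimenRecord]:
    """Read a measurement CSV of the given kind into validated records.

    Row order is preserved; malformed numerics raise :class:`ValidationError`
    naming the row and column, and a missing column raises :class:`SchemaError`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if table_kind == "diameters":
            _check_header(header, _DIAMETER_HEADER[:-2], table_kind)
            return _read_diameter_rows(reader, table_kind)
        if table_kind == "lumen":
            _check_header(header, _PANEL_HEADER, table_kind)
            return _read_panel_rows(reader, table_kind, LUMEN_VARIABLES)
        if table_kind == "angles":
            _check_header(header, _PANEL_HEADER, table_kind)
            return _read_panel_rows(reader, table_kind, ANGLE_VARIABLES)
        raise LookupError(f"unknown table kind {table_kind!r}")


def _format_number(x: float) -> str:
    """Render without float noise so write->read round-trips exactly."""
    return repr(x)


def write_measurement_table(
    records: Iterable[SpecimenRecord], path: str | Path, table_kind: TableKind
) -> None:
    """Write records back to CSV in the layout of the given kind."""
    path = Path(path)
    records = list(records)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if table_kind == "diameters":
            writer.writerow(_DIAMETER_HEADER)
            for rec in records:
                row: list[str] = [rec.taxon, rec.specimen_id]
                for cid in CANAL_IDS:
                    canal = rec.canal(cid)
                    row += [_format_number(canal.major_d), _format_number(canal.minor_d)]
                row.append(
                    "" if rec.log10_bm_grams is None else _format_number(rec.log10_bm_grams)
                )
                row.append(str(rec.bm_estimated))
                writer.writerow(row)
        elif table_kind in ("lumen", "angles"):
            allowed = LUMEN_VARIABLES if table_kind == "lumen" else ANGLE_VARIABLES
            writer.writerow(_PANEL_HEADER)
            for rec in records:
                for vid in allowed:
                    if vid in rec.panels:
                        writer.writerow(
                            [rec.specimen_id, vid]
                            + [_format_number(v) for v in rec.panels[vid].values]
                        )
        else:
            raise LookupError(f"unknown table kind {table_kind!r}")


_FIXTURE_KINDS: dict[str, TableKind] = {
    "table1": "diameters",
    "table2": "lumen",
    "table3": "angles",
}


def fixture(name: str) -> list[SpecimenRecord]:
    """Return the packaged published measurement table as validated records.

    ``table1`` — canal diameters + body mass for 32 extant mammals, the three
    *Endothiodon* specimens and *Niassodon*; ``table2`` — replicated lumen
    diameters; ``table3`` — replicated inter-canal angles.
    """
    try:
        kind = _FIXTURE_KINDS[name]
    except KeyError:
        raise LookupError(
            f"unknown fixture {name!r}; expected one of {sorted(_FIXTURE_KINDS)}"
        ) from None
    ref = resources.files("canalmorph.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return load_measurement_table(path, kind)


def merge_records(*record_sets: Iterable[SpecimenRecord]) -> list[SpecimenRecord]:
    """Merge per-table record lists on (taxon omitted) specimen_id.

    Later tables contribute panels / masses to existing specimens; canals are
    never overwritten.
    """
    merged: dict[str, SpecimenRecord] = {}
    for records in record_sets:
        for rec in records:
            if rec.specimen_id not in merged:
                merged[rec.specimen_id] = replace(
                    rec, canals=dict(rec.canals), panels=dict(rec.panels)
                )
                continue
            tgt = merged[rec.specimen_id]
            for cid, canal in rec.canals.items():
                tgt.canals.setdefault(cid, canal)
            for vid, panel in rec.panels.items():
                tgt.panels.setdefault(vid, panel)
            if tgt.log10_bm_grams is None:
                tgt.log10_bm_grams = rec.log10_bm_grams
                tgt.bm_estimated = rec.bm_estimated
            if not tgt.taxon:
                tgt.taxon = rec.taxon
    return list(merged.values())
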