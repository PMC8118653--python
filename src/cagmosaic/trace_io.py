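"""Reading and writing fragment-analysis peak tables and packaged cohort tables.

Fragment traces come from GeneMapper-style exports of capillary-electrophoresis
runs of the HTT CAG-repeat PCR: one row per called peak, tab-separated, with
sample name, called allele, peak size in base pairs, peak height, peak area,
and scan (data point) number.  Export header strings vary between GeneMapper
versions and locales, so column matching goes through a configurable alias
table (:class:`GeneMapperDialect`).

Three cohort tables ship with the package as plain CSV fixtures:

``longitudinal``
    50 HD mutation carriers with 2-3 blood samplings each (112 visits),
    reference CAG 39-54, including per-visit expansion indices, disease
    status, UHDRS total motor scores, motor-onset ages, and ages at death
    for the 14 subjects who died during follow-up.
``fetal``
    7 mutation-carrier fetuses (gestational week 13): expansion indices in
    developing cortex, trophoblast, and the carrier parent's blood.
``postmortem``
    15 adult post-mortem frontal-cortex donors with sex, reference CAG,
    expansion index, and age at death (one donor's age at death unknown).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Peak",
    "FragmentTrace",
    "VisitRecord",
    "SubjectRecord",
    "GeneMapperDialect",
    "GeneMapperFormatError",
    "MalformedRowError",
    "FixtureIntegrityError",
    "read_genemapper_table",
    "write_genemapper_table",
    "load_cohort_table",
    "load_cohort_fixture",
]

FEMALE = "female"
MALE = "male"
PREMANIFEST = "premanifest"
MANIFEST = "manifest"
UNKNOWN = "unknown"


class GeneMapperFormatError(ValueError):
    """A peak-table file is structurally unusable (e.g. a mandatory column is absent)."""


class MalformedRowError(ValueError):
    """One or more data rows could not be parsed.

    Attributes
    ----------
    rows : list of (line_number, message)
        1-based line numbers (header is line 1) with a parse diagnostic each.
    """

    def __init__(self, rows: list[tuple[int, str]]):
        self.rows = rows
        detail = "; ".join(f"line {n}: {msg}" for n, msg in rows[:10])
        more = "" if len(rows) <= 10 else f" (+{len(rows) - 10} more)"
        super().__init__(f"{len(rows)} malformed row(s): {detail}{more}")


class FixtureIntegrityError(RuntimeError):
    """A packaged cohort table failed its shape/content check."""


@dataclass
class Peak:
    """A single called peak in an electropherogram.

    Parameters
    ----------
    size_bp : float
        Fragment length in base pairs (> 0).
    height : float
        Fluorescence intensity, arbitrary units (>= 0).
    area : float, optional
        Area under the peak.
    scan : int, optional
        Data-point index of the peak apex.
    repeat_length : int, optional
        Called CAG count; absent until the trace is calibrated.
    off_ladder : bool
        Set by calibration when the peak does not sit on the 3-bp repeat
        ladder within tolerance; such peaks are excluded downstream.
    """

    size_bp: float
    height: float
    area: float | None = None
    scan: int | None = None
    repeat_length: int | None = None
    off_ladder: bool = False

    def __post_init__(self) -> None:
        if not self.size_bp > 0:
            raise ValueError(f"peak size must be positive, got {self.size_bp}")
        if self.height < 0:
            raise ValueError(f"peak height must be non-negative, got {self.height}")
        if self.repeat_length is not None:
            if int(self.repeat_length) != self.repeat_length or self.repeat_length <= 0:
                raise ValueError(f"repeat_length must be a positive integer, got {self.repeat_length}")
            self.repeat_length = int(self.repeat_length)


@dataclass
class FragmentTrace:
    """One sample's electropherogram as an ordered list of called peaks."""

    sample_id: str
    peaks: list[Peak]
    plate_id: str | None = None

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"trace {self.sample_id!r} has no peaks")
        self.peaks = sorted(self.peaks, key=lambda p: p.size_bp)
        for a, b in zip(self.peaks, self.peaks[1:]):
            if not a.size_bp < b.size_bp:
                raise ValueError(
                    f"trace {self.sample_id!r}: peak sizes must be strictly increasing "
                    f"({a.size_bp} then {b.size_bp})"
                )


@dataclass
class VisitRecord:
    """One blood-sampling visit: age, disease status, motor score, expansion index."""

    age: float
    ei: float
    status: str = UNKNOWN
    uhdrs_tms: int | None = None

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"visit age must be positive, got {self.age}")
        if self.ei < 0:
            raise ValueError(f"expansion index must be non-negative, got {self.ei}")
        if self.status not in (PREMANIFEST, MANIFEST, UNKNOWN):
            raise ValueError(f"unknown status {self.status!r}")


@dataclass
class SubjectRecord:
    """One HD mutation carrier with reference CAG and ordered visits."""

    subject_id: str
    cag_ref: int
    sex: str = UNKNOWN
    age_onset: float | None = None
    age_death: float | None = None
    visits: list[VisitRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cag_ref < 36:
            raise ValueError(f"reference CAG must be >= 36, got {self.cag_ref}")
        if self.sex not in (FEMALE, MALE, UNKNOWN):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_death is not None and not self.age_death > 0:
            raise ValueError("age_death must be positive when present")
        ages = [v.age for v in self.visits]
        if any(b < a for a, b in zip(ages, ages[1:])):
            self.visits = sorted(self.visits, key=lambda v: v.age)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def effective_age_onset(self) -> float | None:
        """Age at onset as the earliest of self-reported onset and first manifest visit.

        Motor onset recorded clinically is the earlier of the self-reported age
        and the first examination at which the subject was manifest; a subject
        can therefore be observed manifest at a visit before their self-reported
        onset age, and that earlier age is the one onset-anchored quantities use.
        """
        candidates = [self.age_onset] if self.age_onset is not None else []
        manifest_ages = [v.age for v in self.visits if v.status == MANIFEST]
        if manifest_ages:
            candidates.append(min(manifest_ages))
        return min(candidates) if candidates else None


@dataclass(frozen=True)
class GeneMapperDialect:
    """Accepted (case-insensitive) header names for each peak-table column.

    ``sample``, ``size`` and ``height`` are mandatory; the rest are optional.
    The first alias of each field is the header used when writing.
    """

    sample: tuple[str, ...] = ("Sample Name", "Sample File Name", "Sample")
    allele: tuple[str, ...] = ("Allele", "Called Allele", "CAG")
    size: tuple[str, ...] = ("Size (bp)", "Size", "Size bp")
    height: tuple[str, ...] = ("Height", "Peak Height")
    area: tuple[str, ...] = ("Area", "Area Under Peak")
    scan: tuple[str, ...] = ("Data Point", "Scan", "Scan Number", "Datapoint")

    def resolve(self, header: Sequence[str]) -> dict[str, int | None]:
        lowered = [h.strip().lower() for h in header]
        out: dict[str, int | None] = {}
        for name in ("sample", "allele", "size", "height", "area", "scan"):
            aliases = [a.lower() for a in getattr(self, name)]
            idx = next((i for i, h in enumerate(lowered) if h in aliases), None)
            out[name] = idx
        for mandatory in ("sample", "size", "height"):
            if out[mandatory] is None:
                raise GeneMapperFormatError(
                    f"missing mandatory column {getattr(self, mandatory)[0]!r} "
                    f"(aliases: {', '.join(getattr(self, mandatory))})"
                )
        return out


def _parse_float(text: str, what: str) -> float:
    value = float(text)
    if not math.isfinite(value):
        raise ValueError(f"non-finite {what}")
    return value


def read_genemapper_table(
    path: str | Path,
    dialect: GeneMapperDialect | None = None,
    errors: str = "raise",
) -> list[FragmentTrace] | tuple[list[FragmentTrace], list[tuple[int, str]]]:
    """Read a GeneMapper-style exported peak table into fragment traces.

    One :class:`FragmentTrace` is produced per distinct sample name, with
    peaks sorted by size.  A numeric ``Allele`` column becomes
    ``Peak.repeat_length`` (the called CAG count).

    Parameters
    ----------
    path : path to a tab-separated export.
    dialect : column-name aliases; defaults accept common export variants.
    errors : ``"raise"`` (default) raises :class:`MalformedRowError` listing
        every bad row; ``"collect"`` returns ``(traces, row_errors)`` instead.
    """
    if errors not in ("raise", "collect"):
        raise ValueError("errors must be 'raise' or 'collect'")
    dialect = dialect or GeneMapperDialect()
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise GeneMapperFormatError(f"{path}: empty file") from None
        cols = dialect.resolve(header)
        by_sample: dict[str, list[Peak]] = {}
        row_errors: list[tuple[int, str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                sample = row[cols["sample"]].strip()
                if not sample:
                    raise ValueError("empty sample name")
                size = _parse_float(row[cols["size"]], "size")
                height = _parse_float(row[cols["height"]], "height")

                def _opt(key: str) -> str | None:
                    idx = cols[key]
                    if idx is None or idx >= len(row) or not row[idx].strip():
                        return None
                    return row[idx].strip()

                allele = _opt("allele")
                area = _opt("area")
                scan = _opt("scan")
                peak = Peak(
                    size_bp=size,
                    height=height,
                    area=None if area is None else _parse_float(area, "area"),
                    scan=None if scan is None else int(float(scan)),
                    repeat_length=None if allele is None else int(float(allele)),
                )
            except (ValueError, IndexError) as exc:
                row_errors.append((lineno, str(exc)))
                continue
            by_sample.setdefault(sample, []).append(peak)
    if row_errors and errors == "raise":
        raise MalformedRowError(row_errors)
    traces = [FragmentTrace(sample_id=s, peaks=peaks) for s, peaks in by_sample.items()]
    if errors == "collect":
        return traces, row_errors
    return traces


def write_genemapper_table(traces: Iterable[FragmentTrace], path: str | Path) -> None:
    """Write traces as a tab-separated peak table re-readable by :func:`read_genemapper_table`."""
    dialect = GeneMapperDialect()
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            [dialect.sample[0], dialect.allele[0], dialect.size[0],
             dialect.height[0], dialect.area[0], dialect.scan[0]]
        )
        for trace in traces:
            for p in trace.peaks:
                writer.writerow(
                    [
                        trace.sample_id,
                        "" if p.repeat_length is None else p.repeat_length,
                        repr(p.size_bp),
                        repr(p.height),
                        "" if p.area is None else repr(p.area),
                        "" if p.scan is None else p.scan,
                    ]
                )


# ---------------------------------------------------------------------------
# Packaged cohort tables

_FIXTURES = {"longitudinal": "longitudinal.csv", "fetal": "fetal.csv", "postmortem": "postmortem.csv"}

_STATUS_MAP = {"P": PREMANIFEST, "M": MANIFEST}

#: Documented correction applied by :func:`load_cohort_fixture`: subject 3's
#: first visit is printed "M" with UHDRS-TMS 0 at age 76 and motor onset 80,
#: but the table's own status summary (19 manifest / 31 premanifest at the
#: first visit) requires exactly this row to be premanifest, and the subject's
#: printed extrapolated onset index is only consistent with onset at 80.
_LONGITUDINAL_ERRATA = {("3", 1): {"status": PREMANIFEST}}


def load_cohort_table(which: str) -> pd.DataFrame:
    """Load one packaged cohort table as a DataFrame mirroring the source columns.

    ``er`` and ``ei_ao`` in the longitudinal table are returned as the original
    decimal strings so that printed precision is preserved; all other numeric
    columns are parsed.  Missing cells ("NA") become NaN / <NA>.
    """
    if which not in _FIXTURES:
        raise ValueError(f"unknown cohort table {which!r}; expected one of {sorted(_FIXTURES)}")
    ref = resources.files("cagmosaic").joinpath("data", _FIXTURES[which])
    with resources.as_file(ref) as fp:
        df = pd.read_csv(fp, na_values=["NA"], dtype={"er": "string", "ei_ao": "string"})
    _check_integrity(which, df)
    return df


def _check_integrity(which: str, df: pd.DataFrame) -> None:
    expect_rows = {"longitudinal": 50, "fetal": 7, "postmortem": 15}[which]
    if len(df) != expect_rows:
        raise FixtureIntegrityError(f"{which}: expected {expect_rows} rows, found {len(df)}")
    if which == "longitudinal":
        n_visits = int(df[["ei1", "ei2", "ei3"]].notna().sum().sum())
        if n_visits != 112:
            raise FixtureIntegrityError(f"longitudinal: expected 112 visit records, found {n_visits}")


def load_cohort_fixture(which: str) -> list[SubjectRecord]:
    """Load one packaged cohort table as :class:`SubjectRecord` objects.

    longitudinal
        50 subjects, 112 visits (12 subjects have a third visit); per-subject
        sex is not recorded in the source table and is ``unknown``.
    fetal
        7 records with the fetal-cortex expansion index as a single visit at
        0.25 years (gestational week 13).
    postmortem
        15 records; donors with a known age at death carry one visit at that
        age holding the cortical expansion index.
    """
    df = load_cohort_table(which)
    if which == "longitudinal":
        return [_longitudinal_record(row) for _, row in df.iterrows()]
    if which == "fetal":
        return [
            SubjectRecord(
                subject_id=f"F{int(row.id)}",
                cag_ref=int(row.cag_fetal_brain),
                visits=[VisitRecord(age=13 / 52, ei=float(row.ei_fetal_brain))],
            )
            for _, row in df.iterrows()
        ]
    records = []
    for _, row in df.iterrows():
        dead_at = None if pd.isna(row.age_death) else float(row.age_death)
        visits = [] if dead_at is None else [VisitRecord(age=dead_at, ei=float(row.ei))]
        records.append(
            SubjectRecord(
                subject_id=f"PM{int(row.id)}",
                cag_ref=int(row.cag),
                sex=FEMALE if row.sex == "F" else MALE,
                age_death=dead_at,
                visits=visits,
            )
        )
    return records


def _longitudinal_record(row: pd.Series) -> SubjectRecord:
    subject_id = str(int(row.id))
    visits = []
    for k in (1, 2, 3):
        if pd.isna(row[f"ei{k}"]):
            continue
        status = _STATUS_MAP.get(row[f"status{k}"], UNKNOWN)
        fix = _LONGITUDINAL_ERRATA.get((subject_id, k))
        if fix:
            status = fix.get("status", status)
        uhdrs = row[f"uhdrs{k}"]
        visits.append(
            VisitRecord(
                age=float(row[f"age{k}"]),
                ei=float(row[f"ei{k}"]),
                status=status,
                uhdrs_tms=None if pd.isna(uhdrs) else int(uhdrs),
            )
        )
    return SubjectRecord(
        subject_id=subject_id,
        cag_ref=int(row.cag),
        age_onset=None if pd.isna(row.motor_onset) else float(row.motor_onset),
        age_death=None if pd.isna(row.age_death) else float(row.age_death),
        visits=visits,
    )
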