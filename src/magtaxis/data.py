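"""Data model, CSV I/O and plate-inclusion filters for both assays.

Two small CSV contracts are supported (UTF-8, comma-delimited, ``.``
decimal separator):

* headings table: ``plate_id,condition,angle_deg`` — one row per scored
  worm; conditions ``zero``, ``field1``, ``field2``.
* plates table: ``plate_id,condition,humidity_pct,temp_start_c,temp_end_c,
  duration_min`` — one row per assay plate.
* magnet counts table: ``plate_id,condition,count_target,count_control`` —
  conditions ``magnet``, ``control``, ``diacetyl``.

The plate, not the worm, is the unit of statistical independence: worms on
a plate interact, so all downstream statistics reduce each plate to one
observation.  :func:`filter_plates` implements the environmental inclusion
rules (worms scored, humidity, temperature, temperature drift, duration)
and returns an explicit exclusion log.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from magtaxis.circular import AngleSample

__all__ = [
    "BalanceResult",
    "EnvMetadata",
    "FIELD_CONDITIONS",
    "FieldPlate",
    "FilterConfig",
    "MAGNET_CONDITIONS",
    "MagnetPlate",
    "PlateExclusion",
    "balance_check",
    "filter_plates",
    "read_field_data",
    "read_magnet_data",
    "write_field_data",
    "write_magnet_data",
]

FIELD_CONDITIONS = ("zero", "field1", "field2")
MAGNET_CONDITIONS = ("magnet", "control", "diacetyl")

HEADINGS_COLUMNS = ["plate_id", "condition", "angle_deg"]
PLATES_COLUMNS = [
    "plate_id",
    "condition",
    "humidity_pct",
    "temp_start_c",
    "temp_end_c",
    "duration_min",
]
MAGNET_COLUMNS = ["plate_id", "condition", "count_target", "count_control"]


class DataError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass(frozen=True)
class EnvMetadata:
    """Environmental record of one assay plate.

    humidity_pct: relative humidity (%) at assay start; temp_start_c /
    temp_end_c: temperature (deg C) at start and end; duration_min: assay
    length in minutes.
    """

    humidity_pct: float
    temp_start_c: float
    temp_end_c: float
    duration_min: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.humidity_pct <= 100.0:
            raise ValueError("humidity_pct must lie in [0, 100]")
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")


@dataclass(frozen=True)
class FieldPlate:
    """One horizontal-field assay plate: worm headings plus metadata."""

    plate_id: str
    condition: str
    headings: AngleSample
    env: EnvMetadata

    def __post_init__(self) -> None:
        if self.condition not in FIELD_CONDITIONS:
            raise ValueError(
                f"unknown field condition {self.condition!r}; "
                f"expected one of {FIELD_CONDITIONS}"
            )

    @property
    def n_worms(self) -> int:
        """Worms scored, derived from the headings (never a separate column)."""
        return len(self.headings)


@dataclass(frozen=True)
class MagnetPlate:
    """One two-target assay plate with target (T) and control (C) counts."""

    plate_id: str
    condition: str
    count_target: int
    count_control: int

    def __post_init__(self) -> None:
        if self.condition not in MAGNET_CONDITIONS:
            raise ValueError(
                f"unknown magnet condition {self.condition!r}; "
                f"expected one of {MAGNET_CONDITIONS}"
            )
        if self.count_target < 0 or self.count_control < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def pi_defined(self) -> bool:
        return self.count_target + self.count_control > 0


@dataclass(frozen=True)
class FilterConfig:
    """Plate-inclusion thresholds for the horizontal-field assay.

    Defaults encode the inclusion rules of the assay protocol: at least 30
    worms scored (inclusive), humidity strictly below 50%, both temperature
    readings at most 25 deg C (inclusive), absolute start-to-end temperature
    difference strictly below 2 deg C, and a duration of 55-65 minutes
    inclusive.  Humidity is evaluated at assay start.
    """

    min_worms: int = 30
    max_humidity_pct: float = 50.0
    max_temp_c: float = 25.0
    max_temp_delta_c: float = 2.0
    duration_range_min: tuple[float, float] = (55.0, 65.0)

    def __post_init__(self) -> None:
        if min(
            self.min_worms,
            self.max_humidity_pct,
            self.max_temp_c,
            self.max_temp_delta_c,
        ) <= 0:
            raise ValueError("all thresholds must be positive")
        lo, hi = self.duration_range_min
        if lo > hi:
            raise ValueError("duration range must be ordered")


@dataclass(frozen=True)
class PlateExclusion:
    """A filtered-out plate together with every rule it violated."""

    plate_id: str
    condition: str
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class BalanceResult:
    counts: dict[str, int]
    p_value: float
    balanced: bool


def _require_columns(df: pd.DataFrame, expected: list[str], label: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DataError(f"{label} table is missing columns {missing}")


def _bad_rows(mask: pd.Series) -> list[int]:
    # +2: 1-based rows plus the header line
    return [int(i) + 2 for i in mask[mask].index]


def read_field_data(headings_table: str | Path, plates_table: str | Path) -> list[FieldPlate]:
    """Read and join the headings and plates tables into ``FieldPlate``s.

    Angles are normalized into ``[0, 360)``.  Orphan heading rows, duplicate
    plate ids, unknown condition labels and condition mismatches between the
    two tables raise :class:`DataError` naming the offending rows.
    """
    headings = pd.read_csv(headings_table)
    plates = pd.read_csv(plates_table)
    _require_columns(headings, HEADINGS_COLUMNS, "headings")
    _require_columns(plates, PLATES_COLUMNS, "plates")

    bad = _bad_rows(~plates["condition"].isin(FIELD_CONDITIONS))
    if bad:
        raise DataError(f"plates table: unknown condition label(s) at rows {bad}")
    bad = _bad_rows(~headings["condition"].isin(FIELD_CONDITIONS))
    if bad:
        raise DataError(f"headings table: unknown condition label(s) at rows {bad}")
    dup = _bad_rows(plates["plate_id"].duplicated(keep=False))
    if dup:
        raise DataError(f"plates table: duplicate plate_id at rows {dup}")
    orphan = _bad_rows(~headings["plate_id"].isin(plates["plate_id"]))
    if orphan:
        raise DataError(f"headings table: plate_id not in plates table at rows {orphan}")

    cond_by_plate = dict(zip(plates["plate_id"], plates["condition"]))
    mismatch = _bad_rows(
        headings["condition"] != headings["plate_id"].map(cond_by_plate)
    )
    if mismatch:
        raise DataError(
            f"headings table: condition disagrees with plates table at rows {mismatch}"
        )

    grouped = {pid: grp["angle_deg"].to_numpy(dtype=float) for pid, grp in headings.groupby("plate_id")}
    out: list[FieldPlate] = []
    for row in plates.itertuples(index=False):
        angles = grouped.get(row.plate_id, np.empty(0))
        out.append(
            FieldPlate(
                plate_id=str(row.plate_id),
                condition=str(row.condition),
                headings=AngleSample(angles),
                env=EnvMetadata(
                    humidity_pct=float(row.humidity_pct),
                    temp_start_c=float(row.temp_start_c),
                    temp_end_c=float(row.temp_end_c),
                    duration_min=float(row.duration_min),
                ),
            )
        )
    return out


def read_magnet_data(counts_table: str | Path) -> list[MagnetPlate]:
    """Read the two-target counts table into ``MagnetPlate``s."""
    df = pd.read_csv(counts_table)
    _require_columns(df, MAGNET_COLUMNS, "magnet counts")
    bad = _bad_rows(~df["condition"].isin(MAGNET_CONDITIONS))
    if bad:
        raise DataError(f"magnet counts table: unknown condition label(s) at rows {bad}")
    bad = _bad_rows((df["count_target"] < 0) | (df["count_control"] < 0))
    if bad:
        raise DataError(f"magnet counts table: negative counts at rows {bad}")
    dup = _bad_rows(df["plate_id"].duplicated(keep=False))
    if dup:
        raise DataError(f"magnet counts table: duplicate plate_id at rows {dup}")
    return [
        MagnetPlate(
            plate_id=str(r.plate_id),
            condition=str(r.condition),
            count_target=int(r.count_target),
            count_control=int(r.count_control),
        )
        for r in df.itertuples(index=False)
    ]


# Fixed float formats make write_* byte-stable under read/write round trips.
_ANGLE_FMT = "{:.4f}"
_ENV_FMT = "{:.2f}"


def write_field_data(
    plates: list[FieldPlate], headings_table: str | Path, plates_table: str | Path
) -> None:
    """Write plates back to the two-table CSV contract (stable formatting)."""
    hbuf = io.StringIO()
    hbuf.write(",".join(HEADINGS_COLUMNS) + "\n")
    pbuf = io.StringIO()
    pbuf.write(",".join(PLATES_COLUMNS) + "\n")
    for p in plates:
        for a in p.headings.angles:
            hbuf.write(f"{p.plate_id},{p.condition},{_ANGLE_FMT.format(a)}\n")
        env = p.env
        pbuf.write(
            f"{p.plate_id},{p.condition},"
            f"{_ENV_FMT.format(env.humidity_pct)},{_ENV_FMT.format(env.temp_start_c)},"
            f"{_ENV_FMT.format(env.temp_end_c)},{_ENV_FMT.format(env.duration_min)}\n"
        )
    Path(headings_table).write_text(hbuf.getvalue(), encoding="utf-8")
    Path(plates_table).write_text(pbuf.getvalue(), encoding="utf-8")


def write_magnet_data(plates: list[MagnetPlate], counts_table: str | Path) -> None:
    buf = io.StringIO()
    buf.write(",".join(MAGNET_COLUMNS) + "\n")
    for p in plates:
        buf.write(f"{p.plate_id},{p.condition},{p.count_target},{p.count_control}\n")
    Path(counts_table).write_text(buf.getvalue(), encoding="utf-8")


def _violations(plate: FieldPlate, cfg: FilterConfig) -> tuple[str, ...]:
    reasons = []
    if plate.n_worms < cfg.min_worms:
        reasons.append("min_worms")
    if plate.env.humidity_pct >= cfg.max_humidity_pct:
        reasons.append("humidity")
    if max(plate.env.temp_start_c, plate.env.temp_end_c) > cfg.max_temp_c:
        reasons.append("temperature")
    if abs(plate.env.temp_end_c - plate.env.temp_start_c) >= cfg.max_temp_delta_c:
        reasons.append("temp_delta")
    lo, hi = cfg.duration_range_min
    if not lo <= plate.env.duration_min <= hi:
        reasons.append("duration")
    return tuple(reasons)


def filter_plates(
    plates: list[FieldPlate], config: FilterConfig | None = None
) -> tuple[list[FieldPlate], list[PlateExclusion]]:
    """Apply the plate-inclusion rules; return kept plates and an exclusion log.

    A plate is kept iff worms scored >= min_worms, humidity < max_humidity
    (strict), max(start, end temperature) <= max_temp (inclusive),
    |end - start temperature| < max_temp_delta (strict) and duration inside
    the inclusive range.  Every excluded plate is logged with all violated
    rules, so the log is the exact complement of the kept set.
    """
    cfg = config or FilterConfig()
    kept: list[FieldPlate] = []
    excluded: list[PlateExclusion] = []
    for plate in plates:
        reasons = _violations(plate, cfg)
        if reasons:
            excluded.append(PlateExclusion(plate.plate_id, plate.condition, reasons))
        else:
            kept.append(plate)
    return kept, excluded


def balance_check(kept: list[FieldPlate], alpha: float = 0.05) -> BalanceResult:
    """Advisory chi-square goodness-of-fit check of per-condition plate counts.

    Tests the kept-plate counts against equal allocation across the
    conditions present; "balanced" means the test does not reject at
    ``alpha``.  This is a sanity check that filtering did not skew group
    sizes, not an analysis gate.
    """
    if not kept:
        raise ValueError("balance_check requires at least one kept plate")
    counts: dict[str, int] = {}
    for plate in kept:
        counts[plate.condition] = counts.get(plate.condition, 0) + 1
    observed = np.array(list(counts.values()), dtype=float)
    if observed.size == 1:
        return BalanceResult(counts=counts, p_value=1.0, balanced=True)
    p = float(stats.chisquare(observed).pvalue)
    return BalanceResult(counts=counts, p_value=p, balanced=p >= alpha)
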