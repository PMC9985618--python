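"""Shared fixtures: deterministic plates and the boundary-case filter set."""

from __future__ import annotations

import numpy as np
import pytest

from magtaxis.circular import AngleSample
from magtaxis.data import EnvMetadata, FieldPlate


def make_field_plate(
    plate_id: str,
    condition: str = "zero",
    n_worms: int = 40,
    humidity: float = 40.0,
    temp_start: float = 22.0,
    temp_end: float = 22.5,
    duration: float = 60.0,
    seed: int = 0,
) -> FieldPlate:
    rng = np.random.default_rng(seed)
    return FieldPlate(
        plate_id=plate_id,
        condition=condition,
        headings=AngleSample(rng.uniform(0.0, 360.0, n_worms)),
        env=EnvMetadata(humidity, temp_start, temp_end, duration),
    )


@pytest.fixture
def boundary_plates() -> tuple[list[FieldPlate], dict[str, tuple[str, ...]]]:
    """Eight plates probing every inclusion rule at its boundary.

    Returns the plates and the expected exclusion map (plate_id -> violated
    rules); plates absent from the map must be kept.
    """
    plates = [
        # clean pass
        make_field_plate("keep-clean", "zero", 35, 40.0, 22.0, 22.5, 60.0, seed=1),
        # 29 worms: one short of the inclusive minimum of 30
        make_field_plate("drop-worms", "zero", 29, 40.0, 22.0, 22.5, 60.0, seed=2),
        # humidity exactly 50.0: "below 50%" is strict
        make_field_plate("drop-humidity", "field1", 35, 50.0, 22.0, 22.5, 60.0, seed=3),
        # temperature exactly 25.0: "maximal 25" is inclusive -> kept
        make_field_plate("keep-temp25", "field1", 35, 40.0, 25.0, 24.0, 60.0, seed=4),
        # temperature drift exactly 2.0: "below 2" is strict
        make_field_plate("drop-delta", "field2", 35, 40.0, 22.0, 24.0, 60.0, seed=5),
        # duration 55 and 65: both endpoints inclusive -> kept
        make_field_plate("keep-dur55", "field2", 35, 40.0, 22.0, 22.5, 55.0, seed=6),
        make_field_plate("keep-dur65", "zero", 35, 40.0, 22.0, 22.5, 65.0, seed=7),
        # three simultaneous violations, all of which must be logged
        make_field_plate("drop-multi", "field1", 20, 60.0, 22.0, 22.5, 40.0, seed=8),
    ]
    expected_exclusions = {
        "drop-worms": ("min_worms",),
        "drop-humidity": ("humidity",),
        "drop-delta": ("temp_delta",),
        "drop-multi": ("min_worms", "humidity", "duration"),
    }
    return plates, expected_exclusions
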