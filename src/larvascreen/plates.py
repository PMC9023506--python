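"""96-well plate geometry, the four-plate imaging stage, and plate layouts.

The imaging rig holds four 96-well plates in a 2 x 2 arrangement and captures
all 384 wells in a single image. Wells are addressed as (plate, row, column)
with plates 1-4, rows A-H (top to bottom in the image) and columns 1-12.
Physical dimensions follow the ANSI/SLAS microplate standard (9 mm well
pitch); the well inner diameter of the low-volume plates used in the assay is
7.15 mm.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Iterator

ROWS = "ABCDEFGH"
COLS = tuple(range(1, 13))
WELLS_PER_PLATE = len(ROWS) * len(COLS)

WELL_PITCH_MM = 9.0
#: center of well A1 relative to the plate's top-left corner
A1_OFFSET_MM = (11.24, 14.38)  # (row/y, col/x)
PLATE_SIZE_MM = (85.48, 127.76)  # (height, width)
PLATE_GAP_MM = 6.0  # spacing between plates on the stage

#: stage positions of plates 1-4 in the 2 x 2 arrangement: (grid_row, grid_col)
PLATE_GRID = {1: (0, 0), 2: (0, 1), 3: (1, 0), 4: (1, 1)}

WellAddress = tuple[int, str, int]  # (plate, row letter, column)


class LayoutError(ValueError):
    """Invalid plate layout."""


def well_name(row: str, col: int) -> str:
    return f"{row}{col:02d}"


def well_id(plate: int, row: str, col: int) -> str:
    """Canonical well identifier, e.g. ``P1-A01``."""
    return f"P{plate}-{well_name(row, col)}"


def parse_well_id(wid: str) -> WellAddress:
    plate_part, well_part = wid.split("-")
    return int(plate_part[1:]), well_part[0], int(well_part[1:])


def iter_wells(plates: Iterable[int] = (1, 2, 3, 4)) -> Iterator[WellAddress]:
    """All well addresses in deterministic plate/row/column order."""
    for plate in plates:
        for row in ROWS:
            for col in COLS:
                yield (plate, row, col)


def plate_origin_mm(plate: int) -> tuple[float, float]:
    """(row_mm, col_mm) of a plate's top-left corner on the stage."""
    grid_row, grid_col = PLATE_GRID[plate]
    return (grid_row * (PLATE_SIZE_MM[0] + PLATE_GAP_MM),
            grid_col * (PLATE_SIZE_MM[1] + PLATE_GAP_MM))


def well_center_mm(plate: int, row: str, col: int) -> tuple[float, float]:
    """(row_mm, col_mm) of a well center on the stage (image convention:
    row coordinate increases downward)."""
    oy, ox = plate_origin_mm(plate)
    return (oy + A1_OFFSET_MM[0] + ROWS.index(row) * WELL_PITCH_MM,
            ox + A1_OFFSET_MM[1] + (col - 1) * WELL_PITCH_MM)


def stage_size_mm(plates: Iterable[int]) -> tuple[float, float]:
    """(height_mm, width_mm) of the smallest stage containing the plates."""
    height = width = 0.0
    for plate in plates:
        oy, ox = plate_origin_mm(plate)
        height = max(height, oy + PLATE_SIZE_MM[0])
        width = max(width, ox + PLATE_SIZE_MM[1])
    return height, width


@dataclass
class PlateLayout:
    """Map from well address to treatment label.

    ``controls`` names the labels that act as vehicle/untreated controls;
    the first entry is conventionally the vehicle (DMSO) control used as the
    baseline for behavioral profiles.
    """

    wells: dict[WellAddress, str]
    controls: tuple[str, ...] = ("DMSO", "untreated")

    def __post_init__(self) -> None:
        for (plate, row, col) in self.wells:
            if row not in ROWS or col not in COLS:
                raise LayoutError(f"invalid well address ({plate}, {row}, {col})")

    @property
    def labels(self) -> list[str]:
        """Distinct treatment labels in first-seen order."""
        seen: dict[str, None] = {}
        for addr in sorted(self.wells, key=lambda a: (a[0], ROWS.index(a[1]), a[2])):
            seen.setdefault(self.wells[addr], None)
        return list(seen)

    @property
    def treatment_labels(self) -> list[str]:
        return [lab for lab in self.labels if lab not in self.controls]

    def wells_for_label(self, label: str) -> list[WellAddress]:
        return [a for a in sorted(self.wells, key=lambda a: (a[0], ROWS.index(a[1]), a[2]))
                if self.wells[a] == label]

    def assert_screen_mode(self) -> None:
        """Check the screen constraint: no duplicate drug within one plate."""
        per_plate: dict[int, set[str]] = {}
        for (plate, row, col), label in self.wells.items():
            if label in self.controls:
                continue
            seen = per_plate.setdefault(plate, set())
            if label in seen:
                raise LayoutError(f"duplicate treatment {label!r} within plate {plate}")
            seen.add(label)

    # -- CSV round trip --------------------------------------------------

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["plate", "row", "col", "label"])
            for (plate, row, col) in sorted(self.wells, key=lambda a: (a[0], ROWS.index(a[1]), a[2])):
                writer.writerow([plate, row, col, self.wells[(plate, row, col)]])

    @classmethod
    def from_csv(cls, path, controls: tuple[str, ...] = ("DMSO", "untreated")) -> "PlateLayout":
        wells: dict[WellAddress, str] = {}
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                wells[(int(rec["plate"]), rec["row"], int(rec["col"]))] = rec["label"]
        return cls(wells=wells, controls=controls)


def screen_session_layout(drugs: list[str], plates: Iterable[int] = (1, 2, 3, 4),
                          dmso_label: str = "DMSO",
                          untreated_label: str = "untreated") -> PlateLayout:
    """One imaging session of the primary screen.

    Each 96-well plate holds every drug in exactly one well (at most 80 drugs)
    plus control wells: column 1 carries the DMSO vehicle control and column 12
    the untreated control. With 80 drugs the remaining 80 wells (columns 2-11)
    carry one drug each, so a four-plate session yields 4 duplicate wells per
    drug.
    """
    if len(drugs) > 80:
        raise LayoutError("a 96-well plate holds at most 80 distinct drugs")
    wells: dict[WellAddress, str] = {}
    for plate in plates:
        drug_wells = [(row, col) for row in ROWS for col in COLS if col not in (1, 12)]
        for row in ROWS:
            wells[(plate, row, 1)] = dmso_label
            wells[(plate, row, 12)] = untreated_label
        for (row, col), drug in zip(drug_wells, drugs):
            wells[(plate, row, col)] = drug
        for (row, col) in drug_wells[len(drugs):]:
            wells[(plate, row, col)] = untreated_label
    layout = PlateLayout(wells=wells, controls=(dmso_label, untreated_label))
    layout.assert_screen_mode()
    return layout


def validation_session_layout(groups: list[str], plates: Iterable[int] = (1, 2, 3, 4),
                              controls: tuple[str, ...] = ("DMSO",)) -> PlateLayout:
    """One session of the validation design: 8 rows x 12 experimental groups.

    Each of the 12 columns of every plate carries one group (8 wells), the
    first group conventionally being the DMSO vehicle control. Four plates per
    session x 5 sessions gives the 160 larvae per group used for validation.
    """
    if len(groups) != 12:
        raise LayoutError("validation layout needs exactly 12 group labels")
    wells = {(plate, row, col): groups[col - 1]
             for plate in plates for row in ROWS for col in COLS}
    return PlateLayout(wells=wells, controls=controls)
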