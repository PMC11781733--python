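"""Plate-design and well-level observation types shared by the generator and
the normalization stage.

The default screen design mirrors a 48-well plate with one solvent-control row
and five concentration rows of eight wells each, run as technical triplicates
with the row-to-concentration assignment rotated between replicate plates, so
that every concentration accumulates 24 animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: body-shape categories scored manually; at most three per animal
SHAPE_CATEGORIES = ("contraction", "c_shape", "corkscrew", "pharynx_extrusion", "hyperkinesis")


@dataclass(frozen=True)
class ScreenDesign:
    wells_per_row: int = 8
    concentration_rows_per_plate: int = 5
    replicate_plates: int = 3
    control_row_present: bool = True

    def __post_init__(self) -> None:
        if min(self.wells_per_row, self.concentration_rows_per_plate,
               self.replicate_plates) < 1:
            raise ValidationError("design counts must be positive")

    @property
    def n_per_concentration(self) -> int:
        return self.replicate_plates * self.wells_per_row

    def row_rotation(self, plate_index: int) -> list[int]:
        """Concentration index assigned to each concentration row of one plate.

        Cyclic shift by plate index; replicate plates therefore use distinct
        row orientations.
        """
        k = self.concentration_rows_per_plate
        return [(r + plate_index) % k for r in range(k)]


@dataclass
class WellObservation:
    """One planarian-well: raw endpoint readouts plus exclusion bookkeeping."""

    chemical_id: str
    plate_id: str
    well_id: str
    concentration: float  # uM; 0 for the vehicle control
    continuous: dict[str, float] = field(default_factory=dict)
    binary: dict[str, bool] = field(default_factory=dict)
    shape_categories: frozenset[str] = frozenset()
    excluded_from: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.shape_categories) > 3:
            raise ValidationError("at most three shape categories per animal")
        unknown = set(self.shape_categories) - set(SHAPE_CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown shape categories {sorted(unknown)}")

    def included(self, endpoint: str) -> bool:
        return endpoint not in self.excluded_from
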