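"""Compound table handling: study drugs, counterions and stereochemistry bookkeeping.

The study library is a set of neuroactive drugs from three functional classes
(antidepressants, antipsychotics, anxiolytics) plus counterion controls for the
salt forms.  Compounds are identified by 3-letter codes.  Two derived views of
the library matter downstream:

* a 2D view, in which stereoisomer pairs are collapsed onto one canonical
  structure (racemic escitalopram/citalopram become one entry), and
* a 3D view, in which every racemic drug is expanded into its two enantiomer
  records.
"""

from __future__ import annotations

import csv
import importlib.resources
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("compound_id", "name", "class_code", "solvent", "study_type",
                    "tested_concentrations")

#: default stereoisomer equivalences for the 2D (stereochemistry-blind) view
DEFAULT_2D_EQUIVALENCE: dict[str, str] = {"ESC": "CIT", "CIR": "CIT"}

#: default racemic drugs and their enantiomer codes for the 3D view
DEFAULT_RACEMIC_ISOMERS: dict[str, tuple[str, str]] = {
    "BUP": ("BUA", "BUB"),
    "CIT": ("CIR", "ESC"),
    "FLU": ("FLR", "FLS"),
}


class ClassLabel(Enum):
    """Functional pharmacological class of a compound."""

    AD = 1  # antidepressant
    AP = 2  # antipsychotic
    AX = 3  # anxiolytic
    CI = 4  # counterion control

    @classmethod
    def from_code(cls, code: int) -> "ClassLabel":
        try:
            return cls(int(code))
        except ValueError as exc:
            raise ValidationError(f"class code must be 1-4, got {code!r}") from exc

    @property
    def code(self) -> int:
        return self.value


@dataclass(frozen=True)
class CompoundRecord:
    """One row of the study compound table."""

    compound_id: str
    name: str
    class_code: int
    tested_concentrations: tuple[float, ...] = ()
    solvent: str = ""
    study_flags: frozenset[str] = field(default_factory=frozenset)
    stereo_note: str | None = None

    def __post_init__(self) -> None:
        if self.class_code not in (1, 2, 3, 4):
            raise ValidationError(
                f"{self.compound_id}: class_code must be in 1-4, got {self.class_code}")
        conc = tuple(self.tested_concentrations)
        if "experimental" in self.study_flags:
            if any(c <= 0 for c in conc):
                raise ValidationError(f"{self.compound_id}: concentrations must be positive")
            if any(b <= a for a, b in zip(conc, conc[1:])):
                raise ValidationError(
                    f"{self.compound_id}: concentrations must be strictly increasing")

    @property
    def class_label(self) -> ClassLabel:
        return ClassLabel.from_code(self.class_code)

    @property
    def is_experimental(self) -> bool:
        return "experimental" in self.study_flags

    @property
    def is_drug(self) -> bool:
        return self.class_code in (1, 2, 3)


_CONC_RE = re.compile(r"^\s*(?P<body>[^()]*?)\s*(?:\((?P<unit>[^)]+)\))?\s*$")
_UNIT_SCALE = {"um": 1.0, "μm": 1.0, "µm": 1.0, "mm": 1000.0, "nm": 1e-3}


def parse_concentration_cell(cell: str, *, row: int | None = None) -> tuple[float, ...]:
    """Parse a comma-separated concentration cell with a trailing unit tag.

    Values are returned in micromolar, sorted ascending.  Cells that are empty
    or "NA" yield an empty tuple (computational-only structures).
    """
    cell = (cell or "").strip()
    if not cell or cell.upper() == "NA":
        return ()
    m = _CONC_RE.match(cell)
    unit = (m.group("unit") or "uM").strip().lower() if m else "um"
    scale = _UNIT_SCALE.get(unit)
    if scale is None:
        raise FormatError(f"row {row}: unknown concentration unit {unit!r}")
    values = []
    for tok in (m.group("body") if m else cell).split(","):
        tok = tok.strip()
        if not tok:
            continue
        try:
            values.append(float(tok) * scale)
        except ValueError as exc:
            raise FormatError(f"row {row}: unparseable concentration token {tok!r}") from exc
    return tuple(sorted(values))


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table CSV into records.

    Rows whose study type is computational only ("C") get empty concentration
    lists; experimental rows must carry a parseable, positive concentration
    series.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in REQUIRED_COLUMNS:
            if col not in header:
                raise FormatError(f"compound table is missing required column {col!r}")
        records: list[CompoundRecord] = []
        for i, row in enumerate(reader, start=2):
            flags = set()
            for tag in (row.get("study_type") or "").replace(";", ",").split(","):
                tag = tag.strip().upper()
                if tag == "E":
                    flags.add("experimental")
                elif tag == "C":
                    flags.add("computational")
            conc = parse_concentration_cell(row.get("tested_concentrations") or "", row=i)
            if "experimental" not in flags:
                conc = conc if conc else ()
            try:
                records.append(CompoundRecord(
                    compound_id=row["compound_id"].strip(),
                    name=(row.get("name") or "").strip(),
                    class_code=int(row["class_code"]),
                    tested_concentrations=conc,
                    solvent=(row.get("solvent") or "").strip(),
                    study_flags=frozenset(flags),
                    stereo_note=(row.get("stereo_note") or "").strip() or None,
                ))
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"row {i}: {exc}") from exc
    return records


def study_compound_table() -> list[CompoundRecord]:
    """The packaged study compound table (drugs, stereoisomers, counterions)."""
    ref = importlib.resources.files("phenobar.data").joinpath("study_compounds.csv")
    with importlib.resources.as_file(ref) as path:
        return read_compound_table(path)


def experimental_drugs(records: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """The experimentally screened drugs (classes 1-3), excluding counterions."""
    return [r for r in records if r.is_drug and r.is_experimental]


def experimental_counterions(records: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    return [r for r in records if r.class_code == 4 and r.is_experimental]


def merge_2d_equivalents(
    records: Sequence[CompoundRecord],
    equivalence: Mapping[str, str] | None = None,
) -> list[CompoundRecord]:
    """Collapse stereoisomer records onto their canonical 2D structure.

    ``equivalence`` maps stereoisomer IDs to the canonical ID.  The canonical
    record is kept; merged sources disappear.  Counterions are never touched.
    Chained mappings (A->B while B is itself mapped) are rejected.
    """
    equivalence = DEFAULT_2D_EQUIVALENCE if equivalence is None else dict(equivalence)
    ids = {r.compound_id for r in records}
    for src, dst in equivalence.items():
        if dst in equivalence:
            raise ValidationError(f"non-canonical equivalence target {dst!r} (chained mapping)")
        if dst not in ids:
            raise ValidationError(f"equivalence target {dst!r} absent from records")
    merged = []
    for r in records:
        if r.compound_id in equivalence and r.compound_id in ids and r.class_code != 4:
            log.info("2D merge: %s -> %s", r.compound_id, equivalence[r.compound_id])
            continue
        merged.append(r)
    return merged


def expand_3d_stereoisomers(
    records: Sequence[CompoundRecord],
    racemic_ids: Sequence[str],
    isomer_codes: Mapping[str, tuple[str, str]] | None = None,
) -> list[CompoundRecord]:
    """Replace each racemic drug record by its two enantiomer records (3D view)."""
    isomer_codes = DEFAULT_RACEMIC_ISOMERS if isomer_codes is None else dict(isomer_codes)
    ids = {r.compound_id for r in records}
    for rid in racemic_ids:
        if rid not in ids:
            raise ValidationError(f"racemic id {rid!r} not found in records")
    out: list[CompoundRecord] = []
    for r in records:
        if r.compound_id in racemic_ids:
            codes = isomer_codes.get(r.compound_id) or (f"{r.compound_id}A", f"{r.compound_id}B")
            for code, hand in zip(codes, ("R", "S")):
                out.append(replace(
                    r, compound_id=code,
                    name=f"({hand})-isomer of {r.compound_id}",
                    stereo_note=f"isomer-of:{r.compound_id}"))
        else:
            out.append(r)
    return out


def validate_compounds(records: Sequence[CompoundRecord]) -> tuple[dict[str, int], list[str]]:
    """Per-class counts plus consistency warnings for a compound table."""
    counts: dict[str, int] = {lab.name: 0 for lab in ClassLabel}
    for r in records:
        counts[r.class_label.name] += 1
    warnings = []
    n_ci = len(experimental_counterions(records))
    if n_ci == 4:
        warnings.append(
            "4 experimental counterions present; the computational 2D/3D descriptor "
            "sets are described with 5 counterions (identity of the fifth not listed)")
    dup = {r.compound_id for r in records if
           sum(1 for q in records if q.compound_id == r.compound_id) > 1}
    if dup:
        warnings.append(f"duplicate compound ids: {sorted(dup)}")
    return counts, warnings
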