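"""Phenotypic barcodes: per-concentration vectors and right-aligned master barcodes.

A concentration barcode is a fixed-order 13-vector over the screen endpoints:
the control-corrected incidence (percent) for binary endpoints and the median
per-animal normalized response for continuous endpoints.  Each chemical's
master barcode concatenates its concentration barcodes in relative (rank)
order, right-aligned at the highest tested concentration and truncated to the
top five levels; untested lower blocks are zero-filled, zero standing for "no
effect".  A companion mask records which entries were actually measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .compounds import ClassLabel
from .endpoints import (BARCODE_ORDER, EndpointDefinition, NormalizedResponse,
                        default_endpoint_registry)
from .errors import ValidationError
from .matrix import FeatureMatrix
from .screen import SHAPE_CATEGORIES

log = logging.getLogger(__name__)

#: barcode codes for the optional specific shape-class incidences
SHAPE_CODES: dict[str, str] = {
    "shape_contraction": "SHC",
    "shape_c_shape": "SHS",
    "shape_corkscrew": "SHK",
    "shape_pharynx_extrusion": "SHP2",
    "shape_hyperkinesis": "SHH",
}


def _endpoint_order(registry: Sequence[EndpointDefinition],
                    include_shapes: bool) -> list[tuple[str, str]]:
    """(endpoint name, code) pairs in canonical barcode order."""
    by_code = {e.code: e.name for e in registry}
    order = [(by_code[c], c) for c in BARCODE_ORDER if c in by_code]
    if include_shapes:
        order += [(f"shape_{cat}", SHAPE_CODES[f"shape_{cat}"]) for cat in SHAPE_CATEGORIES]
    return order


@dataclass
class ConcentrationBarcode:
    chemical_id: str
    concentration: float
    values: np.ndarray
    measured: np.ndarray  # False where the endpoint was missing (filled with 0)
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.codes):
            raise ValidationError("barcode length must match the endpoint order")


@dataclass
class MasterBarcode:
    chemical_id: str
    class_label: ClassLabel | None
    column_labels: list[str]
    values: np.ndarray
    measured: np.ndarray


def concentration_barcode(
    responses: Iterable[NormalizedResponse],
    registry: Sequence[EndpointDefinition] | None = None,
    *,
    include_shapes: bool = False,
) -> ConcentrationBarcode:
    """Compile one chemical-concentration's responses into a barcode vector."""
    registry = list(registry) if registry is not None else default_endpoint_registry()
    order = _endpoint_order(registry, include_shapes)
    known = {name for name, _ in order}
    rows = list(responses)
    if not rows:
        raise ValidationError("no responses supplied")
    chems = {r.chemical_id for r in rows}
    concs = {r.concentration for r in rows}
    if len(chems) != 1 or len(concs) != 1:
        raise ValidationError("responses must belong to one chemical and one level")
    for r in rows:
        if r.endpoint not in known:
            raise ValidationError(f"unknown endpoint name {r.endpoint!r}")
    defs = {e.name: e for e in registry}
    values = np.zeros(len(order))
    measured = np.zeros(len(order), dtype=bool)
    by_endpoint: dict[str, list[NormalizedResponse]] = {}
    for r in rows:
        by_endpoint.setdefault(r.endpoint, []).append(r)
    for i, (name, _code) in enumerate(order):
        got = by_endpoint.get(name)
        if not got:
            continue
        kind = defs[name].kind if name in defs else "binary"
        if kind == "continuous":
            values[i] = float(np.median([r.value for r in got]))
        else:
            values[i] = got[0].value
        measured[i] = True
    if not measured.all():
        log.debug("%s @ %g uM: %d endpoints missing, filled with 0",
                  rows[0].chemical_id, rows[0].concentration, int((~measured).sum()))
    return ConcentrationBarcode(rows[0].chemical_id, rows[0].concentration,
                                values, measured, tuple(c for _, c in order))


def master_barcode(
    level_barcodes: Sequence[ConcentrationBarcode],
    max_levels: int = 5,
    *,
    class_label: ClassLabel | None = None,
    top_level_index: int | None = None,
) -> MasterBarcode:
    """Right-aligned, truncated concatenation of per-level barcodes.

    Levels are sorted ascending and only the highest ``max_levels`` retained;
    chemicals tested at fewer levels get zero-filled lower blocks.  Column
    labels are ``CODE_<relative level>``; ``top_level_index`` sets the label
    of the top block (defaults to ``max_levels``) so labels can be aligned on
    a study-wide relative scale.
    """
    if not level_barcodes:
        raise ValidationError("at least one concentration barcode is required")
    codes = level_barcodes[0].codes
    if any(b.codes != codes for b in level_barcodes):
        raise ValidationError("level barcodes use different endpoint orders")
    bars = sorted(level_barcodes, key=lambda b: b.concentration)
    if len({b.concentration for b in bars}) != len(bars):
        raise ValidationError("duplicate concentration levels")
    bars = bars[-max_levels:]  # keep the highest levels, ascending
    n_ep = len(codes)
    values = np.zeros(n_ep * max_levels)
    measured = np.zeros(n_ep * max_levels, dtype=bool)
    offset = max_levels - len(bars)  # zero blocks for untested lower levels
    for k, b in enumerate(bars):
        sl = slice((offset + k) * n_ep, (offset + k + 1) * n_ep)
        values[sl] = b.values
        measured[sl] = b.measured
    top = top_level_index if top_level_index is not None else max_levels
    labels = [f"{c}_{top - max_levels + 1 + blk}"
              for blk in range(max_levels) for c in codes]
    return MasterBarcode(bars[0].chemical_id, class_label, labels, values, measured)


def barcode_matrix(
    normalized: Iterable[NormalizedResponse],
    class_labels: Mapping[str, ClassLabel],
    registry: Sequence[EndpointDefinition] | None = None,
    max_levels: int = 5,
    *,
    include_shapes: bool = False,
    drop_ids: Iterable[str] = (),
) -> FeatureMatrix:
    """Assemble master barcodes for all chemicals into a FeatureMatrix.

    Rows are ordered by class then chemical ID.  ``drop_ids`` removes
    chemicals (e.g. those with no active endpoint anywhere) with a log entry.
    Top-block labels use the study-wide maximum number of tested levels, so a
    chemical tested at 12 levels puts its top block at relative level 12.
    """
    registry = list(registry) if registry is not None else default_endpoint_registry()
    rows: dict[str, dict[float, list[NormalizedResponse]]] = {}
    for r in normalized:
        if r.concentration > 0:
            rows.setdefault(r.chemical_id, {}).setdefault(r.concentration, []).append(r)
    drop = set(drop_ids)
    for d in drop & rows.keys():
        log.info("barcode matrix: dropping inactive chemical %s", d)
    chems = [c for c in rows if c not in drop]
    if not chems:
        raise ValidationError("no chemicals left to assemble")
    global_levels = max(len(v) for v in rows.values())
    top_index = max(global_levels, max_levels)
    masters = []
    for chem in chems:
        bars = [concentration_barcode(grp, registry, include_shapes=include_shapes)
                for _conc, grp in sorted(rows[chem].items())]
        masters.append(master_barcode(bars, max_levels,
                                      class_label=class_labels.get(chem),
                                      top_level_index=top_index))
    labels0 = masters[0].column_labels
    if any(m.column_labels != labels0 for m in masters):
        raise ValidationError("master barcodes have mismatched column labels")
    masters.sort(key=lambda m: (m.class_label.code if m.class_label else 99,
                                m.chemical_id))
    return FeatureMatrix(
        row_ids=[m.chemical_id for m in masters],
        column_names=list(labels0),
        values=np.vstack([m.values for m in masters]),
        class_labels=[m.class_label for m in masters] if
        all(m.class_label is not None for m in masters) else None,
        provenance="behavioral",
    )
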