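"""Endpoint registry and normalization of raw well observations.

The screen scores 13 endpoints: five binary incidences (crawl-out, stickiness,
any abnormal body shape, failed phototaxis, failed scrunching) and eight
continuous locomotor/behavioral measures.  Continuous responses are normalized
per animal against the median of the in-plate vehicle controls, either as a
percent ratio ((chemical/vehicle)*100-100), a percent difference
((chemical-vehicle)*100, for fraction-of-time endpoints) or a raw difference
(locomotor burst counts).  Binary incidences are pooled over the replicate
plates and corrected by the control incidence; negative corrected incidences
are clipped to zero.  Each endpoint carries a benchmark response (BMR), the
noise threshold a response must exceed to count as an effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

from .errors import ComputationError, ValidationError
from .screen import WellObservation

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EndpointDefinition:
    name: str
    code: str  # 3-letter barcode code
    kind: str  # "binary" | "continuous"
    normalization: str  # "ratio_pct" | "diff_pct" | "diff_raw" | "none" | "incidence"
    direction: str  # "+", "-", or "both"
    bmr: float  # benchmark response, percent (or raw units for diff_raw)
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValidationError(f"{self.name}: bad kind {self.kind!r}")
        if self.kind == "binary" and self.normalization not in ("none", "incidence"):
            raise ValidationError(f"{self.name}: binary endpoints use none/incidence")
        if self.bmr <= 0:
            raise ValidationError(f"{self.name}: BMR must be positive")


def default_endpoint_registry() -> list[EndpointDefinition]:
    """The 13 screen endpoints with their normalization modes, directions and BMRs."""
    E = EndpointDefinition
    return [
        E("crawl_out", "CRO", "binary", "none", "+", 25,
          "% animals that crawled out of the water (raw incidence)"),
        E("stickiness", "STK", "binary", "incidence", "+", 25, "% stuck individuals"),
        E("shape_any", "SHP", "binary", "incidence", "+", 25,
          "% individuals with any abnormal body shape"),
        E("scrunching", "SCR", "binary", "incidence", "+", 30,
          "% animals that did not scrunch under noxious heat"),
        E("phototaxis", "PTX", "binary", "incidence", "+", 35,
          "% animals that did not phototax"),
        E("anxiety", "ANX", "continuous", "ratio_pct", "-", 30,
          "fraction of time in the outer region of the well"),
        E("resting_dark", "RSD", "continuous", "diff_pct", "+", 60,
          "fraction of time resting in the 2nd dark cycle"),
        E("resting_blue", "RSB", "continuous", "diff_pct", "+", 35,
          "fraction of time resting in the 2nd blue cycle"),
        E("speed_dark", "SPD", "continuous", "ratio_pct", "-", 60,
          "mean speed in the 2nd dark cycle"),
        E("speed_blue1", "SB1", "continuous", "ratio_pct", "-", 80,
          "mean speed in the 1st 30 s of the blue cycle"),
        E("speed_blue2", "SB2", "continuous", "ratio_pct", "-", 70,
          "mean speed in the 2nd 30 s of the blue cycle"),
        E("locomotor_bursts", "LBT", "continuous", "diff_raw", "+", 20,
          "total locomotor bursts in the phototaxis assay"),
        E("noxious_stimuli", "NSS", "continuous", "ratio_pct", "-", 55,
          "median displacement at the end of noxious heat"),
    ]


#: canonical barcode endpoint order (codes)
BARCODE_ORDER = ("CRO", "STK", "SHP", "SCR", "PTX", "ANX", "RSD", "RSB",
                 "SPD", "SB1", "SB2", "LBT", "NSS")


def registry_by_name(registry: Sequence[EndpointDefinition]) -> dict[str, EndpointDefinition]:
    return {e.name: e for e in registry}


def normalize_continuous(raw_value: float, vehicle_median: float, mode: str,
                         *, context: str = "") -> float:
    """Normalize one continuous readout against the in-plate vehicle median."""
    if mode == "ratio_pct":
        if vehicle_median == 0:
            raise ComputationError(
                f"vehicle median is 0 under ratio_pct normalization ({context})")
        return (raw_value / vehicle_median) * 100.0 - 100.0
    if mode == "diff_pct":
        return (raw_value - vehicle_median) * 100.0
    if mode == "diff_raw":
        return raw_value - vehicle_median
    raise ValidationError(f"unknown normalization mode {mode!r}")


def normalize_binary(affected: int, total: int,
                     control_affected: int, control_total: int) -> float | None:
    """Control-corrected incidence rate in percent.

    The control incidence count is scaled by ``total/control_total`` before
    subtraction so the rule stays well-defined when exclusions unbalance the
    denominators; negative corrected counts are set to 0.  Returns None when
    no animal remains.
    """
    if total == 0:
        return None
    if not (0 <= affected <= total):
        raise ValidationError("need 0 <= affected <= total")
    if control_total <= 0:
        raise ValidationError("control_total must be positive")
    scale = total / control_total
    if not math.isclose(scale, 1.0):
        log.debug("binary normalization scaling control count by %.3f", scale)
    adjusted = affected - control_affected * scale
    if adjusted < 0:
        log.debug("negative corrected incidence (%.2f) clipped to 0", adjusted)
        adjusted = 0.0
    return adjusted / total * 100.0


@dataclass(frozen=True)
class NormalizedResponse:
    """One normalized response: per animal (continuous) or per level (binary)."""

    chemical_id: str
    endpoint: str
    concentration: float
    value: float
    n_included: int
    plate_id: str | None = None
    affected: int | None = None
    total: int | None = None


def normalize_screen(
    wells: Iterable[WellObservation],
    registry: Sequence[EndpointDefinition] | None = None,
    *,
    binary_pooling: str = "pooled",
    include_controls: bool = False,
    include_shape_categories: bool = False,
) -> list[NormalizedResponse]:
    """Normalize a whole screen against its in-plate vehicle controls.

    Continuous endpoints are normalized per animal against the vehicle median
    of the same plate.  Binary endpoints are pooled across replicate plates
    (counts summed, denominator ~24 in the default design) and then corrected
    by the pooled control incidence; ``binary_pooling="per_plate"`` corrects
    per plate before pooling instead.  Wells excluded from an endpoint (e.g.
    after crawl-out) are omitted and shrink ``n_included``.
    """
    registry = list(registry) if registry is not None else default_endpoint_registry()
    if binary_pooling not in ("pooled", "per_plate"):
        raise ValidationError(f"unknown binary_pooling {binary_pooling!r}")
    wells = list(wells)
    out: list[NormalizedResponse] = []

    continuous = [e for e in registry if e.kind == "continuous"]
    binary = [e for e in registry if e.kind == "binary"]

    # --- continuous: per-plate vehicle medians -----------------------------
    plates: dict[str, list[WellObservation]] = {}
    for w in wells:
        plates.setdefault(w.plate_id, []).append(w)

    vehicle_median: dict[tuple[str, str], float] = {}
    for pid, pw in plates.items():
        for e in continuous:
            ctrl = [w.continuous[e.name] for w in pw
                    if w.concentration == 0 and w.included(e.name) and e.name in w.continuous]
            if not ctrl:
                raise ComputationError(
                    f"plate {pid}: no usable vehicle controls for endpoint {e.name}")
            vehicle_median[(pid, e.name)] = median(ctrl)

    # group continuous rows to count inclusions per (chemical, endpoint, level)
    cont_rows: dict[tuple[str, str, float], list[tuple[str, float]]] = {}
    for w in wells:
        for e in continuous:
            if not w.included(e.name) or e.name not in w.continuous:
                continue
            if w.concentration == 0 and not include_controls:
                continue
            v = normalize_continuous(
                w.continuous[e.name], vehicle_median[(w.plate_id, e.name)],
                e.normalization, context=f"plate {w.plate_id}, endpoint {e.name}")
            cont_rows.setdefault((w.chemical_id, e.name, w.concentration), []).append(
                (w.plate_id, v))
    for (chem, name, conc), vals in cont_rows.items():
        n = len(vals)
        for pid, v in vals:
            out.append(NormalizedResponse(chem, name, conc, v, n, plate_id=pid))

    # --- binary: pool counts across replicate plates -----------------------
    by_chem: dict[str, list[WellObservation]] = {}
    for w in wells:
        by_chem.setdefault(w.chemical_id, []).append(w)

    # (output name, exclusion-gate endpoint, corrected?, affected predicate)
    specs: list[tuple[str, str, bool, object]] = []
    for e in binary:
        specs.append((e.name, e.name, e.normalization != "none",
                      lambda w, n=e.name: bool(w.binary.get(n))))
    if include_shape_categories:
        from .screen import SHAPE_CATEGORIES
        for cat in SHAPE_CATEGORIES:
            specs.append((f"shape_{cat}", "shape_any", True,
                          lambda w, c=cat: c in w.shape_categories))

    for chem, cw in by_chem.items():
        levels = sorted({w.concentration for w in cw if w.concentration > 0})
        for name, gate, corrected, hit in specs:
            for conc in levels:
                treated = [w for w in cw if w.concentration == conc and w.included(gate)]
                if not corrected:  # crawl-out: raw incidence
                    total = len(treated)
                    if total == 0:
                        continue
                    affected = sum(hit(w) for w in treated)
                    out.append(NormalizedResponse(chem, name, conc,
                                                  affected / total * 100.0, total,
                                                  affected=affected, total=total))
                    continue
                ctrl = [w for w in cw if w.concentration == 0 and w.included(gate)]
                if not ctrl:
                    raise ComputationError(
                        f"chemical {chem}: no usable vehicle controls for {name}")
                if binary_pooling == "pooled":
                    total = len(treated)
                    affected = sum(hit(w) for w in treated)
                    value = normalize_binary(affected, total,
                                             sum(hit(w) for w in ctrl), len(ctrl))
                else:
                    adj, total, affected = 0.0, 0, 0
                    for pid in sorted({w.plate_id for w in treated}):
                        tp = [w for w in treated if w.plate_id == pid]
                        cp = [w for w in ctrl if w.plate_id == pid]
                        if not cp:
                            raise ComputationError(
                                f"plate {pid}: no usable vehicle controls for {name}")
                        a = sum(hit(w) for w in tp)
                        v = normalize_binary(a, len(tp), sum(hit(w) for w in cp), len(cp))
                        if v is not None:
                            adj += v / 100.0 * len(tp)
                        total += len(tp)
                        affected += a
                    value = adj / total * 100.0 if total else None
                if value is None:
                    continue
                out.append(NormalizedResponse(chem, name, conc, value,
                                              len(treated), affected=affected,
                                              total=len(treated)))
    return out
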