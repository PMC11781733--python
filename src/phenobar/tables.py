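"""CSV serialization for the intermediate pipeline tables.

All pipeline artifacts are plain CSV so runs can be inspected and diffed:
wells (one row per planarian-well), normalized responses (tidy long format)
and BMC results (one row per chemical/endpoint/direction).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bmc import BMCResult
from .endpoints import NormalizedResponse, default_endpoint_registry
from .errors import FormatError
from .screen import WellObservation


def wells_to_frame(wells: Sequence[WellObservation]) -> pd.DataFrame:
    registry = default_endpoint_registry()
    cont = [e.name for e in registry if e.kind == "continuous"]
    binr = [e.name for e in registry if e.kind == "binary"]
    rows = []
    for w in wells:
        row = {"chemical_id": w.chemical_id, "plate": w.plate_id, "well": w.well_id,
               "concentration_uM": w.concentration}
        for name in cont:
            row[name] = w.continuous.get(name, np.nan)
        for name in binr:
            v = w.binary.get(name)
            row[name] = "" if v is None else int(v)
        row["shape_categories"] = ";".join(sorted(w.shape_categories))
        row["excluded_from"] = ";".join(sorted(w.excluded_from))
        rows.append(row)
    return pd.DataFrame(rows)


def wells_to_csv(wells: Sequence[WellObservation], path: str | Path) -> None:
    wells_to_frame(wells).to_csv(path, index=False)


def wells_from_csv(path: str | Path) -> list[WellObservation]:
    df = pd.read_csv(path, keep_default_na=False, na_values=["NA"])
    registry = default_endpoint_registry()
    cont = [e.name for e in registry if e.kind == "continuous"]
    binr = [e.name for e in registry if e.kind == "binary"]
    missing = {"chemical_id", "plate", "well", "concentration_uM"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    wells = []
    for _, r in df.iterrows():
        continuous = {n: float(r[n]) for n in cont
                      if n in df.columns and r[n] != "" and pd.notna(r[n])}
        binary = {n: bool(int(r[n])) for n in binr
                  if n in df.columns and r[n] != "" and pd.notna(r[n])}
        shapes = frozenset(s for s in str(r.get("shape_categories", "")).split(";") if s)
        excluded = frozenset(s for s in str(r.get("excluded_from", "")).split(";") if s)
        wells.append(WellObservation(
            chemical_id=r["chemical_id"], plate_id=r["plate"], well_id=str(r["well"]),
            concentration=float(r["concentration_uM"]), continuous=continuous,
            binary=binary, shape_categories=shapes, excluded_from=excluded))
    return wells


def normalized_to_csv(rows: Iterable[NormalizedResponse], path: str | Path) -> None:
    pd.DataFrame([{
        "chemical_id": r.chemical_id, "endpoint": r.endpoint,
        "concentration_uM": r.concentration, "value": r.value,
        "n_included": r.n_included, "plate": r.plate_id or "",
        "affected": "" if r.affected is None else r.affected,
        "total": "" if r.total is None else r.total,
    } for r in rows]).to_csv(path, index=False)


def normalized_from_csv(path: str | Path) -> list[NormalizedResponse]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(NormalizedResponse(
            chemical_id=r["chemical_id"], endpoint=r["endpoint"],
            concentration=float(r["concentration_uM"]), value=float(r["value"]),
            n_included=int(r["n_included"]),
            plate_id=str(r["plate"]) or None,
            affected=None if r["affected"] == "" else int(float(r["affected"])),
            total=None if r["total"] == "" else int(float(r["total"]))))
    return out


def bmc_to_frame(results: Iterable[BMCResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chemical_id": r.chemical_id, "endpoint": r.endpoint, "direction": r.direction,
        "bmr": r.bmr_used,
        "bmc_median_uM": "" if r.bmc_median is None else r.bmc_median,
        "ci5_uM": "" if r.ci_lower_5th is None else r.ci_lower_5th,
        "ci95_uM": "" if r.ci_upper_95th is None else r.ci_upper_95th,
        "n_boot": r.n_boot, "fraction_active_boots": r.fraction_active_boots,
        "status": "active" if r.active else "inactive",
        "clamped": int(r.clamped),
    } for r in results])


def bmc_to_csv(results: Iterable[BMCResult], path: str | Path) -> None:
    bmc_to_frame(results).to_csv(path, index=False)
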