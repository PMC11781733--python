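"""Benchmark-response and benchmark-concentration estimation.

The benchmark response (BMR) is the noise threshold a normalized response must
exceed to count as an effect; when not fixed by the endpoint registry it falls
back to the 5th (decreasing effects) or 95th (increasing effects) percentile
of the normalized vehicle-control distribution.  The benchmark concentration
(BMC) is the lowest concentration at which the modeled concentration-response
curve exceeds the BMR.  Uncertainty is quantified by bootstrap: each of
``n_boot`` resampled curves (replicates resampled within level for continuous
endpoints, binomial resampling of the pooled incidence for binary endpoints)
is summarized per level, and its first BMR crossing is located by linear
interpolation in log10 concentration.  The chemical-endpoint pair is called
active when at least half the bootstrap curves cross; the median and 5th/95th
percentiles of the active crossings are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .endpoints import EndpointDefinition, NormalizedResponse, default_endpoint_registry
from .errors import ValidationError

log = logging.getLogger(__name__)

ACTIVITY_THRESHOLD = 0.5  # minimum fraction of crossing bootstraps to call activity


@dataclass
class ConcentrationResponseSet:
    """Concentration-response data for one chemical-endpoint pair."""

    chemical_id: str
    endpoint: str
    levels: np.ndarray  # ascending, uM
    replicates: list[np.ndarray] | None = None  # continuous: per-level values
    incidence: list[tuple[float, int]] | None = None  # binary: (affected, total)
    direction: str = "+"

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.size < 2:
            raise ValidationError(f"{self.chemical_id}/{self.endpoint}: need >= 2 levels")
        if np.any(np.diff(self.levels) <= 0):
            raise ValidationError(f"{self.chemical_id}/{self.endpoint}: unordered levels")
        if (self.replicates is None) == (self.incidence is None):
            raise ValidationError("exactly one of replicates/incidence must be given")


@dataclass(frozen=True)
class BMCResult:
    chemical_id: str
    endpoint: str
    direction: str
    bmr_used: float
    bmc_median: float | None  # uM; None when inactive
    ci_lower_5th: float | None
    ci_upper_95th: float | None
    n_boot: int
    fraction_active_boots: float
    clamped: bool = False  # crossing below the lowest tested level

    @property
    def active(self) -> bool:
        return self.bmc_median is not None


def fallback_bmr(vehicle_values: Sequence[float], direction: str,
                 *, min_n: int = 20) -> float:
    """Percentile fallback BMR from normalized vehicle-control responses.

    Direction "+" takes the 95th percentile, "-" the magnitude of the 5th;
    the result is a non-negative magnitude (0 flags a degenerate control set).
    """
    values = np.asarray(vehicle_values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < min_n:
        raise ValidationError(f"need >= {min_n} vehicle-control values, got {values.size}")
    if direction == "+":
        out = float(np.percentile(values, 95))
    elif direction == "-":
        out = float(-np.percentile(values, 5))
    else:
        raise ValidationError(f"direction must be '+' or '-', got {direction!r}")
    if out <= 0:
        log.warning("degenerate fallback BMR (%.3g) for direction %s", out, direction)
        return 0.0
    return out


def estimate_bmc(crs: ConcentrationResponseSet, bmr: float,
                 n_boot: int = 1000, *, seed: int) -> BMCResult:
    """Bootstrap BMC estimate for one chemical-endpoint-direction triple."""
    if bmr <= 0:
        raise ValidationError("bmr must be positive")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    levels = crs.levels
    n_levels = levels.size
    summaries = np.empty((n_boot, n_levels))
    if crs.replicates is not None:
        if len(crs.replicates) != n_levels:
            raise ValidationError("replicates must align with levels")
        for j, vals in enumerate(crs.replicates):
            v = np.asarray(vals, dtype=float)
            if v.size == 0:
                raise ValidationError(f"level {levels[j]}: no replicates")
            idx = rng.integers(0, v.size, size=(n_boot, v.size))
            summaries[:, j] = np.median(v[idx], axis=1)
    else:
        assert crs.incidence is not None
        if len(crs.incidence) != n_levels:
            raise ValidationError("incidence pairs must align with levels")
        for j, (affected, total) in enumerate(crs.incidence):
            if total <= 0:
                raise ValidationError(f"level {levels[j]}: empty denominator")
            p = min(max(affected / total, 0.0), 1.0)
            summaries[:, j] = rng.binomial(total, p, size=n_boot) / total * 100.0

    sign = 1.0 if crs.direction == "+" else -1.0
    effect = sign * summaries
    crossed = effect >= bmr
    has_crossing = crossed.any(axis=1)
    first = np.argmax(crossed, axis=1)

    log_levels = np.log10(levels)
    log_bmc = np.full(n_boot, np.nan)
    clamped = has_crossing & (first == 0)
    log_bmc[clamped] = log_levels[0]  # crossing below the lowest tested level
    interp = has_crossing & (first > 0)
    if interp.any():
        i = first[interp]
        rows = np.nonzero(interp)[0]
        e_hi = effect[rows, i]
        e_lo = effect[rows, i - 1]
        t = (bmr - e_lo) / (e_hi - e_lo)
        log_bmc[interp] = log_levels[i - 1] + t * (log_levels[i] - log_levels[i - 1])

    frac_active = float(has_crossing.mean())
    if frac_active < ACTIVITY_THRESHOLD:
        return BMCResult(crs.chemical_id, crs.endpoint, crs.direction, bmr,
                         None, None, None, n_boot, frac_active)
    active = log_bmc[has_crossing]
    med, lo, hi = (10.0 ** np.percentile(active, q) for q in (50, 5, 95))
    return BMCResult(crs.chemical_id, crs.endpoint, crs.direction, bmr,
                     float(med), float(lo), float(hi), n_boot, frac_active,
                     clamped=bool(clamped.any()))


def build_response_sets(
    normalized: Iterable[NormalizedResponse],
    registry: Sequence[EndpointDefinition] | None = None,
) -> list[ConcentrationResponseSet]:
    """Group normalized responses into per-(chemical, endpoint) response sets.

    Binary endpoints carry the control-corrected incidence as an equivalent
    (affected, total) pair so the bootstrap can resample it binomially.
    """
    registry = list(registry) if registry is not None else default_endpoint_registry()
    defs = {e.name: e for e in registry}
    grouped: dict[tuple[str, str], dict[float, list[NormalizedResponse]]] = {}
    for r in normalized:
        if r.concentration <= 0:
            continue
        grouped.setdefault((r.chemical_id, r.endpoint), {}).setdefault(
            r.concentration, []).append(r)
    out = []
    for (chem, name), by_level in sorted(grouped.items()):
        e = defs[name]
        levels = np.array(sorted(by_level))
        if levels.size < 2:
            continue
        if e.kind == "continuous":
            reps = [np.array([r.value for r in by_level[l]]) for l in levels]
            out.append(ConcentrationResponseSet(chem, name, levels, replicates=reps,
                                                direction=e.direction))
        else:
            inc = []
            for l in levels:
                r = by_level[l][0]
                inc.append((r.value / 100.0 * r.total, r.total))
            out.append(ConcentrationResponseSet(chem, name, levels, incidence=inc,
                                                direction="+"))
    return out


def bmc_table(
    normalized: Iterable[NormalizedResponse],
    registry: Sequence[EndpointDefinition] | None = None,
    n_boot: int = 1000,
    *,
    seed: int,
) -> list[BMCResult]:
    """BMC results for every chemical x endpoint (both directions for 'both')."""
    registry = list(registry) if registry is not None else default_endpoint_registry()
    defs = {e.name: e for e in registry}
    sets = build_response_sets(normalized, registry)
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(sets)) % (2 ** 31)
    results = []
    k = 0
    for crs in sets:
        e = defs[crs.endpoint]
        directions = ["+", "-"] if e.direction == "both" else [crs.direction]
        for d in directions:
            crs.direction = d
            results.append(estimate_bmc(crs, e.bmr, n_boot, seed=int(seeds[k])))
            k += 1
        k += 2 - len(directions)  # keep the seed stream aligned per response set
    return results


def most_sensitive(results: Iterable[BMCResult]) -> dict[str, BMCResult | None]:
    """Lowest active median BMC per chemical (None when fully inactive)."""
    best: dict[str, BMCResult | None] = {}
    for r in results:
        cur = best.get(r.chemical_id)
        if r.active and (cur is None or r.bmc_median < cur.bmc_median):
            best[r.chemical_id] = r
        else:
            best.setdefault(r.chemical_id, None)
    return best


def active_chemicals(results: Iterable[BMCResult]) -> set[str]:
    return {c for c, r in most_sensitive(results).items() if r is not None}
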