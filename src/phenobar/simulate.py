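"""Synthetic screen generator: the test bed standing in for wet-lab data.

Wells are generated with the triplicate rotated-row plate design and a
Hill-curve dose-response effect model: for a class-specific effect with
maximum ``m``, slope ``h`` and midpoint ``ec50``, the expected effect at
concentration ``c`` is ``m * c**h / (ec50**h + c**h)``.  Continuous readouts
are control noise (normal, clipped to the endpoint's physical range) shifted
by the effect; binary outcomes are Bernoulli draws whose probability moves
from the background rate toward the class maximum along the same Hill curve.
Crawl-out is sampled first and excludes the animal from every other endpoint.
Counterions (class CI) carry no signature and generate pure noise.

Defaults are calibrated so that the 5th/95th-percentile fallback benchmark
responses computed from simulated vehicle controls land near the registry
BMRs, and each drug class perturbs a distinct endpoint subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .compounds import ClassLabel, CompoundRecord
from .errors import ValidationError
from .matrix import FeatureMatrix
from .screen import SHAPE_CATEGORIES, ScreenDesign, WellObservation


@dataclass(frozen=True)
class Effect:
    """One Hill-shaped dose-response effect."""

    ec50: float  # uM
    hill_slope: float
    max_effect: float  # % change (continuous) or max incidence probability (binary)
    direction: str = "+"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ec50) and math.isfinite(self.hill_slope)
                and math.isfinite(self.max_effect)):
            raise ValidationError("non-finite signature parameter")
        if self.hill_slope <= 0 or self.ec50 <= 0:
            raise ValidationError("ec50 and hill_slope must be positive")
        if self.direction == "+" and self.max_effect < 0:
            raise ValidationError("direction '+' requires non-negative max_effect")
        if self.direction == "-" and self.max_effect > 0:
            raise ValidationError("direction '-' requires non-positive max_effect")

    def at(self, concentration: float) -> float:
        """Expected effect at a nominal concentration (0 at c=0)."""
        if concentration <= 0:
            return 0.0
        c_h = concentration ** self.hill_slope
        return self.max_effect * c_h / (self.ec50 ** self.hill_slope + c_h)


@dataclass(frozen=True)
class ClassSignature:
    """Per-class phenotypic signature: which endpoints respond, and how much."""

    continuous: Mapping[str, Effect] = field(default_factory=dict)
    binary: Mapping[str, Effect] = field(default_factory=dict)  # incl. crawl_out
    shapes: Mapping[str, Effect] = field(default_factory=dict)  # specific shape classes


@dataclass(frozen=True)
class ContinuousNoise:
    loc: float
    scale: float
    lo: float = -math.inf
    hi: float = math.inf

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError("noise scale must be positive")


@dataclass(frozen=True)
class NoiseModel:
    continuous: Mapping[str, ContinuousNoise]
    binary_background: Mapping[str, float]
    shape_background: Mapping[str, float]
    crawl_out_background: float = 0.01

    def __post_init__(self) -> None:
        probs = [*self.binary_background.values(), *self.shape_background.values(),
                 self.crawl_out_background]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("probabilities must be in [0, 1]")


def default_noise_model() -> NoiseModel:
    """Control noise whose percentile fallback BMRs bracket the registry values."""
    C = ContinuousNoise
    return NoiseModel(
        continuous={
            "anxiety": C(0.60, 0.110, 0.0, 1.0),
            "resting_dark": C(0.40, 0.370, 0.0, 1.0),
            "resting_blue": C(0.30, 0.210, 0.0, 1.0),
            "speed_dark": C(1.00, 0.365, 0.0),
            "speed_blue1": C(1.30, 0.632, 0.0),
            "speed_blue2": C(1.40, 0.596, 0.0),
            "locomotor_bursts": C(15.0, 12.2, 0.0),
            "noxious_stimuli": C(3.00, 1.00, 0.0),
        },
        binary_background={"stickiness": 0.08, "phototaxis": 0.10, "scrunching": 0.08},
        shape_background={cat: 0.01 for cat in SHAPE_CATEGORIES},
        crawl_out_background=0.01,
    )


def default_class_signatures(ec50: float = 5.0, hill: float = 1.5) -> dict[ClassLabel, ClassSignature]:
    """Distinct per-class endpoint subsets; counterions are pure noise."""
    def eff(m: float, direction: str = "+") -> Effect:
        return Effect(ec50, hill, m, direction)

    return {
        ClassLabel.AD: ClassSignature(
            continuous={"speed_blue2": eff(-85.0, "-")},
            binary={"scrunching": eff(0.75)},
            shapes={"hyperkinesis": eff(0.80)},
        ),
        ClassLabel.AP: ClassSignature(
            continuous={"anxiety": eff(-75.0, "-"), "speed_dark": eff(-85.0, "-")},
            binary={"phototaxis": eff(0.90), "scrunching": eff(0.80)},
            shapes={"contraction": eff(0.50), "c_shape": eff(0.40),
                    "hyperkinesis": eff(0.30)},
        ),
        ClassLabel.AX: ClassSignature(
            continuous={"locomotor_bursts": eff(60.0), "resting_blue": eff(65.0),
                        "noxious_stimuli": eff(-80.0, "-")},
            binary={"scrunching": eff(0.60)},
            shapes={"c_shape": eff(0.40), "hyperkinesis": eff(0.40)},
        ),
        ClassLabel.CI: ClassSignature(),
    }


def _hill_fraction(effect: Effect, c: float) -> float:
    if c <= 0 or effect.max_effect == 0:
        return 0.0
    return effect.at(c) / effect.max_effect


def _sample_well(rng: np.random.Generator, chem: str, plate: str, well: str,
                 conc: float, sig: ClassSignature, noise: NoiseModel) -> WellObservation:
    # crawl-out first: it gates every other endpoint
    p_cro = noise.crawl_out_background
    if "crawl_out" in sig.binary:
        e = sig.binary["crawl_out"]
        p_cro = p_cro + (e.max_effect - p_cro) * _hill_fraction(e, conc)
    crawled = bool(rng.random() < p_cro)
    binary: dict[str, bool] = {"crawl_out": crawled}
    continuous: dict[str, float] = {}
    shapes: frozenset[str] = frozenset()
    excluded: frozenset[str] = frozenset()
    if crawled:
        all_names = (set(noise.continuous) | set(noise.binary_background)
                     | {"shape_any"})
        excluded = frozenset(all_names)
    else:
        for name, cn in noise.continuous.items():
            value = rng.normal(cn.loc, cn.scale)
            eff = sig.continuous.get(name)
            if eff is not None:
                shift = eff.at(conc)
                # express the normalized-percent effect on the raw scale
                if name == "locomotor_bursts":
                    value += shift  # diff_raw endpoint: raw units
                elif name in ("resting_dark", "resting_blue"):
                    value += shift / 100.0  # diff_pct endpoint: fraction of time
                else:
                    value *= 1.0 + shift / 100.0  # ratio_pct endpoint
            value = min(max(value, cn.lo), cn.hi)
            if name == "locomotor_bursts":
                value = float(round(value))
            continuous[name] = value
        for name, bg in noise.binary_background.items():
            p = bg
            eff = sig.binary.get(name)
            if eff is not None:
                p = bg + (eff.max_effect - bg) * _hill_fraction(eff, conc)
            binary[name] = bool(rng.random() < p)
        present = []
        for cat in SHAPE_CATEGORIES:
            p = noise.shape_background.get(cat, 0.0)
            eff = sig.shapes.get(cat)
            if eff is not None:
                p = p + (eff.max_effect - p) * _hill_fraction(eff, conc)
            if rng.random() < p:
                present.append(cat)
        if len(present) > 3:  # an animal is scored for at most three categories
            present = list(rng.choice(present, size=3, replace=False))
        shapes = frozenset(present)
        binary["shape_any"] = bool(shapes)
    return WellObservation(chemical_id=chem, plate_id=plate, well_id=well,
                           concentration=conc, continuous=continuous, binary=binary,
                           shape_categories=shapes, excluded_from=excluded)


def simulate_screen(
    compounds: Sequence[CompoundRecord],
    design: ScreenDesign | None = None,
    signatures: Mapping[ClassLabel, ClassSignature] | None = None,
    noise: NoiseModel | None = None,
    *,
    seed: int,
) -> list[WellObservation]:
    """Simulate well-level observations for a whole screen.

    Each chemical's tested concentrations are chunked into plates of
    ``design.concentration_rows_per_plate`` rows plus a control row, run as
    ``design.replicate_plates`` technical replicates with rotated row order,
    so every concentration yields ``replicate_plates * wells_per_row``
    observations and every plate carries its own vehicle-control row.
    """
    if seed is None:  # pragma: no cover - defends against explicit None
        raise ValidationError("a seed is required; no implicit randomness")
    design = design or ScreenDesign()
    signatures = signatures if signatures is not None else default_class_signatures()
    noise = noise or default_noise_model()
    rng = np.random.default_rng(seed)
    wells: list[WellObservation] = []
    for comp in compounds:
        concs = list(comp.tested_concentrations)
        if not concs:
            raise ValidationError(f"{comp.compound_id}: no tested concentrations")
        sig = signatures.get(comp.class_label, ClassSignature())
        k = design.concentration_rows_per_plate
        for b in range(0, len(concs), k):
            chunk = concs[b:b + k]
            for p in range(design.replicate_plates):
                plate = f"{comp.compound_id}-b{b // k}-p{p}"
                # cyclic row rotation over however many rows this chunk fills
                rows = [chunk[(i + p) % len(chunk)] for i in range(len(chunk))]
                level_rows = ([0.0] if design.control_row_present else []) + rows
                for r, conc in enumerate(level_rows):
                    for wcol in range(design.wells_per_row):
                        wells.append(_sample_well(
                            rng, comp.compound_id, plate, f"{r}{chr(65 + wcol)}",
                            conc, sig, noise))
    return wells


def simulate_descriptor_matrix(
    compounds: Sequence[CompoundRecord],
    n_informative: int = 5,
    n_noise: int = 10,
    n_redundant: int = 2,
    class_separation: float = 3.0,
    *,
    seed: int,
) -> FeatureMatrix:
    """Synthetic descriptor table exercising the culling rules.

    Informative columns are class-conditional Gaussians whose class means are
    ``class_separation`` standard deviations apart; redundant columns are
    near-exact (r >= 0.99) linear transforms of informative ones; one constant
    column and one column non-zero for at most 3 rows are always injected.
    """
    if min(n_informative, n_noise, n_redundant) < 0:
        raise ValidationError("column counts must be non-negative")
    if n_redundant > 0 and n_informative == 0:
        raise ValidationError("redundant columns require informative parents")
    labels = [c.class_label for c in compounds]
    classes = sorted({l.name for l in labels})
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes among compounds")
    rng = np.random.default_rng(seed)
    n = len(compounds)
    class_idx = np.array([classes.index(l.name) for l in labels])

    cols: list[np.ndarray] = []
    names: list[str] = []
    for j in range(n_informative):
        order = rng.permutation(len(classes))
        means = order * class_separation
        cols.append(means[class_idx] + rng.normal(size=n))
        names.append(f"inf_{j + 1}")
    for j in range(n_redundant):
        parent = cols[j % n_informative]
        cols.append(1.7 * parent + 0.3 + rng.normal(scale=0.03 * parent.std(), size=n))
        names.append(f"red_{j + 1}")
    for j in range(n_noise):
        cols.append(rng.normal(size=n))
        names.append(f"noise_{j + 1}")
    const = np.full(n, 3.14)
    sparse = np.zeros(n)
    for i in rng.choice(n, size=min(2, n), replace=False):
        sparse[i] = rng.normal(loc=5.0)
    cols += [const, sparse]
    names += ["const_1", "sparse_1"]
    return FeatureMatrix(row_ids=[c.compound_id for c in compounds],
                         column_names=names, values=np.column_stack(cols),
                         class_labels=labels, provenance="chemical_2d")
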