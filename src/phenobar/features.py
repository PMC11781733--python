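"""Column culling and standardization applied before every classifier.

Two culling passes exist.  The basic pass removes columns that carry no
information at all: non-numeric (all values unparseable), all-zero,
all-missing, singleton (one non-missing value) and constant.  The model pass,
applied on top, additionally removes columns that are identical to an earlier
column, have a coefficient of variation <= 1%, are non-zero for at most three
rows, or are correlated |r| >= 0.98 with an earlier kept column (the earlier
column wins).  Standardization brings every surviving column to mean 0, SD 1
(sample SD), ignoring missing entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ComputationError, ValidationError
from .matrix import FeatureMatrix


@dataclass
class CullingReport:
    removed: list[tuple[str, str]] = field(default_factory=list)
    kept_count: int = 0
    input_count: int = 0
    correlation_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def reasons(self) -> dict[str, str]:
        return dict(self.removed)


def _apply_removal(m: FeatureMatrix, report: CullingReport) -> FeatureMatrix:
    gone = {name for name, _ in report.removed}
    keep = [j for j, c in enumerate(m.column_names) if c not in gone]
    if not keep:
        raise ComputationError("no informative columns remain after culling")
    report.kept_count = len(keep)
    report.input_count = m.n_columns
    return replace(m, column_names=[m.column_names[j] for j in keep],
                   values=m.values[:, keep])


def cull_basic(m: FeatureMatrix) -> tuple[FeatureMatrix, CullingReport]:
    """Remove non-numeric, all-zero, all-missing, singleton and constant columns."""
    report = CullingReport(input_count=m.n_columns, kept_count=m.n_columns)
    for j, name in enumerate(m.column_names):
        col = m.values[:, j]
        finite = col[~np.isnan(col)]
        if finite.size == 0:
            # read_feature_matrix records non-numeric cells as NaN, so an
            # all-NaN column may be either; both are uninformative
            report.removed.append((name, "all_missing"))
        elif finite.size == 1:
            report.removed.append((name, "singleton"))
        elif np.all(finite == 0):
            report.removed.append((name, "all_zero"))
        elif np.all(finite == finite[0]):
            report.removed.append((name, "constant"))
    return _apply_removal(m, report), report


def cull_model_descriptors(
    m: FeatureMatrix,
    cv_max: float = 0.01,
    underrep_max: int = 3,
    r_max: float = 0.98,
) -> tuple[FeatureMatrix, CullingReport]:
    """Model-stage culling: identical / low-CV / under-represented / correlated.

    Runs after :func:`cull_basic`.  CV is SD/|mean|; columns with mean 0 are
    exempt from the CV rule (their CV is undefined).  For a correlated pair
    the later column in input order is removed and the pair is logged.
    """
    m, basic_report = cull_basic(m)
    report = CullingReport(removed=list(basic_report.removed),
                           input_count=basic_report.input_count)
    X = m.values
    removed_idx: set[int] = set()

    for j, name in enumerate(m.column_names):
        col = X[:, j][~np.isnan(X[:, j])]
        mean, sd = col.mean(), col.std(ddof=1)
        if mean != 0 and sd / abs(mean) <= cv_max:
            report.removed.append((name, "low_cv"))
            removed_idx.add(j)
            continue
        nonzero = np.count_nonzero(np.nan_to_num(X[:, j]))
        if 1 <= nonzero <= underrep_max:
            report.removed.append((name, "under_represented"))
            removed_idx.add(j)

    for j in range(m.n_columns):
        if j in removed_idx:
            continue
        for i in range(j):
            if i in removed_idx:
                continue
            a, b = X[:, i], X[:, j]
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 2:
                continue
            if np.array_equal(a[ok], b[ok]):
                report.removed.append((m.column_names[j], "identical"))
                removed_idx.add(j)
                break
            sa, sb = a[ok].std(), b[ok].std()
            if sa == 0 or sb == 0:
                continue
            r = float(np.corrcoef(a[ok], b[ok])[0, 1])
            if abs(r) >= r_max:
                report.removed.append((m.column_names[j], "high_correlation"))
                report.correlation_pairs.append((m.column_names[i], m.column_names[j], r))
                removed_idx.add(j)
                break
    return _apply_removal(m, report), report


def standardize(m: FeatureMatrix) -> FeatureMatrix:
    """Scale every column to mean 0, SD 1 (sample SD), ignoring missing values."""
    X = m.values.copy()
    for j, name in enumerate(m.column_names):
        col = X[:, j]
        finite = col[~np.isnan(col)]
        if finite.size < 2 or np.all(finite == finite[0]):
            raise ValidationError(
                f"column {name!r} is constant; culling must run before standardize")
        mean, sd = finite.mean(), finite.std(ddof=1)
        X[:, j] = (col - mean) / sd
    return replace(m, values=X)
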