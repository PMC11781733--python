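"""Machine-learning classifiers: stratified splits, genetic-algorithm feature
selection, a small neural-net ensemble with verification-set early stopping,
SVMs, nine-indicator evaluation, and parsimony-penalized model ranking.

The ensemble (ANNE) combines single-hidden-layer feed-forward nets.  Each
submodel draws its own random initial weights, splits its training chemicals
into internal training and verification subsets in an approximate 2:1 ratio,
and halts training once the verification-set k-class Youden index stops
improving for a set number of checks.  Submodels are scored as
``verification_J - |verification_J - training_J|`` and the ensemble predicts
by majority vote with a mean-score tie-break.

A battery runs ``n_models`` independent (split, select, train, evaluate)
pipelines from seeds derived from one master seed; models are then ranked by
``S = (J+MCC+Acc)_train + (J+MCC+Acc)_test + 100*N_min/N (+ 100*D_min/D)``
with average-rank ties, which rewards accuracy obtained with few neurons and
few descriptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.svm import SVC

from .compounds import ClassLabel
from .errors import ValidationError
from .matrix import FeatureMatrix
from .metrics import (DEFAULT_CLASS_ORDER, MetricSet, confusion, metric_set)

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# splits

@dataclass(frozen=True)
class SplitSpec:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int


def stratified_split(m: FeatureMatrix, test_count: int | None = None,
                     test_ratio: float | None = None, *, seed: int) -> SplitSpec:
    """Randomized stratified test-set selection by class.

    Per-class test counts are proportional to class sizes with
    largest-remainder rounding (remainder ties go to the larger class, then
    class order); members are drawn uniformly within class.
    """
    if m.class_labels is None:
        raise ValidationError("feature matrix carries no class labels")
    n = m.n_rows
    if test_count is None:
        if test_ratio is None:
            raise ValidationError("give test_count or test_ratio")
        test_count = int(round(test_ratio * n))
    if test_count >= n:
        raise ValidationError("test_count must be below the number of samples")
    rng = np.random.default_rng(seed)
    classes = [c for c in DEFAULT_CLASS_ORDER if c in set(m.class_labels)]
    members = {c: sorted(r for r, l in zip(m.row_ids, m.class_labels) if l is c)
               for c in classes}
    quotas = {c: test_count * len(members[c]) / n for c in classes}
    take = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = test_count - sum(take.values())
    order = sorted(classes, key=lambda c: (-(quotas[c] - take[c]),
                                           -len(members[c]), c.code))
    for c in order[:short]:
        take[c] += 1
    test: list[str] = []
    for c in classes:
        k = min(take[c], len(members[c]))
        if k:
            test += list(rng.choice(members[c], size=k, replace=False))
    test_set = set(test)
    train = tuple(r for r in m.row_ids if r not in test_set)
    return SplitSpec(train, tuple(sorted(test_set)), seed)


# --------------------------------------------------------------------------
# small feed-forward net and ensemble

def _encode(labels: Sequence[ClassLabel],
            class_order: Sequence[ClassLabel]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_order)}
    return np.array([index[l] for l in labels])


def _fast_youden(y_true: np.ndarray, y_pred: np.ndarray, k: int) -> float:
    """k-class macro one-vs-rest Youden on integer-encoded labels, percent."""
    total = y_true.size
    acc = 0.0
    for c in range(k):
        tp = np.sum((y_true == c) & (y_pred == c))
        fn = np.sum(y_true == c) - tp
        fp = np.sum(y_pred == c) - tp
        tn = total - tp - fn - fp
        acc += (tp / (tp + fn) if tp + fn else 0.0)
        acc += (tn / (tn + fp) if tn + fp else 0.0)
    return (acc / k - 1.0) * 100.0


class _TinyNet:
    """Single-hidden-layer net: logistic hidden units, softmax output,
    full-batch Adam on the cross-entropy."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int,
                 rng: np.random.Generator):
        s = 1.0 / np.sqrt(max(n_in, 1))
        self.W1 = rng.normal(scale=s, size=(n_in, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.normal(scale=1.0 / np.sqrt(n_hidden), size=(n_hidden, n_out))
        self.b2 = np.zeros(n_out)
        self._adam = [np.zeros_like(p) for p in (self.W1, self.b1, self.W2, self.b2)
                      for _ in (0, 1)]
        self._t = 0

    def _forward(self, X: np.ndarray):
        H = 1.0 / (1.0 + np.exp(-(X @ self.W1 + self.b1)))
        Z = H @ self.W2 + self.b2
        Z -= Z.max(axis=1, keepdims=True)
        P = np.exp(Z)
        P /= P.sum(axis=1, keepdims=True)
        return H, P

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(X)[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def step(self, X: np.ndarray, Y: np.ndarray, lr: float = 0.05) -> None:
        H, P = self._forward(X)
        n = X.shape[0]
        dZ = (P - Y) / n
        gW2 = H.T @ dZ
        gb2 = dZ.sum(axis=0)
        dH = dZ @ self.W2.T * H * (1 - H)
        gW1 = X.T @ dH
        gb1 = dH.sum(axis=0)
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        params = (self.W1, self.b1, self.W2, self.b2)
        for i, (p, g) in enumerate(zip(params, (gW1, gb1, gW2, gb2))):
            m, v = self._adam[2 * i], self._adam[2 * i + 1]
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mh = m / (1 - b1 ** self._t)
            vh = v / (1 - b2 ** self._t)
            p -= lr * mh / (np.sqrt(vh) + eps)

    def get_weights(self):
        return [p.copy() for p in (self.W1, self.b1, self.W2, self.b2)]

    def set_weights(self, ws):
        self.W1, self.b1, self.W2, self.b2 = [w.copy() for w in ws]


def _internal_split(y: np.ndarray, rng: np.random.Generator,
                    verification_fraction: float = 1 / 3,
                    max_attempts: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Approximate 2:1 training/verification split keeping every class in
    the training part (resampled up to ``max_attempts`` times)."""
    n = y.size
    n_ver = max(1, int(round(n * verification_fraction)))
    classes = np.unique(y)
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        ver, tr = perm[:n_ver], perm[n_ver:]
        if set(classes) <= set(y[tr]) and ver.size and tr.size:
            return tr, ver
    raise ValidationError("could not build an internal split covering every class")


@dataclass
class ANNSubmodel:
    net: _TinyNet
    hidden_size: int
    score: float  # verification J - |verification J - training J|
    training_log: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class ANNEModel:
    submodels: list[ANNSubmodel]
    class_order: tuple
    descriptor_names: tuple[str, ...]

    @property
    def n_neurons(self) -> int:
        return max(s.hidden_size for s in self.submodels)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def predict(self, X: np.ndarray) -> list:
        votes = np.stack([s.net.predict(X) for s in self.submodels])  # (S, n)
        probs = np.mean([s.net.predict_proba(X) for s in self.submodels], axis=0)
        out = []
        for j in range(X.shape[0]):
            counts = np.bincount(votes[:, j], minlength=len(self.class_order))
            best = np.flatnonzero(counts == counts.max())
            if best.size == 1:
                out.append(self.class_order[best[0]])
            else:  # tie-break by mean ensemble score
                out.append(self.class_order[best[np.argmax(probs[j, best])]])
        return out


def train_anne(
    X: np.ndarray,
    labels: Sequence[ClassLabel],
    descriptor_names: Sequence[str],
    *,
    n_submodels: int = 10,
    hidden_sizes: Sequence[int] = (2, 3, 4, 5),
    patience: int = 20,
    max_epochs: int = 300,
    check_every: int = 5,
    seed: int,
) -> ANNEModel:
    """Train a neural-net ensemble with verification-based early stopping."""
    labels = list(labels)
    class_order = tuple(c for c in DEFAULT_CLASS_ORDER if c in set(labels))
    if len(class_order) < 2:
        raise ValidationError("need at least 2 classes")
    if len(labels) < 6:
        raise ValidationError("need at least 6 training samples")
    y = _encode(labels, class_order)
    k = len(class_order)
    Y = np.eye(k)[y]
    rng = np.random.default_rng(seed)
    subs = []
    for _ in range(n_submodels):
        tr, ver = _internal_split(y, rng)
        net = _TinyNet(X.shape[1], int(rng.choice(hidden_sizes)), k, rng)
        best = {"youden": -np.inf, "weights": net.get_weights(), "stall": 0}
        history = []
        for epoch in range(1, max_epochs + 1):
            net.step(X[tr], Y[tr])
            if epoch % check_every:
                continue
            jv = _fast_youden(y[ver], net.predict(X[ver]), k)
            history.append((epoch, jv))
            if jv > best["youden"]:
                best.update(youden=jv, weights=net.get_weights(), stall=0)
            else:
                best["stall"] += 1
                if best["stall"] >= patience:
                    break
        net.set_weights(best["weights"])
        jt = _fast_youden(y[tr], net.predict(X[tr]), k)
        jv = best["youden"] if np.isfinite(best["youden"]) else 0.0
        subs.append(ANNSubmodel(net, net.W1.shape[1], jv - abs(jv - jt), history))
    return ANNEModel(subs, class_order, tuple(descriptor_names))


# --------------------------------------------------------------------------
# SVM

@dataclass
class SVMModel:
    estimator: SVC
    class_order: tuple
    descriptor_names: tuple[str, ...]
    kernel: str
    C: float

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def predict(self, X: np.ndarray) -> list:
        by_str = {str(c): c for c in self.class_order}
        return [by_str[s] for s in self.estimator.predict(X)]


def train_svm(
    X: np.ndarray,
    labels: Sequence[ClassLabel],
    descriptor_names: Sequence[str],
    *,
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
) -> SVMModel:
    """One-vs-one multi-class SVM (deterministic for a fixed seed)."""
    labels = list(labels)
    class_order = tuple(c for c in DEFAULT_CLASS_ORDER if c in set(labels))
    if len(class_order) < 2:
        raise ValidationError("need at least 2 classes")
    est = SVC(kernel=kernel, C=C, random_state=seed)
    est.fit(X, [str(l) for l in labels])
    return SVMModel(est, class_order, tuple(descriptor_names), kernel, C)


# --------------------------------------------------------------------------
# genetic-algorithm descriptor selection

ModelBuilder = Callable[[np.ndarray, Sequence[ClassLabel], Sequence[str], int], object]


def anne_builder(**kwargs) -> ModelBuilder:
    """Builder producing a single fast ANN (used as the GA fitness model)."""
    opts = {"n_submodels": 1, "max_epochs": 150, "patience": 10, **kwargs}

    def build(X, labels, names, seed):
        return train_anne(X, labels, names, seed=seed, **opts)

    return build


def svm_builder(**kwargs) -> ModelBuilder:
    def build(X, labels, names, seed):
        return train_svm(X, labels, names, seed=seed, **kwargs)

    return build


def ga_select(
    m: FeatureMatrix,
    labels: Sequence[ClassLabel],
    model_builder: ModelBuilder,
    *,
    population: int = 16,
    generations: int = 8,
    mutation_rate: float = 0.05,
    subset_cap: int = 10,
    size_penalty: float = 0.5,
    seed: int,
) -> list[str]:
    """Genetic-algorithm descriptor-subset search.

    Chromosomes are binary masks over the culled descriptor columns; fitness
    is the verification-set Youden of the built model minus
    ``size_penalty`` percentage points per selected descriptor.  One elite
    chromosome survives each generation.  Deterministic for a fixed seed.
    """
    if subset_cap < 1:
        raise ValidationError("subset cap must be >= 1")
    labels = list(labels)
    p = m.n_columns
    rng = np.random.default_rng(seed)
    class_order = tuple(c for c in DEFAULT_CLASS_ORDER if c in set(labels))
    y = _encode(labels, class_order)
    tr, ver = _internal_split(y, rng)
    cache: dict[bytes, float] = {}

    def repair(mask: np.ndarray) -> np.ndarray:
        on = np.flatnonzero(mask)
        if on.size == 0:
            mask[rng.integers(p)] = True
        elif on.size > subset_cap:
            off = rng.choice(on, size=on.size - subset_cap, replace=False)
            mask[off] = False
        return mask

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cols = np.flatnonzero(mask)
            names = [m.column_names[j] for j in cols]
            model = model_builder(m.values[np.ix_(tr, cols)],
                                  [labels[i] for i in tr], names,
                                  int(rng.integers(2 ** 31)))
            pred = model.predict(m.values[np.ix_(ver, cols)])
            jv = _fast_youden(y[ver], _encode(pred, class_order), len(class_order))
            cache[key] = jv - size_penalty * cols.size
        return cache[key]

    pop = []
    for _ in range(population):
        mask = np.zeros(p, dtype=bool)
        mask[rng.choice(p, size=int(rng.integers(1, min(subset_cap, p) + 1)),
                        replace=False)] = True
        pop.append(mask)
    scores = np.array([fitness(c) for c in pop])
    for _gen in range(generations):
        elite = pop[int(scores.argmax())].copy()
        children = [elite]
        while len(children) < population:
            pick = [pop[max(a, b, key=lambda i: scores[i])]
                    for a, b in rng.integers(0, population, size=(2, 2))]
            cross = rng.random(p) < 0.5
            child = np.where(cross, pick[0], pick[1])
            child ^= rng.random(p) < mutation_rate
            children.append(repair(child))
        pop = children
        scores = np.array([fitness(c) for c in pop])
    best = pop[int(scores.argmax())]
    return [m.column_names[j] for j in np.flatnonzero(best)]


# --------------------------------------------------------------------------
# evaluation, batteries and ranking

@dataclass
class ModelReport:
    model_id: str
    model_type: str  # "anne" | "svm"
    metrics_train: MetricSet
    metrics_test: MetricSet | None
    metrics_all: MetricSet
    n_neurons: int | None
    n_descriptors: int
    descriptor_names: tuple[str, ...]
    misclassified_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int
    test_covers_all_classes: bool = True


def evaluate(model, split: SplitSpec, m: FeatureMatrix,
             *, model_id: str = "model", seed: int = 0) -> ModelReport:
    """Score a fitted model on the training set, test set and all chemicals."""
    if m.class_labels is None:
        raise ValidationError("feature matrix carries no class labels")
    names = list(model.descriptor_names)
    sub = m.select_columns(names)
    by_id = {r: i for i, r in enumerate(sub.row_ids)}
    labels = {r: m.class_labels[by_id[r]] for r in sub.row_ids}
    classes = tuple(c for c in DEFAULT_CLASS_ORDER if c in set(labels.values()))

    def metrics_for(ids: Sequence[str]) -> tuple[MetricSet, list[str]]:
        idx = [by_id[r] for r in ids]
        pred = model.predict(sub.values[idx])
        true = [labels[r] for r in ids]
        cm = confusion(true, pred, classes)
        wrong = [r for r, t, q in zip(ids, true, pred) if t != q]
        return metric_set(cm), wrong

    mt_train, wrong_train = metrics_for(list(split.train_ids))
    if split.test_ids:
        mt_test, wrong_test = metrics_for(list(split.test_ids))
    else:
        log.info("%s: empty test set, test metrics absent", model_id)
        mt_test, wrong_test = None, []
    mt_all, wrong_all = metrics_for(list(split.train_ids) + list(split.test_ids))
    covered = set(labels[r] for r in split.test_ids) == set(labels.values())
    return ModelReport(
        model_id=model_id,
        model_type="anne" if isinstance(model, ANNEModel) else "svm",
        metrics_train=mt_train, metrics_test=mt_test, metrics_all=mt_all,
        n_neurons=model.n_neurons if isinstance(model, ANNEModel) else None,
        n_descriptors=model.n_descriptors,
        descriptor_names=tuple(model.descriptor_names),
        misclassified_ids=tuple(wrong_all), test_ids=tuple(split.test_ids),
        seed=seed, test_covers_all_classes=covered)


def run_model_battery(
    m: FeatureMatrix,
    model_type: str,
    n_models: int = 10,
    *,
    master_seed: int,
    test_count: int | None = None,
    test_ratio: float = 0.22,
    ga_options: dict | None = None,
    model_options: dict | None = None,
) -> list[ModelReport]:
    """``n_models`` independent split/select/train/evaluate runs.

    Each run uses a distinct seed derived from the master seed, mirroring the
    ten-final-models protocol; the battery is fully reproducible.
    """
    if model_type not in ("anne", "svm"):
        raise ValidationError(f"unknown model type {model_type!r}")
    if m.class_labels is None:
        raise ValidationError("feature matrix carries no class labels")
    seeds = np.random.SeedSequence(master_seed).generate_state(3 * n_models) % (2 ** 31)
    ga_options = dict(ga_options or {})
    model_options = dict(model_options or {})
    reports = []
    for i in range(n_models):
        s_split, s_ga, s_fit = (int(s) for s in seeds[3 * i:3 * i + 3])
        split = stratified_split(m, test_count=test_count,
                                 test_ratio=None if test_count else test_ratio,
                                 seed=s_split)
        train = m.select_rows(list(split.train_ids))
        builder = (anne_builder(**model_options) if model_type == "anne"
                   else svm_builder(**model_options))
        selected = ga_select(train, train.class_labels, builder,
                             seed=s_ga, **ga_options)
        Xtr = train.select_columns(selected).values
        if model_type == "anne":
            model = train_anne(Xtr, train.class_labels, selected, seed=s_fit,
                               **model_options)
        else:
            model = train_svm(Xtr, train.class_labels, selected, seed=s_fit,
                              **model_options)
        reports.append(evaluate(model, split, m,
                                model_id=f"{model_type}_{i + 1:02d}", seed=s_fit))
    return reports


def battery_summary(reports: Sequence[ModelReport]) -> dict[str, tuple[float, float]]:
    """Mean and SE over models for each of the nine indicators."""
    out = {}
    for part in ("train", "test", "all"):
        for name in ("youden_j", "mcc", "accuracy"):
            vals = [getattr(getattr(r, f"metrics_{part}"), name)
                    for r in reports if getattr(r, f"metrics_{part}") is not None]
            if not vals:
                continue
            mean = float(np.mean(vals))
            se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 \
                else float("nan")
            if len(vals) == 1:
                log.info("battery of one model: SE undefined")
            out[f"{part}_{name}"] = (mean, se)
    return out


@dataclass
class RankingTable:
    model_ids: list[str]
    scores: list[float]
    ranks: list[float]
    best_model_id: str
    note: str = ""


def rank_models(reports: Sequence[ModelReport], model_type: str) -> RankingTable:
    """Parsimony-penalized ranking.

    ``S = sum(train J, MCC, Acc) + sum(test J, MCC, Acc) + 100*N_min/N
    (ANNE only) + 100*D_min/D`` with battery minima for N_min and D_min;
    models rank by descending S with average-rank ties.  Models without test
    metrics are excluded with a log entry.
    """
    usable = [r for r in reports if r.metrics_test is not None]
    skipped = [r.model_id for r in reports if r.metrics_test is None]
    if skipped:
        log.info("excluded from ranking (no test metrics): %s", skipped)
    if not usable:
        raise ValidationError("no rankable models")
    d_min = min(r.n_descriptors for r in usable)
    scores = []
    for r in usable:
        s = sum(r.metrics_train.as_dict().values()) + sum(r.metrics_test.as_dict().values())
        if model_type == "anne":
            n_min = min(q.n_neurons for q in usable)
            s += 100.0 * n_min / r.n_neurons
        s += 100.0 * d_min / r.n_descriptors
        scores.append(float(s))
    ranks = rankdata([-s for s in scores], method="average")
    best_i = int(np.argmin(ranks))
    note = ""
    if not usable[best_i].test_covers_all_classes:
        covered = [(rk, r) for rk, r in zip(ranks, usable) if r.test_covers_all_classes]
        if covered:
            alt = min(covered, key=lambda t: t[0])[1]
            note = (f"top-ranked model's test set lacks a class; "
                    f"next-ranked model covering all classes: {alt.model_id}")
    return RankingTable([r.model_id for r in usable], scores, list(map(float, ranks)),
                        usable[best_i].model_id, note)
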