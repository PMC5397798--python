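"""The coreness regressor: logistic transforms of nearest-class distance.

Prediction is two-step: (1) find the nearest training window over all
structured classes under the learned class distances, giving a distance
delta and a nearest class; (2) map delta through a fitted logistic —
f_core (decreasing) if the nearest class is core, f_non (increasing) if it
is structured non-core.  The logistics are fit by nonlinear least squares to
smoothed empirical average-coreness-vs-distance curves, with floor and
ceiling pinned to the observed minimum and maximum average coreness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.metrics import roc_auc_score

from .io import Alignment, SSConfidence, register_model
from .metric import (
    BruteForceIndex,
    DistanceModel,
    batch_nearest_structured,
    build_nn_index,
    nearest_structured,
    stack_profiles,
)
from .windows import (
    Window,
    WindowSets,
    bottom_class,
    core_classes,
    extract_windows,
    structured_classes,
)


@register_model("logistic_transform")
@dataclass
class LogisticTransform:
    """f(x) = kappa + (lambda - kappa) / (1 + exp(-slope * (x - beta))).

    ``kappa`` and ``ceiling`` are the minimum and maximum average-coreness
    values measured on the fitting examples; slope and beta control the
    shape.  A zero slope marks a degenerate (flat) transform.
    """

    kappa: float
    ceiling: float  # lambda in the functional form
    slope: float
    beta: float

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.slope == 0.0:
            out = np.full_like(x, (self.kappa + self.ceiling) / 2.0)
        else:
            out = self.kappa + (self.ceiling - self.kappa) / (
                1.0 + np.exp(-self.slope * (x - self.beta))
            )
        return out if out.shape else float(out)

    @property
    def degenerate(self) -> bool:
        return self.slope == 0.0 or self.kappa == self.ceiling

    def to_json(self) -> dict:
        return {
            "kappa": self.kappa,
            "ceiling": self.ceiling,
            "slope": self.slope,
            "beta": self.beta,
        }

    @classmethod
    def from_json(cls, d: dict) -> "LogisticTransform":
        return cls(d["kappa"], d["ceiling"], d["slope"], d["beta"])


@dataclass
class CurvePoint:
    """One smoothed point of the empirical distance-to-coreness curve."""

    delta: float
    avg_coreness: float


def empirical_curve(
    examples: list[tuple[float, float]], ell: int
) -> list[CurvePoint]:
    """Average true coreness around each distinct observed distance.

    Examples are (distance, true coreness).  At each distinct distance, the
    average runs over all exact ties plus the ``ell`` examples below and the
    ``ell`` above in distance order (truncated at the ends).
    """
    if not examples:
        raise ValueError("no examples to build a curve from")
    if ell < 0:
        raise ValueError("ell must be >= 0")
    arr = sorted(examples)
    deltas = np.array([d for d, _ in arr])
    cors = np.array([c for _, c in arr])
    csum = np.concatenate([[0.0], np.cumsum(cors)])
    points = []
    start = 0
    n = len(arr)
    while start < n:
        stop = start
        while stop < n and deltas[stop] == deltas[start]:
            stop += 1
        lo = max(0, start - ell)
        hi = min(n, stop + ell)
        points.append(
            CurvePoint(float(deltas[start]), float((csum[hi] - csum[lo]) / (hi - lo)))
        )
        start = stop
    return points


def fit_logistic(
    points: list[CurvePoint], orientation: str
) -> LogisticTransform:
    """Least-squares fit of slope and inflection with pinned floor/ceiling.

    ``orientation`` constrains monotonicity: 'decreasing' for the core
    transform, 'increasing' for the non-core transform.
    """
    if orientation not in ("decreasing", "increasing"):
        raise ValueError("orientation must be 'decreasing' or 'increasing'")
    if len(points) < 4:
        raise ValueError("need at least 4 curve points to fit a logistic")
    x = np.array([p.delta for p in points])
    y = np.array([p.avg_coreness for p in points])
    kappa, ceiling = float(y.min()), float(y.max())
    if ceiling - kappa < 1e-12:
        return LogisticTransform(kappa, ceiling, 0.0, float(np.median(x)))

    def f(xx, slope, beta):
        return kappa + (ceiling - kappa) / (1.0 + np.exp(-slope * (xx - beta)))

    span = max(x.max() - x.min(), 1e-9)
    sign = -1.0 if orientation == "decreasing" else 1.0
    bounds = ((-np.inf, -np.inf), (0.0, np.inf)) if sign < 0 else (
        (0.0, -np.inf),
        (np.inf, np.inf),
    )
    try:
        popt, _ = curve_fit(
            f,
            x,
            y,
            p0=(sign * 4.0 / span, float(np.median(x))),
            bounds=bounds,
            maxfev=20000,
        )
    except RuntimeError as exc:
        resid = float(np.sum((f(x, sign * 4.0 / span, np.median(x)) - y) ** 2))
        raise RuntimeError(
            f"logistic fit did not converge (initial residual {resid:.3g})"
        ) from exc
    return LogisticTransform(kappa, ceiling, float(popt[0]), float(popt[1]))


@register_model("coreness_regressor")
@dataclass
class CorenessRegressor:
    """Distance model + per-class training windows + the two transforms."""

    model: DistanceModel
    train: dict[str, list[Window]]  # structured classes only
    f_core: LogisticTransform
    f_non: LogisticTransform
    _indices: dict = field(default=None, repr=False, compare=False)

    def indices(self, method: str = "brute") -> dict[str, BruteForceIndex]:
        if self._indices is None:
            object.__setattr__(
                self,
                "_indices",
                {
                    c: build_nn_index(self.train[c], self.model, c, method=method)
                    for c in self.train
                },
            )
        return self._indices

    @property
    def core_set(self) -> set[str]:
        return set(core_classes(self.model.width))

    def to_json(self) -> dict:
        return {
            "model": self.model.to_json(),
            "train": {
                c: [w.profiles.tolist() for w in pool]
                for c, pool in self.train.items()
            },
            "f_core": self.f_core.to_json(),
            "f_non": self.f_non.to_json(),
        }

    @classmethod
    def from_json(cls, d: dict) -> "CorenessRegressor":
        return cls(
            model=DistanceModel.from_json(d["model"]),
            train={
                c: [Window(np.array(p)) for p in pool]
                for c, pool in d["train"].items()
            },
            f_core=LogisticTransform.from_json(d["f_core"]),
            f_non=LogisticTransform.from_json(d["f_non"]),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CorenessRegressor):
            return NotImplemented
        return (
            self.model == other.model
            and self.f_core == other.f_core
            and self.f_non == other.f_non
            and {c: [w.profiles.tolist() for w in p] for c, p in self.train.items()}
            == {c: [w.profiles.tolist() for w in p] for c, p in other.train.items()}
        )


def predict_coreness(reg: CorenessRegressor, W: Window) -> float:
    """Predicted coreness of the window's center column, clamped to [0,1]."""
    cls, _, delta = nearest_structured(reg.indices(), W)
    fn = reg.f_core if cls in reg.core_set else reg.f_non
    return float(np.clip(fn(delta), 0.0, 1.0))


def predict_windows(reg: CorenessRegressor, windows: list[Window]) -> np.ndarray:
    """Vectorized prediction for many windows."""
    profs = stack_profiles(windows)
    order = [c for c in structured_classes(reg.model.width) if c in reg.train]
    ci, dist = batch_nearest_structured(reg.indices(), profs)
    is_core = np.array([order[i] in reg.core_set for i in ci])
    out = np.where(is_core, reg.f_core(dist), reg.f_non(dist))
    return np.clip(out, 0.0, 1.0)


def predict_alignment(
    reg: CorenessRegressor,
    aln: Alignment,
    ss: dict[str, SSConfidence] | list[SSConfidence],
) -> np.ndarray:
    """Per-column predicted coreness for a computed alignment."""
    wins = extract_windows(aln, ss, reg.model.width, reg.model.alphabet)
    return predict_windows(reg, wins)


def nn_examples(
    model: DistanceModel, sets: WindowSets
) -> list[tuple[float, float, bool]]:
    """(distance, true coreness, nearest-class-is-core) for the sample
    windows, excluding each window from its own class's search pool."""
    classes = structured_classes(sets.width)
    stacks = {c: stack_profiles(sets.train[c]) for c in classes}
    cores = set(core_classes(sets.width))
    out = []
    from .metric import cross_distances

    all_classes = classes + [bottom_class(sets.width)]
    for c in all_classes:
        pool = sets.train.get(c)
        if not pool:
            continue
        s_idx = np.asarray(sets.sample_idx[c])
        if len(s_idx) == 0:
            continue
        queries = stack_profiles([pool[i] for i in s_idx])
        best_d = np.full(len(s_idx), np.inf)
        best_core = np.zeros(len(s_idx), dtype=bool)
        for rank, b in enumerate(classes):
            D = cross_distances(model, b, queries, stacks[b])
            if b == c:
                D[np.arange(len(s_idx)), s_idx] = np.inf
            d = D.min(axis=1)
            better = d < best_d
            best_core[better] = b in cores
            best_d[better] = d[better]
        for j, si in enumerate(s_idx):
            out.append((float(best_d[j]), float(pool[si].coreness), bool(best_core[j])))
    return out


def fit_regressor(
    model: DistanceModel,
    sets: WindowSets,
    curve_ell: int = 100,
    examples: list[tuple[float, float, bool]] | None = None,
) -> CorenessRegressor:
    """Fit both transforms from sample-window NN distances and assemble the
    regressor over the structured training pools."""
    if examples is None:
        examples = nn_examples(model, sets)
    core_ex = [(d, c) for d, c, is_core in examples if is_core]
    non_ex = [(d, c) for d, c, is_core in examples if not is_core]

    def fit(ex, orientation):
        if len(ex) < 4:
            mean = float(np.mean([c for _, c in ex])) if ex else 0.5
            return LogisticTransform(mean, mean, 0.0, 0.0)
        pts = empirical_curve(ex, curve_ell)
        if len(pts) < 4:
            mean = float(np.mean([p.avg_coreness for p in pts]))
            return LogisticTransform(mean, mean, 0.0, 0.0)
        return fit_logistic(pts, orientation)

    f_core = fit(core_ex, "decreasing")
    f_non = fit(non_ex, "increasing")
    train = {c: sets.train[c] for c in structured_classes(sets.width)}
    return CorenessRegressor(model, train, f_core, f_non)


def classification_auc(predictions, labels) -> float:
    """Rank-based ROC AUC (ties count half); labels are binary."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both label values present")
    return float(roc_auc_score(labels, np.asarray(predictions, dtype=float)))


def evaluate_auc(
    reg: CorenessRegressor, windows: list[Window], threshold: float = 0.5
) -> float:
    """AUC of predicted coreness against the windows' core/non-core truth."""
    labeled = [w for w in windows if w.coreness is not None]
    preds = predict_windows(reg, labeled)
    labels = np.array([w.coreness > threshold for w in labeled])
    return classification_auc(preds, labels)
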