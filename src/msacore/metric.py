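"""Window distance functions and exact metric nearest-neighbor search.

The distance between two windows from a structured class c is the bilinear
form d_c(V,W) = sum_i sum_{p,q} V_i(p) W_i(q) sigma_{c,i}(p,q) over
class- and position-specific substitution scores sigma.  When every table
satisfies the state-level triangle inequality (along with symmetry and
non-negativity), d_c itself satisfies the triangle inequality — profiles are
distributions, so the state-level bound lifts to the bilinear form — which
licenses metric-pruned nearest-neighbor search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import StateAlphabet
from .io import register_model
from .windows import Window, structured_classes

TRIANGLE_TOL = 1e-6


@register_model("distance_model")
@dataclass
class DistanceModel:
    """Per-class, per-position substitution-score tables plus threshold tau.

    ``tables[c]`` has shape (2w+1, |Q|, |Q|); each position's matrix is
    symmetric, non-negative, zero on the gap-gap entry, and has minimal
    diagonal (sigma(p,p) <= sigma(p,q)).
    """

    tables: dict[str, np.ndarray]
    tau: float
    width: int
    alphabet: StateAlphabet

    def __post_init__(self) -> None:
        for c, t in self.tables.items():
            self.tables[c] = np.asarray(t, dtype=float)
            if self.tables[c].shape != (
                2 * self.width + 1,
                self.alphabet.size,
                self.alphabet.size,
            ):
                raise ValueError(f"bad table shape for class {c}")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")

    @property
    def classes(self) -> list[str]:
        return list(self.tables)

    def to_json(self) -> dict:
        return {
            "tables": {c: t.tolist() for c, t in self.tables.items()},
            "tau": self.tau,
            "width": self.width,
            "alphabet": self.alphabet.describe(),
        }

    @classmethod
    def from_json(cls, d: dict) -> "DistanceModel":
        return cls(
            tables={c: np.array(t) for c, t in d["tables"].items()},
            tau=d["tau"],
            width=d["width"],
            alphabet=StateAlphabet.from_description(d["alphabet"]),
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DistanceModel)
            and self.tau == other.tau
            and self.width == other.width
            and self.alphabet == other.alphabet
            and set(self.tables) == set(other.tables)
            and all(np.array_equal(self.tables[c], other.tables[c]) for c in self.tables)
        )


def window_distance(model: DistanceModel, cls: str, V: Window, W: Window) -> float:
    """d_c(V, W); symmetric in V and W for symmetric tables."""
    if V.width != model.width or W.width != model.width:
        raise ValueError("window width does not match the model")
    return float(
        np.einsum("ip,ipq,iq->", V.profiles, model.tables[cls], W.profiles)
    )


def cross_distances(
    model: DistanceModel, cls: str, A: np.ndarray, B: np.ndarray
) -> np.ndarray:
    """(|A|, |B|) distance matrix between stacked window profile arrays.

    ``A`` has shape (nA, 2w+1, |Q|) and likewise ``B``.
    """
    T = model.tables[cls]
    out = np.zeros((A.shape[0], B.shape[0]))
    for i in range(T.shape[0]):
        out += A[:, i, :] @ T[i] @ B[:, i, :].T
    return out


def stack_profiles(windows: list[Window]) -> np.ndarray:
    return np.stack([w.profiles for w in windows])


# ---------------------------------------------------------------------------
# Default (bootstrap) distance


def _aa_dissimilarity(alphabet: StateAlphabet, matrix_name: str) -> np.ndarray:
    """Group-level dissimilarity from a published substitution matrix,
    rescaled per matrix to [0,1] so self-scores map near 0."""
    import biotite.sequence.align as bsa
    import biotite.sequence as bseq

    mat = bsa.SubstitutionMatrix(
        bseq.ProteinSequence.alphabet, bseq.ProteinSequence.alphabet, matrix_name
    )
    aas = "ACDEFGHIKLMNPQRSTVWY"
    scores = np.array(
        [[mat.get_score(a, b) for b in aas] for a in aas], dtype=float
    )
    dis = (scores.max() - scores) / (scores.max() - scores.min())
    n = alphabet.n_groups
    out = np.zeros((n, n))
    idx = {a: i for i, a in enumerate(aas)}
    for gi, ga in enumerate(alphabet.groups):
        for gj, gb in enumerate(alphabet.groups):
            out[gi, gj] = np.mean([[dis[idx[a], idx[b]] for b in gb] for a in ga])
    np.fill_diagonal(out, 0.0)  # a self-substitution is no substitution
    return out


def default_distance_model(
    alphabet: StateAlphabet,
    w: int = 1,
    gamma_mix: float = 0.5,
    matrix_name: str = "PAM200",
) -> DistanceModel:
    """Bootstrap distance: a convex mix of substitution dissimilarity on the
    amino acids and non-identity on the secondary-structure types.

    The positional score is gamma_mix * aa_dissim + (1-gamma_mix) * [ss
    differs]; the gap state scores 0 against itself and 1 (maximal) against
    any residue state.  Positions are weighted with the center column at
    twice the weight of each flank, normalized to sum to 1; the same table
    serves every structured class.
    """
    if not 0.0 <= gamma_mix <= 1.0:
        raise ValueError("gamma_mix must lie in [0,1]")
    S = alphabet.size
    aadis = _aa_dissimilarity(alphabet, matrix_name)
    base = np.ones((S, S))
    for p in range(S - 1):
        gp, sp = divmod(p, 3)
        for q in range(S - 1):
            gq, sq = divmod(q, 3)
            base[p, q] = gamma_mix * aadis[gp, gq] + (1 - gamma_mix) * (sp != sq)
    base[alphabet.gap_state, alphabet.gap_state] = 0.0
    weights = np.ones(2 * w + 1)
    weights[w] = 2.0
    weights /= weights.sum()
    tables = {
        c: np.stack([wt * base for wt in weights]) for c in structured_classes(w)
    }
    return DistanceModel(tables=tables, tau=0.0, width=w, alphabet=alphabet)


def default_distance(
    V: Window,
    W: Window,
    gamma_mix: float = 0.5,
    alphabet: StateAlphabet | None = None,
    model: DistanceModel | None = None,
) -> float:
    if model is None:
        if alphabet is None:
            raise ValueError("need an alphabet (or a prebuilt default model)")
        model = default_distance_model(alphabet, V.width, gamma_mix)
    return window_distance(model, structured_classes(model.width)[0], V, W)


# ---------------------------------------------------------------------------
# Triangle verification


@dataclass
class TriangleReport:
    """Outcome of state-level and window-level triangle checks."""

    sigma_max_violation: float
    sigma_worst: tuple | None
    window_max_violation: float
    n_window_triples: int

    @property
    def ok(self) -> bool:
        return self.sigma_max_violation <= TRIANGLE_TOL


def sigma_triangle_violation(table: np.ndarray) -> tuple[float, tuple | None]:
    """Max of sigma(p,r) - min_q (sigma(p,q)+sigma(q,r)) over all p, r."""
    best = np.min(table[:, :, None] + table[None, :, :], axis=1)  # min over q
    viol = table - best
    worst = float(viol.max())
    if worst <= 0:
        return max(worst, 0.0), None
    p, r = np.unravel_index(np.argmax(viol), viol.shape)
    return worst, (int(p), int(r))


def verify_triangle(
    model: DistanceModel,
    n_triples: int = 1000,
    seed: int = 0,
    windows: list[Window] | None = None,
) -> TriangleReport:
    """Check the triangle inequality at the score-table level (exhaustively)
    and at the window-distance level (on random triples)."""
    rng = np.random.default_rng(seed)
    worst_sigma, worst_at = 0.0, None
    for c, tab in model.tables.items():
        for i in range(tab.shape[0]):
            v, at = sigma_triangle_violation(tab[i])
            if v > worst_sigma:
                worst_sigma, worst_at = v, (c, i, at)
    S = model.alphabet.size
    L = 2 * model.width + 1
    worst_window = 0.0
    classes = list(model.tables)
    for _ in range(n_triples):
        if windows is not None and len(windows) >= 3:
            U, V, W = (windows[i] for i in rng.choice(len(windows), 3, replace=False))
        else:
            U, V, W = (
                Window(rng.dirichlet(np.ones(S) * 0.3, size=L)) for _ in range(3)
            )
        c = classes[rng.integers(len(classes))]
        gap = window_distance(model, c, U, W) - (
            window_distance(model, c, U, V) + window_distance(model, c, V, W)
        )
        worst_window = max(worst_window, gap)
    return TriangleReport(worst_sigma, worst_at, worst_window, n_triples)


def validate_model(model: DistanceModel, tol: float = TRIANGLE_TOL) -> list[str]:
    """All score-table invariants; returns a list of violation descriptions."""
    problems = []
    gap = model.alphabet.gap_state
    for c, tab in model.tables.items():
        for i in range(tab.shape[0]):
            M = tab[i]
            if np.abs(M - M.T).max() > tol:
                problems.append(f"{c}[{i}]: asymmetric")
            if M.min() < -tol:
                problems.append(f"{c}[{i}]: negative score")
            if abs(M[gap, gap]) > tol:
                problems.append(f"{c}[{i}]: sigma(gap,gap) != 0")
            diag = np.diag(M)
            if (diag[:, None] - M).max() > tol:
                problems.append(f"{c}[{i}]: sigma(p,p) > sigma(p,q)")
            v, _ = sigma_triangle_violation(M)
            if v > tol:
                problems.append(f"{c}[{i}]: triangle violation {v:.2e}")
    if model.tau < -tol:
        problems.append("tau < 0")
    return problems


# ---------------------------------------------------------------------------
# Nearest-neighbor indices


class BruteForceIndex:
    """Exact NN search by a vectorized scan; the oracle for the vp-tree."""

    def __init__(self, windows: list[Window], model: DistanceModel, cls: str):
        if not windows:
            raise ValueError(f"empty window set for class {cls}")
        self.windows = windows
        self.model = model
        self.cls = cls
        self._stack = stack_profiles(windows)

    def __len__(self) -> int:
        return len(self.windows)

    def query(
        self, W: Window, i: int = 1, exclude: int | None = None
    ) -> list[tuple[float, int]]:
        """i nearest neighbors as (distance, index), ties by insertion order."""
        d = cross_distances(self.model, self.cls, self._stack, W.profiles[None])[:, 0]
        if exclude is not None:
            d = d.copy()
            d[exclude] = np.inf
        order = np.argsort(d, kind="stable")[:i]
        return [(float(d[j]), int(j)) for j in order]

    def query_batch(self, profiles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """1-NN distances and indices for a stack of query windows."""
        D = cross_distances(self.model, self.cls, profiles, self._stack)
        idx = np.argmin(D, axis=1)
        return D[np.arange(D.shape[0]), idx], idx


class VPTreeIndex:
    """Exact vantage-point tree under a class distance satisfying the
    triangle inequality.

    Vantage points are chosen deterministically (first element in insertion
    order), and pruning uses non-strict bounds, so results match the
    brute-force scan exactly, including insertion-order tie-breaking.
    """

    _LEAF = 8

    def __init__(
        self,
        windows: list[Window],
        model: DistanceModel,
        cls: str,
        verify: bool = True,
    ):
        if not windows:
            raise ValueError(f"empty window set for class {cls}")
        self.windows = windows
        self.model = model
        self.cls = cls
        self._stack = stack_profiles(windows)
        if verify:
            worst = max(
                sigma_triangle_violation(model.tables[cls][i])[0]
                for i in range(2 * model.width + 1)
            )
            if worst > TRIANGLE_TOL:
                raise ValueError(
                    f"score table for class {cls} violates the triangle "
                    f"inequality by {worst:.2e}; use BruteForceIndex"
                )
        self.n_distance_evals = 0
        self._root = self._build(np.arange(len(windows)))

    def _dists(self, idx: np.ndarray, W_profiles: np.ndarray) -> np.ndarray:
        self.n_distance_evals += len(idx)
        return cross_distances(
            self.model, self.cls, self._stack[idx], W_profiles[None]
        )[:, 0]

    def _build(self, idx: np.ndarray):
        if len(idx) <= self._LEAF:
            return ("leaf", idx)
        vantage = idx[0]
        rest = idx[1:]
        d = self._dists(rest, self._stack[vantage])
        mu = float(np.median(d))
        inner = rest[d <= mu]
        outer = rest[d > mu]
        if len(inner) == 0 or len(outer) == 0:
            return ("leaf", idx)
        return ("node", vantage, mu, self._build(inner), self._build(outer))

    def query(
        self, W: Window, i: int = 1, exclude: int | None = None
    ) -> list[tuple[float, int]]:
        best: list[tuple[float, int]] = []  # sorted by (distance, index)

        def consider(indices: np.ndarray) -> None:
            d = self._dists(indices, W.profiles)
            for dist, j in zip(d, indices):
                if j == exclude:
                    continue
                best.append((float(dist), int(j)))
            best.sort()
            del best[i:]

        def kth() -> float:
            return best[-1][0] if len(best) == i else np.inf

        def visit(node) -> None:
            if node[0] == "leaf":
                consider(node[1])
                return
            _, vantage, mu, inner, outer = node
            dv = float(self._dists(np.array([vantage]), W.profiles)[0])
            if vantage != exclude:
                best.append((dv, int(vantage)))
                best.sort()
                del best[i:]
            near_first = dv <= mu
            order = (
                [(inner, max(dv - mu, 0.0)), (outer, max(mu - dv, 0.0))]
                if near_first
                else [(outer, max(mu - dv, 0.0)), (inner, max(dv - mu, 0.0))]
            )
            for child, bound in order:
                if bound <= kth():  # non-strict: equal-distance ties must be seen
                    visit(child)

        visit(self._root)
        return best

    def __len__(self) -> int:
        return len(self.windows)


def build_nn_index(
    windows: list[Window],
    model: DistanceModel,
    cls: str,
    method: str = "vptree",
) -> VPTreeIndex | BruteForceIndex:
    """Build an exact NN index for one structured class.

    Falls back to the brute-force scan (with a warning) if the class table
    violates the triangle inequality beyond tolerance.
    """
    if method == "brute":
        return BruteForceIndex(windows, model, cls)
    try:
        return VPTreeIndex(windows, model, cls)
    except ValueError as exc:
        if "triangle" not in str(exc):
            raise
        import warnings

        warnings.warn(str(exc), stacklevel=2)
        return BruteForceIndex(windows, model, cls)


def nearest_structured(
    indices: dict[str, BruteForceIndex | VPTreeIndex], W: Window
) -> tuple[str, Window, float]:
    """Global nearest neighbor over all structured classes.

    Ties are broken by canonical class order (CCC, CCN, NCC, CNN, NNC),
    then insertion order within a class.
    """
    if not indices:
        raise ValueError("no class indices provided")
    order = [c for c in structured_classes() if c in indices] or list(indices)
    best: tuple[float, int, str, int] | None = None
    for rank, cls in enumerate(order):
        (dist, j), *_ = indices[cls].query(W, 1)
        cand = (dist, rank, cls, j)
        if best is None or cand[:2] < best[:2]:
            best = cand
    dist, _, cls, j = best
    return cls, indices[cls].windows[j], dist


def batch_nearest_structured(
    indices: dict[str, BruteForceIndex], profiles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (class index, distance) of the nearest structured neighbor
    for a stack of query windows; classes ordered canonically."""
    order = [c for c in structured_classes() if c in indices] or list(indices)
    D = np.full((profiles.shape[0], len(order)), np.inf)
    for ci, cls in enumerate(order):
        idx = indices[cls]
        stack = idx._stack if hasattr(idx, "_stack") else stack_profiles(idx.windows)
        D[:, ci] = cross_distances(idx.model, cls, profiles, stack).min(axis=1)
    ci = np.argmin(D, axis=1)  # argmin takes the first (canonical) on ties
    return ci, D[np.arange(D.shape[0]), ci]
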