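"""Learning class distance functions by linear programming.

For each sample window W of a structured class c, the LP pulls in *targets*
(near windows of the same class) by penalizing d_c(V,W) - tau, and pushes
away *impostors* (near windows of other structured classes b) by penalizing
tau - d_b(V,W) + 1, with a unit margin; completely non-core windows
additionally act as impostor anchors against the core classes.  Subject to
symmetry, non-negativity, minimal diagonals, and state-level triangle
constraints on the substitution scores sigma, it minimizes a blend of the
average target error and the average impostor error.

Triangle constraints are the size bottleneck (Theta(s^3) rows per table);
for large alphabets they are generated lazily: solve, add the most violated
triples, re-solve until none are violated beyond tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .alphabet import StateAlphabet
from .metric import DistanceModel, cross_distances, stack_profiles
from .windows import WindowSets, Window, bottom_class, core_classes, structured_classes

TOL = 1e-6


# ---------------------------------------------------------------------------
# Neighborhoods


@dataclass
class Neighborhoods:
    """Targets and impostors for every sample window.

    ``targets[c][s]`` are indices into T_c of the k targets of the s-th
    sample of class c; ``impostors[c][s][b]`` are indices into T_b of its
    ell impostors from structured class b != c.  ``bottom_impostors[s][b]``
    are impostors from core class b for the s-th completely-non-core sample.
    """

    sets: WindowSets
    k: int
    ell: int
    mode: str
    seed: int
    targets: dict[str, list[np.ndarray]]
    impostors: dict[str, list[dict[str, np.ndarray]]]
    bottom_impostors: list[dict[str, np.ndarray]]


def _nn_indices(
    model: DistanceModel,
    cls: str,
    pool: list[Window],
    queries: np.ndarray,
    n: int,
    exclude: np.ndarray | None = None,
) -> list[np.ndarray]:
    """n nearest pool members (by d_cls) for each query, insertion-order ties."""
    D = cross_distances(model, cls, queries, stack_profiles(pool))
    if exclude is not None:
        D[np.arange(len(exclude))[exclude >= 0], exclude[exclude >= 0]] = np.inf
    return [np.argsort(row, kind="stable")[:n] for row in D]


def build_neighborhoods(
    sets: WindowSets,
    mode: str,
    k: int,
    ell: int,
    seed: int,
    model: DistanceModel | None = None,
) -> Neighborhoods:
    """Choose targets and impostors by NN search (default/model) or uniform
    sampling (random); reproducible by seed."""
    if k < 1 or ell < 1:
        raise ValueError("k and ell must be >= 1")
    if mode not in ("default", "random", "model"):
        raise ValueError(f"unknown neighborhood mode {mode!r}")
    if mode == "model" and model is None:
        raise ValueError("mode 'model' requires a distance model")
    if mode == "default" and model is None:
        from .metric import default_distance_model

        model = default_distance_model(_alphabet_of(sets), sets.width)
    rng = np.random.default_rng(seed)
    classes = structured_classes(sets.width)
    bot = bottom_class(sets.width)
    for c in classes:
        if len(sets.train[c]) < k + 1:
            raise ValueError(f"class {c} has < k+1 = {k + 1} training windows")

    stacks = {c: stack_profiles(sets.train[c]) for c in classes}
    targets: dict[str, list[np.ndarray]] = {}
    impostors: dict[str, list[dict[str, np.ndarray]]] = {}
    for c in classes:
        s_idx = sets.sample_idx[c]
        queries = stacks[c][s_idx]
        nT = len(sets.train[c])
        if mode == "random":
            tg = []
            for si in s_idx:
                choices = np.setdiff1d(np.arange(nT), [si])
                tg.append(rng.choice(choices, size=k, replace=False))
            targets[c] = tg
        else:
            targets[c] = _nn_indices(
                model, c, sets.train[c], queries, k, exclude=np.asarray(s_idx)
            )
        imp_per_sample: list[dict[str, np.ndarray]] = [dict() for _ in s_idx]
        for b in classes:
            if b == c:
                continue
            nB = len(sets.train[b])
            ll = min(ell, nB)
            if mode == "random":
                for d in imp_per_sample:
                    d[b] = rng.choice(nB, size=ll, replace=False)
            else:
                got = _nn_indices(model, b, sets.train[b], queries, ll)
                for d, g in zip(imp_per_sample, got):
                    d[b] = g
        impostors[c] = imp_per_sample

    bottom_imp: list[dict[str, np.ndarray]] = []
    bot_samples = sets.samples(bot)
    if bot_samples:
        bq = stack_profiles(bot_samples)
        for s in range(len(bot_samples)):
            bottom_imp.append({})
        for b in core_classes(sets.width):
            nB = len(sets.train[b])
            ll = min(ell, nB)
            if mode == "random":
                for d in bottom_imp:
                    d[b] = rng.choice(nB, size=ll, replace=False)
            else:
                got = _nn_indices(model, b, sets.train[b], bq, ll)
                for d, g in zip(bottom_imp, got):
                    d[b] = g
    return Neighborhoods(sets, k, ell, mode, seed, targets, impostors, bottom_imp)


def _alphabet_of(sets: WindowSets) -> StateAlphabet:
    # profiles carry no alphabet; infer the size and refuse ambiguity
    S = next(iter(sets.train.values()))[0].profiles.shape[1]
    from .alphabet import full_alphabet, reduced_alphabet, DAYHOFF6

    if S == full_alphabet().size:
        return full_alphabet()
    if S == reduced_alphabet(DAYHOFF6).size:
        return reduced_alphabet(DAYHOFF6)
    raise ValueError("cannot infer alphabet; pass a default model explicitly")


# ---------------------------------------------------------------------------
# LP construction


def _pair_index(p: int, q: int, S: int) -> int:
    if p > q:
        p, q = q, p
    return p * S - p * (p - 1) // 2 + (q - p)


@dataclass
class LinearProgram:
    """Sparse LP in A_ub x <= b_ub form plus the variable layout."""

    alphabet: StateAlphabet
    width: int
    classes: list[str]
    alpha: float
    n_sig: int
    e_index: dict[tuple[str, int, int], int]  # (class, sample pos, target pos)
    f_index: dict[tuple[str, int], int]  # (class or bottom, sample pos)
    tau_index: int
    c_obj: np.ndarray
    rows: list  # (cols, vals) per inequality row
    rhs: list[float]
    bounds: list[tuple[float, float | None]]
    neighborhoods: Neighborhoods
    triangle_rows: str  # "eager" or "lazy"

    @property
    def n_vars(self) -> int:
        return self.tau_index + 1

    def sig_var(self, cls: str, pos: int, p: int, q: int) -> int:
        S = self.alphabet.size
        P = S * (S + 1) // 2
        L = 2 * self.width + 1
        ci = self.classes.index(cls)
        return (ci * L + pos) * P + _pair_index(p, q, S)


def _distance_entries(lp: LinearProgram, cls: str, Vp: np.ndarray, Wp: np.ndarray):
    """Column/value pairs expressing d_cls(V,W) in the sigma variables."""
    S = lp.alphabet.size
    cols, vals = [], []
    for i in range(Vp.shape[0]):
        nv = np.flatnonzero(Vp[i])
        nw = np.flatnonzero(Wp[i])
        for p in nv:
            vp = Vp[i, p]
            for q in nw:
                cols.append(lp.sig_var(cls, i, int(p), int(q)))
                vals.append(vp * Wp[i, q])
    return cols, vals


def build_lp(
    neighborhoods: Neighborhoods,
    alphabet: StateAlphabet,
    alpha: float = 0.5,
    triangle: str = "auto",
    sigma_l1: float = 1e-7,
) -> LinearProgram:
    """Assemble objective, target/impostor rows, diagonal-dominance rows,
    and (eagerly or lazily) the triangle rows.

    ``sigma_l1`` adds a vanishing L1 weight on the substitution scores:
    the error objective is flat along directions that inflate scores the
    constraints never reference, and this tie-break selects the
    minimal-score optimum deterministically (it also keeps the solver out
    of those flat directions).  It perturbs the optimal value by less than
    sigma_l1 times the total score mass.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0,1]")
    sets = neighborhoods.sets
    w = sets.width
    L = 2 * w + 1
    S = alphabet.size
    P = S * (S + 1) // 2
    classes = structured_classes(w)
    bot = bottom_class(w)
    n_sig = len(classes) * L * P
    if triangle == "auto":
        triangle = "eager" if S <= 25 else "lazy"

    e_index: dict[tuple[str, int, int], int] = {}
    f_index: dict[tuple[str, int], int] = {}
    nxt = n_sig
    for c in classes:
        for s in range(len(sets.sample_idx[c])):
            for t in range(len(neighborhoods.targets[c][s])):
                e_index[(c, s, t)] = nxt
                nxt += 1
    for c in classes:
        for s in range(len(sets.sample_idx[c])):
            f_index[(c, s)] = nxt
            nxt += 1
    for s in range(len(neighborhoods.bottom_impostors)):
        f_index[(bot, s)] = nxt
        nxt += 1
    tau = nxt
    n_vars = tau + 1

    c_obj = np.zeros(n_vars)
    c_obj[:n_sig] = sigma_l1
    n_classes_all = len(classes) + 1  # |C| includes the unstructured class
    for c in classes:
        ns = len(sets.sample_idx[c])
        for s in range(ns):
            kk = len(neighborhoods.targets[c][s])
            for t in range(kk):
                c_obj[e_index[(c, s, t)]] = alpha / (len(classes) * ns * kk)
            c_obj[f_index[(c, s)]] = (1 - alpha) / (n_classes_all * ns)
    nb = len(neighborhoods.bottom_impostors)
    for s in range(nb):
        c_obj[f_index[(bot, s)]] = (1 - alpha) / (n_classes_all * nb)

    rows: list = []
    rhs: list[float] = []

    def add_row(cols, vals, b):
        rows.append((np.asarray(cols, dtype=np.int64), np.asarray(vals, dtype=float)))
        rhs.append(b)

    lp = LinearProgram(
        alphabet, w, classes, alpha, n_sig, e_index, f_index, tau,
        c_obj, rows, rhs, [], neighborhoods, triangle,
    )

    for c in classes:
        T_c = sets.train[c]
        for s, si in enumerate(sets.sample_idx[c]):
            Wp = T_c[si].profiles
            for t, vi in enumerate(neighborhoods.targets[c][s]):
                cols, vals = _distance_entries(lp, c, T_c[int(vi)].profiles, Wp)
                add_row(cols + [tau, e_index[(c, s, t)]], vals + [-1.0, -1.0], 0.0)
            for b, imps in neighborhoods.impostors[c][s].items():
                for vi in imps:
                    cols, vals = _distance_entries(
                        lp, b, sets.train[b][int(vi)].profiles, Wp
                    )
                    add_row(
                        [tau, f_index[(c, s)]] + cols,
                        [1.0, -1.0] + [-v for v in vals],
                        -1.0,
                    )
    bot_samples = sets.samples(bot)
    for s, imp_map in enumerate(neighborhoods.bottom_impostors):
        Wp = bot_samples[s].profiles
        for b, imps in imp_map.items():
            for vi in imps:
                cols, vals = _distance_entries(
                    lp, b, sets.train[b][int(vi)].profiles, Wp
                )
                add_row(
                    [tau, f_index[(bot, s)]] + cols,
                    [1.0, -1.0] + [-v for v in vals],
                    -1.0,
                )

    # sigma(p,p) <= sigma(p,q)
    for c in classes:
        for i in range(L):
            for p in range(S):
                for q in range(S):
                    if p == q:
                        continue
                    add_row(
                        [lp.sig_var(c, i, p, p), lp.sig_var(c, i, p, q)],
                        [1.0, -1.0],
                        0.0,
                    )
    if triangle == "eager":
        for c in classes:
            for i in range(L):
                _add_triangle_rows_eager(lp, c, i)

    gap = alphabet.gap_state
    bounds: list[tuple[float, float | None]] = []
    gap_pair = _pair_index(gap, gap, S)
    for ci in range(len(classes)):
        for i in range(L):
            for u in range(P):
                bounds.append((0.0, 0.0) if u == gap_pair else (0.0, None))
    bounds += [(0.0, None)] * (n_vars - n_sig)
    lp.bounds = bounds
    return lp


def _add_triangle_rows_eager(lp: LinearProgram, cls: str, pos: int) -> None:
    S = lp.alphabet.size
    for p in range(S):
        for r in range(p + 1, S):
            for q in range(S):
                if q == p or q == r:
                    continue
                lp.rows.append(
                    (
                        np.array(
                            [
                                lp.sig_var(cls, pos, p, r),
                                lp.sig_var(cls, pos, p, q),
                                lp.sig_var(cls, pos, q, r),
                            ]
                        ),
                        np.array([1.0, -1.0, -1.0]),
                    )
                )
                lp.rhs.append(0.0)


def _assemble(lp: LinearProgram) -> tuple[sp.csr_matrix, np.ndarray]:
    data, ri, ci = [], [], []
    for r, (cols, vals) in enumerate(lp.rows):
        ri.extend([r] * len(cols))
        ci.extend(cols.tolist())
        data.extend(vals.tolist())
    A = sp.coo_matrix(
        (data, (ri, ci)), shape=(len(lp.rows), lp.n_vars)
    ).tocsr()  # coo sums duplicate (row, col) entries, merging p==q terms
    return A, np.asarray(lp.rhs)


@dataclass
class LPSolution:
    """Optimal distance model plus error variables and solver diagnostics."""

    model: DistanceModel
    e: dict[tuple[str, int, int], float]
    f: dict[tuple[str, int], float]
    objective: float  # the blended error objective (tie-break term removed)
    status: str
    n_lazy_rounds: int = 0
    solver_objective: float = 0.0  # including the L1 tie-break term
    x: np.ndarray | None = None
    lp: LinearProgram | None = None


def _decode(lp: LinearProgram, x: np.ndarray) -> DistanceModel:
    S = lp.alphabet.size
    P = S * (S + 1) // 2
    L = 2 * lp.width + 1
    tables = {}
    iu = np.triu_indices(S)
    for ci, c in enumerate(lp.classes):
        tab = np.zeros((L, S, S))
        for i in range(L):
            off = (ci * L + i) * P
            M = np.zeros((S, S))
            M[iu] = x[off : off + P]
            tab[i] = M + M.T - np.diag(np.diag(M))
        tables[c] = tab
    return DistanceModel(tables, float(max(x[lp.tau_index], 0.0)), lp.width, lp.alphabet)


def _violated_triples(tab: np.ndarray, tol: float) -> list[tuple[int, int, int]]:
    """Most violated (p, q, r) per violated (p, r) under the current tables."""
    through = tab[:, :, None] + tab[None, :, :]  # through[p, q, r]
    qmin = np.argmin(through, axis=1)
    best = np.min(through, axis=1)
    out = []
    viol = tab - best
    for p, r in zip(*np.nonzero(viol > tol)):
        if p < r:
            out.append((int(p), int(qmin[p, r]), int(r)))
    return out


def solve_lp(lp: LinearProgram, max_lazy_rounds: int = 60) -> LPSolution:
    """Solve with HiGHS; under lazy triangle generation, re-solve adding the
    most violated triples per table until none exceed tolerance."""
    L = 2 * lp.width + 1
    rounds = 0
    while True:
        A, b = _assemble(lp)
        res = linprog(lp.c_obj, A_ub=A, b_ub=b, bounds=lp.bounds, method="highs")
        if res.status != 0:
            raise RuntimeError(f"LP solver failed: {res.message}")
        model = _decode(lp, res.x)
        if lp.triangle_rows == "eager":
            break
        added = 0
        for c in lp.classes:
            for i in range(L):
                for p, q, r in _violated_triples(model.tables[c][i], TOL):
                    lp.rows.append(
                        (
                            np.array(
                                [
                                    lp.sig_var(c, i, p, r),
                                    lp.sig_var(c, i, p, q),
                                    lp.sig_var(c, i, q, r),
                                ]
                            ),
                            np.array([1.0, -1.0, -1.0]),
                        )
                    )
                    lp.rhs.append(0.0)
                    added += 1
        rounds += 1
        if added == 0:
            break
        if rounds >= max_lazy_rounds:
            raise RuntimeError("lazy triangle generation did not converge")
    e = {key: float(res.x[idx]) for key, idx in lp.e_index.items()}
    f = {key: float(res.x[idx]) for key, idx in lp.f_index.items()}
    tiebreak = float(lp.c_obj[: lp.n_sig] @ res.x[: lp.n_sig])
    return LPSolution(
        model, e, f, float(res.fun) - tiebreak, "optimal", rounds,
        solver_objective=float(res.fun), x=res.x, lp=lp,
    )


# ---------------------------------------------------------------------------
# Feasibility / identity audits


def recomputed_errors(
    sol: LPSolution, neighborhoods: Neighborhoods
) -> tuple[dict, dict]:
    """e and f recomputed from sigma and tau via their max-expressions."""
    sets = neighborhoods.sets
    model, tau = sol.model, sol.model.tau
    bot = bottom_class(sets.width)
    e: dict[tuple[str, int, int], float] = {}
    f: dict[tuple[str, int], float] = {}
    for c in structured_classes(sets.width):
        T_c = sets.train[c]
        for s, si in enumerate(sets.sample_idx[c]):
            Wp = T_c[si].profiles[None]
            for t, vi in enumerate(neighborhoods.targets[c][s]):
                d = cross_distances(model, c, T_c[int(vi)].profiles[None], Wp)[0, 0]
                e[(c, s, t)] = max(d - tau, 0.0)
            worst = 0.0
            for b, imps in neighborhoods.impostors[c][s].items():
                D = cross_distances(
                    model, b, stack_profiles([sets.train[b][int(v)] for v in imps]), Wp
                )[:, 0]
                worst = max(worst, float(np.max(tau - D + 1.0)))
            f[(c, s)] = max(worst, 0.0)
    bot_samples = sets.samples(bot)
    for s, imp_map in enumerate(neighborhoods.bottom_impostors):
        Wp = bot_samples[s].profiles[None]
        worst = 0.0
        for b, imps in imp_map.items():
            D = cross_distances(
                model, b, stack_profiles([sets.train[b][int(v)] for v in imps]), Wp
            )[:, 0]
            worst = max(worst, float(np.max(tau - D + 1.0)))
        f[(bot, s)] = max(worst, 0.0)
    return e, f


def audit_solution(sol: LPSolution) -> dict:
    """Constraint residuals and error-variable identities for a solved LP."""
    lp = sol.lp
    A, b = _assemble(lp)
    resid = float(np.max(A @ sol.x - b)) if len(lp.rhs) else 0.0
    from .metric import validate_model

    problems = validate_model(sol.model, tol=1e-5)
    e2, f2 = recomputed_errors(sol, lp.neighborhoods)
    e_gap = max((abs(sol.e[k] - e2[k]) for k in e2), default=0.0)
    f_gap = max((abs(sol.f[k] - f2[k]) for k in f2), default=0.0)
    return {
        "max_constraint_violation": max(resid, 0.0),
        "model_problems": problems,
        "e_identity_gap": e_gap,
        "f_identity_gap": f_gap,
    }


def export_lp(lp: LinearProgram, path) -> None:
    """Write the LP in CPLEX LP text format (solver-independent export)."""
    lines = ["Minimize", " obj: " + _lincomb(lp.c_obj), "Subject To"]
    for r, ((cols, vals), b) in enumerate(zip(lp.rows, lp.rhs)):
        terms = {}
        for cc, vv in zip(cols, vals):
            terms[int(cc)] = terms.get(int(cc), 0.0) + float(vv)
        expr = " + ".join(f"{v:.17g} x{c}" for c, v in sorted(terms.items()) if v)
        expr = expr.replace("+ -", "- ")
        lines.append(f" r{r}: {expr} <= {b:.17g}")
    lines.append("Bounds")
    for j, (lo, hi) in enumerate(lp.bounds):
        hi_s = "+inf" if hi is None else f"{hi:.17g}"
        lines.append(f" {lo:.17g} <= x{j} <= {hi_s}")
    lines.append("End")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def _lincomb(c: np.ndarray) -> str:
    expr = " + ".join(f"{v:.17g} x{j}" for j, v in enumerate(c) if v)
    return expr.replace("+ -", "- ") or "0 x0"


# ---------------------------------------------------------------------------
# Iterated training


def iterate_training(
    sets: WindowSets,
    n_iters: int,
    k: int,
    ell: int,
    alpha: float,
    seed: int,
    alphabet: StateAlphabet,
    first_mode: str = "default",
    curve_ell: int = 20,
) -> list[tuple[DistanceModel, float, float]]:
    """Repeatedly solve the LP, rebuilding neighborhoods under the previous
    iteration's distances; returns (model, train AUC, test AUC) per iteration.
    """
    from . import regress

    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    out = []
    model = None
    for it in range(n_iters):
        if it == 0:
            from .metric import default_distance_model

            boot = (
                default_distance_model(alphabet, sets.width)
                if first_mode == "default"
                else None
            )
            neigh = build_neighborhoods(
                sets, first_mode, k, ell, seed, model=boot
            )
        else:
            neigh = build_neighborhoods(sets, "model", k, ell, seed + it, model=model)
        sol = solve_lp(build_lp(neigh, alphabet, alpha))
        model = sol.model
        reg = regress.fit_regressor(model, sets, curve_ell=curve_ell)
        train_auc = regress.evaluate_auc(reg, _flat_train_windows(sets))
        test_auc = regress.evaluate_auc(reg, sets.test)
        out.append((model, train_auc, test_auc))
    return out


def _flat_train_windows(sets: WindowSets) -> list[Window]:
    out = []
    for pool in sets.train.values():
        out.extend(pool)
    return out
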