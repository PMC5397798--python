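"""Distance-learning LP: optimality against an LP-solver-free grid oracle,
feasibility audits, error-variable identities, and iterated training."""

import itertools

import numpy as np
import pytest

from msacore.alphabet import COARSE3, StateAlphabet
from msacore import lp_train
from msacore.lp_train import (
    Neighborhoods,
    build_lp,
    build_neighborhoods,
    solve_lp,
)
from msacore.windows import Window, WindowSets

#: Coarse 3-group alphabet (10 states): keeps w=1 LPs small in unit tests.
COARSE = StateAlphabet(COARSE3)


def point_window(state: int, S: int, L: int, label: str, coreness: float) -> Window:
    profs = np.zeros((L, S))
    profs[:, state] = 1.0
    return Window(profs, label=label, coreness=coreness)


def make_w0_sets(alphabet, states_core, states_bottom, seed=0) -> WindowSets:
    """Width-0 window sets from point-mass windows on distinct states."""
    S = alphabet.size
    train = {
        "C": [point_window(s, S, 1, "C", 1.0) for s in states_core],
        "N": [point_window(s, S, 1, "N", 0.0) for s in states_bottom],
    }
    return WindowSets(
        width=0,
        train=train,
        sample_idx={
            "C": np.arange(len(states_core)),
            "N": np.arange(len(states_bottom)),
        },
        test=[],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Grid oracle: evaluates the printed objective directly from the max-
# expressions on a refined grid over the instance's score entries and tau.
# Independent of any LP machinery: only the objective/constraint definitions
# are shared knowledge.


def _oracle_terms(neigh: Neighborhoods, states: list[int]):
    """Target pair-indices and impostor groups in grid-variable coordinates."""
    sets = neigh.sets
    pair_of = {}
    pairs = list(itertools.combinations(sorted(states), 2))
    for u, (p, q) in enumerate(pairs):
        pair_of[(p, q)] = u
        pair_of[(q, p)] = u

    def state_of(window):
        return int(np.argmax(window.profiles[0]))

    target_terms = []  # list of pair-variable index
    for c in ["C"]:
        for s, si in enumerate(sets.sample_idx[c]):
            wst = state_of(sets.train[c][si])
            for vi in neigh.targets[c][s]:
                target_terms.append(pair_of[(state_of(sets.train[c][int(vi)]), wst)])
    bottom_groups = []  # per bottom sample: list of pair-variable indices
    bots = sets.samples("N")
    for s, imp_map in enumerate(neigh.bottom_impostors):
        wst = state_of(bots[s])
        group = []
        for b, imps in imp_map.items():
            for vi in imps:
                group.append(pair_of[(state_of(sets.train[b][int(vi)]), wst)])
        bottom_groups.append(group)
    return pairs, target_terms, bottom_groups


def grid_oracle(neigh: Neighborhoods, states, alpha, lo=0.0, hi=4.0):
    """Minimum of the blended error objective by nested grid refinement.

    The objective with the error variables eliminated is convex piecewise-
    linear in the score entries and tau; the triangle inequalities among the
    instance's states are enforced as a feasibility mask.
    """
    pairs, target_terms, bottom_groups = _oracle_terms(neigh, states)
    nv = len(pairs) + 1  # grid variables: off-diagonal entries, then tau
    n_core_samples = len(neigh.sets.sample_idx["C"])
    n_bot = len(bottom_groups)
    k = max(1, len(target_terms) // max(n_core_samples, 1))
    tri = []
    for p, q, r in itertools.permutations(sorted(states), 3):
        if p < r:
            tri.append((pairs.index(tuple(sorted((p, r)))),
                        pairs.index(tuple(sorted((p, q)))),
                        pairs.index(tuple(sorted((q, r))))))

    def objective(grid):  # grid: (nv, npoints)
        sig, tau = grid[:-1], grid[-1]
        feasible = np.ones(grid.shape[1], dtype=bool)
        for a, b, c in tri:
            feasible &= sig[a] <= sig[b] + sig[c] + 1e-12
        e_term = np.zeros(grid.shape[1])
        for u in target_terms:
            e_term += np.maximum(sig[u] - tau, 0.0)
        e_term *= 1.0 / max(n_core_samples * k, 1)
        f_core = 0.0  # core samples have no impostors at w=0
        f_bot = np.zeros(grid.shape[1])
        for group in bottom_groups:
            worst = np.zeros(grid.shape[1])
            for u in group:
                worst = np.maximum(worst, tau - sig[u] + 1.0)
            f_bot += worst
        f_bot *= 1.0 / max(n_bot, 1)
        # |structured| = 1 for the e-average; |C| = 2 for the f-average,
        # whose core-class term is identically zero here
        obj = alpha * e_term + (1 - alpha) * 0.5 * (f_core + f_bot)
        return np.where(feasible, obj, np.inf)

    # nested refinement: the eliminated objective is convex, so shrinking a
    # generous box around each stage's grid minimum converges to the optimum
    npts, n_stages = (17, 6) if nv <= 4 else (7, 18)
    centers = np.full(nv, (lo + hi) / 2)
    half = (hi - lo) / 2
    best_val = np.inf
    for _ in range(n_stages):
        step = 2 * half / (npts - 1)
        axes = [
            np.clip(np.linspace(c - half, c + half, npts), lo, None)
            for c in centers
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        grid = np.stack([m.ravel() for m in mesh])
        vals = objective(grid)
        j = int(np.argmin(vals))
        best_val = float(vals[j])
        centers = grid[:, j]
        half = 2 * step
    return best_val


def random_w0_instance(rng, alphabet, n_states):
    states = rng.choice(alphabet.size - 1, size=n_states, replace=False)
    n_core = int(rng.integers(2, n_states))
    sets = make_w0_sets(alphabet, states[:n_core], states[n_core:])
    k = 1
    ell = int(rng.integers(1, n_core + 1))
    neigh = build_neighborhoods(sets, "random", k, ell, int(rng.integers(2**31)))
    alpha = float(rng.uniform(0.2, 0.8))
    return sets, neigh, list(map(int, states)), alpha


def test_lp_matches_grid_oracle_on_tiny_instances(alphabet):
    """LP optimum equals the solver-free grid refinement on random width-0
    instances with 3-4 point-mass states."""
    rng = np.random.default_rng(2024)
    checked = 0
    while checked < 20:
        n_states = 4 if checked % 5 == 0 else 3
        sets, neigh, states, alpha = random_w0_instance(rng, alphabet, n_states)
        sol = solve_lp(build_lp(neigh, alphabet, alpha))
        oracle = grid_oracle(neigh, states, alpha)
        assert sol.objective == pytest.approx(oracle, abs=1e-3)
        checked += 1


def test_hand_instance_separable_optimum(alphabet):
    """One sample with one target and one far impostor: the LP drives the
    error to zero by zeroing the target score and pushing the impostor
    score past the margin."""
    S = alphabet.size
    p, q, r = 0, 3, 6
    sets = make_w0_sets(alphabet, [p, q], [r])
    neigh = build_neighborhoods(sets, "random", 1, 1, 5)
    sol = solve_lp(build_lp(neigh, alphabet, 0.5))
    assert sol.objective == pytest.approx(0.0, abs=1e-6)
    tab = sol.model.tables["C"][0]
    assert tab[p, q] <= sol.model.tau + 1e-6
    assert min(tab[r, p], tab[r, q]) >= sol.model.tau + 1.0 - 1e-6


def test_zero_solution_bounds_optimum(alphabet):
    """sigma=0, tau=0 is always feasible with impostor error exactly 1, so
    the optimum never exceeds (1-alpha)."""
    rng = np.random.default_rng(77)
    for _ in range(5):
        sets, neigh, states, alpha = random_w0_instance(rng, alphabet, 4)
        sol = solve_lp(build_lp(neigh, alphabet, alpha))
        assert -1e-9 <= sol.objective <= (1 - alpha) + 1e-6


def test_feasibility_and_error_identity(small_suite):
    """Audit a realistic solve: every constraint holds within 1e-6 and the
    returned e/f equal their max-expressions recomputed from sigma, tau."""
    from msacore import workflows

    sets = workflows.prepare_window_sets(
        small_suite, COARSE, n_train=40, n_sample=50, n_test=0,
        seed=5, n_folds=3,
    )
    neigh = build_neighborhoods(sets, "random", 2, 5, 3)
    sol = solve_lp(build_lp(neigh, COARSE, 0.5))
    audit = lp_train.audit_solution(sol)
    assert audit["max_constraint_violation"] <= 1e-6
    assert audit["model_problems"] == []
    assert audit["e_identity_gap"] <= 1e-6
    assert audit["f_identity_gap"] <= 1e-6


def test_variable_and_row_counts():
    sets = make_w0_sets(COARSE, [0, 1, 2], [4, 5])
    neigh = build_neighborhoods(sets, "random", 1, 2, 0)
    lp = build_lp(neigh, COARSE, 0.5)
    S = COARSE.size
    P = S * (S + 1) // 2
    n_targets = 3  # one per core sample
    n_f = 3 + 2  # every sample gets an f variable
    assert lp.n_vars == 1 * 1 * P + n_targets + n_f + 1
    n_tri = S * (S - 1) // 2 * (S - 2)
    n_self = S * (S - 1)
    n_imp = 2 * 2  # bottom samples x ell impostors (single structured class)
    assert len(lp.rows) == n_targets + n_imp + n_self + n_tri


def test_alpha_one_ignores_impostor_error():
    sets = make_w0_sets(COARSE, [0, 1, 2], [4, 5])
    neigh = build_neighborhoods(sets, "random", 1, 2, 0)
    lp = build_lp(neigh, COARSE, alpha=1.0)
    for key, idx in lp.f_index.items():
        assert lp.c_obj[idx] == 0.0


def test_neighborhood_modes_and_invariants(small_sets):
    neigh1 = build_neighborhoods(small_sets, "random", 2, 4, 9)
    neigh2 = build_neighborhoods(small_sets, "random", 2, 4, 9)
    for c in neigh1.targets:
        for a, b in zip(neigh1.targets[c], neigh2.targets[c]):
            np.testing.assert_array_equal(a, b)
        for s, (d1, d2) in enumerate(zip(neigh1.impostors[c], neigh2.impostors[c])):
            assert set(d1) == set(d2)
            # impostors never come from the sample's own class
            assert c not in d1
        # targets exclude the sample window itself
        for s, si in enumerate(small_sets.sample_idx[c]):
            assert si not in neigh1.targets[c][s]


def test_default_mode_targets_match_bruteforce(small_sets, alphabet):
    from msacore.metric import cross_distances, default_distance_model, stack_profiles

    model = default_distance_model(alphabet, 1)
    neigh = build_neighborhoods(small_sets, "default", 2, 3, 0, model=model)
    c = "CCC"
    pool = small_sets.train[c]
    stack = stack_profiles(pool)
    for s, si in enumerate(small_sets.sample_idx[c][:5]):
        D = cross_distances(model, c, stack, pool[si].profiles[None])[:, 0]
        D[si] = np.inf
        expect = np.argsort(D, kind="stable")[:2]
        np.testing.assert_array_equal(neigh.targets[c][s], expect)


def test_small_class_raises(alphabet):
    sets = make_w0_sets(alphabet, [0, 1], [4])
    with pytest.raises(ValueError, match="k\\+1"):
        build_neighborhoods(sets, "random", 2, 1, 0)


def test_export_lp_text(tmp_path):
    sets = make_w0_sets(COARSE, [0, 1], [4])
    neigh = build_neighborhoods(sets, "random", 1, 1, 0)
    lp = build_lp(neigh, COARSE, 0.5)
    lp_train.export_lp(lp, tmp_path / "prob.lp")
    text = (tmp_path / "prob.lp").read_text()
    assert text.startswith("Minimize") and "Subject To" in text and "End" in text


def test_iterate_training_improves_or_holds_training_auc(small_suite):
    """Iteration 2 rebuilds neighborhoods under the learned metric; on a
    separable synthetic suite the training AUC should not collapse."""
    from msacore import workflows

    sets = workflows.prepare_window_sets(
        small_suite, COARSE, n_train=25, n_sample=30, n_test=100,
        seed=5, n_folds=3,
    )
    hist = lp_train.iterate_training(
        sets, 2, k=2, ell=5, alpha=0.5, seed=4, alphabet=COARSE,
        first_mode="default", curve_ell=10,
    )
    assert len(hist) == 2
    (m1, tr1, te1), (m2, tr2, te2) = hist
    assert tr2 >= tr1 - 0.05
    assert 0.0 <= te1 <= 1.0 and 0.0 <= te2 <= 1.0
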