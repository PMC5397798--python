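"""End-to-end pipelines: suite -> window sets -> LP training -> regressor ->
estimator evaluation.  Thin compositions of the other modules, shared by the
command-line interface and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import estimator as est
from . import lp_train, regress, truth
from .alphabet import StateAlphabet
from .io import Benchmark
from .windows import (
    WindowSets,
    assemble_window_sets,
    assign_folds,
    labeled_windows,
)


def benchmark_difficulty(bench: Benchmark) -> float:
    """True accuracy of the default-setting alignment (from the manifest
    extras when present, else recomputed)."""
    if "difficulty" in bench.extras:
        return float(bench.extras["difficulty"])
    default_id = bench.extras.get("default_id", bench.computed[0][0])
    aln = dict(bench.computed)[default_id]
    return truth.true_accuracy(aln, bench.reference, bench.core)


def prepare_window_sets(
    benchmarks: list[Benchmark],
    alphabet: StateAlphabet,
    w: int = 1,
    n_train: int = 200,
    n_sample: int = 200,
    n_test: int = 500,
    seed: int = 0,
    n_folds: int = 4,
    test_folds: set[int] = frozenset({0}),
    threshold: float = 0.5,
    source: str = "computed",
) -> WindowSets:
    """Label windows on all benchmarks, split folds balanced by difficulty,
    and sample the training pools / samples / test set."""
    wins = [
        labeled_windows(b, w, alphabet, threshold=threshold, source=source)
        for b in benchmarks
    ]
    fold_of = assign_folds([benchmark_difficulty(b) for b in benchmarks], n_folds)
    return assemble_window_sets(
        wins, fold_of, set(test_folds), n_train, n_sample, n_test, seed, w=w
    )


def train_coreness_regressor(
    sets: WindowSets,
    alphabet: StateAlphabet,
    mode: str = "random",
    k: int = 2,
    ell: int = 20,
    alpha: float = 0.5,
    seed: int = 0,
    curve_ell: int = 20,
) -> tuple[regress.CorenessRegressor, lp_train.LPSolution]:
    """Solve the distance-learning LP once (the shipped protocol uses random
    neighborhoods, no iteration) and fit the two logistic transforms."""
    neigh = lp_train.build_neighborhoods(sets, mode, k, ell, seed)
    sol = lp_train.solve_lp(lp_train.build_lp(neigh, alphabet, alpha))
    reg = regress.fit_regressor(sol.model, sets, curve_ell=curve_ell)
    return reg, sol


def advising_instances(
    benchmarks: list[Benchmark],
    regressor: regress.CorenessRegressor | None,
    kappa: float = 0.5,
    normalizer: est.NormalizerModel | None = None,
) -> list[dict]:
    """Feature/accuracy tables per benchmark for estimator evaluation."""
    out = []
    for bench in benchmarks:
        cands = {}
        for pid, aln in bench.computed:
            feats = est.compute_features(
                aln, bench.ss, regressor=regressor, kappa=kappa,
                normalizer=normalizer,
            )
            acc = bench.extras.get("realized_accuracy", {}).get(pid)
            if acc is None:
                acc = truth.true_accuracy(aln, bench.reference, bench.core)
            cands[pid] = (feats, float(acc))
        out.append(
            {"difficulty": benchmark_difficulty(bench), "candidates": cands}
        )
    return out


def estimator_correlation(instances: list[dict], model: est.EstimatorModel) -> float:
    """Spearman correlation between estimated and true accuracy over all
    computed alignments of the instances."""
    from scipy.stats import spearmanr

    scores, accs = [], []
    for inst in instances:
        for feats, acc in inst["candidates"].values():
            scores.append(est.estimate_accuracy(model, feats))
            accs.append(acc)
    rho = spearmanr(scores, accs).statistic
    return float(rho)


def fixed_candidate_baseline(instances: list[dict]) -> tuple[str, float]:
    """Best single parameter setting by bin-averaged true accuracy."""
    pids = sorted(instances[0]["candidates"])
    best = (None, -1.0)
    for pid in pids:
        by_bin: dict[int, list[float]] = {}
        for inst in instances:
            by_bin.setdefault(
                truth.difficulty_bin(inst["difficulty"]), []
            ).append(inst["candidates"][pid][1])
        score = float(np.mean([np.mean(v) for v in by_bin.values()]))
        if score > best[1]:
            best = (pid, score)
    return best
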