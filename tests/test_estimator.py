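"""Feature functions, the core-column-count normalizer, estimator fitting,
and the parameter advisor."""

import itertools

import numpy as np
import pytest

from msacore import estimator as est
from msacore.io import Alignment, SSConfidence

from tests.conftest import one_hot_ss


def ss_list(aln, state="H"):
    return [one_hot_ss(aln.ungapped(i), state) for i in range(aln.k)]


# ---------------------------------------------------------------------------
# Sequence stats and normalizer


def test_sequence_stats_identical_pair():
    s = est.sequence_stats(["ACDEFGHIKL", "ACDEFGHIKL"])
    assert (s.l_min, s.l_avg, s.l_max) == (10, 10, 10)
    assert s.p_min == s.p_avg == s.p_max == 1.0
    assert s.q_min == s.q_avg == 1.0
    assert s.r_min == s.r_avg == 0.0


def test_sequence_stats_lcs_example():
    # LCS("ACGT","ACT") = 3 (G dropped)
    s = est.sequence_stats(["ACGT", "ACT"])
    assert s.p_min == pytest.approx(1.0)  # 3 / min(4,3)
    assert s.p_max == pytest.approx(0.75)
    assert s.r_min == pytest.approx(1 / 3)
    assert s.q_min == pytest.approx(0.75)
    # invariance to order
    s2 = est.sequence_stats(["ACT", "ACGT"])
    assert s == s2


def test_normalizer_printed_coefficients_toy_value():
    """Identical length-10 pair: only the three indel-free terms fire,
    giving 1.020*10 + 0.151*10 + 0.035*10 = 12.06."""
    s = est.sequence_stats(["ACDEFGHIKL", "ACDEFGHIKL"])
    val = est.normalizer_value(est.NormalizerModel.default(), s)
    assert val == pytest.approx(12.06)
    assert est.normalizer_value(est.NormalizerModel({}), s) == 0.0


def test_normalizer_scales_linearly_in_length():
    a = "ACDEFGHIKL"
    v1 = est.normalizer_value(
        est.NormalizerModel.default(), est.sequence_stats([a, a])
    )
    v2 = est.normalizer_value(
        est.NormalizerModel.default(), est.sequence_stats([a * 2, a * 2])
    )
    assert v2 == pytest.approx(2 * v1)


def test_candidate_terms_count():
    terms = est.candidate_terms()
    assert len(terms) == 72
    assert len(set(terms)) == 72


def test_fit_normalizer_recovers_planted_model():
    rng = np.random.default_rng(8)
    stats = []
    for _ in range(12):
        n = int(rng.integers(3, 6))
        L = int(rng.integers(20, 60))
        seqs = [
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                               size=L + int(rng.integers(0, 8))))
            for _ in range(n)
        ]
        stats.append(est.sequence_stats(seqs))
    planted = [(s, 1.5 * s.l_min * s.p_max * s.q_min) for s in stats]
    model = est.fit_normalizer(planted)
    resid = sum(
        abs(est.normalizer_value(model, s) - y) for s, y in planted
    )
    assert resid == pytest.approx(0.0, abs=1e-6)
    # the fit should never be worse than the shipped default coefficients
    default_resid = sum(
        abs(est.normalizer_value(est.NormalizerModel.default(), s) - y)
        for s, y in planted
    )
    assert resid <= default_resid + 1e-9


# ---------------------------------------------------------------------------
# Feature functions


def test_gap_features_hand_counts():
    aln = Alignment(["a", "b"], ["AA--", "A-AA"])
    f_go, f_ge = est.feature_gaps(aln)
    assert f_ge == pytest.approx(3 / 8)
    assert f_go == pytest.approx(2 / 3)
    assert est.feature_gaps(Alignment(["a", "b"], ["AC", "AC"])) == (0.0, 0.0)


def test_identity_features_identical_sequences():
    aln = Alignment(["a", "b"], ["ACDE", "ACDE"])
    feats = est.feature_identity_family(aln, ss_list(aln))
    assert feats["F_SI"] == 1.0
    assert feats["F_AI"] == 1.0
    assert 0.0 <= feats["F_AS"] <= 1.0


def test_augmented_equals_unaugmented_at_unit_weights(small_suite):
    bench = small_suite[0]
    aln = bench.computed[3][1]
    feats = est.feature_identity_family(aln, bench.ss, weights=np.ones(aln.m))
    assert feats["Fp_SI"] == pytest.approx(feats["F_SI"])
    assert feats["Fp_AI"] == pytest.approx(feats["F_AI"])
    assert feats["Fp_AS"] == pytest.approx(feats["F_AS"])
    bl = est.feature_blockiness(aln, bench.ss)
    blw = est.feature_blockiness(aln, bench.ss, weights=np.ones(aln.m))
    assert blw == pytest.approx(bl)


def test_weighted_identity_hand_example():
    """Two columns, one SS-matching and one not; zero weight on the second
    leaves a pure match ratio of 1."""
    aln = Alignment(["a", "b"], ["AA", "AA"])
    ss = [
        SSConfidence("AA", np.array([[1, 0, 0], [1, 0, 0]])),
        SSConfidence("AA", np.array([[1, 0, 0], [0, 1, 0]])),
    ]
    feats = est.feature_identity_family(aln, ss, weights=np.array([1.0, 0.0]))
    assert feats["F_SI"] == pytest.approx(0.5)
    assert feats["Fp_SI"] == pytest.approx(1.0)


def brute_force_blockiness(aln, ss, weights=None, min_width=1, min_seqs=2):
    """Exhaustive packing enumeration over all disjoint interval sets."""
    k, m = aln.k, aln.m
    w = np.ones(m) if weights is None else np.asarray(weights, float)
    ords = aln.residue_ordinals()
    argmax_ss = [np.argmax(s.probs, axis=1) for s in ss]

    def block_score(i, j):
        best = 0.0
        for s in range(3):
            rows = [
                r
                for r in range(k)
                if all(
                    ords[r, c] >= 0 and argmax_ss[r][ords[r, c]] == s
                    for c in range(i, j + 1)
                )
            ]
            if len(rows) >= min_seqs:
                pairs = len(rows) * (len(rows) - 1) / 2
                best = max(best, float(np.sum(w[i : j + 1])) * pairs)
        return best

    intervals = [
        (i, j) for i in range(m) for j in range(i + min_width - 1, m)
    ]
    best_total = 0.0
    for r in range(len(intervals) + 1):
        for combo in itertools.combinations(intervals, r):
            ok = all(
                a2 > b1 or a1 > b2
                for (a1, b1), (a2, b2) in itertools.combinations(combo, 2)
            )
            if ok:
                best_total = max(
                    best_total, sum(block_score(i, j) for i, j in combo)
                )
        if r > 3:
            break
    residues = (ords >= 0).sum(axis=0)
    denom = float(np.sum(w * residues * (residues - 1) / 2))
    return best_total / denom if denom > 0 else 0.0


def test_blockiness_uniform_helix_is_one():
    aln = Alignment(["a", "b", "c"], ["ACDE", "ACDE", "ACDE"])
    assert est.feature_blockiness(aln, ss_list(aln, "H")) == pytest.approx(1.0)


def test_blockiness_alternating_types_and_min_width():
    aln = Alignment(["a", "b"], ["ACAC", "ACAC"])
    ss = [
        SSConfidence("ACAC", np.array([[1, 0, 0], [0, 1, 0]] * 2)),
        SSConfidence("ACAC", np.array([[1, 0, 0], [0, 1, 0]] * 2)),
    ]
    # width-1 blocks still cover every pair
    assert est.feature_blockiness(aln, ss) == pytest.approx(1.0)
    # requiring width >= 2 makes uniform blocks impossible here
    assert est.feature_blockiness(aln, ss, min_width=2) == pytest.approx(0.0)


def test_blockiness_dp_matches_enumeration_on_random_inputs():
    rng = np.random.default_rng(5)
    for trial in range(8):
        k = int(rng.integers(2, 5))
        m = int(rng.integers(2, 6))
        rows = []
        for _ in range(k):
            rows.append(
                "".join(
                    "-" if rng.random() < 0.25 else
                    str(rng.choice(list("ACDE"))) for _ in range(m)
                )
            )
        # keep at least one residue per row for ss attachment
        rows = [r if r.strip("-") else "A" + r[1:] for r in rows]
        aln = Alignment([f"s{i}" for i in range(k)], rows)
        ss = []
        for i in range(k):
            n = len(aln.ungapped(i))
            probs = np.zeros((n, 3))
            probs[np.arange(n), rng.integers(0, 3, size=n)] = 1.0
            ss.append(SSConfidence(aln.ungapped(i), probs))
        weights = rng.random(m) if trial % 2 else None
        got = est.feature_blockiness(aln, ss, weights=weights)
        expect = brute_force_blockiness(aln, ss, weights=weights)
        assert got == pytest.approx(expect, abs=1e-9)


def test_ss_agreement_extremes():
    aln = Alignment(["a", "b"], ["ACDE", "ACDE"])
    assert est.feature_ss_agreement(aln, ss_list(aln, "H")) == pytest.approx(1.0)
    ss = [ss_list(aln, "H")[0], ss_list(aln, "E")[1]]
    assert est.feature_ss_agreement(aln, ss) == pytest.approx(0.0)
    uniform = [
        SSConfidence(aln.ungapped(i), np.full((4, 3), 1 / 3)) for i in range(2)
    ]
    assert est.feature_ss_agreement(aln, uniform) == pytest.approx(1 / 3)


def test_feature_ranges_on_random_suite(small_suite):
    for bench in small_suite[:2]:
        for pid, aln in bench.computed[:3]:
            feats = est.compute_features(aln, bench.ss)
            for name in ("F_SI", "F_AI", "F_AS", "F_SA", "F_GO", "F_GE", "F_BL"):
                assert 0.0 <= feats[name] <= 1.0, name


# ---------------------------------------------------------------------------
# Estimator and advisor


def test_estimate_accuracy_printed_coefficients():
    names = list(est.DEFAULT_ESTIMATOR_COEFFS)
    ones = {n: 1.0 for n in names}
    model = est.EstimatorModel.default()
    assert est.estimate_accuracy(model, ones) == pytest.approx(1.088)
    zeros = {n: 0.0 for n in names}
    assert est.estimate_accuracy(model, zeros) == 0.0
    single = est.EstimatorModel({"F_SI": 1.0})
    assert est.estimate_accuracy(single, {"F_SI": 0.37}) == pytest.approx(0.37)
    with pytest.raises(KeyError, match="missing"):
        est.estimate_accuracy(model, {"F_SI": 1.0})


def test_fit_estimator_recovers_planted_coefficient():
    rng = np.random.default_rng(3)
    benches = []
    for _ in range(6):
        rows = []
        for _ in range(5):
            feats = {n: float(rng.random()) for n in est.FEATURE_NAMES}
            rows.append((feats, 0.7 * feats["F_SI"]))
        benches.append(rows)
    model = est.fit_estimator(benches)
    assert model.coefficients.get("F_SI", 0.0) == pytest.approx(0.7, abs=1e-6)
    others = {n: c for n, c in model.coefficients.items() if n != "F_SI"}
    assert all(abs(c) < 1e-6 for c in others.values())
    # duplicated rows leave the fit unchanged
    model2 = est.fit_estimator(benches + benches)
    assert model2.coefficients.get("F_SI", 0.0) == pytest.approx(
        model.coefficients["F_SI"], abs=1e-9
    )


def test_advise_argmax_and_ties():
    model = est.EstimatorModel({"F_SI": 1.0})
    feats = [{"F_SI": v} for v in (0.3, 0.9, 0.5)]
    assert est.advise(feats, model) == 1
    assert est.advise([{"F_SI": 0.4}], model) == 0
    assert est.advise([{"F_SI": 0.7}, {"F_SI": 0.7}], model) == 0


def test_evaluate_advising_oracle_dominates():
    rng = np.random.default_rng(9)
    instances = []
    for i in range(8):
        cands = {}
        for j in range(4):
            acc = float(rng.random())
            cands[f"p{j}"] = ({"F_SI": acc}, acc)  # oracle feature
        instances.append(
            {"difficulty": float(rng.random()), "candidates": cands}
        )
    oracle = est.EstimatorModel({"F_SI": 1.0})
    per_bin, overall = est.evaluate_advising(instances, oracle)
    # the oracle advisor picks each benchmark's best candidate
    for inst in instances:
        best = max(acc for _, acc in inst["candidates"].values())
        from msacore.truth import difficulty_bin

        assert per_bin[difficulty_bin(inst["difficulty"])] >= 0.0
    anti = est.EstimatorModel({"F_GE": 1.0})
    for inst in instances:
        for pid in inst["candidates"]:
            inst["candidates"][pid][0]["F_GE"] = float(rng.random())
    _, other = est.evaluate_advising(instances, anti)
    assert overall >= other - 1e-12


def test_evaluate_advising_single_bin_mean():
    instances = [
        {"difficulty": 0.55, "candidates": {"p0": ({"F_SI": 1.0}, 0.6)}},
        {"difficulty": 0.52, "candidates": {"p0": ({"F_SI": 1.0}, 0.8)}},
    ]
    per_bin, overall = est.evaluate_advising(
        instances, est.EstimatorModel({"F_SI": 1.0})
    )
    assert per_bin == {5: pytest.approx(0.7)}
    assert overall == pytest.approx(0.7)
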