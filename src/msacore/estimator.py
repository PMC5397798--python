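"""Alignment accuracy estimation with coreness-augmented features, and the
parameter advisor built on it.

The estimator is a non-negative linear combination of feature functions of
an alignment (all roughly in [0,1]).  Features that are sums over column
residue pairs (secondary-structure identity, amino-acid identity, average
substitution score, blockiness) have *augmented* variants in which each
column's contribution — numerator and denominator alike — is weighted by the
column's predicted coreness.  The Predicted-Alignment-Coreness feature
counts predicted-core columns, normalized by an estimate L(S) of the
reference's true core-column count that depends only on the ungapped
sequences, so alternate alignments of the same sequences share the
denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog, nnls

from .alphabet import GAP
from .io import Alignment, SSConfidence, attach_ss, register_model

#: Amino-acid equivalence classes for the Amino Acid Identity feature.
AA_CLASSES = ("LVIM", "C", "A", "G", "ST", "P", "FYW", "EDNQ", "KR", "H")

#: Canonical feature order for fitted coefficient vectors.
FEATURE_NAMES = [
    "F_AC", "Fp_SI", "Fp_BL", "Fp_AI", "Fp_AS",
    "F_SI", "F_BL", "F_AI", "F_AS", "F_SA", "F_GO", "F_GE",
]

#: Window weights (relative) for Secondary Structure Agreement, offsets -2..+2.
SA_WEIGHTS = np.array([1.0, 2.0, 4.0, 2.0, 1.0])


def _blosum62_scaled() -> dict[tuple[str, str], float]:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    aas = "ACDEFGHIKLMNPQRSTVWY"
    vals = np.array([[mat[a, b] for b in aas] for a in aas], dtype=float)
    scaled = (vals - vals.min()) / (vals.max() - vals.min())
    return {
        (a, b): scaled[i, j]
        for i, a in enumerate(aas)
        for j, b in enumerate(aas)
    }


_BLOSUM = None


def blosum62_pair_score(a: str, b: str) -> float:
    """BLOSUM62 similarity rescaled to [0,1] over the 20x20 entries."""
    global _BLOSUM
    if _BLOSUM is None:
        _BLOSUM = _blosum62_scaled()
    return _BLOSUM[(a, b)]


# ---------------------------------------------------------------------------
# Sequence statistics and the core-column-count normalizer


@dataclass(frozen=True)
class SequenceStats:
    """Length aggregates and pairwise LCS/length ratios of a sequence set."""

    l_min: float
    l_avg: float
    l_max: float
    p_min: float
    p_avg: float
    p_max: float
    q_min: float
    q_avg: float
    r_min: float
    r_avg: float

    def __getitem__(self, key: str) -> float:
        return getattr(self, key)


def _lcs_length(a: str, b: str) -> int:
    # standard O(|a||b|) dynamic program, rolling rows
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    for ca in a:
        cur = prev.copy()
        match = np.frombuffer(b.encode(), dtype=np.uint8) == ord(ca)
        for j in range(1, len(b) + 1):
            cur[j] = prev[j - 1] + 1 if match[j - 1] else max(cur[j - 1], prev[j])
        prev = cur
    return int(prev[-1])


def sequence_stats(sequences: list[str]) -> SequenceStats:
    """Pairwise LCS identity, length quotient, and relative-indel averages."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    if any(len(s) == 0 for s in sequences):
        raise ValueError("empty sequence")
    lens = np.array([len(s) for s in sequences], dtype=float)
    p = {"min": [], "avg": [], "max": []}
    q = {"min": [], "avg": []}
    r = {"min": [], "avg": []}
    for i, j in itertools.combinations(range(len(sequences)), 2):
        la, lb = lens[i], lens[j]
        lcs = _lcs_length(sequences[i], sequences[j])
        agg = {"min": min(la, lb), "avg": (la + lb) / 2, "max": max(la, lb)}
        for key in p:
            p[key].append(lcs / agg[key])
        q["min"].append(agg["min"] / agg["max"])
        q["avg"].append(agg["avg"] / agg["max"])
        r["min"].append(abs(la - lb) / agg["min"])
        r["avg"].append(abs(la - lb) / agg["avg"])
    return SequenceStats(
        float(lens.min()), float(lens.mean()), float(lens.max()),
        *(float(np.mean(p[k])) for k in ("min", "avg", "max")),
        float(np.mean(q["min"])), float(np.mean(q["avg"])),
        float(np.mean(r["min"])), float(np.mean(r["avg"])),
    )


_LENGTHS = ("l_min", "l_avg", "l_max")
_RATIO_GROUPS = (("p_min", "p_avg", "p_max"), ("q_min", "q_avg"), ("r_min", "r_avg"))


def candidate_terms() -> list[tuple[str, ...]]:
    """All 72 candidate normalizer terms: one length aggregate times at most
    two ratios from distinct ratio groups."""
    terms = []
    for ell in _LENGTHS:
        terms.append((ell,))
        for grp in _RATIO_GROUPS:
            for ratio in grp:
                terms.append((ell, ratio))
        for g1, g2 in itertools.combinations(_RATIO_GROUPS, 2):
            for r1 in g1:
                for r2 in g2:
                    terms.append((ell, r1, r2))
    return terms


#: Fitted default coefficients of the core-column-count normalizer L(S).
DEFAULT_NORMALIZER_TERMS = {
    ("l_min", "p_max", "q_min"): 1.020,
    ("l_min", "q_min"): 0.151,
    ("l_avg", "p_max", "q_avg"): 0.035,
    ("l_avg", "p_min", "r_min"): 0.032,
    ("l_max", "p_avg", "r_avg"): 0.003,
}


@register_model("normalizer_model")
@dataclass
class NormalizerModel:
    """Non-negative linear combination over the candidate terms."""

    coefficients: dict[tuple[str, ...], float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.coefficients.values()):
            raise ValueError("normalizer coefficients must be non-negative")

    def to_json(self) -> dict:
        return {"terms": [[list(t), v] for t, v in self.coefficients.items()]}

    @classmethod
    def from_json(cls, d: dict) -> "NormalizerModel":
        return cls({tuple(t): v for t, v in d["terms"]})

    @classmethod
    def default(cls) -> "NormalizerModel":
        return cls(dict(DEFAULT_NORMALIZER_TERMS))


def normalizer_value(model: NormalizerModel, stats: SequenceStats) -> float:
    """L(S): the estimated number of core columns in the unknown reference."""
    total = 0.0
    for term, coef in model.coefficients.items():
        prod = coef
        for factor in term:
            prod *= stats[factor]
        total += prod
    return total


def fit_normalizer(
    training: list[tuple[SequenceStats, float]]
) -> NormalizerModel:
    """L1 fit of the normalizer to true core-column counts by LP.

    Minimizes sum_b |L(S_b) - y_b| over non-negative coefficients on the
    72-term candidate set; solved deterministically with HiGHS.
    """
    if len(training) < 2:
        raise ValueError("need at least 2 training benchmarks")
    terms = candidate_terms()
    X = np.array(
        [[np.prod([s[f] for f in t]) for t in terms] for s, _ in training]
    )
    y = np.array([c for _, c in training], dtype=float)
    nT, nB = len(terms), len(training)
    # variables: coefficients (nT) then residual magnitudes (nB)
    c = np.concatenate([np.zeros(nT), np.ones(nB)])
    A = np.block(
        [[X, -np.eye(nB)], [-X, -np.eye(nB)]]
    )
    b = np.concatenate([y, -y])
    res = linprog(c, A_ub=A, b_ub=b, bounds=[(0, None)] * (nT + nB), method="highs")
    if res.status != 0:
        raise RuntimeError(f"normalizer LP failed: {res.message}")
    coefs = {t: float(v) for t, v in zip(terms, res.x[:nT]) if v > 1e-12}
    return NormalizerModel(coefs)


# ---------------------------------------------------------------------------
# Feature functions


def _column_pair_data(aln: Alignment, ss: list[SSConfidence]):
    """Per column: list of (row, ordinal) residues, for pair iteration."""
    ords = aln.residue_ordinals()
    cols = []
    for j in range(aln.m):
        cols.append(
            [(i, int(ords[i, j])) for i in range(aln.k) if ords[i, j] >= 0]
        )
    return cols


def _weighted_ratio(nums: np.ndarray, dens: np.ndarray, weights) -> float:
    w = np.ones_like(nums) if weights is None else np.asarray(weights, dtype=float)
    den = float(np.sum(w * dens))
    return float(np.sum(w * nums)) / den if den > 0 else 0.0


def feature_identity_family(
    aln: Alignment,
    ss: list[SSConfidence] | dict[str, SSConfidence],
    weights=None,
) -> dict[str, float]:
    """Secondary-structure identity, amino-acid identity, and average
    substitution score, plus their coreness-weighted variants.

    Each is a ratio of summed per-column pair counts (or pair scores); the
    augmented variants weight both numerator and denominator column terms by
    the column's predicted coreness.
    """
    if isinstance(ss, dict):
        ss = attach_ss(aln, ss)
    cols = _column_pair_data(aln, ss)
    argmax_ss = [np.argmax(s.probs, axis=1) for s in ss]
    aa_class = {a: ci for ci, grp in enumerate(AA_CLASSES) for a in grp}
    m = aln.m
    si = np.zeros(m)
    ai = np.zeros(m)
    asum = np.zeros(m)
    npairs = np.zeros(m)
    for j, residues in enumerate(cols):
        for (i1, o1), (i2, o2) in itertools.combinations(residues, 2):
            a1, a2 = aln.rows[i1][j], aln.rows[i2][j]
            npairs[j] += 1
            si[j] += argmax_ss[i1][o1] == argmax_ss[i2][o2]
            ai[j] += aa_class[a1] == aa_class[a2]
            asum[j] += blosum62_pair_score(a1, a2)
    out = {
        "F_SI": _weighted_ratio(si, npairs, None),
        "F_AI": _weighted_ratio(ai, npairs, None),
        "F_AS": _weighted_ratio(asum, npairs, None),
    }
    w = np.ones(m) if weights is None else np.asarray(weights, dtype=float)
    out["Fp_SI"] = _weighted_ratio(si, npairs, w)
    out["Fp_AI"] = _weighted_ratio(ai, npairs, w)
    out["Fp_AS"] = _weighted_ratio(asum, npairs, w)
    return out


def feature_blockiness(
    aln: Alignment,
    ss: list[SSConfidence] | dict[str, SSConfidence],
    weights=None,
    min_width: int = 1,
    min_seqs: int = 2,
) -> float:
    """Best packing of secondary-structure blocks, as a fraction of all
    (coreness-weighted) residue pairs.

    A block is a column interval with a subset of >= ``min_seqs`` sequences
    that is gap-free and uniform in predicted secondary structure; a packing
    uses disjoint intervals; the score of a block is its (weighted) count of
    within-column residue pairs.  Solved exactly by dynamic programming over
    the column intervals.
    """
    if isinstance(ss, dict):
        ss = attach_ss(aln, ss)
    k, m = aln.k, aln.m
    w = np.ones(m) if weights is None else np.asarray(weights, dtype=float)
    ords = aln.residue_ordinals()
    # ok[s, row, col]: residue present with argmax secondary structure s
    ok = np.zeros((3, k, m), dtype=bool)
    for i in range(k):
        am = np.argmax(ss[i].probs, axis=1)
        for j in range(m):
            if ords[i, j] >= 0:
                ok[am[ords[i, j]], i, j] = True
    residues_per_col = (ords >= 0).sum(axis=0)
    total_pairs = float(np.sum(w * residues_per_col * (residues_per_col - 1) / 2))
    if total_pairs <= 0:
        return 0.0
    best = np.zeros(m + 1)
    for j in range(1, m + 1):
        best[j] = best[j - 1]
        alive = ok[:, :, j - 1].copy()  # per ss-type row masks over [i..j]
        for i in range(j, 0, -1):
            if i < j:
                alive &= ok[:, :, i - 1]
            if j - i + 1 < min_width:
                continue
            wsum = float(np.sum(w[i - 1 : j]))
            counts = alive.sum(axis=1)
            score = 0.0
            for s in range(3):
                n = int(counts[s])
                if n >= min_seqs:
                    score = max(score, wsum * n * (n - 1) / 2)
            if score > 0:
                best[j] = max(best[j], best[i - 1] + score)
    return float(best[m] / total_pairs)


def feature_gaps(aln: Alignment) -> tuple[float, float]:
    """(F_GO, F_GE): gap-run starts over gaps, and gaps over all entries."""
    gaps = runs = 0
    for row in aln.rows:
        prev = None
        for ch in row:
            if ch == GAP:
                gaps += 1
                if prev != GAP:
                    runs += 1
            prev = ch
    f_ge = gaps / (aln.k * aln.m)
    f_go = runs / gaps if gaps else 0.0
    return f_go, f_ge


def feature_ss_agreement(
    aln: Alignment, ss: list[SSConfidence] | dict[str, SSConfidence]
) -> float:
    """Probability that column residue pairs share a secondary-structure
    state, estimated in a weighted +-2 window along the two sequences and
    averaged over all pairs."""
    if isinstance(ss, dict):
        ss = attach_ss(aln, ss)
    cols = _column_pair_data(aln, ss)
    total = 0.0
    n = 0
    for residues in cols:
        for (i1, o1), (i2, o2) in itertools.combinations(residues, 2):
            p1, p2 = ss[i1].probs, ss[i2].probs
            acc = wsum = 0.0
            for t, wt in zip(range(-2, 3), SA_WEIGHTS):
                a, b = o1 + t, o2 + t
                if 0 <= a < len(p1) and 0 <= b < len(p2):
                    acc += wt * float(p1[a] @ p2[b])
                    wsum += wt
            if wsum > 0:
                total += acc / wsum
                n += 1
    return total / n if n else 0.0


def feature_predicted_alignment_coreness(
    aln: Alignment,
    ss,
    regressor,
    kappa: float = 0.5,
    normalizer: NormalizerModel | None = None,
) -> float:
    """F_AC: predicted-core column count over the normalizer L(S)."""
    from .regress import predict_alignment

    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0,1]")
    normalizer = normalizer or NormalizerModel.default()
    chi = predict_alignment(regressor, aln, ss)
    L = normalizer_value(normalizer, sequence_stats([aln.ungapped(i) for i in range(aln.k)]))
    count = int(np.sum(chi >= kappa))
    return count / L if L > 0 else 0.0


def compute_features(
    aln: Alignment,
    ss: dict[str, SSConfidence] | list[SSConfidence],
    regressor=None,
    kappa: float = 0.5,
    normalizer: NormalizerModel | None = None,
    coreness_weights=None,
) -> dict[str, float]:
    """All feature values for one alignment.

    Column coreness weights come from the regressor when given (or can be
    passed directly); without either, the augmented features coincide with
    their unaugmented versions and F_AC is 0.
    """
    if isinstance(ss, dict):
        ss = attach_ss(aln, ss)
    weights = coreness_weights
    f_ac = 0.0
    if regressor is not None:
        from .regress import predict_alignment

        if weights is None:
            weights = predict_alignment(regressor, aln, ss)
        normalizer = normalizer or NormalizerModel.default()
        stats = sequence_stats([aln.ungapped(i) for i in range(aln.k)])
        L = normalizer_value(normalizer, stats)
        f_ac = float(np.sum(np.asarray(weights) >= kappa)) / L if L > 0 else 0.0
    feats = feature_identity_family(aln, ss, weights)
    feats["F_BL"] = feature_blockiness(aln, ss, None)
    feats["Fp_BL"] = feature_blockiness(aln, ss, weights)
    feats["F_SA"] = feature_ss_agreement(aln, ss)
    feats["F_GO"], feats["F_GE"] = feature_gaps(aln)
    feats["F_AC"] = f_ac
    return feats


# ---------------------------------------------------------------------------
# The estimator and the advisor


#: Fitted default coefficients of the coreness-augmented estimator.
DEFAULT_ESTIMATOR_COEFFS = {
    "Fp_SI": 0.656,
    "Fp_BL": 0.128,
    "F_SA": 0.123,
    "F_SI": 0.089,
    "F_BL": 0.064,
    "F_AC": 0.015,
    "F_GE": 0.007,
    "F_GO": 0.006,
}


@register_model("estimator_model")
@dataclass
class EstimatorModel:
    """Non-negative feature coefficients of the accuracy estimator."""

    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.coefficients.values()):
            raise ValueError("estimator coefficients must be non-negative")
        if not any(v > 0 for v in self.coefficients.values()):
            raise ValueError("estimator needs at least one non-zero coefficient")

    def to_json(self) -> dict:
        return {"coefficients": self.coefficients}

    @classmethod
    def from_json(cls, d: dict) -> "EstimatorModel":
        return cls(dict(d["coefficients"]))

    @classmethod
    def default(cls) -> "EstimatorModel":
        return cls(dict(DEFAULT_ESTIMATOR_COEFFS))


def estimate_accuracy(model: EstimatorModel, features: dict[str, float]) -> float:
    """Dot product of coefficients and feature values."""
    missing = [f for f in model.coefficients if f not in features]
    if missing:
        raise KeyError(f"missing feature(s): {missing}")
    return float(sum(c * features[f] for f, c in model.coefficients.items()))


def fit_estimator(
    benchmarks: list[list[tuple[dict[str, float], float]]],
    feature_names: list[str] | None = None,
) -> EstimatorModel:
    """Fit coefficients by non-negative least squares on within-benchmark
    differences of true accuracy against differences of features.

    Each benchmark contributes its alignment pairs, oriented so the accuracy
    difference is non-negative; this targets the ranking behavior an advisor
    needs.  Deterministic.
    """
    names = feature_names or FEATURE_NAMES
    rows, resp = [], []
    for bench in benchmarks:
        for (f1, a1), (f2, a2) in itertools.combinations(bench, 2):
            if a1 == a2:
                continue
            if a1 < a2:
                (f1, a1), (f2, a2) = (f2, a2), (f1, a1)
            rows.append([f1[n] - f2[n] for n in names])
            resp.append(a1 - a2)
    if not rows:
        raise ValueError("need at least one benchmark with >= 2 alignments "
                         "of distinct accuracy")
    coefs, _ = nnls(np.asarray(rows), np.asarray(resp))
    out = {n: float(c) for n, c in zip(names, coefs) if c > 1e-12}
    if not out:
        out = {names[0]: 1.0}
    return EstimatorModel(out)


def advise(
    candidate_features: list[dict[str, float]], model: EstimatorModel
) -> int:
    """Index of the candidate of highest estimated accuracy (ties: lowest)."""
    if not candidate_features:
        raise ValueError("no candidates")
    scores = [estimate_accuracy(model, f) for f in candidate_features]
    return int(np.argmax(scores))


def evaluate_advising(
    instances: list[dict],
    model: EstimatorModel,
    advisor_set: list[str] | None = None,
) -> tuple[dict[int, float], float]:
    """Bin-averaged advising accuracy.

    Each instance is ``{"difficulty": float, "candidates": {pid: (features,
    true_accuracy)}}``.  Within each difficulty bin the advised alignments'
    true accuracies are averaged; the final score is the mean over non-empty
    bins (so easy benchmarks do not dominate).
    """
    from .truth import difficulty_bin

    by_bin: dict[int, list[float]] = {}
    for inst in instances:
        cands = inst["candidates"]
        pids = advisor_set if advisor_set is not None else sorted(cands)
        feats = [cands[p][0] for p in pids]
        chosen = pids[advise(feats, model)]
        acc = cands[chosen][1]
        by_bin.setdefault(difficulty_bin(inst["difficulty"]), []).append(acc)
    per_bin = {b: float(np.mean(v)) for b, v in sorted(by_bin.items())}
    overall = float(np.mean(list(per_bin.values())))
    return per_bin, overall
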