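"""Column profiles, windows, window classes, and training-set assembly.

A column is summarized by its *profile*: a distribution over the state set Q
(amino-acid x secondary-structure pairs plus the gap state) obtained by
spreading each residue's secondary-structure confidence over its states and
counting gaps.  A *window* is 2w+1 consecutive profiles centered on the
column of interest; its *class* is the pattern of core/non-core labels of
its columns (for w=1: CCC, CCN, NCC core; CNN, NNC structured non-core;
NNN unstructured).  Patterns with the center flanked by the opposite label
on both sides (NCN, CNC) are excluded from training, as they essentially
never occur in reference alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import GAP, StateAlphabet
from .io import Alignment, Benchmark, SSConfidence, attach_ss
from . import truth

EXCLUDED = "excluded"
CORE, NONCORE = "C", "N"


def window_classes(w: int = 1) -> list[str]:
    """Structured classes in canonical order, then the all-N class last.

    For w=1 this is the fixed order CCC, CCN, NCC, CNN, NNC, NNN used for
    deterministic tie-breaking throughout.
    """
    n = 2 * w + 1
    pats: list[str] = []
    for bits in range(2**n):
        s = "".join(CORE if (bits >> i) & 1 == 0 else NONCORE for i in range(n))
        if window_class(s) not in (EXCLUDED, None):
            pats.append(s)
    core = sorted(
        (p for p in pats if p[w] == CORE), key=lambda s: (s.count(NONCORE), s)
    )
    non = sorted(
        (p for p in pats if p[w] == NONCORE and CORE in p),
        key=lambda s: (s.count(CORE), s),
    )
    bottom = NONCORE * n
    return core + non + [bottom]


def structured_classes(w: int = 1) -> list[str]:
    return window_classes(w)[:-1]


def core_classes(w: int = 1) -> list[str]:
    return [c for c in structured_classes(w) if c[w] == CORE]


def bottom_class(w: int = 1) -> str:
    return NONCORE * (2 * w + 1)


def window_class(labels) -> str:
    """Class string for a window's column labels, or ``"excluded"``.

    Excluded patterns have a center column flanked on both immediate sides
    by the opposite label (NCN-like or CNC-like centers).
    """
    s = "".join(labels)
    w = (len(s) - 1) // 2
    if w >= 1:
        c, left, right = s[w], s[w - 1], s[w + 1]
        if c == CORE and left == right == NONCORE:
            return EXCLUDED
        if c == NONCORE and left == right == CORE:
            return EXCLUDED
    return s


@dataclass
class Window:
    """2w+1 consecutive column profiles with optional training metadata."""

    profiles: np.ndarray  # shape (2w+1, |Q|)
    label: str | None = None  # class string, "excluded", or None if unlabeled
    coreness: float | None = None  # true coreness of the center column
    source: str = ""

    @property
    def width(self) -> int:
        return (self.profiles.shape[0] - 1) // 2


def column_profile(
    column: str, ss_triples: np.ndarray, alphabet: StateAlphabet
) -> np.ndarray:
    """Profile of one column: C(a,s) = (1/k) sum of confidences, C(gap) = gap
    frequency.

    ``ss_triples`` holds one (helix, strand, coil) triple per non-gap residue
    of the column, in row order.
    """
    k = len(column)
    prof = np.zeros(alphabet.size)
    it = iter(np.asarray(ss_triples, dtype=float))
    for ch in column:
        if ch == GAP:
            prof[alphabet.gap_state] += 1.0 / k
        else:
            triple = next(it, None)
            if triple is None:
                raise ValueError("missing secondary-structure triple for residue")
            base = 3 * alphabet.group_of(ch)
            prof[base : base + 3] += triple / k
    return prof


def alignment_profiles(
    aln: Alignment, ss: list[SSConfidence], alphabet: StateAlphabet
) -> np.ndarray:
    """(m, |Q|) profile matrix for all columns of an alignment."""
    ords = aln.residue_ordinals()
    profs = np.zeros((aln.m, alphabet.size))
    k = aln.k
    for i, row in enumerate(aln.rows):
        probs = ss[i].probs
        for j, ch in enumerate(row):
            if ch == GAP:
                profs[j, alphabet.gap_state] += 1.0 / k
            else:
                base = 3 * alphabet.group_of(ch)
                profs[j, base : base + 3] += probs[ords[i, j]] / k
    return profs


def pad_profiles(profiles: np.ndarray, w: int, alphabet: StateAlphabet) -> np.ndarray:
    """Pad w pure-gap-state profiles on each side (columns beyond the edges)."""
    pad = np.zeros((w, alphabet.size))
    pad[:, alphabet.gap_state] = 1.0
    return np.vstack([pad, profiles, pad])


def extract_windows(
    aln: Alignment,
    ss: list[SSConfidence] | dict[str, SSConfidence],
    w: int,
    alphabet: StateAlphabet,
    labels: np.ndarray | None = None,
    coreness: np.ndarray | None = None,
    source: str = "",
) -> list[Window]:
    """One window per column, edge-padded with pure-gap profiles."""
    if w < 1:
        raise ValueError("window width must be >= 1")
    if isinstance(ss, dict):
        ss = attach_ss(aln, ss)
    profs = pad_profiles(alignment_profiles(aln, ss, alphabet), w, alphabet)
    out = []
    for j in range(aln.m):
        lab = None
        if labels is not None:
            padded = [NONCORE] * w + list(labels) + [NONCORE] * w
            lab = window_class(padded[j : j + 2 * w + 1])
        out.append(
            Window(
                profiles=profs[j : j + 2 * w + 1].copy(),
                label=lab,
                coreness=None if coreness is None else float(coreness[j]),
                source=source,
            )
        )
    return out


def labeled_windows(
    bench: Benchmark,
    w: int,
    alphabet: StateAlphabet,
    threshold: float = 0.5,
    source: str = "computed",
) -> list[Window]:
    """Windows with class labels derived from true coreness.

    ``source`` selects whether windows come from the benchmark's computed
    alignments, its reference alignment, or both.
    """
    out: list[Window] = []
    if source in ("reference", "both"):
        cor = np.asarray(bench.core, dtype=float)
        labs = truth.label_columns(cor, threshold)
        out += extract_windows(
            bench.reference, bench.ss, w, alphabet, labs, cor,
            source=f"{bench.name}/reference",
        )
    if source in ("computed", "both"):
        for pid, aln in bench.computed:
            cor = truth.column_coreness_vector(aln, bench.reference, bench.core)
            labs = truth.label_columns(cor, threshold)
            out += extract_windows(
                aln, bench.ss, w, alphabet, labs, cor,
                source=f"{bench.name}/{pid}",
            )
    return out


@dataclass
class WindowSets:
    """Per-class training pools T_c, sample indices S_c, and test windows."""

    width: int
    train: dict[str, list[Window]]  # class -> T_c (bottom class included)
    sample_idx: dict[str, np.ndarray]  # class -> indices of S_c within T_c
    test: list[Window]
    seed: int

    def samples(self, cls: str) -> list[Window]:
        return [self.train[cls][i] for i in self.sample_idx[cls]]

    @property
    def classes(self) -> list[str]:
        return structured_classes(self.width)


def assign_folds(
    difficulties: list[float], n_folds: int = 12
) -> np.ndarray:
    """Round-robin fold assignment within difficulty bins (balanced folds)."""
    bins = [truth.difficulty_bin(d) for d in difficulties]
    folds = np.zeros(len(bins), dtype=int)
    counter = 0
    for b in sorted(set(bins)):
        for idx in [i for i, bb in enumerate(bins) if bb == b]:
            folds[idx] = counter % n_folds
            counter += 1
    return folds


def assemble_window_sets(
    windows_by_benchmark: list[list[Window]],
    fold_of: np.ndarray,
    test_folds: set[int],
    n_train: int,
    n_sample: int,
    n_test: int,
    seed: int,
    w: int = 1,
    n_train_bottom: int | None = None,
) -> WindowSets:
    """Sample per-class training pools and a mixed test set from disjoint folds.

    ``n_train`` windows per structured class form T_c; ``n_sample`` *total*
    windows (spread evenly over structured classes) form the samples S_c;
    ``n_test`` windows over all classes form the test set.  Sampling is
    uniform without replacement and reproducible by seed.
    """
    rng = np.random.default_rng(seed)
    classes = structured_classes(w)
    bot = bottom_class(w)
    pools: dict[str, list[Window]] = {c: [] for c in classes + [bot]}
    test_pool: list[Window] = []
    for bench_idx, wins in enumerate(windows_by_benchmark):
        is_test = fold_of[bench_idx] in test_folds
        for win in wins:
            if win.label == EXCLUDED or win.label is None:
                if is_test:
                    test_pool.append(win)  # prediction does not see labels
                continue
            if is_test:
                test_pool.append(win)
            else:
                pools[win.label].append(win)

    def sample(pool: list, n: int, what: str) -> list:
        if n > len(pool):
            raise ValueError(
                f"requested {n} {what} windows but only {len(pool)} available"
            )
        idx = rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in idx]

    train = {c: sample(pools[c], n_train, c) for c in classes}
    n_bot = len(pools[bot]) if n_train_bottom is None else n_train_bottom
    train[bot] = sample(pools[bot], min(n_bot, len(pools[bot])), bot)
    per_class = max(1, n_sample // len(classes))
    sample_idx = {
        c: rng.choice(n_train, size=min(per_class, n_train), replace=False)
        for c in classes
    }
    sample_idx[bot] = rng.choice(
        len(train[bot]), size=min(per_class, len(train[bot])), replace=False
    )
    test = sample(test_pool, n_test, "test") if n_test else list(test_pool)
    return WindowSets(w, train, sample_idx, test, seed)
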