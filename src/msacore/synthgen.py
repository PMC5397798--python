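"""Synthetic benchmark suites with known core columns and controlled
computed-alignment accuracy.

The generator emulates the structure that makes core columns learnable in
real benchmarks: core columns are gap-free and conserved (a consensus
residue with occasional substitutions, helix or strand secondary structure
in runs), while non-core columns are gappy with near-uniform residues and
mostly coil structure.  Alternate "computed" alignments of prescribed true
accuracy are made by displacing residues out of a chosen set of core
columns, which destroys a controlled number of core residue pairs; the
realized accuracy is recorded exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import AMINO_ACIDS, GAP
from .io import (
    Alignment,
    Benchmark,
    SSConfidence,
    write_alignment,
    write_core_annotation,
    write_manifest,
    write_ss2,
)


@dataclass
class SuiteConfig:
    """Study conditions for a synthetic suite; the seed is mandatory."""

    seed: int
    n_benchmarks: int = 12
    k: int = 6  # sequences per benchmark
    m: int = 60  # reference columns
    core_fraction: float = 0.4
    core_conservation: float = 0.9  # P(consensus residue) in core columns
    noncore_gap_rate: float = 0.4
    ss_run_mean: float = 6.0  # mean run length of non-core SS segments
    confidence_sharpness: float = 10.0  # Dirichlet peaking toward the label
    accuracy_levels: tuple[float, ...] = (
        0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95,
    )

    def __post_init__(self) -> None:
        for p in (
            self.core_fraction,
            self.core_conservation,
            self.noncore_gap_rate,
            *self.accuracy_levels,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")


def _core_layout(m: int, n_core: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean core mask: core runs of length >= 2 separated by non-core."""
    if n_core < 2:
        raise ValueError("need at least 2 core columns (minimum run length 2)")
    n_non = m - n_core
    # split the core columns into runs of >= 2
    max_runs = min(n_core // 2, max(n_non, 1))
    n_runs = int(rng.integers(1, max_runs + 1))
    runs = np.full(n_runs, 2)
    for _ in range(n_core - 2 * n_runs):
        runs[rng.integers(n_runs)] += 1
    # distribute non-core columns into the n_runs+1 slots, interior >= 1
    slots = np.zeros(n_runs + 1, dtype=int)
    slots[1:n_runs] = 1
    for _ in range(n_non - max(n_runs - 1, 0)):
        slots[rng.integers(n_runs + 1)] += 1
    mask = []
    for r in range(n_runs):
        mask += [False] * slots[r] + [True] * runs[r]
    mask += [False] * slots[n_runs]
    return np.array(mask)


def _ss_labels(core_mask: np.ndarray, run_mean: float, rng) -> np.ndarray:
    """Per-column SS label index (0=H, 1=E, 2=C), coherent in runs.

    Each core run gets a single helix-or-strand type; non-core stretches are
    split into runs that are mostly coil.
    """
    m = len(core_mask)
    labels = np.full(m, 2)
    j = 0
    while j < m:
        if core_mask[j]:
            end = j
            while end < m and core_mask[end]:
                end += 1
            labels[j:end] = rng.integers(0, 2)  # helix or strand
            j = end
        else:
            seg_end = j
            while seg_end < m and not core_mask[seg_end]:
                seg_end += 1
            run = max(1, int(rng.poisson(run_mean)))
            end = min(j + run, seg_end)
            labels[j:end] = rng.choice(3, p=[0.15, 0.15, 0.7])
            j = end
    return labels


def generate_reference(
    config: SuiteConfig, seed: int
) -> tuple[Alignment, np.ndarray, dict[str, SSConfidence]]:
    """One reference alignment with core annotation and SS confidences."""
    rng = np.random.default_rng(seed)
    k, m = config.k, config.m
    n_core = int(round(config.core_fraction * m))
    if n_core == 0:
        raise ValueError("core_fraction yields zero core columns")
    mask = _core_layout(m, n_core, rng)
    aas = np.array(list(AMINO_ACIDS))
    cols = []
    for j in range(m):
        if mask[j]:
            consensus = rng.choice(aas)
            col = [
                consensus if rng.random() < config.core_conservation
                else rng.choice(aas)
                for _ in range(k)
            ]
        else:
            col = [
                GAP if rng.random() < config.noncore_gap_rate else rng.choice(aas)
                for _ in range(k)
            ]
            if all(c == GAP for c in col):
                col[int(rng.integers(k))] = str(rng.choice(aas))
        cols.append(col)
    rows = ["".join(cols[j][i] for j in range(m)) for i in range(k)]
    ids = [f"s{i}" for i in range(k)]
    aln = Alignment(ids, rows)
    annotation = mask.astype(float)
    labels = _ss_labels(mask, config.ss_run_mean, rng)
    ss: dict[str, SSConfidence] = {}
    for i in range(k):
        res_labels = [labels[j] for j in range(m) if rows[i][j] != GAP]
        residues = rows[i].replace(GAP, "")
        alpha = np.ones((len(res_labels), 3))
        alpha[np.arange(len(res_labels)), res_labels] += config.confidence_sharpness
        probs = np.vstack([rng.dirichlet(a) for a in alpha]) if res_labels else (
            np.zeros((0, 3))
        )
        ss[ids[i]] = SSConfidence(residues, probs)
    return aln, annotation, ss


def generate_computed(
    reference: Alignment,
    annotation: np.ndarray,
    target_accuracy: float,
    seed: int,
) -> tuple[Alignment, float]:
    """A computed alignment whose true accuracy is within +-0.05 of target.

    Residues are displaced out of core columns into fresh single-residue
    columns inserted alongside, destroying exactly the displaced residues'
    core pairs; the realized fraction of preserved core pairs is returned.
    """
    if not 0.0 <= target_accuracy <= 1.0:
        raise ValueError("target accuracy must lie in [0,1]")
    rng = np.random.default_rng(seed)
    k, m = reference.k, reference.m
    core_cols = np.flatnonzero(np.asarray(annotation) >= 1.0)
    pair_per_col = k * (k - 1) // 2
    total = len(core_cols) * pair_per_col
    if total == 0:
        if target_accuracy < 1.0:
            raise ValueError("no core pairs to disturb; only accuracy 1 reachable")
        return Alignment(list(reference.ids), list(reference.rows)), 1.0
    target_destroyed = (1.0 - target_accuracy) * total
    destroyed = 0
    plan: dict[int, list[int]] = {}
    for j in rng.permutation(core_cols):
        if destroyed >= target_destroyed:
            break
        order = rng.permutation(k)
        moved: list[int] = []
        for n_moved, row in enumerate(order):
            inc = k - 1 - n_moved
            if abs(destroyed + inc - target_destroyed) >= abs(
                destroyed - target_destroyed
            ):
                break
            moved.append(int(row))
            destroyed += inc
        if moved:
            plan[int(j)] = moved
    realized = 1.0 - destroyed / total
    if abs(realized - target_accuracy) > 0.05:
        raise ValueError(
            f"cannot reach accuracy {target_accuracy} (closest {realized:.3f})"
        )
    out_cols: list[list[str]] = []
    for j in range(m):
        col = [reference.rows[i][j] for i in range(k)]
        if j in plan:
            for row in plan[j]:
                extra = [GAP] * k
                extra[row] = col[row]
                col[row] = GAP
                out_cols.append(extra)
        out_cols.append(col)
    rows = ["".join(c[i] for c in out_cols) for i in range(k)]
    return Alignment(list(reference.ids), rows), realized


def generate_benchmark(config: SuiteConfig, index: int) -> Benchmark:
    """Benchmark ``index`` of the suite: reference plus one computed
    alignment per accuracy level.

    Parameter setting ``p_j`` reaches accuracy level ``(index + j) mod
    n_levels`` on benchmark ``index``: no fixed setting is best everywhere
    (as with a real aligner's parameters), and the default setting ``p00``
    spans the difficulty bins across the suite.
    """
    seed_seq = np.random.SeedSequence([config.seed, index])
    n_levels = len(config.accuracy_levels)
    seeds = seed_seq.generate_state(1 + n_levels)
    ref, annotation, ss = generate_reference(config, int(seeds[0]))
    computed = []
    realized = {}
    for j in range(n_levels):
        pid = f"p{j:02d}"
        level = config.accuracy_levels[(index + j) % n_levels]
        aln, acc = generate_computed(ref, annotation, level, int(seeds[1 + j]))
        computed.append((pid, aln))
        realized[pid] = acc
    default_pid = "p00"
    extras = {
        "realized_accuracy": realized,
        "default_id": default_pid,
        "difficulty": realized[default_pid],
    }
    return Benchmark(f"bench_{index:03d}", ref, annotation, ss, computed, extras)


def generate_suite_in_memory(config: SuiteConfig) -> list[Benchmark]:
    return [generate_benchmark(config, i) for i in range(config.n_benchmarks)]


def generate_suite(config: SuiteConfig, outdir: str | Path) -> list[Path]:
    """Write the suite to disk (one directory per benchmark) and return the
    manifest paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifests = []
    for bench in generate_suite_in_memory(config):
        bdir = outdir / bench.name
        bdir.mkdir(exist_ok=True)
        write_alignment(bench.reference, bdir / "reference.fasta")
        write_core_annotation(bench.core, bdir / "core.tsv")
        for sid, ss in bench.ss.items():
            write_ss2(ss, bdir / f"{sid}.ss2")
        entries = []
        for pid, aln in bench.computed:
            write_alignment(aln, bdir / f"computed_{pid}.fasta")
            entries.append({"id": pid, "path": f"computed_{pid}.fasta"})
        doc = {
            "reference": "reference.fasta",
            "core_annotation": "core.tsv",
            "ss2": {sid: f"{sid}.ss2" for sid in bench.ss},
            "computed": entries,
            "extras": bench.extras,
        }
        path = bdir / "manifest.json"
        write_manifest(doc, path)
        manifests.append(path)
    return manifests
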