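"""Ground-truth quantities derived from a reference alignment.

True accuracy of a computed alignment is the fraction of residue pairs
aligned in core columns of the reference that are recovered in columns of
the computed alignment; true coreness of a computed column is the fraction
of its residue pairs that are such core pairs.  Residues are identified by
(sequence, residue ordinal), so these quantities are invariant to how either
alignment places its gaps.
"""

from __future__ import annotations

import numpy as np

from .io import Alignment

#: A residue pair: ((seq index a, ordinal i), (seq index b, ordinal j)), a < b.
ResiduePair = tuple[tuple[int, int], tuple[int, int]]


def _match_sequences(computed: Alignment, reference: Alignment) -> list[int]:
    """Map computed row index -> reference row index.

    Matches by ungapped sequence string, falling back to id for duplicated
    sequences.
    """
    ref_ungapped: dict[str, list[int]] = {}
    for i in range(reference.k):
        ref_ungapped.setdefault(reference.ungapped(i), []).append(i)
    mapping: list[int] = []
    used: set[int] = set()
    for i in range(computed.k):
        candidates = [
            j for j in ref_ungapped.get(computed.ungapped(i), []) if j not in used
        ]
        if len(candidates) > 1:
            by_id = [j for j in candidates if reference.ids[j] == computed.ids[i]]
            candidates = by_id or candidates
        if not candidates:
            raise ValueError(
                f"sequence {computed.ids[i]!r} has no match in the reference"
            )
        mapping.append(candidates[0])
        used.add(candidates[0])
    return mapping


def core_pairs(reference: Alignment, annotation: np.ndarray) -> set[ResiduePair]:
    """All unordered residue pairs co-occurring in core columns (weight 1)."""
    pairs: set[ResiduePair] = set()
    ords = reference.residue_ordinals()
    for j in np.flatnonzero(np.asarray(annotation) >= 1.0):
        present = [(i, int(ords[i, j])) for i in range(reference.k) if ords[i, j] >= 0]
        for x in range(len(present)):
            for y in range(x + 1, len(present)):
                pairs.add((present[x], present[y]))
    return pairs


def _computed_pairs(computed: Alignment, row_map: list[int]) -> set[ResiduePair]:
    pairs: set[ResiduePair] = set()
    ords = computed.residue_ordinals()
    for j in range(computed.m):
        present = [
            (row_map[i], int(ords[i, j])) for i in range(computed.k) if ords[i, j] >= 0
        ]
        present.sort()
        for x in range(len(present)):
            for y in range(x + 1, len(present)):
                pairs.add((present[x], present[y]))
    return pairs


def true_accuracy(
    computed: Alignment, reference: Alignment, annotation: np.ndarray
) -> float:
    """Fraction of reference core pairs recovered by the computed alignment.

    Defined as 1.0 when the reference has no core pairs.
    """
    ref_pairs = core_pairs(reference, annotation)
    if not ref_pairs:
        return 1.0
    row_map = _match_sequences(computed, reference)
    comp = _computed_pairs(computed, row_map)
    return len(ref_pairs & comp) / len(ref_pairs)


def true_column_coreness(
    computed: Alignment,
    column: int,
    reference: Alignment,
    annotation: np.ndarray,
    _core: set[ResiduePair] | None = None,
    _row_map: list[int] | None = None,
) -> float:
    """Fraction of a computed column's residue pairs that are core pairs.

    Columns with fewer than two residues have coreness 0 (no pairs exist).
    Only residue-residue pairs enter the denominator.
    """
    core = core_pairs(reference, annotation) if _core is None else _core
    row_map = _match_sequences(computed, reference) if _row_map is None else _row_map
    ords = computed.residue_ordinals()
    present = [
        (row_map[i], int(ords[i, column]))
        for i in range(computed.k)
        if ords[i, column] >= 0
    ]
    if len(present) < 2:
        return 0.0
    present.sort()
    total = hits = 0
    for x in range(len(present)):
        for y in range(x + 1, len(present)):
            total += 1
            if (present[x], present[y]) in core:
                hits += 1
    return hits / total


def column_coreness_vector(
    computed: Alignment, reference: Alignment, annotation: np.ndarray
) -> np.ndarray:
    """True coreness for every column of a computed alignment."""
    core = core_pairs(reference, annotation)
    row_map = _match_sequences(computed, reference)
    return np.array(
        [
            true_column_coreness(
                computed, j, reference, annotation, _core=core, _row_map=row_map
            )
            for j in range(computed.m)
        ]
    )


def label_columns(coreness: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary labels: 'C' iff coreness strictly exceeds the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0,1]")
    return np.where(np.asarray(coreness) > threshold, "C", "N")


def difficulty_bin(accuracy: float) -> int:
    """Ten equal-width difficulty bins over [0,1]; bin 9 absorbs accuracy 1."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0,1]")
    return min(int(accuracy * 10), 9)
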