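"""State alphabets for column profiles.

A *state* is an (amino acid, secondary structure) pair; the gap state pairs
the gap character with itself.  Profiles and substitution-score tables are
indexed by a :class:`StateAlphabet`, which supports both the full 20-letter
amino-acid alphabet (61 states) and reduced alphabets built from amino-acid
equivalence classes, which shrink the number of learned substitution scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: Secondary-structure types: H = alpha-helix, E = beta-strand, C = coil/other.
SS_TYPES = "HEC"
AMBIGUOUS = {
    "B": "DN",
    "Z": "EQ",
    "J": "IL",
    "X": AMINO_ACIDS,
    "U": "C",
    "O": "K",
}

#: Dayhoff-style 6-class grouping, the stock reduced alphabet (19 states).
DAYHOFF6 = ("AGPST", "C", "DENQ", "FWY", "HKR", "ILMV")

#: Hydrophobic / polar / charged 3-class grouping (10 states); coarse but
#: cheap — the substitution-score tables stay tiny for smoke runs.
COARSE3 = ("AVLIMCFWY", "GSTPNQH", "DEKR")


@dataclass(frozen=True)
class StateAlphabet:
    """Indexes the state set Q = (residue classes x SS types) + gap.

    ``groups`` partitions the 20 amino acids; with singleton groups this is
    the full 61-state alphabet.  States are laid out group-major
    ((g0,H), (g0,E), (g0,C), (g1,H), ...) with the gap state last.
    """

    groups: tuple[str, ...] = tuple(AMINO_ACIDS)
    _aa_to_group: dict = field(init=False, repr=False, hash=False, compare=False)

    def __post_init__(self) -> None:
        seen = "".join(self.groups)
        if sorted(seen) != sorted(AMINO_ACIDS):
            raise ValueError("groups must partition the 20 amino acids")
        object.__setattr__(
            self,
            "_aa_to_group",
            {aa: gi for gi, grp in enumerate(self.groups) for aa in grp},
        )

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def size(self) -> int:
        """Number of states |Q| (61 for the full alphabet)."""
        return 3 * self.n_groups + 1

    @property
    def gap_state(self) -> int:
        return self.size - 1

    def state_index(self, aa: str, ss: str) -> int:
        if aa == GAP:
            return self.gap_state
        return 3 * self._aa_to_group[aa] + SS_TYPES.index(ss)

    def group_of(self, aa: str) -> int:
        return self._aa_to_group[aa]

    def state_label(self, idx: int) -> tuple[str, str]:
        if idx == self.gap_state:
            return (GAP, GAP)
        gi, si = divmod(idx, 3)
        return (self.groups[gi], SS_TYPES[si])

    def describe(self) -> dict:
        return {"groups": list(self.groups)}

    @classmethod
    def from_description(cls, desc: dict) -> "StateAlphabet":
        return cls(tuple(desc["groups"]))


def full_alphabet() -> StateAlphabet:
    return StateAlphabet()


def reduced_alphabet(groups: tuple[str, ...] = DAYHOFF6) -> StateAlphabet:
    return StateAlphabet(tuple(groups))
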