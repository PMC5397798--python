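"""On-disk formats: aligned FASTA, PSIPRED .ss2, core-column TSV, benchmark
manifests, and JSON model files.

All formats are plain text.  Secondary-structure confidences follow the
PSIPRED VFORMAT column order (coil, helix, strand) on disk and are reordered
internally to (helix, strand, coil).  Core-column annotations are a TSV with
1-based column indices, since benchmark suites do not share a standard
encoding for core labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMINO_ACIDS, GAP

MODEL_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Alignments


@dataclass
class Alignment:
    """A protein multiple sequence alignment over the 20 amino acids + '-'.

    ``rows`` are equal-length uppercase strings; ``k``/``m`` are the number
    of sequences and columns.
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise FormatError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise FormatError("alignment needs at least 2 sequences")
        m = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != m:
                raise FormatError(f"unequal row lengths (record {rid!r})")
            bad = set(row) - set(AMINO_ACIDS + GAP)
            if bad:
                raise FormatError(
                    f"illegal symbol(s) {sorted(bad)} in record {rid!r}"
                )

    @property
    def k(self) -> int:
        return len(self.rows)

    @property
    def m(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def residue_ordinals(self) -> np.ndarray:
        """(k, m) array: 0-based residue ordinal at each cell, -1 at gaps."""
        out = np.full((self.k, self.m), -1, dtype=np.int64)
        for i, row in enumerate(self.rows):
            n = 0
            for j, ch in enumerate(row):
                if ch != GAP:
                    out[i, j] = n
                    n += 1
        return out


def _clean_row(seq: str, map_ambiguous: bool) -> str:
    s = seq.upper().replace(".", GAP)
    if map_ambiguous:
        # ambiguity codes are resolved downstream when building profiles;
        # here we only validate.  Alignment itself stays on the strict
        # alphabet, so expand single-residue codes and reject the rest.
        s = s.replace("U", "C").replace("O", "K")
    return s


def read_alignment(path: str | Path, map_ambiguous: bool = False) -> Alignment:
    """Read an aligned FASTA file ('-' gaps; '.' treated as '-')."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"empty or unparseable FASTA file: {path}")
    ids = [r.id for r in records]
    rows = [_clean_row(str(r.seq), map_ambiguous) for r in records]
    return Alignment(ids, rows)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=rid, description="")
        for rid, row in zip(aln.ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Secondary-structure confidences


@dataclass
class SSConfidence:
    """Per-residue secondary-structure confidences for one ungapped sequence.

    ``probs`` has shape (n_residues, 3) ordered (helix, strand, coil) and each
    row sums to 1 after renormalization.  PSIPRED emits confidence values, not
    calibrated probabilities; renormalization only fixes rounding.
    """

    residues: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.residues), 3):
            raise FormatError("confidence shape does not match residue count")
        if (self.probs < 0).any():
            raise FormatError("negative secondary-structure confidence")
        totals = self.probs.sum(axis=1)
        if (totals <= 0).any():
            raise FormatError("all-zero confidence row")
        self.probs = self.probs / totals[:, None]

    def __len__(self) -> int:
        return len(self.residues)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SSConfidence)
            and self.residues == other.residues
            and np.array_equal(self.probs, other.probs)
        )


def read_ss2(path: str | Path) -> SSConfidence:
    """Parse one PSIPRED .ss2 file.

    Data rows are ``index residue state c_coil c_helix c_strand``; comment
    lines (leading '#') and blanks are skipped.
    """
    residues: list[str] = []
    rows: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise FormatError(f"malformed .ss2 row: {line!r}")
        residues.append(parts[1].upper())
        coil, helix, strand = (float(x) for x in parts[3:6])
        if min(coil, helix, strand) < 0:
            raise FormatError(f"negative confidence in row: {line!r}")
        rows.append([helix, strand, coil])
    if not rows:
        raise FormatError(f"no data rows in .ss2 file: {path}")
    return SSConfidence("".join(residues), np.array(rows))


def write_ss2(ss: SSConfidence, path: str | Path) -> None:
    lines = ["# PSIPRED VFORMAT (synthetic)", ""]
    for i, aa in enumerate(ss.residues):
        h, e, c = ss.probs[i]
        state = "HEC"[int(np.argmax(ss.probs[i]))]
        lines.append(f"{i + 1:4d} {aa} {state}  {c:6.3f} {h:6.3f} {e:6.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def attach_ss(aln: Alignment, ss_by_id: dict[str, SSConfidence]) -> list[SSConfidence]:
    """Order confidences by alignment row, checking residue counts."""
    out = []
    for rid, row in zip(aln.ids, aln.rows):
        if rid not in ss_by_id:
            raise FormatError(f"no secondary structure for sequence {rid!r}")
        ss = ss_by_id[rid]
        n = len(row) - row.count(GAP)
        if len(ss) != n:
            raise FormatError(
                f"length mismatch for {rid!r}: {len(ss)} ss rows vs {n} residues"
            )
        out.append(ss)
    return out


# ---------------------------------------------------------------------------
# Core-column annotations


def read_core_annotation(path: str | Path, n_columns: int) -> np.ndarray:
    """Read a core-column TSV (header ``column<TAB>coreness``, 1-based).

    Returns a dense vector of length ``n_columns``; unlisted columns are 0.
    """
    vec = np.zeros(n_columns)
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:2] != ["column", "coreness"]:
        raise FormatError(f"missing 'column\\tcoreness' header in {path}")
    for line in lines[1:]:
        if not line.strip():
            continue
        col_s, val_s = line.split("\t")[:2]
        col, val = int(col_s), float(val_s)
        if not 1 <= col <= n_columns:
            raise FormatError(f"column index {col} out of range 1..{n_columns}")
        if not 0.0 <= val <= 1.0:
            raise FormatError(f"coreness {val} outside [0,1] at column {col}")
        vec[col - 1] = val
    return vec


def write_core_annotation(vec: np.ndarray, path: str | Path) -> None:
    lines = ["column\tcoreness"]
    for j, v in enumerate(vec):
        if v != 0:
            lines.append(f"{j + 1}\t{float(v):.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Benchmarks


@dataclass
class BenchmarkManifest:
    """Paths making up one benchmark: reference, annotation, ss2, computed."""

    reference: Path
    core_annotation: Path
    ss2: dict[str, Path]
    computed: list[tuple[str, Path]]
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.computed]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate parameter-setting ids in manifest")
        for p in [self.reference, self.core_annotation, *self.ss2.values()] + [
            p for _, p in self.computed
        ]:
            if not Path(p).exists():
                raise FormatError(f"manifest references missing file: {p}")


@dataclass
class Benchmark:
    """A loaded benchmark: reference alignment with core labels plus
    alternate computed alignments."""

    name: str
    reference: Alignment
    core: np.ndarray
    ss: dict[str, SSConfidence]
    computed: list[tuple[str, Alignment]]
    extras: dict = field(default_factory=dict)


def read_manifest(path: str | Path) -> BenchmarkManifest:
    path = Path(path)
    raw = json.loads(path.read_text())
    base = path.parent
    return BenchmarkManifest(
        reference=base / raw["reference"],
        core_annotation=base / raw["core_annotation"],
        ss2={k: base / v for k, v in raw["ss2"].items()},
        computed=[(d["id"], base / d["path"]) for d in raw["computed"]],
        extras=raw.get("extras", {}),
    )


def write_manifest(manifest_dict: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest_dict, indent=1) + "\n")


def load_benchmark(manifest: BenchmarkManifest, name: str = "") -> Benchmark:
    ref = read_alignment(manifest.reference)
    core = read_core_annotation(manifest.core_annotation, ref.m)
    ss = {k: read_ss2(p) for k, p in manifest.ss2.items()}
    attach_ss(ref, ss)
    computed = [(pid, read_alignment(p)) for pid, p in manifest.computed]
    return Benchmark(name or str(manifest.reference), ref, core, ss, computed,
                     dict(manifest.extras))


# ---------------------------------------------------------------------------
# Model serialization

_MODEL_REGISTRY: dict[str, type] = {}


def register_model(kind: str):
    """Class decorator: register a model type for JSON (de)serialization.

    Registered classes provide ``to_json() -> dict`` and
    ``from_json(dict) -> model``.
    """

    def deco(cls):
        _MODEL_REGISTRY[kind] = cls
        cls._model_kind = kind
        return cls

    return deco


def save_model(model, path: str | Path) -> None:
    kind = getattr(model, "_model_kind", None)
    if kind is None or kind not in _MODEL_REGISTRY:
        raise TypeError(f"unregistered model type: {type(model).__name__}")
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "kind": kind,
        "payload": model.to_json(),
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_model(path: str | Path):
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"model schema version {doc.get('schema_version')} "
            f"!= supported {MODEL_SCHEMA_VERSION}"
        )
    kind = doc.get("kind")
    if kind not in _MODEL_REGISTRY:
        raise FormatError(f"unknown model kind {kind!r}")
    try:
        return _MODEL_REGISTRY[kind].from_json(doc["payload"])
    except KeyError as exc:
        raise FormatError(f"model file missing field: {exc}") from exc
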