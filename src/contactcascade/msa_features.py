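"""Multiple-sequence-alignment input: parsing, filtering, pair statistics.

Evolutionary information for the encoder comes from an MSA of the target
protein: per-pair amino-acid pair frequencies, per-position conservation
weights and 3-state secondary structure (H/E/C). Two dialects are read:

* plain FASTA MSA — the first record is the target; conservation is
  computed from the columns and secondary structure is unknown;
* an HSSP-like plain-text fixture dialect (documented below) carrying
  aligned rows plus per-position DSSP state and conservation weight.

HSSP-like dialect (line-oriented, ``#`` comments allowed)::

    >MASTER <name>
    <aligned target sequence, gaps as '-'>
    >ALIGNED <name>
    <aligned row>
    ...
    #PROFILE pos aa ss weight     (one line per target position)
    1 M H 0.63
    ...

DSSP 8-state letters in the profile are reduced to 3 states
(H,G,I -> H; E,B -> E; else C).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from Bio import AlignIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: k for k, a in enumerate(STANDARD_AA)}
GAP_CODE = 20  # gaps and non-standard letters share one code

_DSSP_TO_3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}
SS_STATES = "HEC"


class AlignmentError(ValueError):
    pass


def _encode_row(row: str) -> np.ndarray:
    return np.fromiter(
        (AA_INDEX.get(c, GAP_CODE) for c in row.upper()), dtype=np.int8, count=len(row)
    )


@dataclass
class Alignment:
    """An MSA anchored on a target sequence of length N.

    ``rows`` includes the target itself as row 0. ``per_position_ss`` holds
    'H'/'E'/'C' or None (unknown); ``per_position_conservation`` holds
    annotated weights in [0, 1] or None (fall back to column statistics).
    """

    target_sequence: str
    rows: list[str]
    per_position_conservation: list[float | None] | None = None
    per_position_ss: list[str | None] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.target_sequence)
        if not self.rows:
            raise AlignmentError("no sequences")
        for r in self.rows:
            if len(r) != n:
                raise AlignmentError("ragged alignment")
        if self.per_position_conservation is None:
            self.per_position_conservation = [None] * n
        if self.per_position_ss is None:
            self.per_position_ss = [None] * n

    def __len__(self) -> int:
        return len(self.target_sequence)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @cached_property
    def codes(self) -> np.ndarray:
        """(rows, N) int8 matrix; 0-19 standard residues, 20 gap/other."""
        return np.vstack([_encode_row(r) for r in self.rows])


def read_alignment(file_text: str, format_hint: str = "fasta") -> Alignment:
    """Parse an MSA from text. ``format_hint`` is ``"fasta"`` or ``"hssp-like"``."""
    if format_hint == "fasta":
        return _read_fasta_msa(file_text)
    if format_hint in ("hssp-like", "hssplike", "hssp"):
        return _read_hssp_like(file_text)
    raise AlignmentError(f"unknown alignment format: {format_hint!r}")


def _read_fasta_msa(text: str) -> Alignment:
    if not text.strip():
        raise AlignmentError("no sequences")
    try:
        aln = AlignIO.read(io.StringIO(text), "fasta")
    except ValueError as exc:
        raise AlignmentError(str(exc)) from exc
    rows = [str(rec.seq).upper() for rec in aln]
    return Alignment(
        target_sequence=rows[0], rows=rows, name=aln[0].id,
    )


def _read_hssp_like(text: str) -> Alignment:
    target = None
    name = ""
    rows: list[str] = []
    profile: list[tuple[int, str, str, float]] = []
    lines = iter(text.splitlines())
    in_profile = False
    for line in lines:
        stripped = line.strip()
        if not stripped or stripped.startswith("#PROFILE"):
            in_profile = stripped.startswith("#PROFILE")
            continue
        if stripped.startswith("#"):
            continue
        if stripped.startswith(">MASTER"):
            name = stripped.split(maxsplit=1)[1] if " " in stripped else ""
            target = next(lines).strip().upper()
            rows.insert(0, target)
            in_profile = False
        elif stripped.startswith(">ALIGNED"):
            rows.append(next(lines).strip().upper())
            in_profile = False
        elif in_profile:
            parts = stripped.split()
            profile.append((int(parts[0]), parts[1], parts[2], float(parts[3])))
    if target is None:
        raise AlignmentError("no sequences")
    n = len(target)
    cons: list[float | None] = [None] * n
    ss: list[str | None] = [None] * n
    for pos, _aa, state, weight in profile:
        if not 1 <= pos <= n:
            raise AlignmentError(f"profile position {pos} out of range")
        cons[pos - 1] = float(np.clip(weight, 0.0, 1.0))
        state = state.upper()
        ss[pos - 1] = None if state in ("-", ".", "?") else _DSSP_TO_3.get(state, "C")
    return Alignment(
        target_sequence=target, rows=rows,
        per_position_conservation=cons, per_position_ss=ss, name=name,
    )


def row_identity(row: str, target: str) -> float:
    """Fraction of mutually aligned (both non-gap) columns that match.

    Returns 0.0 when no column is aligned in both rows.
    """
    a, b = _encode_row(row), _encode_row(target)
    both = (a != GAP_CODE) & (b != GAP_CODE)
    n = int(both.sum())
    return float((a[both] == b[both]).sum() / n) if n else 0.0


def filter_alignment(
    aln: Alignment, max_identity: float = 0.80, max_rows: int = 100
) -> Alignment:
    """Drop near-duplicate rows, then cap depth.

    Non-target rows with identity to the target >= ``max_identity`` are
    removed; remaining rows are truncated to ``max_rows`` total (the target,
    always kept, counts toward the cap). File order is preserved.
    """
    kept = [aln.rows[0]]
    for row in aln.rows[1:]:
        if row_identity(row, aln.target_sequence) < max_identity:
            kept.append(row)
    kept = kept[:max_rows]
    return Alignment(
        target_sequence=aln.target_sequence,
        rows=kept,
        per_position_conservation=list(aln.per_position_conservation),
        per_position_ss=list(aln.per_position_ss),
        name=aln.name,
    )


def pair_frequency(aln: Alignment, i: int, j: int) -> np.ndarray:
    """210-element unordered amino-acid pair frequency vector for columns
    (i, j), 1-based.

    Each alignment row with standard residues at both positions increments
    its unordered pair category; counts are divided by the total number of
    rows, so gapped rows shrink the vector sum. Symmetric in (i, j).
    """
    from .pair_encoder import PAIR_INDEX_TABLE  # local to avoid cycle

    n = len(aln)
    if not (1 <= i <= n and 1 <= j <= n):
        raise AlignmentError(f"bad position: ({i}, {j}) for length {n}")
    a = aln.codes[:, i - 1]
    b = aln.codes[:, j - 1]
    valid = (a != GAP_CODE) & (b != GAP_CODE)
    counts = np.bincount(PAIR_INDEX_TABLE[a[valid], b[valid]], minlength=210)
    return counts.astype(float) / aln.n_rows


def conservation_weight(aln: Alignment, i: int) -> float:
    """Conservation of column i (1-based): the annotated weight when
    present, otherwise the frequency of the most common non-gap residue
    among non-gap rows (0.0 for an all-gap column)."""
    if not 1 <= i <= len(aln):
        raise AlignmentError(f"bad position: {i}")
    annotated = aln.per_position_conservation[i - 1]
    if annotated is not None:
        return float(annotated)
    col = aln.codes[:, i - 1]
    col = col[col != GAP_CODE]
    if col.size == 0:
        return 0.0
    return float(np.bincount(col, minlength=20).max() / col.size)


def ss_coding(aln: Alignment, i: int) -> np.ndarray:
    """3-element one-hot over (H, E, C) for column i; all zeros if unknown."""
    if not 1 <= i <= len(aln):
        raise AlignmentError(f"bad position: {i}")
    state = aln.per_position_ss[i - 1]
    vec = np.zeros(3)
    if state in ("H", "E", "C"):
        vec[SS_STATES.index(state)] = 1.0
    return vec


def conservation_vector(aln: Alignment) -> np.ndarray:
    """Per-position conservation for all N columns (vectorised helper)."""
    return np.array([conservation_weight(aln, i) for i in range(1, len(aln) + 1)])


def ss_matrix(aln: Alignment) -> np.ndarray:
    """(N, 3) one-hot secondary-structure matrix (rows of zeros = unknown)."""
    return np.vstack([ss_coding(aln, i) for i in range(1, len(aln) + 1)])
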