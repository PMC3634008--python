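"""The staged 1747-element input coding for a residue pair.

For a residue pair (i, j) of a protein of length N the encoder stacks:

* a 218-element *base block* for the pair itself: 210 unordered
  amino-acid pair frequencies from the MSA, plus conservation weight (1)
  and secondary-structure one-hot (3) for each of the two positions
  (210 + 2*(1+3) = 218);
* four more base blocks for the *content windows*: the shifted pairs
  (i+d, j+d) for d in {-2, -1, +1, +2} (5 x 218 = 1090 so far);
* three base blocks for the *segment window* around the midpoint
  k = floor((i+j)/2): the pairs (k, k), (k-1, k+1), (k-2, k+2)
  (8 x 218 = 1744 so far);
* three *global descriptors*: sequence separation j-i, sequence length N
  and segment separation j-i-1, each divided by 450 (the longest
  supported chain), giving 1747 values in total.

A window block whose positions leave [1, N] is all zeros. The encoding is
symmetric: encoding (j, i) equals encoding (i, j).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .msa_features import (
    Alignment,
    GAP_CODE,
    STANDARD_AA,
    conservation_vector,
    ss_matrix,
)

N_PAIR_CATEGORIES = 210
BASE_BLOCK = 218
CONTENT_STAGE = 5 * BASE_BLOCK  # 1090
SEGMENT_STAGE = 8 * BASE_BLOCK  # 1744
TOTAL_LENGTH = SEGMENT_STAGE + 3  # 1747
LENGTH_NORM = 450.0  # longest supported chain

#: Block order in the vector; base (d=0) block sits at offset 0 so the
#: printed stage lengths 210 / 218 / 1090 / 1744 / 1747 are plain prefixes.
_CONTENT_ORDER = (0, -2, -1, 1, 2)

LAYOUT: dict[str, tuple[int, int]] = {}
_off = 0
for _d in _CONTENT_ORDER:
    _name = "base" if _d == 0 else f"content_{_d:+d}"
    LAYOUT[_name] = (_off, _off + BASE_BLOCK)
    _off += BASE_BLOCK
for _d in range(3):
    LAYOUT[f"segment_{_d}"] = (_off, _off + BASE_BLOCK)
    _off += BASE_BLOCK
LAYOUT["global"] = (_off, _off + 3)
del _off, _d, _name


def _build_pair_index_table() -> np.ndarray:
    """(21, 21) table mapping residue-code pairs to unordered categories.

    Codes 0-19 follow alphabetical one-letter order; code 20 (gap/other)
    maps to the overflow category 210 so callers can mask it cheaply.
    """
    table = np.full((21, 21), N_PAIR_CATEGORIES, dtype=np.int32)
    idx = 0
    for a in range(20):
        for b in range(a, 20):
            table[a, b] = idx
            table[b, a] = idx
            idx += 1
    assert idx == N_PAIR_CATEGORIES
    return table


PAIR_INDEX_TABLE = _build_pair_index_table()


class EncodingError(ValueError):
    pass


def pair_category_index(aa1: str, aa2: str) -> int:
    """Category in [0, 210) for the unordered amino-acid pair (aa1, aa2).

    Categories are ordered lexicographically over sorted pairs, so
    (A, A) -> 0 and (Y, Y) -> 209; swapping the arguments never changes
    the result.
    """
    try:
        a = STANDARD_AA.index(aa1.upper())
        b = STANDARD_AA.index(aa2.upper())
    except (ValueError, AttributeError):
        raise EncodingError(f"bad residue: ({aa1!r}, {aa2!r})") from None
    return int(PAIR_INDEX_TABLE[a, b])


@dataclass
class AlignmentFeatures:
    """Cached per-position statistics of one alignment, ready for encoding."""

    codes: np.ndarray  # (rows, N) int8
    conservation: np.ndarray  # (N,)
    ss_onehot: np.ndarray  # (N, 3)
    n_rows: int

    @classmethod
    def from_alignment(cls, aln: Alignment) -> "AlignmentFeatures":
        return cls(
            codes=aln.codes,
            conservation=conservation_vector(aln),
            ss_onehot=ss_matrix(aln),
            n_rows=aln.n_rows,
        )

    @property
    def length(self) -> int:
        return self.codes.shape[1]


def _as_features(features) -> AlignmentFeatures:
    if isinstance(features, AlignmentFeatures):
        return features
    if isinstance(features, Alignment):
        return AlignmentFeatures.from_alignment(features)
    raise TypeError("features must be an Alignment or AlignmentFeatures")


def _base_blocks_batch(
    feat: AlignmentFeatures, pos_i: np.ndarray, pos_j: np.ndarray
) -> np.ndarray:
    """(P, 218) base blocks for 1-based position arrays; out-of-range rows
    are all zeros. Self-pairs (i == j) are valid (diagonal categories)."""
    n = feat.length
    p = len(pos_i)
    out = np.zeros((p, BASE_BLOCK), dtype=np.float32)
    valid = (pos_i >= 1) & (pos_i <= n) & (pos_j >= 1) & (pos_j <= n)
    if not valid.any():
        return out
    ii = pos_i[valid] - 1
    jj = pos_j[valid] - 1
    cat = PAIR_INDEX_TABLE[feat.codes[:, ii], feat.codes[:, jj]]  # (rows, V)
    v = cat.shape[1]
    flat = cat + (np.arange(v, dtype=np.int64) * (N_PAIR_CATEGORIES + 1))[None, :]
    counts = np.bincount(
        flat.ravel(), minlength=v * (N_PAIR_CATEGORIES + 1)
    ).reshape(v, N_PAIR_CATEGORIES + 1)
    freqs = counts[:, :N_PAIR_CATEGORIES].astype(np.float32) / feat.n_rows
    block = np.empty((v, BASE_BLOCK), dtype=np.float32)
    block[:, :N_PAIR_CATEGORIES] = freqs
    block[:, 210] = feat.conservation[ii]
    block[:, 211:214] = feat.ss_onehot[ii]
    block[:, 214] = feat.conservation[jj]
    block[:, 215:218] = feat.ss_onehot[jj]
    out[valid] = block
    return out


def encode_pairs(
    features,
    pairs: np.ndarray,
    n_residues: int | None = None,
    segment_scheme: str = "midpoint_pairs",
) -> np.ndarray:
    """Encode many residue pairs at once into a (P, 1747) float32 matrix.

    ``pairs`` is a (P, 2) array of 1-based (i, j) with i < j. The batched
    path is exactly equivalent to :func:`encode_pair` row by row.
    """
    feat = _as_features(features)
    n = int(n_residues) if n_residues is not None else feat.length
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    i, j = pairs[:, 0], pairs[:, 1]
    if np.any(i >= j):
        raise EncodingError("unordered pair required: need i < j")
    if np.any((i < 1) | (j > n)):
        raise EncodingError("bad pair: position outside [1, N]")

    out = np.empty((len(pairs), TOTAL_LENGTH), dtype=np.float32)
    for d in _CONTENT_ORDER:
        name = "base" if d == 0 else f"content_{d:+d}"
        lo, hi = LAYOUT[name]
        out[:, lo:hi] = _base_blocks_batch(feat, i + d, j + d)
    k = (i + j) // 2
    for d in range(3):
        lo, hi = LAYOUT[f"segment_{d}"]
        if segment_scheme == "midpoint_pairs":
            out[:, lo:hi] = _base_blocks_batch(feat, k - d, k + d)
        elif segment_scheme == "midpoint_self":
            out[:, lo:hi] = _base_blocks_batch(feat, k + d - 1, k + d - 1)
        else:
            raise EncodingError(f"unknown segment scheme: {segment_scheme!r}")
    lo, hi = LAYOUT["global"]
    out[:, lo] = (j - i) / LENGTH_NORM
    out[:, lo + 1] = n / LENGTH_NORM
    out[:, lo + 2] = (j - i - 1) / LENGTH_NORM
    return out


@dataclass
class PairEncoding:
    """One residue pair's 1747-element input vector plus its slice layout."""

    vector: np.ndarray
    layout: dict[str, tuple[int, int]]

    def block(self, name: str) -> np.ndarray:
        lo, hi = self.layout[name]
        return self.vector[lo:hi]

    def __len__(self) -> int:
        return len(self.vector)


def encode_base_block(features, i: int, j: int) -> np.ndarray:
    """The 218-element base block for pair (i, j) (1-based, both valid)."""
    feat = _as_features(features)
    n = feat.length
    if not (1 <= i <= n and 1 <= j <= n):
        raise EncodingError(f"bad position: ({i}, {j}) for length {n}")
    return _base_blocks_batch(
        feat, np.array([i], dtype=np.int64), np.array([j], dtype=np.int64)
    )[0]


def encode_pair(
    features,
    i: int,
    j: int,
    n_residues: int | None = None,
    segment_scheme: str = "midpoint_pairs",
) -> PairEncoding:
    """Full 1747-element encoding of residue pair (i, j), 1-based.

    (i, j) is canonicalised to i < j, so the encoding of a map cell and its
    transpose is computed once; i == j raises.
    """
    if i == j:
        raise EncodingError("unordered pair required: i == j")
    if i > j:
        i, j = j, i
    vec = encode_pairs(
        features, np.array([[i, j]]), n_residues, segment_scheme=segment_scheme
    )[0]
    return PairEncoding(vector=vec, layout=dict(LAYOUT))


def global_features(n_residues: int, i: int, j: int) -> np.ndarray:
    """The three normalised global descriptors for pair (i, j) of a chain
    of ``n_residues``: (j-i, N, j-i-1) each divided by 450."""
    if not (1 <= i < j <= n_residues):
        raise EncodingError("bad pair: need 1 <= i < j <= N")
    return np.array([j - i, n_residues, j - i - 1], dtype=float) / LENGTH_NORM


def layout_json() -> str:
    """The slice layout (name -> [start, stop)) as a JSON document."""
    return json.dumps({k: list(v) for k, v in LAYOUT.items()}, indent=2)


def save_encodings(path_prefix: str, matrix: np.ndarray) -> None:
    """Persist an encoding matrix (``<prefix>.npy``) with its layout
    descriptor (``<prefix>.layout.json``) for training reuse."""
    np.save(path_prefix + ".npy", np.asarray(matrix, dtype=np.float32))
    with open(path_prefix + ".layout.json", "w") as fh:
        fh.write(layout_json())


def load_encodings(path_prefix: str) -> tuple[np.ndarray, dict]:
    matrix = np.load(path_prefix + ".npy")
    with open(path_prefix + ".layout.json") as fh:
        layout = {k: tuple(v) for k, v in json.load(fh).items()}
    return matrix, layout
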