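"""Structure parsing, chain curation and contact-map extraction.

A residue pair is "in contact" when the Euclidean distance between their
representative atoms — the side-chain beta-carbon (Cβ), or the alpha-carbon
(Cα) for glycine, which has no Cβ — is strictly below a cutoff (8 Å by
default). The resulting N×N binary matrix is symmetric with a unit diagonal.

All user-facing residue indices are 1-based.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: Three-letter -> one-letter codes for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class ChainParseError(ValueError):
    """Raised when a chain cannot be turned into a usable ChainRecord."""


@dataclass
class ChainRecord:
    """One protein chain reduced to a sequence plus one coordinate per residue.

    ``residue_coords[k]`` is the representative atom (Cβ, or Cα for glycine)
    of residue ``k`` (0-based internally; interfaces report 1-based indices).
    """

    chain_id: str
    sequence: str
    residue_coords: np.ndarray  # (N, 3) float array, Å
    representative_atom: list[str]  # per-residue "CB" or "CA"
    experiment_method: str = ""
    resolution: float | None = None
    backbone_complete: bool = True
    has_nonstandard_residues: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.residue_coords = np.asarray(self.residue_coords, dtype=float)
        if len(self.sequence) != len(self.residue_coords):
            raise ValueError("sequence and coordinate lengths differ")
        if len(self.sequence) != len(self.representative_atom):
            raise ValueError("sequence and representative_atom lengths differ")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ContactMap:
    """Binary symmetric residue-contact matrix with its distance cutoff."""

    length: int
    cells: np.ndarray  # (N, N) uint8, symmetric, unit diagonal
    cutoff: float = 8.0

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.uint8)
        if self.cells.shape != (self.length, self.length):
            raise ValueError("cells shape does not match length")

    def contact_pairs(self, min_separation: int = 0) -> list[tuple[int, int]]:
        """1-based (i, j) pairs with i < j, j - i >= min_separation, C[i][j] = 1."""
        ii, jj = np.nonzero(np.triu(self.cells, k=max(min_separation, 1)))
        return [(int(i) + 1, int(j) + 1) for i, j in zip(ii, jj)]


@dataclass
class CurationConfig:
    """Chain-level curation filters for building clean data sets.

    Defaults mirror a high-resolution X-ray curation protocol: resolution
    at most 1.5 Å, X-ray structures only, intact backbones, standard
    residues only, and lengths between 51 and 450 residues.
    """

    max_resolution: float = 1.5
    allowed_method: str = "x-ray"
    min_length: int = 51
    max_length: int = 450
    require_backbone: bool = True
    require_standard_residues: bool = True

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length exceeds max_length")
        if self.max_resolution <= 0:
            raise ValueError("max_resolution must be positive")


def _first_altloc(atom):
    """Resolve a possibly disordered atom to its first-occurring altloc."""
    if atom.is_disordered():
        ids = atom.disordered_get_id_list()
        return atom.disordered_get(ids[0])
    return atom


def parse_structure(
    pdb_text: str,
    chain_id: str,
    *,
    strict: bool = False,
    name: str = "",
) -> ChainRecord:
    """Parse PDB-format text into a :class:`ChainRecord` for one chain.

    The representative coordinate of each residue is its Cβ atom; glycine
    uses Cα. A non-glycine residue lacking Cβ falls back to Cα with a
    warning, or raises if ``strict`` is set. Residues follow file order;
    HETATM records are ignored; disordered atoms resolve to the first
    altloc.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(name or "chain", io.StringIO(pdb_text))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise ChainParseError(f"chain not found: {chain_id!r}")
    chain = model[chain_id]

    seq: list[str] = []
    coords: list[np.ndarray] = []
    rep: list[str] = []
    backbone_complete = True
    has_nonstandard = False
    idx = 0
    for res in chain:
        if res.id[0] != " ":  # HETATM / water
            continue
        if not is_aa(res, standard=False):
            continue
        resname = res.get_resname().strip()
        one = THREE_TO_ONE.get(resname)
        if one is None:
            has_nonstandard = True
            continue
        idx += 1
        if not all(a in res for a in ("N", "CA", "C")):
            backbone_complete = False
        if one != "G" and "CB" in res:
            atom, label = _first_altloc(res["CB"]), "CB"
        elif "CA" in res:
            atom, label = _first_altloc(res["CA"]), "CA"
            if one != "G":
                if strict:
                    raise ChainParseError(
                        f"unusable residue at index {idx}: non-glycine missing CB"
                    )
                logger.warning(
                    "residue %d (%s) missing CB; falling back to CA", idx, resname
                )
        else:
            raise ChainParseError(
                f"unusable residue at index {idx}: no CB or CA atom"
            )
        seq.append(one)
        coords.append(np.asarray(atom.get_coord(), dtype=float))
        rep.append(label)

    if not seq:
        raise ChainParseError(f"chain {chain_id!r} has no standard residues")

    header = structure.header or {}
    method = (header.get("structure_method") or "").strip()
    resolution = header.get("resolution")
    return ChainRecord(
        chain_id=chain_id,
        sequence="".join(seq),
        residue_coords=np.vstack(coords),
        representative_atom=rep,
        experiment_method=method,
        resolution=resolution,
        backbone_complete=backbone_complete,
        has_nonstandard_residues=has_nonstandard,
        name=name,
    )


def filter_chains(
    chains: list[ChainRecord], config: CurationConfig | None = None
) -> list[ChainRecord]:
    """Retain exactly the chains passing every enabled curation filter.

    Order is preserved; an empty result is legal. A chain with unknown
    resolution fails the resolution filter (it cannot be shown compliant).
    """
    config = config or CurationConfig()
    kept = []
    for ch in chains:
        if config.allowed_method:
            if config.allowed_method.lower().replace("-", "") not in (
                ch.experiment_method.lower().replace("-", "").replace(" ", "")
            ):
                continue
        if ch.resolution is None or ch.resolution > config.max_resolution:
            continue
        if config.require_backbone and not ch.backbone_complete:
            continue
        if config.require_standard_residues and ch.has_nonstandard_residues:
            continue
        if not (config.min_length <= len(ch) <= config.max_length):
            continue
        kept.append(ch)
    return kept


def contact_map(chain: ChainRecord, cutoff: float = 8.0) -> ContactMap:
    """Contact map of ``chain``: C[i][j] = 1 iff d(i, j) < cutoff (strict)."""
    if cutoff <= 0:
        raise ValueError("invalid cutoff: must be positive")
    d = cdist(chain.residue_coords, chain.residue_coords)
    cells = (d < cutoff).astype(np.uint8)
    return ContactMap(length=len(chain), cells=cells, cutoff=cutoff)


def separation_mask(cmap_or_length, s: int) -> list[tuple[int, int]]:
    """All 1-based residue pairs (i, j), i < j, with sequence separation
    j - i >= s.

    Accepts either a :class:`ContactMap` or a plain length. Used to restrict
    both training labels and evaluation to non-trivial pairs.
    """
    if s < 0:
        raise ValueError("invalid separation: must be >= 0")
    n = cmap_or_length.length if isinstance(cmap_or_length, ContactMap) else int(cmap_or_length)
    s_eff = max(s, 1)  # i < j already implies separation >= 1
    out = []
    for i in range(1, n + 1):
        for j in range(i + s_eff, n + 1):
            out.append((i, j))
    return out


def write_pair_list(cmap: ContactMap, min_separation: int = 0) -> str:
    """Contacts as tab-separated ``i<TAB>j`` lines, 1-based, i < j."""
    return "\n".join(f"{i}\t{j}" for i, j in cmap.contact_pairs(min_separation)) + "\n"


def read_pair_list(text: str) -> set[tuple[int, int]]:
    """Inverse of :func:`write_pair_list`; blank lines ignored."""
    pairs = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        i, j = line.split()[:2]
        i, j = int(i), int(j)
        pairs.add((min(i, j), max(i, j)))
    return pairs


def write_matrix(cmap: ContactMap) -> str:
    """Contact map as a square whitespace-separated 0/1 matrix."""
    return "\n".join(" ".join(str(int(v)) for v in row) for row in cmap.cells) + "\n"
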