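"""Synthetic fixtures: compact 3D chains, MSAs and labeled pair data sets.

Everything needed to exercise the pipeline without external downloads.
The chain generator grows a self-avoiding walk inside a sphere of radius
proportional to N^(1/3), so the number of 8 Å contacts grows roughly
linearly with chain length while the number of candidate pairs grows
quadratically — reproducing the thin-density regime in which contact
density falls off as ~1/N.

Sequences are assigned from geometry: buried residues (close to the
centroid) draw mostly from a hydrophobic alphabet and exposed ones from a
polar alphabet, so MSA pair statistics carry genuine, if simplified,
signal about contacts. Mutated MSA rows use a uniform substitution model
over the 19 alternative residues — adequate for exercising frequency
counting, not for biological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa_features import Alignment, STANDARD_AA
from .structure_io import ChainRecord, ContactMap, contact_map
from .cascade_model import ProteinSample

HYDROPHOBIC = "AVLIMFWC"
POLAR = "RNDQEHKPSTY"  # G handled separately

BOND_LENGTH = 3.8  # consecutive representative-atom spacing, Å
BOND_JITTER = 0.1
MIN_CLASH = 3.0  # minimum non-consecutive spacing, Å
RADIUS_COEFF = 3.2  # confinement sphere radius = coeff * N^(1/3), Å


class PackingError(RuntimeError):
    pass


@dataclass
class SyntheticSpec:
    """Study conditions for a generated data set."""

    lengths: tuple[int, ...]
    msa_rows: int = 40
    mutation_rate: float = 0.25
    cutoff: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 2 <= n for n in self.lengths):
            raise ValueError("lengths must be >= 2")
        if not 1 <= self.msa_rows <= 100:
            raise ValueError("msa_rows must be in [1, 100]")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")


def _grow_walk(n: int, rng: np.random.Generator, radius: float) -> np.ndarray:
    """One attempt at a confined self-avoiding walk; raises on dead ends."""
    coords = np.zeros((n, 3))
    coords[0] = rng.normal(scale=1.0, size=3)
    for k in range(1, n):
        placed = False
        for _try in range(120):
            step = rng.normal(size=3)
            step *= (BOND_LENGTH + rng.uniform(-BOND_JITTER, BOND_JITTER)) / np.linalg.norm(step)
            cand = coords[k - 1] + step
            if np.linalg.norm(cand) > radius:
                continue
            if k >= 2:
                d = np.linalg.norm(coords[: k - 1] - cand, axis=1)
                if d.min() < MIN_CLASH:
                    continue
            coords[k] = cand
            placed = True
            break
        if not placed:
            raise PackingError(f"dead end at residue {k + 1}")
    return coords - coords.mean(axis=0)


def synth_coords(n: int, seed: int = 0) -> np.ndarray:
    """Compact self-avoiding chain coordinates, (N, 3) in Å."""
    radius = RADIUS_COEFF * n ** (1 / 3)
    rng = np.random.default_rng(seed)
    for attempt in range(50):
        try:
            return _grow_walk(n, rng, radius)
        except PackingError:
            continue
    raise PackingError(f"packing failed for N={n}; reseed")


def _assign_sequence(coords: np.ndarray, rng: np.random.Generator) -> str:
    """Residue letters from burial: core positions hydrophobic, surface
    polar, ~8% glycine everywhere, 15% label noise."""
    r = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
    buried = r <= np.median(r)
    seq = []
    for b in buried:
        if rng.random() < 0.08:
            seq.append("G")
            continue
        pool = HYDROPHOBIC if (b != (rng.random() < 0.15)) else POLAR
        seq.append(pool[rng.integers(len(pool))])
    return "".join(seq)


def chain_to_pdb(chain: ChainRecord, name: str = "SYNT") -> str:
    """Emit minimal PDB-format text that round-trips through parsing.

    The representative coordinate is written as the residue's CB atom (CA
    for glycine); CA/N/C backbone atoms are written at small offsets so
    the chain counts as backbone-complete. Synthetic header records mark
    the entry as a 1.2 Å X-ray structure so curation filters accept it.
    """
    one_to_three = {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
        "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
        "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
        "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    }
    lines = [
        f"HEADER    SYNTHETIC CHAIN                         01-JAN-20   {name[:4].upper():<4}",
        "EXPDTA    X-RAY DIFFRACTION",
        "REMARK   2 RESOLUTION.    1.20 ANGSTROMS.",
    ]
    serial = 1

    def atom_line(serial, atom, resname, resseq, xyz, element):
        return (
            f"ATOM  {serial:>5} {atom:^4} {resname} {chain.chain_id}{resseq:>4}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2}"
        )

    for k, (aa, xyz) in enumerate(zip(chain.sequence, chain.residue_coords), start=1):
        resname = one_to_three[aa]
        is_gly = aa == "G"
        ca = xyz if is_gly else xyz + np.array([0.0, 0.0, 1.53])
        for atom, pos in (
            ("N", ca + np.array([1.46, 0.0, 0.0])),
            ("CA", ca),
            ("C", ca + np.array([0.0, 1.52, 0.0])),
        ):
            lines.append(atom_line(serial, atom, resname, k, pos, atom[0]))
            serial += 1
        if not is_gly:
            lines.append(atom_line(serial, "CB", resname, k, xyz, "C"))
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def synth_chain(n: int, seed: int = 0, name: str = "SYNT") -> tuple[ChainRecord, str]:
    """A compact synthetic chain plus its PDB-format text.

    Consecutive representative atoms sit 3.8 ± 0.1 Å apart;
    non-consecutive atoms never come closer than 3.0 Å. Deterministic
    given the seed; the emitted text round-trips through parsing.
    """
    if n < 2:
        raise ValueError("need N >= 2")
    coords = synth_coords(n, seed)
    rng = np.random.default_rng(seed + 1)
    seq = _assign_sequence(coords, rng)
    chain = ChainRecord(
        chain_id="A",
        sequence=seq,
        residue_coords=coords,
        representative_atom=["CA" if a == "G" else "CB" for a in seq],
        experiment_method="x-ray diffraction",
        resolution=1.2,
        backbone_complete=True,
        has_nonstandard_residues=False,
        name=name,
    )
    return chain, chain_to_pdb(chain, name)


def synth_msa(
    sequence: str, n_rows: int = 40, mutation_rate: float = 0.25, seed: int = 0
) -> Alignment:
    """Target plus mutated copies; substitutions are uniform over the 19
    other letters, so expected row identity is 1 - mutation_rate."""
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    rows = [sequence]
    alphabet = np.array(list(STANDARD_AA))
    seq_arr = np.array(list(sequence))
    for _ in range(n_rows - 1):
        row = seq_arr.copy()
        mutate = rng.random(len(row)) < mutation_rate
        for pos in np.flatnonzero(mutate):
            choices = alphabet[alphabet != row[pos]]
            row[pos] = choices[rng.integers(len(choices))]
        rows.append("".join(row))
    return Alignment(target_sequence=sequence, rows=rows)


def synth_dataset(spec: SyntheticSpec) -> list[ProteinSample]:
    """One (chain, MSA, contact map) triple per requested length.

    Contact maps come from the generated geometry at the spec's cutoff;
    across the set, contact counts at separation >= 6 grow roughly
    linearly with N, so density falls as ~1/N. Deterministic given the
    spec and seed.
    """
    samples = []
    for idx, n in enumerate(spec.lengths):
        sub_seed = (spec.seed * 100003 + idx * 97 + n) % (2**31)
        name = f"SYN{idx:03d}_L{n}"
        chain, _pdb = synth_chain(n, seed=sub_seed, name=name)
        aln = synth_msa(
            chain.sequence, n_rows=spec.msa_rows,
            mutation_rate=spec.mutation_rate, seed=sub_seed + 1,
        )
        cmap = contact_map(chain, cutoff=spec.cutoff)
        samples.append(
            ProteinSample(name=name, alignment=aln, contact_map=cmap, chain=chain)
        )
    return samples


def write_fixture_dir(spec: SyntheticSpec, directory: str) -> list[str]:
    """Materialise a data-set directory: PDB files, FASTA MSAs, truth pair
    lists and a manifest JSON recording the spec and seed."""
    import json
    import os

    from .structure_io import write_pair_list

    os.makedirs(directory, exist_ok=True)
    samples = synth_dataset(spec)
    names = []
    for sample in samples:
        with open(os.path.join(directory, f"{sample.name}.pdb"), "w") as fh:
            fh.write(chain_to_pdb(sample.chain, sample.name))
        with open(os.path.join(directory, f"{sample.name}.msa.fasta"), "w") as fh:
            for k, row in enumerate(sample.alignment.rows):
                fh.write(f">{sample.name}_{k}\n{row}\n")
        with open(os.path.join(directory, f"{sample.name}.contacts.tsv"), "w") as fh:
            fh.write(write_pair_list(sample.contact_map, min_separation=1))
        names.append(sample.name)
    manifest = {
        "spec": {
            "lengths": list(spec.lengths),
            "msa_rows": spec.msa_rows,
            "mutation_rate": spec.mutation_rate,
            "cutoff": spec.cutoff,
            "seed": spec.seed,
        },
        "proteins": names,
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return names


def separable_dataset(
    n_samples: int, seed: int = 0, width: int = 1747
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly separable 1747-wide encodings for training sanity checks.

    The label is a linear function of two designated coordinates (0 and 1)
    plus small noise; classes are balanced to within ±10% by construction.
    """
    if n_samples < 4:
        raise ValueError("need n_samples >= 4")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 0.05, size=(n_samples, width)).astype(np.float32)
    a = rng.uniform(0, 1, size=n_samples)
    b = rng.uniform(0, 1, size=n_samples)
    x[:, 0] = a
    x[:, 1] = b
    y = (a - b + rng.normal(scale=0.02, size=n_samples)) > 0
    # enforce near-balance deterministically by flipping surplus labels' rows
    while abs(int(y.sum()) * 2 - n_samples) > n_samples // 10:
        surplus = y.sum() * 2 > n_samples
        idx = int(rng.choice(np.flatnonzero(y == surplus)))
        x[idx, 0], x[idx, 1] = x[idx, 1], x[idx, 0]
        y[idx] = not surplus
    return x, y.astype(int)
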