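import numpy as np
import pytest

from contactcascade import neural_net as nn
from contactcascade.cascade_model import CascadeBundle, LengthPartition
from contactcascade.msa_features import Alignment


def pdb_atom_line(serial, atom, resname, chain, resseq, xyz, element=None):
    element = element or atom[0]
    return (
        f"ATOM  {serial:>5} {atom:^4} {resname} {chain}{resseq:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2}"
    )


def make_pdb(residues, chain="A", header=True):
    """Build PDB text from [(resname, {atom: xyz})] residue descriptions."""
    lines = []
    if header:
        lines += [
            "HEADER    TEST PROTEIN                            01-JAN-20   TEST",
            "EXPDTA    X-RAY DIFFRACTION",
            "REMARK   2 RESOLUTION.    1.20 ANGSTROMS.",
        ]
    serial = 1
    for resseq, (resname, atoms) in enumerate(residues, start=1):
        for atom, xyz in atoms.items():
            lines.append(pdb_atom_line(serial, atom, resname, chain, resseq, xyz))
            serial += 1
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"


def backbone(xyz):
    """Backbone atoms near a representative coordinate."""
    x = np.asarray(xyz, dtype=float)
    return {
        "N": x + [1.4, 0.0, 1.5],
        "CA": x + [0.0, 0.0, 1.5],
        "C": x + [0.0, 1.5, 1.5],
    }


@pytest.fixture
def three_residue_pdb():
    """ALA-GLY-ALA chain: CB on the alanines, CA-only glycine."""
    residues = []
    for k, resname in enumerate(("ALA", "GLY", "ALA")):
        xyz = [4.0 * k, 0.0, 0.0]
        atoms = backbone(xyz)
        if resname == "GLY":
            atoms["CA"] = np.asarray(xyz, dtype=float)
        else:
            atoms["CB"] = np.asarray(xyz, dtype=float)
        residues.append((resname, atoms))
    return make_pdb(residues)


@pytest.fixture
def hssp_like_text():
    return "\n".join([
        ">MASTER toy",
        "ACDEF",
        ">ALIGNED r1",
        "ACDEF",
        ">ALIGNED r2",
        "AC-EF",
        "#PROFILE pos aa ss weight",
        "1 A H 0.63",
        "2 C E 0.50",
        "3 D G 0.40",
        "4 E - 0.30",
        "5 F B 0.20",
    ]) + "\n"


@pytest.fixture
def small_alignment():
    """4-row, 12-column alignment with computed conservation, unknown ss."""
    return Alignment(
        target_sequence="ACDEFGHIKLMN",
        rows=[
            "ACDEFGHIKLMN",
            "ACDEFGHIKLMN",
            "MCDEFGHIKLYN",
            "AC-EFGHIKL-N",
        ],
    )


@pytest.fixture(scope="session")
def stub_bundle():
    """An untrained-weights bundle flagged trained, for prediction plumbing."""
    subnets = {}
    for sid in range(1, 7):
        m = nn.init_network((1747, 5, 1), seed=sid)
        m.trained = True
        subnets[sid] = m
    cascade = nn.init_network((9, 6, 1), seed=99)
    cascade.trained = True
    return CascadeBundle(subnets=subnets, cascade=cascade,
                         partition=LengthPartition())


@pytest.fixture(scope="session")
def constant_bundle():
    """All-zero-weight bundle: every network outputs exactly 0.5."""
    subnets = {}
    for sid in range(1, 7):
        m = nn.init_network((1747, 5, 1), seed=sid)
        for k in ("w1", "b1", "w2", "b2"):
            setattr(m, k, np.zeros_like(getattr(m, k)))
        m.trained = True
        subnets[sid] = m
    cascade = nn.init_network((9, 6, 1), seed=0)
    for k in ("w1", "b1", "w2", "b2"):
        setattr(cascade, k, np.zeros_like(getattr(cascade, k)))
    cascade.trained = True
    return CascadeBundle(subnets=subnets, cascade=cascade,
                         partition=LengthPartition())
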