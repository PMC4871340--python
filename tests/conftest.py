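import numpy as np
import pytest

from fluctnet.structure_io import CoordinateEnsemble, State
from fluctnet.synthetic import build_toy_receptor


def make_pdb(path, frames, atoms):
    """Write a small multi-model PDB by hand.

    ``atoms`` is a list of (name, element, resname, resid); ``frames`` an
    array (F, N, 3).
    """
    frames = np.asarray(frames, dtype=float)
    lines = []
    multi = frames.shape[0] > 1
    for f, frame in enumerate(frames):
        if multi:
            lines.append(f"MODEL     {f + 1:>4}")
        for k, ((name, element, resname, resid), xyz) in enumerate(zip(atoms, frame)):
            lines.append(
                f"ATOM  {k + 1:>5} {name:<4}{resname:<4}A{resid:>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
                f"{element:>2}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_pdb(tmp_path):
    """3-residue, 10-atom topology with 2 hydrogens, single model."""
    atoms = [
        ("N", "N", "GLY", 1),
        ("CA", "C", "GLY", 1),
        ("C", "C", "GLY", 1),
        ("H", "H", "GLY", 1),
        ("N", "N", "ALA", 2),
        ("CA", "C", "ALA", 2),
        ("C", "C", "ALA", 2),
        ("HA", "H", "ALA", 2),
        ("N", "N", "SER", 3),
        ("CA", "C", "SER", 3),
    ]
    rng = np.random.default_rng(0)
    coords = rng.uniform(0, 20, size=(1, len(atoms), 3)).round(3)
    return make_pdb(tmp_path / "toy.pdb", coords, atoms), atoms, coords[0]


@pytest.fixture
def toy_receptor():
    return build_toy_receptor(20, 4)


def ensemble_from(coords, ligand_id="LIG", state=State.ACTIVE, **kw):
    return CoordinateEnsemble(
        ligand_id=ligand_id, state=state, coordinates=np.asarray(coords, float), **kw
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
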