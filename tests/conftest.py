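"""Shared fixtures: handwritten PDB snippets and parameterized toy atoms."""
import numpy as np
import pytest

from hotforge.structure_io import AtomRecord, StructureModel
from hotforge.synthetic import HelixDimerSpec, make_helix_dimer


def pdb_line(serial, name, res_name, chain, res_seq, x, y, z,
             element=None, record="ATOM", icode=" "):
    """One fixed-column PDB coordinate record."""
    element = element or name[0]
    aligned = f" {name:<3}" if len(name) < 4 else name
    return (
        f"{record:<6}{serial:>5} {aligned:<4} {res_name:<3} {chain}{res_seq:>4}{icode}"
        f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}\n"
    )


@pytest.fixture
def two_atom_pdb(tmp_path):
    text = (
        pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C")
        + pdb_line(2, "CA", "GLY", "A", 2, 3.0, 0.0, 0.0, "C")
        + "END\n"
    )
    path = tmp_path / "two_atoms.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def two_atom_with_water_pdb(tmp_path):
    text = (
        pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C")
        + pdb_line(2, "CA", "GLY", "A", 2, 3.0, 0.0, 0.0, "C")
        + pdb_line(3, "O", "HOH", "A", 101, 9.0, 9.0, 9.0, "O", record="HETATM")
        + "END\n"
    )
    path = tmp_path / "with_water.pdb"
    path.write_text(text)
    return path


def make_atom(serial=1, name="X", chain="A", res_name="ALA", res_seq=1,
              pos=(0.0, 0.0, 0.0), charge=0.0, sigma=3.4, epsilon=0.1,
              element=None, is_hetero=False):
    """A fully parameterized toy atom for direct energetics tests."""
    element = element or name[0]
    return AtomRecord(
        serial=serial, name=name, element=element, chain_id=chain,
        res_name=res_name, res_seq=res_seq, insertion_code="",
        position=np.asarray(pos, dtype=float),
        is_hydrogen=element == "H", is_hetero=is_hetero,
        partial_charge=charge, lj_sigma=sigma, lj_epsilon=epsilon,
    )


def model_from_atoms(atoms):
    return StructureModel(list(atoms), source_id="test")


@pytest.fixture(scope="session")
def salt_bridge_dimer():
    """Close-packed helix dimer with one engineered Glu/Lys salt bridge."""
    spec = HelixDimerSpec(
        n_residues=12, separation=5.5, salt_bridge_positions=((5, 6),), rng_seed=7,
    )
    return make_helix_dimer(spec)


@pytest.fixture(scope="session")
def plain_dimer():
    """All-alanine dimer without engineered bridges."""
    return make_helix_dimer(HelixDimerSpec(n_residues=10, separation=5.0, rng_seed=11))
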