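"""Read and normalize protein complex coordinates.

PDB files are parsed (via gemmi) into a flat chain/residue/atom model suited
to inter-chain energetic analysis: every atom carries its identity keys and,
after parameter assignment, nonbonded parameters. Residue identifiers are kept
verbatim from the file so published residue labels (e.g. Glu957) survive into
all downstream tables, and every residue has a canonical string form
``chain:resname:resseq[icode]`` used in all CSV exports.

Alternate locations are resolved deterministically (altloc '' or 'A' kept,
others dropped) and water residues (HOH/WAT) are retained but flagged so that
contact aggregation can exclude them.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import EmptyStructureError, UnknownChainError

logger = logging.getLogger(__name__)

#: Residue names treated as water throughout the package.
WATER_RES_NAMES = frozenset({"HOH", "WAT"})

_KEPT_ALTLOCS = ("", "A")


@dataclass
class AtomRecord:
    """One atom with coordinates, identity keys and nonbonded parameters.

    ``partial_charge``/``lj_sigma``/``lj_epsilon`` stay ``None`` until
    :func:`hotforge.forcefield.assign_parameters` populates them.
    """

    serial: int
    name: str
    element: str
    chain_id: str
    res_name: str
    res_seq: int
    insertion_code: str
    position: np.ndarray
    is_hydrogen: bool
    is_hetero: bool = False
    partial_charge: float | None = None
    lj_sigma: float | None = None
    lj_epsilon: float | None = None

    @property
    def residue_key(self) -> "ResidueKey":
        return ResidueKey(self.chain_id, self.res_name, self.res_seq, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_RES_NAMES


@dataclass(frozen=True)
class ResidueKey:
    """Canonical residue identity: chain, 3-letter code, number, icode."""

    chain_id: str
    res_name: str
    res_seq: int
    insertion_code: str = ""

    def canonical(self) -> str:
        return f"{self.chain_id}:{self.res_name}:{self.res_seq}{self.insertion_code}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical()


def canonical_key(obj: "AtomRecord | ResidueKey") -> str:
    """Canonical string ``chain:resname:resseq[icode]`` for an atom or residue."""
    key = obj.residue_key if isinstance(obj, AtomRecord) else obj
    return key.canonical()


def parse_residue_key(label: str) -> ResidueKey:
    """Inverse of :func:`canonical_key`; raises ``ValueError`` on bad input."""
    parts = label.split(":")
    if len(parts) != 3:
        raise ValueError(f"not a canonical residue key: {label!r}")
    chain, res_name, tail = parts
    num = tail
    icode = ""
    while num and not num[-1].isdigit() and num[-1] != "-":
        icode = num[-1] + icode
        num = num[:-1]
    if not num or not (num.lstrip("-").isdigit()):
        raise ValueError(f"not a canonical residue key: {label!r}")
    return ResidueKey(chain, res_name, int(num), icode)


@dataclass
class StructureModel:
    """Ordered atoms plus a residue index, as parsed from one MODEL block."""

    atoms: list[AtomRecord]
    source_id: str = ""
    residues: dict[ResidueKey, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residues:
            self._reindex()

    def _reindex(self) -> None:
        self.residues = {}
        for i, atom in enumerate(self.atoms):
            self.residues.setdefault(atom.residue_key, []).append(i)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for atom in self.atoms:
            seen.setdefault(atom.chain_id, None)
        return list(seen)

    def residue_atoms(self, key: ResidueKey) -> list[AtomRecord]:
        return [self.atoms[i] for i in self.residues[key]]

    def with_atoms(self, atoms: Iterable[AtomRecord]) -> "StructureModel":
        return StructureModel(list(atoms), source_id=self.source_id)


@dataclass(frozen=True)
class InterfaceSpec:
    """Receptor/ligand chain assignment for inter-chain analysis."""

    receptor_chains: frozenset[str]
    ligand_chains: frozenset[str]

    def __post_init__(self) -> None:
        rec = frozenset(self.receptor_chains)
        lig = frozenset(self.ligand_chains)
        object.__setattr__(self, "receptor_chains", rec)
        object.__setattr__(self, "ligand_chains", lig)
        if not rec or not lig:
            raise ValueError("receptor and ligand chain sets must be non-empty")
        if rec & lig:
            raise ValueError(f"receptor/ligand chain sets overlap: {sorted(rec & lig)}")


def load_structure(path: str | Path, model_index: int = 0) -> StructureModel:
    """Parse one MODEL block of a PDB file into a :class:`StructureModel`.

    Alternate locations other than '' / 'A' are dropped; waters are retained
    (flagged through ``res_name``). Raises :class:`EmptyStructureError` if the
    selected model holds no atoms.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, OSError, ValueError) as exc:
        raise IOError(f"could not read PDB file {path}: {exc}") from exc
    if model_index >= len(st) or model_index < 0:
        raise IndexError(f"model index {model_index} out of range for {path} ({len(st)} models)")
    model = st[model_index]
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            icode = residue.seqid.icode.strip()
            for atom in residue:
                if atom.altloc not in ("\0", *_KEPT_ALTLOCS):
                    continue
                element = atom.element.name.upper()
                atoms.append(AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    element=element,
                    chain_id=chain.name,
                    res_name=residue.name,
                    res_seq=residue.seqid.num,
                    insertion_code=icode,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float),
                    is_hydrogen=element in ("H", "D"),
                    is_hetero=het,
                ))
    if not atoms:
        raise EmptyStructureError(f"no ATOM/HETATM records in {path} (model {model_index})")
    return StructureModel(atoms, source_id=str(path))


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model back to PDB (coordinates at standard 3-decimal precision)."""
    st = gemmi.Structure()
    st.name = "hotforge"
    gm = gemmi.Model("1")
    # group atoms by chain, then residue, preserving file order
    by_chain: dict[str, list[AtomRecord]] = {}
    for atom in model.atoms:
        by_chain.setdefault(atom.chain_id, []).append(atom)
    for chain_id, chain_atoms in by_chain.items():
        chain = gemmi.Chain(chain_id)
        current: gemmi.Residue | None = None
        current_key: ResidueKey | None = None
        for atom in chain_atoms:
            key = atom.residue_key
            if key != current_key:
                if current is not None:
                    chain.add_residue(current)
                current = gemmi.Residue()
                current.name = atom.res_name
                current.seqid = gemmi.SeqId(atom.res_seq, atom.insertion_code or " ")
                current.het_flag = "H" if atom.is_hetero else "A"
                current_key = key
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element.capitalize())
            ga.pos = gemmi.Position(*atom.position)
            ga.serial = atom.serial
            current.add_atom(ga)
        if current is not None:
            chain.add_residue(current)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def strip_waters(model: StructureModel) -> StructureModel:
    """Return a copy with all HOH/WAT residues removed (order preserved)."""
    kept = [a for a in model.atoms if not a.is_water]
    if not kept:
        logger.warning("strip_waters: model %s contained only waters", model.source_id)
    return model.with_atoms(kept)


def select_interface(
    model: StructureModel, spec: InterfaceSpec
) -> tuple[list[AtomRecord], list[AtomRecord]]:
    """Partition atoms into (receptor, ligand) lists per the interface spec.

    Atoms on chains in neither set are excluded. Raises
    :class:`UnknownChainError` when a named chain is absent.
    """
    available = set(model.chain_ids)
    missing = (spec.receptor_chains | spec.ligand_chains) - available
    if missing:
        raise UnknownChainError(
            f"chain(s) {sorted(missing)} not in model; available: {sorted(available)}"
        )
    receptor = [a for a in model.atoms if a.chain_id in spec.receptor_chains]
    ligand = [a for a in model.atoms if a.chain_id in spec.ligand_chains]
    return receptor, ligand


def copy_atom(atom: AtomRecord, **changes) -> AtomRecord:
    """Shallow copy of an atom record with ``position`` duplicated."""
    new = replace(atom, **changes)
    if "position" not in changes:
        new.position = atom.position.copy()
    return new


def coordinates(atoms: Sequence[AtomRecord]) -> np.ndarray:
    """(n, 3) coordinate array for a list of atoms."""
    if not atoms:
        return np.zeros((0, 3))
    return np.stack([a.position for a in atoms])
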