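"""Inter-chain nonbonded pair energetics.

For every receptor-ligand atom pair within a distance threshold (default
4.5 A, inclusive) the Lennard-Jones 12-6 and Coulomb energies are evaluated
with Lorentz-Berthelot combination rules:

    E_LJ   = 4 eps_ij [ (sig_ij / r)^12 - (sig_ij / r)^6 ]
    E_coul = K q_i q_j / r                      (vacuum)
    E_coul = K q_i q_j / (s r^2)                (screened, eps(r) = s r)

with K = 332.0636 kcal A mol^-1 e^-2. The screened form is the standard
distance-dependent-dielectric implicit-solvent approximation; the screening
factor ``s`` defaults to 1 and is configurable so eps(r) = 4r conventions can
be matched. No switching or shifting function is applied: energies are the
bare formulas, and an infinite cutoff is supported for exhaustive sums.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ParameterizationError
from .structure_io import AtomRecord, ResidueKey, canonical_key, coordinates

#: Coulomb constant, kcal A mol^-1 e^-2 (Amber convention).
COULOMB_K = 332.0636

#: Default atom-pair enumeration threshold, A.
DEFAULT_CUTOFF = 4.5


@dataclass(frozen=True)
class DielectricModel:
    """Electrostatic environment: vacuum (1/r) or screened (1/(s r^2))."""

    mode: str = "screened"
    screening_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("vacuum", "screened"):
            raise ValueError(f"dielectric mode must be 'vacuum' or 'screened', got {self.mode!r}")
        if self.screening_factor <= 0:
            raise ValueError("screening_factor must be > 0")


VACUUM = DielectricModel("vacuum")
SCREENED = DielectricModel("screened", 1.0)


@dataclass
class AtomPairContact:
    """One inter-chain atom pair with its distance and energy decomposition."""

    atom_i: int
    atom_j: int
    residue_i: ResidueKey
    residue_j: ResidueKey
    distance: float
    e_lj: float
    e_coul: float

    @property
    def e_total(self) -> float:
        return self.e_lj + self.e_coul


def pair_energy(
    q_i: float, q_j: float,
    sigma_i: float, sigma_j: float,
    eps_i: float, eps_j: float,
    r: float,
    dielectric: DielectricModel = SCREENED,
) -> tuple[float, float]:
    """(E_LJ, E_coul) in kcal/mol for one atom pair at separation ``r`` A."""
    if r <= 0:
        raise ValueError(f"pair distance must be positive, got {r}")
    sig = 0.5 * (sigma_i + sigma_j)
    eps = math.sqrt(eps_i * eps_j)
    sr6 = (sig / r) ** 6
    e_lj = 4.0 * eps * (sr6 * sr6 - sr6)
    if dielectric.mode == "vacuum":
        e_coul = COULOMB_K * q_i * q_j / r
    else:
        e_coul = COULOMB_K * q_i * q_j / (dielectric.screening_factor * r * r)
    return e_lj, e_coul


def _param_arrays(atoms: list[AtomRecord], side: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    for a in atoms:
        if a.partial_charge is None or a.lj_sigma is None or a.lj_epsilon is None:
            raise ParameterizationError(
                f"{side} atom {a.name} of {canonical_key(a)} has no assigned parameters"
            )
    q = np.array([a.partial_charge for a in atoms])
    sig = np.array([a.lj_sigma for a in atoms])
    eps = np.array([a.lj_epsilon for a in atoms])
    return q, sig, eps


def enumerate_contacts(
    receptor_atoms: list[AtomRecord],
    ligand_atoms: list[AtomRecord],
    distance_cutoff: float = DEFAULT_CUTOFF,
    dielectric: DielectricModel = SCREENED,
) -> list[AtomPairContact]:
    """All cross-chain atom pairs with distance <= cutoff, with energies.

    Ordering is deterministic: receptor atom index, then ligand atom index.
    ``distance_cutoff`` may be ``math.inf`` for exhaustive enumeration.
    """
    if distance_cutoff <= 0:
        raise ValueError("distance_cutoff must be > 0")
    if not receptor_atoms or not ligand_atoms:
        return []
    q_r, sig_r, eps_r = _param_arrays(receptor_atoms, "receptor")
    q_l, sig_l, eps_l = _param_arrays(ligand_atoms, "ligand")
    xyz_r = coordinates(receptor_atoms)
    xyz_l = coordinates(ligand_atoms)

    if math.isinf(distance_cutoff):
        pairs_i, pairs_j = np.meshgrid(
            np.arange(len(receptor_atoms)), np.arange(len(ligand_atoms)), indexing="ij"
        )
        pairs_i = pairs_i.ravel()
        pairs_j = pairs_j.ravel()
    else:
        tree_r = cKDTree(xyz_r)
        tree_l = cKDTree(xyz_l)
        neighbor_lists = tree_r.query_ball_tree(tree_l, distance_cutoff)
        pairs_i = np.array(
            [i for i, js in enumerate(neighbor_lists) for _ in js], dtype=int
        )
        pairs_j = np.array(
            [j for js in neighbor_lists for j in sorted(js)], dtype=int
        )
    if pairs_i.size == 0:
        return []
    d = np.linalg.norm(xyz_r[pairs_i] - xyz_l[pairs_j], axis=1)
    keep = d <= distance_cutoff
    pairs_i, pairs_j, d = pairs_i[keep], pairs_j[keep], d[keep]

    sig = 0.5 * (sig_r[pairs_i] + sig_l[pairs_j])
    eps = np.sqrt(eps_r[pairs_i] * eps_l[pairs_j])
    sr6 = (sig / d) ** 6
    e_lj = 4.0 * eps * (sr6 * sr6 - sr6)
    qq = q_r[pairs_i] * q_l[pairs_j]
    if dielectric.mode == "vacuum":
        e_coul = COULOMB_K * qq / d
    else:
        e_coul = COULOMB_K * qq / (dielectric.screening_factor * d * d)

    return [
        AtomPairContact(
            atom_i=int(i), atom_j=int(j),
            residue_i=receptor_atoms[i].residue_key,
            residue_j=ligand_atoms[j].residue_key,
            distance=float(dd), e_lj=float(lj), e_coul=float(cl),
        )
        for i, j, dd, lj, cl in zip(pairs_i, pairs_j, d, e_lj, e_coul)
    ]


def contacts_to_dataframe(contacts: list[AtomPairContact]) -> pd.DataFrame:
    """Atom-pair contact table: one row per pair, canonical residue ids."""
    return pd.DataFrame({
        "residue_i": [canonical_key(c.residue_i) for c in contacts],
        "residue_j": [canonical_key(c.residue_j) for c in contacts],
        "atom_i": [c.atom_i for c in contacts],
        "atom_j": [c.atom_j for c in contacts],
        "distance_A": [c.distance for c in contacts],
        "e_lj": [c.e_lj for c in contacts],
        "e_coul": [c.e_coul for c in contacts],
        "e_total": [c.e_total for c in contacts],
    })


def residue_pair_table(contacts: list[AtomPairContact]) -> pd.DataFrame:
    """Aggregate atom pairs to one row per (residue_i, residue_j) pair.

    Columns: residue_i, residue_j, min_distance_A, mean_distance_A,
    sum_e_total, n_atom_pairs. The sum of ``sum_e_total`` over rows equals the
    sum of atom-pair ``e_total`` (energy conservation under aggregation).
    """
    cols = ["residue_i", "residue_j", "min_distance_A", "mean_distance_A",
            "sum_e_total", "n_atom_pairs"]
    if not contacts:
        return pd.DataFrame(columns=cols)
    df = contacts_to_dataframe(contacts)
    grouped = df.groupby(["residue_i", "residue_j"], sort=False).agg(
        min_distance_A=("distance_A", "min"),
        mean_distance_A=("distance_A", "mean"),
        sum_e_total=("e_total", "sum"),
        n_atom_pairs=("e_total", "size"),
    ).reset_index()
    return grouped[cols]
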