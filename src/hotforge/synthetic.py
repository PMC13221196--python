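"""Self-contained synthetic test inputs.

Everything the pipeline consumes can be generated here with no downloads:

* toy two-chain alpha-helical complexes with engineered Glu/Lys salt bridges
  and known closest-contact geometry (:func:`make_helix_dimer`),
* mock external residue-pair contact tables whose aggregation recovers a
  planned per-residue strength profile (:func:`make_mock_contact_table`),
* mutated design-sequence ensembles with conserved interface positions
  (:func:`make_sequence_ensemble`),
* mock design-metrics tables with a controlled pass fraction
  (:func:`make_mock_metrics`).

All generators are pure functions of their spec plus an explicit seed; there
is no global RNG state. Helix backbones are grown with ideal internal
coordinates (phi = -57 deg, psi = -47 deg, omega = 180 deg; standard bond
lengths/angles), which yields the canonical ~1.5 A rise and ~100 deg twist
per residue. Side chains are idealized extended templates oriented radially
outward - plausible, not crystallographic, geometry.

The spec's ``separation`` is the closest approach between the two CA traces
(the interface gap): helix axes are placed ``separation + 2 r_CA`` apart and
each chain is rotated about its axis so one residue faces the partner, so the
minimum inter-chain CA-CA distance comes out near ``separation``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmark import ExternalContactTable, MOE_LIKE_DIALECT
from .ensemble_metrics import METRICS_COLUMNS
from .structure_io import AtomRecord, StructureModel, parse_residue_key

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Idealized side-chain heavy-atom templates in a local frame:
# (atom_name, a, b) -> CA + a * outward + b * z_hat  [A].
_SC = {
    "ALA": [("CB", 1.53, 0.0)],
    "GLY": [],
    "SER": [("CB", 1.53, 0.0), ("OG", 2.68, 0.65)],
    "CYS": [("CB", 1.53, 0.0), ("SG", 2.90, 0.70)],
    "THR": [("CB", 1.53, 0.0), ("OG1", 2.50, 0.90), ("CG2", 2.50, -0.90)],
    "VAL": [("CB", 1.53, 0.0), ("CG1", 2.50, 0.90), ("CG2", 2.50, -0.90)],
    "LEU": [("CB", 1.53, 0.0), ("CG", 2.78, 0.65), ("CD1", 3.75, 1.62), ("CD2", 3.75, -0.32)],
    "ILE": [("CB", 1.53, 0.0), ("CG1", 2.78, 0.65), ("CG2", 2.40, -1.00), ("CD1", 4.03, 1.30)],
    "MET": [("CB", 1.53, 0.0), ("CG", 2.78, 0.65), ("SD", 4.10, 0.00), ("CE", 5.40, 0.70)],
    "ASP": [("CB", 1.53, 0.0), ("CG", 2.78, 0.65), ("OD1", 3.50, 1.70), ("OD2", 3.60, -0.30)],
    "ASN": [("CB", 1.53, 0.0), ("CG", 2.78, 0.65), ("OD1", 3.50, 1.70), ("ND2", 3.60, -0.30)],
    "GLU": [("CB", 1.53, 0.0), ("CG", 2.78, 0.65), ("CD", 4.03, 0.00),
            ("OE1", 4.70, 1.05), ("OE2", 4.90, -1.00)],
    "GLN": [("CB", 1.53, 0.0), ("CG", 2.78, 0.65), ("CD", 4.03, 0.00),
            ("OE1", 4.70, 1.05), ("NE2", 4.90, -1.00)],
    "LYS": [("CB", 1.53, 0.0), ("CG", 2.78, 0.65), ("CD", 4.03, 0.00),
            ("CE", 5.28, 0.65), ("NZ", 6.40, 0.00)],
    "ARG": [("CB", 1.53, 0.0), ("CG", 2.78, 0.65), ("CD", 4.03, 0.00),
            ("NE", 5.28, 0.65), ("CZ", 6.50, 0.40), ("NH1", 7.20, 1.40), ("NH2", 7.30, -0.60)],
    "HIS": [("CB", 1.53, 0.0), ("CG", 2.90, 0.40), ("ND1", 3.71, 1.51),
            ("CD2", 3.71, -0.71), ("CE1", 5.02, 1.09), ("NE2", 5.02, -0.29)],
    "PHE": [("CB", 1.53, 0.0), ("CG", 2.90, 0.30), ("CD1", 3.60, 1.50), ("CD2", 3.60, -0.90),
            ("CE1", 4.99, 1.50), ("CE2", 4.99, -0.90), ("CZ", 5.68, 0.30)],
    "TYR": [("CB", 1.53, 0.0), ("CG", 2.90, 0.30), ("CD1", 3.60, 1.50), ("CD2", 3.60, -0.90),
            ("CE1", 4.99, 1.50), ("CE2", 4.99, -0.90), ("CZ", 5.68, 0.30), ("OH", 7.04, 0.30)],
    "TRP": [("CB", 1.53, 0.0), ("CG", 2.90, 0.30), ("CD1", 3.50, 1.55), ("NE1", 4.85, 1.60),
            ("CE2", 5.30, 0.35), ("CD2", 4.15, -0.50), ("CE3", 4.30, -1.90),
            ("CZ2", 6.55, 0.10), ("CH2", 6.90, -1.20), ("CZ3", 5.80, -2.20)],
    "PRO": [("CB", 1.40, 0.40), ("CG", 2.20, -0.60), ("CD", 1.40, -1.60)],
}

# Directed (salt-bridge) chains: distance of each atom from CA along the
# engineered direction; terminal branch atoms get a perpendicular offset.
_DIRECTED = {
    "GLU": ([("CB", 1.53), ("CG", 2.80), ("CD", 4.03)], [("OE1", 5.20, 0.9), ("OE2", 5.20, -0.9)], 5.20),
    "ASP": ([("CB", 1.53), ("CG", 2.80)], [("OD1", 3.95, 0.9), ("OD2", 3.95, -0.9)], 3.95),
    "LYS": ([("CB", 1.53), ("CG", 2.80), ("CD", 4.03), ("CE", 5.30)], [("NZ", 6.40, 0.0)], 6.40),
    "ARG": ([("CB", 1.53), ("CG", 2.80), ("CD", 4.03), ("NE", 5.30), ("CZ", 6.50)],
            [("NH1", 7.10, 0.9), ("NH2", 7.10, -0.9)], 6.50),
}

_ELEMENT = {"C": "C", "N": "N", "O": "O", "S": "S"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT.get(atom_name[0], atom_name[0])


@dataclass(frozen=True)
class HelixDimerSpec:
    """Two parallel ideal helices with optional engineered salt bridges.

    ``salt_bridge_positions`` lists 0-based (pos_a, pos_b) residue indices;
    those positions become GLU (chain A) / LYS (chain B) unless the provided
    sequences already put another charged pair there.
    """

    n_residues: int = 12
    separation: float = 9.0
    sequence_a: str | None = None
    sequence_b: str | None = None
    salt_bridge_positions: tuple[tuple[int, int], ...] = ()
    rng_seed: int = 0
    jitter_sd: float = 0.02
    bridge_contact_distance: float = 2.9

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise ValueError("separation must be > 0")
        for pa, pb in self.salt_bridge_positions:
            if not (0 <= pa < self.n_residues and 0 <= pb < self.n_residues):
                raise ValueError(f"salt bridge position ({pa}, {pb}) out of bounds")


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D from three predecessors with internal coordinates."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        bond * math.sin(theta) * math.sin(phi),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _ideal_helix_backbone(n_res: int, phi=-57.0, psi=-47.0, omega=180.0):
    """(N, CA, C, O) coordinate arrays of an ideal helix, arbitrary frame."""
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (1.458, 0.0, 0.0)
    ang = math.radians(180.0 - 111.2)
    C[0] = CA[0] + 1.525 * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], 1.329, 116.6, psi)
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], 1.458, 121.9, omega)
        C[i] = _nerf(C[i - 1], N[i], CA[i], 1.525, 111.2, phi)
    for i in range(n_res):
        O[i] = _nerf(N[i], CA[i], C[i], 1.231, 120.5, psi + 180.0)
    return N, CA, C, O


def _axis_frame(ca: np.ndarray):
    """Rotation matrix sending the helix axis to +z, plus the centered CAs."""
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    # build orthonormal basis with axis as new z
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = np.cross(ref, axis)
    x /= np.linalg.norm(x)
    y = np.cross(axis, x)
    rot = np.stack([x, y, axis])  # world -> helix frame
    return rot, ca.mean(axis=0)


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_helix_dimer(spec: HelixDimerSpec) -> StructureModel:
    """Build the two-chain helical complex described by ``spec``."""
    n = spec.n_residues
    seq_a = list(spec.sequence_a or "A" * n)
    seq_b = list(spec.sequence_b or "A" * n)
    if len(seq_a) != n or len(seq_b) != n:
        raise ValueError("sequence length must match n_residues")
    for pa, pb in spec.salt_bridge_positions:
        if seq_a[pa] not in "EDKR":
            seq_a[pa] = "E"
        if seq_b[pb] not in "EDKR":
            seq_b[pb] = "K"
    for letter in seq_a + seq_b:
        if letter not in ONE_TO_THREE:
            raise ValueError(f"invalid residue code {letter!r}")

    face_a, face_b = (spec.salt_bridge_positions[0] if spec.salt_bridge_positions
                      else (n // 2, n // 2))

    # per-chain backbone in its own axis frame (axis = z through origin)
    backbones = []
    for face in (face_a, face_b):
        N, CA, C, O = _ideal_helix_backbone(n)
        rot, center = _axis_frame(CA)
        coords = {k: (v - center) @ rot.T for k, v in zip("N A C O".split(), (N, CA, C, O))}
        ca = coords["A"]
        phase = math.atan2(ca[face, 1], ca[face, 0])
        backbones.append((coords, phase, ca))
    r_ca = float(np.mean([np.linalg.norm(ca[:, :2], axis=1).mean() for _, _, ca in backbones]))
    axis_sep = spec.separation + 2.0 * r_ca

    chains: dict[str, dict[str, np.ndarray]] = {}
    for chain_id, (coords, phase, _), want in (
        ("A", backbones[0], 0.0),            # facing residue points +x
        ("B", backbones[1], math.pi),        # facing residue points -x
    ):
        rz = _rot_z(want - phase)
        rotated = {k: v @ rz.T for k, v in coords.items()}
        chains[chain_id] = rotated
    # chain B sits at x = axis_sep; align facing residues in z
    dz = chains["A"]["A"][face_a, 2] - chains["B"]["A"][face_b, 2]
    for k in chains["B"]:
        chains["B"][k] = chains["B"][k] + np.array([axis_sep, 0.0, dz])

    bridge_a = {pa for pa, _ in spec.salt_bridge_positions}
    bridge_b = {pb for _, pb in spec.salt_bridge_positions}
    rng = np.random.default_rng(spec.rng_seed)
    atoms: list[AtomRecord] = []
    serial = 1

    def add_atom(name: str, pos: np.ndarray, chain: str, res3: str, res_seq: int):
        nonlocal serial
        atoms.append(AtomRecord(
            serial=serial, name=name, element=_element_of(name), chain_id=chain,
            res_name=res3, res_seq=res_seq, insertion_code="",
            position=np.asarray(pos, dtype=float).copy(),
            is_hydrogen=False,
        ))
        serial += 1

    def axis_point(chain: str, z: float) -> np.ndarray:
        x0 = 0.0 if chain == "A" else axis_sep
        return np.array([x0, 0.0, z])

    # engineered side-chain directions: solved per bridge below
    directed: dict[tuple[str, int], np.ndarray] = {}
    for pa, pb in spec.salt_bridge_positions:
        ca_a = chains["A"]["A"][pa]
        ca_b = chains["B"]["A"][pb]
        res_a = ONE_TO_THREE[seq_a[pa]]
        res_b = ONE_TO_THREE[seq_b[pb]]
        reach_a = _DIRECTED.get(res_a, (None, None, 5.2))[2]
        reach_b = _DIRECTED.get(res_b, (None, None, 6.4))[2]
        w = ca_b - ca_a
        w[2] = 0.0
        d0 = np.linalg.norm(w)
        w /= d0
        zhat = np.array([0.0, 0.0, 1.0])
        best_t, best_err = 0.0, math.inf
        for t_deg in np.arange(0.0, 85.0, 0.25):
            t = math.radians(t_deg)
            tip_a = ca_a + reach_a * (math.cos(t) * w + math.sin(t) * zhat)
            tip_b = ca_b + reach_b * (math.cos(t) * (-w) + math.sin(t) * zhat)
            gap = d0 - (reach_a + reach_b) * math.cos(t)
            dist = np.linalg.norm(tip_a - tip_b)
            err = abs(dist - spec.bridge_contact_distance)
            if gap >= 0 and err < best_err:
                best_t, best_err = t, err
        t = best_t
        directed[("A", pa)] = math.cos(t) * w + math.sin(t) * zhat
        directed[("B", pb)] = math.cos(t) * (-w) + math.sin(t) * zhat

    for chain_id, seq, bridge in (("A", seq_a, bridge_a), ("B", seq_b, bridge_b)):
        bb = chains[chain_id]
        for i in range(n):
            res3 = ONE_TO_THREE[seq[i]]
            res_seq = i + 1
            for name, key in (("N", "N"), ("CA", "A"), ("C", "C"), ("O", "O")):
                add_atom(name, bb[key][i], chain_id, res3, res_seq)
            ca = bb["A"][i]
            if (chain_id, i) in directed and res3 in _DIRECTED:
                d = directed[(chain_id, i)]
                q = np.cross(d, np.array([0.0, 0.0, 1.0]))
                if np.linalg.norm(q) < 1e-6:
                    q = np.array([0.0, 1.0, 0.0])
                else:
                    q /= np.linalg.norm(q)
                stem, tips, _ = _DIRECTED[res3]
                for name, dist in stem:
                    add_atom(name, ca + dist * d, chain_id, res3, res_seq)
                for name, dist, off in tips:
                    add_atom(name, ca + dist * d + off * q, chain_id, res3, res_seq)
            else:
                u = ca - axis_point(chain_id, ca[2])
                u[2] = 0.0
                u /= np.linalg.norm(u)
                zhat = np.array([0.0, 0.0, 1.0])
                for name, a_off, b_off in _SC[res3]:
                    add_atom(name, ca + a_off * u + b_off * zhat, chain_id, res3, res_seq)

    model = StructureModel(atoms, source_id=f"helix_dimer(seed={spec.rng_seed})")
    if spec.jitter_sd > 0:
        for atom in model.atoms:
            atom.position = atom.position + rng.normal(0.0, spec.jitter_sd, size=3)
    return model


def make_mock_contact_table(
    hotspot_plan: dict[str, float],
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    partner_chain: str = "X",
) -> ExternalContactTable:
    """Residue-pair rows whose per-residue sums recover a planned profile.

    ``hotspot_plan`` maps canonical residue ids to target strengths (>= 0,
    in kcal/mol). Each planned residue is paired with one or more distinct
    partner residues on ``partner_chain``; row energies are negative with
    magnitude summing to the planned strength (each row at or below the
    -1.0 kcal/mol favorability threshold when the strength allows), plus
    optional Gaussian noise. Zero noise -> exact round trip through
    residue-pair aggregation.
    """
    rng = np.random.default_rng(rng_seed)
    rows = {"residue_i": [], "residue_j": [], "min_distance_A": [], "sum_e_total": []}
    partner_seq = 900
    for residue_id, strength in hotspot_plan.items():
        if strength < 0:
            raise ValueError(f"planned strength must be >= 0 ({residue_id}: {strength})")
        parse_residue_key(residue_id)  # validate
        k = max(1, int(strength // 1.5)) if strength >= 1.0 else 1
        for _ in range(k):
            rows["residue_i"].append(residue_id)
            rows["residue_j"].append(f"{partner_chain}:GLY:{partner_seq}")
            rows["min_distance_A"].append(float(rng.uniform(2.5, 3.4)))
            e = -strength / k + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows["sum_e_total"].append(e)
            partner_seq += 1
    return ExternalContactTable(
        rows=pd.DataFrame(rows), dialect=dict(MOE_LIKE_DIALECT),
        source=f"mock(seed={rng_seed})",
    )


def make_sequence_ensemble(
    consensus: str,
    n_designs: int,
    per_site_mutation_rate: float,
    conserved_positions: "tuple[int, ...] | list[int]" = (),
    rng_seed: int = 0,
) -> tuple[list[str], list[str]]:
    """(ids, sequences): seeded point-mutant ensemble around a consensus.

    Non-conserved positions mutate independently with the given per-site
    rate, to a uniformly random *different* residue; conserved positions
    never change (emulating the low entropy of interface positions in
    design ensembles).
    """
    if not 0.0 <= per_site_mutation_rate <= 1.0:
        raise ValueError("per_site_mutation_rate must be in [0, 1]")
    conserved = set(conserved_positions)
    for p in conserved:
        if not 0 <= p < len(consensus):
            raise ValueError(f"conserved position {p} out of bounds")
    rng = np.random.default_rng(rng_seed)
    ids, seqs = [], []
    for d in range(n_designs):
        chars = list(consensus)
        for i, c in enumerate(chars):
            if i in conserved:
                continue
            if rng.random() < per_site_mutation_rate:
                options = [a for a in AMINO_ALPHABET if a != c]
                chars[i] = options[rng.integers(len(options))]
        ids.append(f"design_{d:04d}")
        seqs.append("".join(chars))
    return ids, seqs


def write_fasta(ids: "list[str]", seqs: "list[str]", path) -> None:
    with open(path, "w") as fh:
        for i, s in zip(ids, seqs):
            fh.write(f">{i}\n{s}\n")


def make_mock_metrics(
    n_rows: int,
    fraction_passing: float,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Mock unified design-metrics table with a controlled pass fraction.

    Exactly ``round(n_rows * fraction_passing)`` rows satisfy the default
    confidence thresholds (mean pLDDT >= 80 AND iPAE <= 15); the rest violate
    at least one of them. Row order is shuffled deterministically.
    """
    if not 0.0 <= fraction_passing <= 1.0:
        raise ValueError("fraction_passing must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    n_pass = int(round(n_rows * fraction_passing))
    recs = []
    for i in range(n_rows):
        passing = i < n_pass
        if passing:
            plddt = float(rng.uniform(80.0, 97.0))
            ipae = float(rng.uniform(3.0, 15.0))
        else:
            mode = rng.integers(3)
            plddt = float(rng.uniform(50.0, 79.9)) if mode in (0, 2) else float(rng.uniform(80.0, 97.0))
            ipae = float(rng.uniform(15.1, 30.0)) if mode in (1, 2) else float(rng.uniform(3.0, 15.0))
        length = int(rng.integers(55, 76))
        seq = "".join(AMINO_ALPHABET[k] for k in rng.integers(0, len(AMINO_ALPHABET), size=length))
        recs.append({
            "design_id": f"design_{i:04d}", "length": length, "seq": seq,
            "mean_plddt": plddt, "ipae": ipae,
            "binder_rmsd": float(rng.uniform(0.8, 25.0)),
            "n_interface_residues": int(rng.integers(6, 25)),
            "hotspot_engagement": int(rng.integers(0, 8)),
            "helicity": float(rng.uniform(0.3, 0.95)),
            "mpnn_score": float(rng.uniform(-2.5, -0.5)),
        })
    df = pd.DataFrame(recs, columns=METRICS_COLUMNS)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31 - 1))).reset_index(drop=True)
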