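"""Design-ensemble triage and diagnostics.

Generative binder pipelines emit, per candidate design, a set of structure
confidence and sequence metrics (mean pLDDT on the 0-100 scale, interface
predicted aligned error, RMSD to target, ProteinMPNN score, helicity, ...).
This module consumes that unified metrics table and provides:

* confidence triage: keep designs with mean pLDDT >= 80 and iPAE <= 15
  (inclusive thresholds), ranked by ascending iPAE then descending pLDDT
  then design id, truncated to the top 100 by default;
* per-residue backbone RMSD of a design against a native interface chain
  (N, CA, C, O atoms after one Kabsch least-squares superposition over all
  mapped backbone atoms);
* energy-distance regression over residue-pair tables (packing-quality
  diagnostic: favorable energies should concentrate at short distances);
* Needleman-Wunsch global alignment (affine gaps, BLOSUM62 by default) with
  deterministic diagonal-over-up-over-left tie-breaking;
* ensemble diversity: pairwise identity matrices, normalized Hamming
  distance distributions, and per-column Shannon entropy in bits.

iPAE is treated as an engine-reported scalar: thresholds are applied verbatim
with no unit conversion. helicity and mpnn_score are upstream pass-through
columns, not recomputed.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices
from scipy import stats

from .errors import SuperpositionError
from .structure_io import ResidueKey, StructureModel, canonical_key

logger = logging.getLogger(__name__)

PLDDT_MIN_DEFAULT = 80.0
IPAE_MAX_DEFAULT = 15.0
KEEP_DEFAULT = 100
BACKBONE_ATOMS = ("N", "CA", "C", "O")

METRICS_COLUMNS = [
    "design_id", "length", "seq", "mean_plddt", "ipae", "binder_rmsd",
    "n_interface_residues", "hotspot_engagement", "helicity", "mpnn_score",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "HIE": "H", "HID": "H", "HIP": "H",
    "ILE": "I", "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class DesignMetricsRow:
    """One design's confidence/interface/sequence metrics."""

    design_id: str
    length: int
    mean_plddt: float
    ipae: float
    binder_rmsd: float = float("nan")
    n_interface_residues: int = 0
    hotspot_engagement: int = 0
    helicity: float = float("nan")
    mpnn_score: float = float("nan")
    sequence: str = ""


def rows_to_dataframe(rows: Iterable[DesignMetricsRow]) -> pd.DataFrame:
    recs = [
        {
            "design_id": r.design_id, "length": r.length, "seq": r.sequence,
            "mean_plddt": r.mean_plddt, "ipae": r.ipae, "binder_rmsd": r.binder_rmsd,
            "n_interface_residues": r.n_interface_residues,
            "hotspot_engagement": r.hotspot_engagement,
            "helicity": r.helicity, "mpnn_score": r.mpnn_score,
        }
        for r in rows
    ]
    return pd.DataFrame(recs, columns=METRICS_COLUMNS)


def read_metrics_csv(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path)


def write_metrics_csv(df: pd.DataFrame, path: "str | Path") -> None:
    df.to_csv(path, index=False)


def filter_designs(
    rows: "pd.DataFrame | list[DesignMetricsRow]",
    plddt_min: float = PLDDT_MIN_DEFAULT,
    ipae_max: float = IPAE_MAX_DEFAULT,
    keep: int = KEEP_DEFAULT,
) -> pd.DataFrame:
    """Confidence triage: mean_plddt >= plddt_min AND ipae <= ipae_max.

    Both comparisons are inclusive. Survivors are ranked by ascending ipae,
    then descending mean_plddt, then design_id (a deterministic total order)
    and truncated to ``keep`` rows. An empty result is allowed.
    """
    df = rows if isinstance(rows, pd.DataFrame) else rows_to_dataframe(rows)
    kept = df[(df["mean_plddt"] >= plddt_min) & (df["ipae"] <= ipae_max)]
    kept = kept.sort_values(
        by=["ipae", "mean_plddt", "design_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return kept.head(keep).reset_index(drop=True)


def confidence_scatter(rows: pd.DataFrame) -> pd.DataFrame:
    """Lossless (design_id, ipae, mean_plddt) projection for plotting."""
    return rows.loc[:, ["design_id", "ipae", "mean_plddt"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Backbone RMSD profiling

def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal least-squares rigid superposition (rotation, translation).

    Returns (R, t) such that ``mobile @ R.T + t`` best fits ``reference`` in
    the least-squares sense; proper rotation guaranteed (det = +1).
    """
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cr - rot @ cm
    return rot, trans


@dataclass
class RmsdProfile:
    """Per-residue backbone RMSD after one global superposition."""

    residue_pairs: list[tuple[str, str]]  # (model residue id, reference residue id)
    per_residue: np.ndarray
    global_rmsd: float
    interface_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def _backbone_coords(model: StructureModel, key: ResidueKey, atom_names) -> np.ndarray | None:
    by_name = {a.name: a for a in model.residue_atoms(key)}
    if not all(n in by_name for n in atom_names):
        return None
    return np.stack([by_name[n].position for n in atom_names])


def per_residue_rmsd(
    model: StructureModel,
    reference: StructureModel,
    correspondence: "Sequence[tuple[ResidueKey, ResidueKey]] | None" = None,
    atom_names: tuple[str, ...] = BACKBONE_ATOMS,
    interface_residues: "set[str] | None" = None,
) -> RmsdProfile:
    """Backbone RMSD per mapped residue after one Kabsch superposition.

    ``correspondence`` maps model residues to reference residues; when
    omitted it is derived with :func:`residue_correspondence`. Residues
    missing any of the backbone atoms on either side are skipped with a
    warning. Fewer than 3 usable residues raises
    :class:`SuperpositionError`.
    """
    if correspondence is None:
        correspondence = residue_correspondence(model, reference)
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    mob_blocks: list[np.ndarray] = []
    ref_blocks: list[np.ndarray] = []
    for mk, rk in correspondence:
        mcoord = _backbone_coords(model, mk, atom_names)
        rcoord = _backbone_coords(reference, rk, atom_names)
        if mcoord is None or rcoord is None:
            logger.warning(
                "residue pair %s/%s lacks backbone atoms; skipped",
                canonical_key(mk), canonical_key(rk),
            )
            continue
        pairs.append((mk, rk))
        mob_blocks.append(mcoord)
        ref_blocks.append(rcoord)
    if len(pairs) < 3:
        raise SuperpositionError(
            f"only {len(pairs)} mapped residues with complete backbones; need >= 3"
        )
    mob = np.concatenate(mob_blocks)
    ref = np.concatenate(ref_blocks)
    rot, trans = kabsch(mob, ref)
    fitted = mob @ rot.T + trans
    sq = ((fitted - ref) ** 2).sum(axis=1)
    n_at = len(atom_names)
    per_res = np.sqrt(sq.reshape(-1, n_at).mean(axis=1))
    global_rmsd = float(np.sqrt(sq.mean()))
    ids = [(canonical_key(m), canonical_key(r)) for m, r in pairs]
    if interface_residues is not None:
        mask = np.array([r in interface_residues for _, r in ids], dtype=bool)
    else:
        mask = np.zeros(len(ids), dtype=bool)
    return RmsdProfile(
        residue_pairs=ids, per_residue=per_res, global_rmsd=global_rmsd, interface_mask=mask,
    )


def chain_sequence(model: StructureModel, chain_id: str) -> tuple[str, list[ResidueKey]]:
    """One-letter sequence and residue keys of a chain (CA-bearing residues)."""
    seq = []
    keys = []
    for key, indices in model.residues.items():
        if key.chain_id != chain_id:
            continue
        if not any(model.atoms[i].name == "CA" for i in indices):
            continue
        seq.append(THREE_TO_ONE.get(key.res_name, "X"))
        keys.append(key)
    return "".join(seq), keys


def residue_correspondence(
    model: StructureModel,
    reference: StructureModel,
    model_chain: str | None = None,
    reference_chain: str | None = None,
) -> list[tuple[ResidueKey, ResidueKey]]:
    """Map model residues onto reference residues by sequence alignment.

    Chains default to the first chain of each structure. The two one-letter
    sequences are globally aligned and non-gap aligned columns become residue
    pairs; identical numbering therefore maps trivially, while renumbered
    designs map through their sequence.
    """
    mc = model_chain or model.chain_ids[0]
    rc = reference_chain or reference.chain_ids[0]
    mseq, mkeys = chain_sequence(model, mc)
    rseq, rkeys = chain_sequence(reference, rc)
    aln = global_align(mseq, rseq)
    pairs = []
    i = j = 0
    for a, b in zip(aln.aligned_a, aln.aligned_b):
        if a != "-" and b != "-":
            pairs.append((mkeys[i], rkeys[j]))
        if a != "-":
            i += 1
        if b != "-":
            j += 1
    return pairs


# ---------------------------------------------------------------------------
# Energy-distance correlation

@dataclass
class EnergyDistanceFit:
    pearson_r: float | None
    slope: float | None
    intercept: float | None
    n: int
    defined: bool


def energy_distance_correlation(residue_pairs: pd.DataFrame) -> EnergyDistanceFit:
    """Least-squares line of residue-pair energy vs mean contact distance.

    Expects columns ``mean_distance_A`` and ``sum_e_total`` (the aggregated
    residue-pair table). Zero variance in either variable is reported as an
    undefined correlation rather than an error.
    """
    if len(residue_pairs) < 3:
        raise ValueError("need >= 3 residue pairs for a regression")
    x = residue_pairs["mean_distance_A"].to_numpy(dtype=float)
    y = residue_pairs["sum_e_total"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return EnergyDistanceFit(None, None, None, len(x), False)
    fit = stats.linregress(x, y)
    return EnergyDistanceFit(
        pearson_r=float(fit.rvalue), slope=float(fit.slope),
        intercept=float(fit.intercept), n=len(x), defined=True,
    )


# ---------------------------------------------------------------------------
# Needleman-Wunsch global alignment (affine gaps, Gotoh recursion)

_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


@dataclass
class GlobalAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    @property
    def identity(self) -> float:
        matches = sum(a == b and a != "-" for a, b in zip(self.aligned_a, self.aligned_b))
        return matches / self.length if self.length else 0.0


def substitution_score(a: str, b: str, matrix=None) -> float:
    m = matrix if matrix is not None else _blosum62()
    try:
        return float(m[a, b])
    except (KeyError, IndexError):
        return float(m["X", "X"]) if "X" in m.alphabet else 0.0


def global_align(
    seq_a: str,
    seq_b: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> GlobalAlignment:
    """Optimal global alignment with affine gap penalties.

    A gap of length L costs ``gap_open + L * gap_extend`` (BLAST-style
    existence/extension convention). Ties during traceback prefer the
    diagonal (substitution) move over a gap in ``seq_b`` (up) over a gap in
    ``seq_a`` (left), making the reported alignment deterministic.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    m = matrix if matrix is not None else _blosum62()
    n, w = len(seq_a), len(seq_b)
    neg = -math.inf
    first = gap_open + gap_extend  # cost of the first gapped position
    M = np.full((n + 1, w + 1), neg)
    Ix = np.full((n + 1, w + 1), neg)  # gap in seq_b: seq_a residue over '-'
    Iy = np.full((n + 1, w + 1), neg)  # gap in seq_a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, w + 1):
        Iy[0, j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        for j in range(1, w + 1):
            s = substitution_score(ai, seq_b[j - 1], m)
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - first, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - first, Iy[i, j - 1] - gap_extend)
    score = max(M[n, w], Ix[n, w], Iy[n, w])

    def _eq(x: float, y: float) -> bool:
        return x == y or abs(x - y) < 1e-9

    # traceback; state priority M (diagonal) > Ix (up) > Iy (left)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, w
    state = "M" if _eq(M[i, j], score) else ("Ix" if _eq(Ix[i, j], score) else "Iy")
    while i > 0 or j > 0:
        if state == "M":
            s = substitution_score(seq_a[i - 1], seq_b[j - 1], m)
            prev = M[i, j] - s
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = "M" if _eq(M[i, j], prev) else ("Ix" if _eq(Ix[i, j], prev) else "Iy")
        elif state == "Ix":
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            came_open = _eq(M[i - 1, j] - first, Ix[i, j])
            i -= 1
            state = "M" if came_open else "Ix"
            if i == 0 and j == 0:
                break
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            came_open = _eq(M[i, j - 1] - first, Iy[i, j])
            j -= 1
            state = "M" if came_open else "Iy"
            if i == 0 and j == 0:
                break
        if i == 0 and j > 0 and state == "M":
            state = "Iy"
        if j == 0 and i > 0 and state == "M":
            state = "Ix"
    return GlobalAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), float(score))


# ---------------------------------------------------------------------------
# Ensemble diversity

@dataclass
class DiversityReport:
    """Pairwise identity/Hamming statistics and per-column entropy (bits)."""

    ids: list[str]
    identity_matrix: np.ndarray
    hamming_distribution: np.ndarray  # condensed upper-triangle order
    entropy_profile: np.ndarray


def normalized_hamming(seq_a: str, seq_b: str) -> float:
    """Fraction of differing positions between two equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length for direct Hamming distance")
    if not seq_a:
        return 0.0
    return sum(a != b for a, b in zip(seq_a, seq_b)) / len(seq_a)


def column_entropy(column: "Sequence[str]") -> float:
    """Shannon entropy H = -sum_i p_i log2 p_i over residue frequencies.

    Gap characters are ignored; a fully conserved column has entropy 0."""
    residues = [c for c in column if c != "-"]
    if not residues:
        return 0.0
    _, counts = np.unique(np.array(residues), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum()) + 0.0


def frequency_matrix(sequences: "Sequence[str]") -> pd.DataFrame:
    """Per-column residue frequency matrix (rows: positions, cols: residues).

    The exportable substrate for sequence-logo rendering."""
    if not sequences:
        return pd.DataFrame()
    length = len(sequences[0])
    alphabet = sorted({c for s in sequences for c in s if c != "-"})
    rows = []
    for i in range(length):
        col = [s[i] for s in sequences if i < len(s) and s[i] != "-"]
        total = len(col) or 1
        rows.append({a: col.count(a) / total for a in alphabet})
    return pd.DataFrame(rows).fillna(0.0)


def diversity_report(
    sequences: "Sequence[str]",
    ids: "Sequence[str] | None" = None,
    mode: str = "equal_length",
) -> DiversityReport:
    """Identity matrix, Hamming distribution, and entropy profile.

    ``equal_length`` mode computes Hamming distances directly and entropy per
    ungapped column. ``align`` mode aligns each pair globally, counts gap
    columns as mismatches (normalized by alignment length), and computes the
    entropy profile over the columns of the first sequence by projecting each
    pairwise alignment onto it.
    """
    if len(sequences) < 2:
        raise ValueError("need >= 2 sequences")
    if ids is None:
        ids = [f"seq_{i}" for i in range(len(sequences))]
    n = len(sequences)
    ident = np.eye(n)
    condensed = []
    if mode == "equal_length":
        for i in range(n):
            for j in range(i + 1, n):
                h = normalized_hamming(sequences[i], sequences[j])
                condensed.append(h)
                ident[i, j] = ident[j, i] = 1.0 - h
        entropy = np.array([
            column_entropy([s[k] for s in sequences]) for k in range(len(sequences[0]))
        ])
    elif mode == "align":
        ref = sequences[0]
        msa_columns: list[list[str]] = [[c] for c in ref]
        for i in range(n):
            for j in range(i + 1, n):
                aln = global_align(sequences[i], sequences[j])
                mismatch = sum(
                    a != b for a, b in zip(aln.aligned_a, aln.aligned_b)
                ) / aln.length
                condensed.append(mismatch)
                ident[i, j] = ident[j, i] = 1.0 - mismatch
        for s in sequences[1:]:
            aln = global_align(ref, s)
            k = 0
            for a, b in zip(aln.aligned_a, aln.aligned_b):
                if a != "-":
                    msa_columns[k].append(b)
                    k += 1
        entropy = np.array([column_entropy(col) for col in msa_columns])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DiversityReport(
        ids=list(ids),
        identity_matrix=ident,
        hamming_distribution=np.array(condensed),
        entropy_profile=entropy,
    )


def read_fasta(path: "str | Path") -> tuple[list[str], list[str]]:
    """(ids, sequences) from a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    return [r.id for r in records], [str(r.seq) for r in records]
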