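"""Residue-level hotspot aggregation, ranking and Top-N selection.

A hotspot is an interface residue that carries a disproportionate share of
the favorable inter-chain interaction energy. Two favorable-contact
definitions are supported as first-class aggregation modes:

* ``atom_pair`` (default, the open physics-engine path): an atom pair
  qualifies iff its total nonbonded energy is negative and its distance is
  within the threshold (default 4.5 A);
* ``residue_pair`` (the contact-table path): a residue pair qualifies iff its
  summed energy is <= the energy threshold (default -1.0 kcal/mol) and its
  minimum interatomic distance is <= the distance threshold (default 3.5 A).

Each qualifying contribution adds |energy| to exactly one residue on each
side, so total receptor-side strength equals total ligand-side strength.
Residues are ranked by descending strength with a documented total-order
tie-break (chain id, then residue number) so Top-N selections are
reproducible across runs and platforms.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import UnknownResidueError
from .energetics import AtomPairContact, DEFAULT_CUTOFF
from .structure_io import (
    ResidueKey, StructureModel, WATER_RES_NAMES, canonical_key, coordinates, parse_residue_key,
)

logger = logging.getLogger(__name__)

TOP_N_DEFAULT = (5, 10, 20, 30, 50)

#: Residue names counted as protein in residue-level aggregation.
PROTEIN_RES_NAMES = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HIE", "HID", "HIP", "HSD", "HSE", "HSP", "CYX", "MSE",
})


@dataclass(frozen=True)
class HotspotCriteria:
    """Favorability thresholds and the aggregation mode that applies them."""

    aggregation: str = "atom_pair"
    energy_threshold: float | None = None   # default depends on mode
    distance_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.aggregation not in ("atom_pair", "residue_pair"):
            raise ValueError(f"unknown aggregation mode {self.aggregation!r}")
        if self.energy_threshold is None:
            object.__setattr__(
                self, "energy_threshold", 0.0 if self.aggregation == "atom_pair" else -1.0
            )
        if self.distance_threshold is None:
            object.__setattr__(
                self, "distance_threshold", 4.5 if self.aggregation == "atom_pair" else 3.5
            )
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be > 0")


@dataclass
class HotspotTable:
    """Ranked per-residue favorable-energy strengths for one interface side.

    ``rows`` has columns residue_id, strength_kcal_mol, n_favorable, rank;
    rank is 1-based by descending strength (ties: chain id, residue number).
    """

    rows: pd.DataFrame
    side: str
    criteria: HotspotCriteria
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.rows)

    def top_n(self, n: int) -> list[str]:
        return top_n(self, n)

    def strengths(self) -> pd.Series:
        return self.rows.set_index("residue_id")["strength_kcal_mol"]


def _rank_rows(per_residue: dict[ResidueKey, tuple[float, int]]) -> pd.DataFrame:
    recs = [
        {
            "residue_id": canonical_key(k),
            "strength_kcal_mol": s,
            "n_favorable": n,
            "_chain": k.chain_id,
            "_seq": k.res_seq,
            "_icode": k.insertion_code,
        }
        for k, (s, n) in per_residue.items()
    ]
    df = pd.DataFrame(recs, columns=[
        "residue_id", "strength_kcal_mol", "n_favorable", "_chain", "_seq", "_icode",
    ])
    if len(df):
        df = df.sort_values(
            by=["strength_kcal_mol", "_chain", "_seq", "_icode"],
            ascending=[False, True, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns=["_chain", "_seq", "_icode"])


def _is_water_key(key: ResidueKey) -> bool:
    return key.res_name in WATER_RES_NAMES


def aggregate_hotspots(
    contacts: "list[AtomPairContact] | pd.DataFrame",
    criteria: HotspotCriteria | None = None,
    include_hetero: bool = False,
) -> tuple[HotspotTable, HotspotTable]:
    """(receptor table, ligand table) of per-residue hotspot strengths.

    ``contacts`` is a list of :class:`AtomPairContact` (atom_pair mode) or a
    residue-pair DataFrame with columns residue_i/residue_j/min_distance_A/
    sum_e_total (residue_pair mode). Waters never contribute; non-protein
    (HETATM ligand/ion) residues are excluded unless ``include_hetero`` is
    set, so residue-level hotspots cover protein residues only by default.
    """
    criteria = criteria or HotspotCriteria()
    rec: dict[ResidueKey, tuple[float, int]] = {}
    lig: dict[ResidueKey, tuple[float, int]] = {}

    def _add(d: dict, key: ResidueKey, magnitude: float) -> None:
        s, n = d.get(key, (0.0, 0))
        d[key] = (s + magnitude, n + 1)

    def _excluded(key: ResidueKey) -> bool:
        if _is_water_key(key):
            return True
        return not include_hetero and key.res_name not in PROTEIN_RES_NAMES

    if criteria.aggregation == "atom_pair":
        if isinstance(contacts, pd.DataFrame):
            raise TypeError("atom_pair aggregation needs atom-pair contacts, not a residue table")
        for c in contacts:
            if _excluded(c.residue_i) or _excluded(c.residue_j):
                continue
            if c.e_total < 0 and c.distance <= criteria.distance_threshold:
                _add(rec, c.residue_i, abs(c.e_total))
                _add(lig, c.residue_j, abs(c.e_total))
    else:
        if not isinstance(contacts, pd.DataFrame):
            from .energetics import residue_pair_table
            contacts = residue_pair_table(list(contacts))
        for row in contacts.itertuples(index=False):
            key_i = parse_residue_key(row.residue_i)
            key_j = parse_residue_key(row.residue_j)
            if _excluded(key_i) or _excluded(key_j):
                continue
            if (row.sum_e_total <= criteria.energy_threshold
                    and row.min_distance_A <= criteria.distance_threshold):
                _add(rec, key_i, abs(row.sum_e_total))
                _add(lig, key_j, abs(row.sum_e_total))

    return (
        HotspotTable(_rank_rows(rec), side="receptor", criteria=criteria),
        HotspotTable(_rank_rows(lig), side="ligand", criteria=criteria),
    )


def top_n(table: HotspotTable, n: int) -> list[str]:
    """First min(n, len) residue ids by rank (deterministic under ties)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return table.rows.nsmallest(min(n, len(table.rows)), "rank")["residue_id"].tolist() \
        if len(table.rows) else []


def energy_weighted_histogram(table: HotspotTable) -> pd.DataFrame:
    """Per-residue bar series (residue_id, strength), ordered by sequence.

    Bar height is the summed magnitude of favorable interaction energies
    (Sigma |E_neg|) for each residue.
    """
    if not len(table.rows):
        return pd.DataFrame(columns=["residue_id", "strength_kcal_mol"])
    df = table.rows.copy()
    keys = df["residue_id"].map(parse_residue_key)
    df["_chain"] = [k.chain_id for k in keys]
    df["_seq"] = [k.res_seq for k in keys]
    df["_icode"] = [k.insertion_code for k in keys]
    df = df.sort_values(["_chain", "_seq", "_icode"], kind="mergesort")
    return df[["residue_id", "strength_kcal_mol"]].reset_index(drop=True)


def hotspot_engagement(
    model: StructureModel,
    binder_chains: "frozenset[str] | set[str]",
    hotspot_residues: "list[str] | list[ResidueKey]",
    contact_cutoff: float = DEFAULT_CUTOFF,
) -> int:
    """Number of listed target hotspot residues with a heavy atom within
    ``contact_cutoff`` A of any binder heavy atom."""
    binder_chains = set(binder_chains)
    binder_atoms = [
        a for a in model.atoms if a.chain_id in binder_chains and not a.is_hydrogen
    ]
    if not binder_atoms:
        return 0
    tree = cKDTree(coordinates(binder_atoms))
    count = 0
    for res in hotspot_residues:
        key = parse_residue_key(res) if isinstance(res, str) else res
        if key not in model.residues:
            raise UnknownResidueError(f"hotspot residue {canonical_key(key)} not in model")
        heavy = [a for a in model.residue_atoms(key) if not a.is_hydrogen]
        if not heavy:
            continue
        d, _ = tree.query(coordinates(heavy), k=1)
        if np.min(d) <= contact_cutoff:
            count += 1
    return count


def write_hotspot_csv(table: HotspotTable, path: "str | Path", dielectric_mode: str = "") -> None:
    """Write a hotspot table with a JSON header block recording the criteria."""
    header = {
        "side": table.side,
        "criteria": asdict(table.criteria),
        "dielectric_mode": dielectric_mode,
        "provenance": table.provenance,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        out = table.rows.copy()
        out.insert(1, "side", table.side)
        out.to_csv(fh, index=False)


def read_hotspot_csv(path: "str | Path") -> HotspotTable:
    """Read a hotspot table written by :func:`write_hotspot_csv`."""
    with open(path) as fh:
        first = fh.readline()
        header = json.loads(first.lstrip("# ")) if first.startswith("#") else {}
        if not first.startswith("#"):
            fh.seek(0)
        rows = pd.read_csv(fh)
    crit = header.get("criteria")
    criteria = HotspotCriteria(**crit) if crit else HotspotCriteria()
    if "side" in rows.columns:
        rows = rows.drop(columns=["side"])
    return HotspotTable(
        rows=rows, side=header.get("side", ""), criteria=criteria,
        provenance=header.get("provenance", ""),
    )
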