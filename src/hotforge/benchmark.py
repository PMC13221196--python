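"""Concordance benchmarking between two per-residue hotspot rankings.

Typically one table comes from the package's own physics engine and the other
from an imported commercial contact-table export (a residue-pair CSV with
per-vendor column naming and residue labels such as ``GLU 957 (A)``). After
canonicalizing residue identifiers and dropping waters, the external table is
aggregated with the same residue-pair criteria as native tables, and the two
rankings are compared with:

* Spearman rank correlation over residues present in BOTH tables (ties get
  average ranks),
* Pearson correlation of strength magnitudes over the same shared residues,
* Top-N overlap statistics (intersection size, Jaccard index, and recall) at
  configurable N (default 5, 10, 20, 30, 50).

``recall_a`` is |TopN_a intersect TopN_b| / N, the recall of A's Top-N by B at
the same N, and symmetrically for ``recall_b``. With fewer than 3 shared
residues the correlations are reported as undefined (flagged) while the
overlap statistics are still computed.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DialectError
from .hotspots import HotspotCriteria, HotspotTable, TOP_N_DEFAULT, aggregate_hotspots, top_n
from .structure_io import ResidueKey, WATER_RES_NAMES, canonical_key

#: Column mapping + residue-label regex for a MOE-like contact export.
MOE_LIKE_DIALECT = {
    "residue_i": "residue_1",
    "residue_j": "residue_2",
    "distance": "distance_A",
    "energy": "energy_kcal_mol",
    "label_pattern": r"^\s*(?P<res_name>[A-Z]{2,3})\s+(?P<res_seq>-?\d+)(?P<icode>[A-Za-z]?)\s*\((?P<chain>[A-Za-z0-9])\)\s*$",
}


def parse_residue_label(label: str, pattern: str) -> ResidueKey:
    """Parse one raw residue label under a dialect's regex."""
    m = re.match(pattern, str(label))
    if not m:
        raise DialectError(f"cannot parse residue label {label!r}")
    g = m.groupdict()
    return ResidueKey(
        chain_id=g["chain"], res_name=g["res_name"].upper(),
        res_seq=int(g["res_seq"]), insertion_code=g.get("icode", "") or "",
    )


@dataclass
class ExternalContactTable:
    """Canonicalized, water-free residue-pair table from an external export."""

    rows: pd.DataFrame  # residue_i, residue_j, min_distance_A, sum_e_total
    dialect: dict = field(default_factory=lambda: dict(MOE_LIKE_DIALECT))
    source: str = ""

    def to_hotspots(self, criteria: HotspotCriteria | None = None) -> tuple[HotspotTable, HotspotTable]:
        criteria = criteria or HotspotCriteria(aggregation="residue_pair")
        df = self.rows.rename(columns={})
        agg = df.groupby(["residue_i", "residue_j"], sort=False).agg(
            min_distance_A=("min_distance_A", "min"),
            mean_distance_A=("min_distance_A", "mean"),
            sum_e_total=("sum_e_total", "sum"),
            n_atom_pairs=("sum_e_total", "size"),
        ).reset_index()
        return aggregate_hotspots(agg, criteria)


def ingest_external_table(
    path: "str | Path", dialect: dict | None = None
) -> ExternalContactTable:
    """Read an external residue-pair CSV and canonicalize it.

    Rows involving water residues are dropped (waters are excluded from
    contact aggregation). Unmappable residue labels raise
    :class:`DialectError` quoting the offending label.
    """
    dialect = dict(MOE_LIKE_DIALECT, **(dialect or {}))
    raw = pd.read_csv(path)
    for role in ("residue_i", "residue_j", "distance", "energy"):
        if dialect[role] not in raw.columns:
            raise DialectError(
                f"column {dialect[role]!r} (for {role}) missing from {path}; "
                f"have {list(raw.columns)}"
            )
    pattern = dialect["label_pattern"]
    keys_i = [parse_residue_label(v, pattern) for v in raw[dialect["residue_i"]]]
    keys_j = [parse_residue_label(v, pattern) for v in raw[dialect["residue_j"]]]
    keep = [
        ki.res_name not in WATER_RES_NAMES and kj.res_name not in WATER_RES_NAMES
        for ki, kj in zip(keys_i, keys_j)
    ]
    rows = pd.DataFrame({
        "residue_i": [canonical_key(k) for k, ok in zip(keys_i, keep) if ok],
        "residue_j": [canonical_key(k) for k, ok in zip(keys_j, keep) if ok],
        "min_distance_A": raw.loc[keep, dialect["distance"]].to_numpy(dtype=float),
        "sum_e_total": raw.loc[keep, dialect["energy"]].to_numpy(dtype=float),
    })
    return ExternalContactTable(rows=rows, dialect=dialect, source=str(path))


def export_external_table(table: ExternalContactTable, path: "str | Path") -> None:
    """Round-trippable export of a canonicalized table in its dialect."""
    from .structure_io import parse_residue_key

    def fmt(canonical: str) -> str:
        k = parse_residue_key(canonical)
        return f"{k.res_name} {k.res_seq}{k.insertion_code} ({k.chain_id})"

    d = table.dialect
    out = pd.DataFrame({
        d["residue_i"]: table.rows["residue_i"].map(fmt),
        d["residue_j"]: table.rows["residue_j"].map(fmt),
        d["distance"]: table.rows["min_distance_A"],
        d["energy"]: table.rows["sum_e_total"],
    })
    out.to_csv(path, index=False)


@dataclass
class BenchmarkReport:
    """Concordance statistics between two hotspot tables."""

    n_shared: int
    spearman_rho: float | None
    pearson_r: float | None
    correlations_defined: bool
    per_n: pd.DataFrame  # N, intersection_size, jaccard, recall_a, recall_b
    unique_to_a: list[str]
    unique_to_b: list[str]

    def to_json(self) -> str:
        payload = {
            "n_shared": self.n_shared,
            "spearman_rho": self.spearman_rho,
            "pearson_r": self.pearson_r,
            "correlations_defined": self.correlations_defined,
            "recall_definition": "recall_a = |TopN_a & TopN_b| / N (B's recovery of A's Top-N); symmetric for recall_b",
            "per_n": self.per_n.to_dict(orient="records"),
            "unique_to_a": self.unique_to_a,
            "unique_to_b": self.unique_to_b,
        }
        return json.dumps(payload, indent=2)


def concordance(
    table_a: HotspotTable,
    table_b: HotspotTable,
    n_set: tuple[int, ...] = TOP_N_DEFAULT,
) -> BenchmarkReport:
    """Compare two hotspot rankings of the same interface side."""
    sa = table_a.strengths()
    sb = table_b.strengths()
    shared = sa.index.intersection(sb.index)
    n_shared = len(shared)
    if n_shared >= 3:
        rho = float(stats.spearmanr(sa[shared], sb[shared]).statistic)
        # Pearson of strength magnitudes; degenerate (zero-variance) -> undefined
        if np.std(sa[shared]) > 0 and np.std(sb[shared]) > 0:
            r = float(stats.pearsonr(sa[shared], sb[shared]).statistic)
        else:
            r = None
        defined = True
    else:
        rho = r = None
        defined = False
    records = []
    for n in n_set:
        top_a = set(top_n(table_a, n))
        top_b = set(top_n(table_b, n))
        inter = len(top_a & top_b)
        union = len(top_a | top_b)
        records.append({
            "N": n,
            "intersection_size": inter,
            "jaccard": inter / union if union else 0.0,
            # recall of A's Top-N by B at the same N (and symmetrically);
            # denominators fall back to the actual set size for short tables
            "recall_a": inter / len(top_a) if top_a else 0.0,
            "recall_b": inter / len(top_b) if top_b else 0.0,
        })
    return BenchmarkReport(
        n_shared=n_shared,
        spearman_rho=rho,
        pearson_r=r,
        correlations_defined=defined,
        per_n=pd.DataFrame(records),
        unique_to_a=sorted(sa.index.difference(sb.index)),
        unique_to_b=sorted(sb.index.difference(sa.index)),
    )
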