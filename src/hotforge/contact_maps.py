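"""Chain-aware contact cartography.

Three complementary geometric views of a complex are built from C-alpha
coordinates over an ordered list of chains:

* a CA-CA distance matrix (A),
* a reciprocal-distance map, 100/d, which accentuates short-range contacts,
* a binary contact matrix, 1 iff d <= cutoff (default 8 A, inclusive).

Chain boundaries are recorded so inter-chain blocks can be sliced out to
inspect interface packing separately from intra-chain structure. The
reciprocal map's diagonal (and any near-coincident pair, d < 1e-6 A) is
masked as NaN rather than infinite so exports stay finite and plottable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyStructureError, UnknownChainError
from .structure_io import ResidueKey, StructureModel, canonical_key

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 8.0


@dataclass
class ContactMapSet:
    """Distance / reciprocal / binary matrices over concatenated chains."""

    labels: list[ResidueKey]
    chain_bounds: dict[str, tuple[int, int]]  # chain -> [start, stop) row range
    distance: np.ndarray
    reciprocal: np.ndarray
    binary: np.ndarray
    cutoff: float

    def __len__(self) -> int:
        return len(self.labels)

    def label_strings(self) -> list[str]:
        return [canonical_key(k) for k in self.labels]


def build_contact_maps(
    model: StructureModel,
    chains: list[str],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactMapSet:
    """Build the three matrices over the CA atoms of the named chains.

    Residues without a CA atom (e.g. HETATM ligands) are skipped with a
    warning. Raises :class:`EmptyStructureError` if no CA atoms remain.
    """
    available = set(model.chain_ids)
    missing = [c for c in chains if c not in available]
    if missing:
        raise UnknownChainError(
            f"chain(s) {missing} not in model; available: {sorted(available)}"
        )
    labels: list[ResidueKey] = []
    coords: list[np.ndarray] = []
    bounds: dict[str, tuple[int, int]] = {}
    for chain in chains:
        start = len(labels)
        for key, indices in model.residues.items():
            if key.chain_id != chain:
                continue
            ca = next((model.atoms[i] for i in indices if model.atoms[i].name == "CA"), None)
            if ca is None:
                logger.warning("residue %s has no CA atom; skipped from maps", canonical_key(key))
                continue
            labels.append(key)
            coords.append(ca.position)
        bounds[chain] = (start, len(labels))
    if not labels:
        raise EmptyStructureError(f"no CA atoms found on chains {chains}")
    xyz = np.stack(coords)
    diff = xyz[:, None, :] - xyz[None, :, :]
    distance = np.sqrt((diff * diff).sum(axis=-1))
    with np.errstate(divide="ignore"):
        reciprocal = np.where(distance < 1e-6, np.nan, 100.0 / distance)
    binary = (distance <= cutoff).astype(np.int8)
    return ContactMapSet(
        labels=labels, chain_bounds=bounds,
        distance=distance, reciprocal=reciprocal, binary=binary, cutoff=cutoff,
    )


@dataclass
class InterchainBlock:
    """Rectangular interface block: rows from one chain, columns from another."""

    row_labels: list[ResidueKey]
    col_labels: list[ResidueKey]
    distance: np.ndarray
    reciprocal: np.ndarray
    binary: np.ndarray


def interchain_block(maps: ContactMapSet, chain_a: str, chain_b: str) -> InterchainBlock:
    """Sub-matrices restricted to chain_a rows x chain_b columns."""
    for c in (chain_a, chain_b):
        if c not in maps.chain_bounds:
            raise UnknownChainError(f"chain {c!r} not in maps; have {list(maps.chain_bounds)}")
    a0, a1 = maps.chain_bounds[chain_a]
    b0, b1 = maps.chain_bounds[chain_b]
    return InterchainBlock(
        row_labels=maps.labels[a0:a1],
        col_labels=maps.labels[b0:b1],
        distance=maps.distance[a0:a1, b0:b1],
        reciprocal=maps.reciprocal[a0:a1, b0:b1],
        binary=maps.binary[a0:a1, b0:b1],
    )


def maps_to_dataframes(maps: ContactMapSet) -> dict[str, pd.DataFrame]:
    """Dense labelled DataFrames ('distance', 'reciprocal', 'binary')."""
    idx = maps.label_strings()
    return {
        name: pd.DataFrame(getattr(maps, name), index=idx, columns=idx)
        for name in ("distance", "reciprocal", "binary")
    }


def write_maps(maps: ContactMapSet, out_prefix: str) -> list[str]:
    """Write the three matrices as residue_id-labelled CSVs; returns paths."""
    paths = []
    for name, df in maps_to_dataframes(maps).items():
        path = f"{out_prefix}{name}.csv"
        df.to_csv(path, index_label="residue_id")
        paths.append(path)
    return paths


def render_maps(maps: ContactMapSet, out_path: str) -> None:
    """Basic three-panel heatmap rendering (distance / 100/d / binary)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, name, cmap in zip(
        axes, ("distance", "reciprocal", "binary"), ("viridis", "magma", "Greys")
    ):
        im = ax.imshow(getattr(maps, name), cmap=cmap)
        ax.set_title(name)
        fig.colorbar(im, ax=ax, shrink=0.8)
        for bound in maps.chain_bounds.values():
            if bound[0] > 0:
                ax.axhline(bound[0] - 0.5, color="w", lw=0.6)
                ax.axvline(bound[0] - 0.5, color="w", lw=0.6)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
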