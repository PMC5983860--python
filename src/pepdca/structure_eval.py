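"""Contact maps from structures and structural evaluation of ranked pairs.

Residues are keyed by structure residue number (int) for the protein chain
and by ``"P1".."PK"`` labels for a peptide chain merged onto it.  "Heavy
atoms" means all non-hydrogen atoms, side chains included; alternate
locations are resolved to highest occupancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

ResidueKey = int | str


@dataclass
class ResidueCoordinates:
    """Heavy-atom coordinates per residue."""

    coords: dict[ResidueKey, np.ndarray]  # key -> (n_atoms, 3)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def keys(self) -> list[ResidueKey]:
        # ints first in numeric order, then peptide labels in positional order
        ints = sorted(k for k in self.coords if isinstance(k, int))
        peps = sorted((k for k in self.coords if isinstance(k, str)), key=lambda s: int(s[1:]))
        return [*ints, *peps]


@dataclass
class ContactMap:
    """Minimum heavy-atom distances and thresholded contacts per residue pair."""

    residues: list[ResidueKey]
    min_distance: np.ndarray  # (n, n), symmetric, zero diagonal
    threshold: float

    @property
    def contacts(self) -> np.ndarray:
        """Boolean contact matrix: min distance <= threshold (inclusive)."""
        c = self.min_distance <= self.threshold
        np.fill_diagonal(c, False)
        return c

    def index(self, key: ResidueKey) -> int:
        return self.residues.index(key)

    def is_contact(self, a: ResidueKey, b: ResidueKey) -> bool:
        return bool(self.contacts[self.index(a), self.index(b)])


@dataclass
class PrecisionCurve:
    """Precision(k) = true positives among the top-k predictions, k = 1..k_max."""

    k: np.ndarray
    precision: np.ndarray
    n_skipped: int  # predictions unmappable to resolved residues


def read_structure(
    pdb_path: str,
    chain: str,
    peptide_chain: str | None = None,
) -> ResidueCoordinates:
    """Read heavy-atom coordinates for one chain, optionally merging a peptide.

    Peptide-chain residues are relabeled ``P1..PK`` in residue order so a
    merged complex uses a single residue namespace, mirroring reformatted
    single-chain complexes used for stability scans.
    """
    pdb = PDBFile.read(str(pdb_path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    atoms = atoms[~np.isin(atoms.element, ("H", "D"))]
    atoms = atoms[~atoms.hetero]
    coords: dict[ResidueKey, np.ndarray] = {}

    def collect(chain_id: str) -> list[tuple[int, np.ndarray]]:
        sel = atoms[atoms.chain_id == chain_id]
        if sel.array_length() == 0:
            raise ValueError(f"chain {chain_id!r} not found or has no heavy atoms")
        out = []
        for res_id in np.unique(sel.res_id):
            res_atoms = sel[sel.res_id == res_id]
            out.append((int(res_id), res_atoms.coord.astype(float)))
        return out

    for res_id, xyz in collect(chain):
        coords[res_id] = xyz
    if peptide_chain is not None:
        for pos, (_, xyz) in enumerate(collect(peptide_chain), start=1):
            coords[f"P{pos}"] = xyz
    return ResidueCoordinates(coords=coords)


def contact_map(coords: ResidueCoordinates, threshold: float = 8.0) -> ContactMap:
    """Minimum heavy-atom distance between every residue pair.

    Contacts are inclusive at the threshold (distance <= threshold).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keys = coords.keys
    n = len(keys)
    dist = np.zeros((n, n))
    for a in range(n):
        xa = coords.coords[keys[a]]
        for b in range(a + 1, n):
            d = cdist(xa, coords.coords[keys[b]]).min()
            dist[a, b] = dist[b, a] = d
    return ContactMap(residues=keys, min_distance=dist, threshold=threshold)


def precision_curve(
    ranked_pairs,
    cmap: ContactMap,
    column_map: np.ndarray | None = None,
    k_max: int = 900,
) -> PrecisionCurve:
    """Precision over the top-k ranked pairs against a structural contact map.

    Alignment columns are translated to structure residue numbers through
    ``column_map`` (1-based); predictions involving residues unresolved in
    the structure are skipped, not counted as false positives.
    """
    lookup = {key: idx for idx, key in enumerate(cmap.residues)}
    contacts = cmap.contacts
    hits: list[bool] = []
    skipped = 0
    for i, j, _ in ranked_pairs:
        if len(hits) >= k_max:
            break
        key_i = _map_column(i, column_map)
        key_j = _map_column(j, column_map)
        ai, aj = lookup.get(key_i), lookup.get(key_j)
        if ai is None or aj is None:
            skipped += 1
            continue
        hits.append(bool(contacts[ai, aj]))
    if not hits:
        raise ValueError("no ranked pair could be mapped onto the structure")
    tp = np.cumsum(hits)
    k = np.arange(1, len(hits) + 1)
    return PrecisionCurve(k=k, precision=tp / k, n_skipped=skipped)


def _map_column(col: int, column_map: np.ndarray | None) -> ResidueKey:
    """Alignment column -> residue key; ligand-block string labels pass through."""
    if isinstance(col, str):
        return col
    if column_map is None:
        return int(col) + 1
    mapped = column_map[col]
    return mapped if isinstance(mapped, str) else int(mapped)


def contacts_per_site(coords: ResidueCoordinates, threshold: float = 5.0) -> dict[ResidueKey, int]:
    """Number of other residues within ``threshold`` of each residue.

    Merged peptide residues both receive counts and contribute to the counts
    of protein residues.
    """
    cmap = contact_map(coords, threshold)
    counts = cmap.contacts.sum(axis=1)
    return {key: int(counts[idx]) for idx, key in enumerate(cmap.residues)}


def long_range_contacts_per_site(
    coords: ResidueCoordinates,
    threshold: float = 5.0,
    min_separation: int = 4,
) -> dict[ResidueKey, int]:
    """Contacts restricted to sequence-distant partners.

    Partners on the same (numeric) chain count only when
    ``|residue number difference| > min_separation``; pairs involving a
    merged peptide residue are inter-chain and always count.
    """
    cmap = contact_map(coords, threshold)
    keys = cmap.residues
    contacts = cmap.contacts
    out: dict[ResidueKey, int] = {}
    for a, key_a in enumerate(keys):
        n = 0
        for b, key_b in enumerate(keys):
            if a == b or not contacts[a, b]:
                continue
            if isinstance(key_a, int) and isinstance(key_b, int):
                if abs(key_a - key_b) <= min_separation:
                    continue
            n += 1
        out[key_a] = n
    return out
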