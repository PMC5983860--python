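"""Synthetic benchmark generators: planted-coupling alignments, ligand
datasets with anchor-residue specificity, toy structures and enrichment
ranking fixtures.

All generators are pure functions of their spec plus a seed.  The default
simulation alphabet is smaller than the 21-state protein alphabet so that
brute-force oracles stay cheap; downstream modules are alphabet-size
generic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from pepdca.alignment_io import MSA, LigandSet

#: letters used for simulation alphabets (no gap: sampled sequences are ungapped)
_SIM_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


def simulation_alphabet(q_sim: int) -> str:
    """First ``q_sim`` amino-acid letters; the last one doubles as the gauge
    state downstream."""
    if not 2 <= q_sim <= len(_SIM_LETTERS):
        raise ValueError(f"q_sim must be in [2, {len(_SIM_LETTERS)}]")
    return _SIM_LETTERS[:q_sim]


@dataclass
class PottsSpec:
    """Specification for a pairwise-model alignment with planted couplings."""

    n_columns: int
    n_sequences: int
    seed: int
    q_sim: int = 8
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    burn_in: int = 1000
    thinning: int = 10
    min_separation: int = 4

    def __post_init__(self) -> None:
        for i, j, strength in self.planted_pairs:
            if abs(i - j) <= self.min_separation:
                raise ValueError(f"planted pair ({i}, {j}) violates the separation constraint")
            if not np.isfinite(strength):
                raise ValueError("coupling strength must be finite")
            if not (0 <= i < self.n_columns and 0 <= j < self.n_columns):
                raise ValueError(f"planted pair ({i}, {j}) outside [0, {self.n_columns})")


@dataclass
class LigandCouplingSpec:
    """One protein column statistically determines a ligand anchor column.

    Each protein sequence is uniform random; each of its ligands carries, at
    ``anchor_column`` (1-based within the ligand), the amino acid matching
    the protein's residue at ``protein_column`` with probability
    ``preference``, and a uniform draw over the other letters otherwise.
    """

    n_proteins: int
    protein_len: int
    ligand_len: int
    n_ligands: int
    protein_column: int  # 0-based
    anchor_column: int  # 1-based, in [1, ligand_len]
    preference: float
    seed: int
    q_sim: int = 8

    def __post_init__(self) -> None:
        if not 1 <= self.anchor_column <= self.ligand_len:
            raise ValueError("anchor_column must be within [1, ligand_len]")
        if not 1.0 / self.q_sim < self.preference <= 1.0:
            raise ValueError("preference must exceed the uniform rate 1/q_sim and be <= 1")
        if not 0 <= self.protein_column < self.protein_len:
            raise ValueError("protein_column outside the protein block")


def sample_potts_msa(spec: PottsSpec) -> MSA:
    """Gibbs-sample sequences from a zero-field pairwise model.

    Planted pairs (i, j, strength) carry ferromagnetic couplings
    ``J(A, B) = strength * delta(A, B)``; all other column pairs are
    uncoupled, so unplanted columns are independently uniform.  Sequences are
    taken from independent parallel chains (one per output sequence), each
    run for ``burn_in + thinning`` full sweeps from a uniform random start.
    """
    rng = np.random.default_rng(spec.seed)
    L, N, q = spec.n_columns, spec.n_sequences, spec.q_sim
    partners: dict[int, list[tuple[int, float]]] = {}
    for i, j, s in spec.planted_pairs:
        partners.setdefault(i, []).append((j, s))
        partners.setdefault(j, []).append((i, s))

    state = rng.integers(0, q, size=(N, L))
    coupled_sites = sorted(partners)
    n_sweeps = spec.burn_in + spec.thinning
    for _ in range(n_sweeps):
        # uncoupled sites have uniform conditionals: no need to resample them
        for i in coupled_sites:
            logits = np.zeros((N, q))
            for j, s in partners[i]:
                # J(A, B) = s * delta: the partner's state gets a bonus of s
                logits[np.arange(N), state[:, j]] += s
            probs = np.exp(logits - logits.max(axis=1, keepdims=True))
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random((N, 1))
            state[:, i] = (probs.cumsum(axis=1) < u).sum(axis=1)
    ids = [f"seq{r:05d}" for r in range(N)]
    return MSA(sequence_ids=ids, matrix=state, alphabet=simulation_alphabet(q))


def sample_ligand_dataset(spec: LigandCouplingSpec) -> tuple[MSA, LigandSet]:
    """Protein alignment plus ligand sets with a planted anchor rule."""
    rng = np.random.default_rng(spec.seed)
    q = spec.q_sim
    alphabet = simulation_alphabet(q)
    proteins = rng.integers(0, q, size=(spec.n_proteins, spec.protein_len))
    ids = [f"prot{r:05d}" for r in range(spec.n_proteins)]
    anchor = spec.anchor_column - 1
    peptides: dict[str, list[str]] = {}
    for a, sid in enumerate(ids):
        preferred = proteins[a, spec.protein_column]
        peps = []
        for _ in range(spec.n_ligands):
            codes = rng.integers(0, q, size=spec.ligand_len)
            if rng.random() < spec.preference:
                codes[anchor] = preferred
            else:
                # uniform over the non-preferred letters
                other = rng.integers(0, q - 1)
                codes[anchor] = other if other < preferred else other + 1
            peps.append("".join(alphabet[c] for c in codes))
        peptides[sid] = peps
    msa = MSA(sequence_ids=ids, matrix=proteins, alphabet=alphabet)
    return msa, LigandSet(peptides=peptides, length=spec.ligand_len)


def make_toy_structure(
    n_residues: int,
    geometry: str = "line",
    spacing: float = 4.0,
    path: str | Path | None = None,
    chain: str = "A",
) -> PDBFile:
    """Write a minimal single-chain, one-atom-per-residue structure.

    Geometries: ``line`` (collinear at ``spacing`` angstroms), ``helix``
    (ideal alpha-helix CA trace), ``grid`` (square grid at ``spacing``).
    Returns the PDBFile; writes it when ``path`` is given.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    if geometry == "line":
        xyz = np.zeros((n_residues, 3))
        xyz[:, 0] = np.arange(n_residues) * spacing
    elif geometry == "helix":
        t = np.arange(n_residues) * (2 * np.pi / 3.6)
        xyz = np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n_residues)])
    elif geometry == "grid":
        side = int(np.ceil(np.sqrt(n_residues)))
        gx, gy = np.meshgrid(np.arange(side), np.arange(side))
        pts = np.column_stack([gx.ravel(), gy.ravel()])[:n_residues] * spacing
        xyz = np.column_stack([pts, np.zeros(n_residues)])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    atoms = struc.AtomArray(n_residues)
    atoms.coord = xyz.astype(np.float32)
    atoms.chain_id = np.full(n_residues, chain)
    atoms.res_id = np.arange(1, n_residues + 1)
    atoms.res_name = np.full(n_residues, "ALA")
    atoms.atom_name = np.full(n_residues, "CA")
    atoms.element = np.full(n_residues, "C")
    atoms.hetero = np.zeros(n_residues, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    if path is not None:
        pdb.write(str(path))
    return pdb


def sample_ranking_fixture(
    n_sites: int,
    n_labeled: int,
    enrichment_strength: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Ranked values with labels placed with a tunable top-rank bias.

    ``enrichment_strength=0`` places labels uniformly (null);
    ``numpy.inf`` puts every label on the top ranks (perfect separation).
    """
    if not 0 < n_labeled < n_sites:
        raise ValueError("n_labeled must be strictly between 0 and n_sites")
    if enrichment_strength < 0:
        raise ValueError("enrichment_strength must be >= 0")
    rng = np.random.default_rng(seed)
    values = np.sort(rng.random(n_sites))[::-1].copy()
    labels = np.zeros(n_sites, dtype=bool)
    if np.isinf(enrichment_strength):
        labels[:n_labeled] = True
        return values, labels
    rank_quality = 1.0 - np.arange(n_sites) / (n_sites - 1)  # 1 at top, 0 at bottom
    weights = np.exp(enrichment_strength * rank_quality)
    weights /= weights.sum()
    chosen = rng.choice(n_sites, size=n_labeled, replace=False, p=weights)
    labels[chosen] = True
    return values, labels
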