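"""Joint protein+ligand frequency model for multi-ligand coupling analysis.

Each protein sequence may carry several fixed-length peptide ligands.  The
joint model is realized as a row-expanded weighted alignment: one row per
(protein, ligand) pair carrying weight ``w_a / N_a``, where ``w_a = 1/m_a``
is the protein's redundancy weight (computed on the protein block only) and
``N_a`` its ligand count.  Summing these rows reproduces, exactly, the three
frequency definitions: the protein block collapses back to weight ``w_a``,
ligand single-site and ligand-ligand pair frequencies average over ligands,
and protein-ligand pair frequencies factorize over the protein residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from pepdca.alignment_io import MSA, LigandSet
from pepdca.dca_core import (
    FrequencyModel,
    RankedPairs,
    PairScoreMatrix,
    SequenceWeights,
    compute_weights,
    frequencies_from_rows,
)

logger = logging.getLogger(__name__)


@dataclass
class JointAlignment:
    """Row-expanded protein+ligand alignment.

    ``rows`` has one row per (sequence, ligand) with ``L + K`` columns;
    ``row_weights[r] = w_a / N_a`` so the total weight of a sequence's rows
    equals its protein weight ``w_a``.
    """

    rows: np.ndarray
    row_weights: np.ndarray
    sequence_ids: list[str]  # per expanded row
    protein_len: int
    ligand_len: int
    alphabet: str
    meff: float

    @property
    def n_columns(self) -> int:
        return self.protein_len + self.ligand_len

    @property
    def q(self) -> int:
        return len(self.alphabet)


class PairPartition(NamedTuple):
    """Ranked pairs split by molecular block membership."""

    intra: RankedPairs
    inter: RankedPairs
    intra_ligand: RankedPairs


def build_joint_alignment(
    msa: MSA,
    ligands: LigandSet,
    weights: SequenceWeights | None = None,
    identity_threshold: float = 0.8,
) -> JointAlignment:
    """Combine a protein alignment with per-sequence ligand sets.

    Sequences absent from the ligand set are excluded (and logged); sequence
    weights are computed on the retained protein rows only, so ligand content
    never influences redundancy weighting.  Ligand peptides must be ungapped
    and use the alignment's alphabet.
    """
    keep_idx = [a for a, sid in enumerate(msa.sequence_ids) if sid in ligands.peptides]
    dropped = msa.n_sequences - len(keep_idx)
    if dropped:
        logger.info("excluding %d sequences without ligands", dropped)
    if not keep_idx:
        raise ValueError("no overlap between alignment sequence ids and ligand set")

    sub = MSA(
        sequence_ids=[msa.sequence_ids[a] for a in keep_idx],
        matrix=msa.matrix[keep_idx],
        alphabet=msa.alphabet,
        species_labels=None,
        column_map=msa.column_map,
    )
    if weights is None:
        weights = compute_weights(sub, identity_threshold)
    w = weights.w
    if w.shape[0] != sub.n_sequences:
        raise ValueError("weights do not match the retained sequence set")

    index = {c: s for s, c in enumerate(msa.alphabet)}
    gap_idx = index.get("-")
    K = ligands.length
    rows: list[np.ndarray] = []
    row_w: list[float] = []
    row_ids: list[str] = []
    for a, sid in enumerate(sub.sequence_ids):
        peps = ligands.peptides[sid]
        n_a = len(peps)
        for pep in peps:
            codes = np.empty(K, dtype=np.int64)
            for k, ch in enumerate(pep.upper()):
                code = index.get(ch)
                if code is None or code == gap_idx:
                    raise ValueError(f"ligand {pep!r} of {sid!r} contains a non-alphabet or gap character")
                codes[k] = code
            rows.append(np.concatenate([sub.matrix[a], codes]))
            row_w.append(w[a] / n_a)
            row_ids.append(sid)
    return JointAlignment(
        rows=np.asarray(rows, dtype=np.int64),
        row_weights=np.asarray(row_w),
        sequence_ids=row_ids,
        protein_len=sub.n_columns,
        ligand_len=K,
        alphabet=msa.alphabet,
        meff=weights.meff,
    )


def compute_joint_frequencies(
    joint: JointAlignment,
    pseudocount: float | str = "meff",
) -> FrequencyModel:
    """Frequency model over all ``L + K`` joint columns.

    The default pseudocount equals the protein-block effective sequence
    number, matching the plain-alignment convention.
    """
    lam = joint.meff if pseudocount == "meff" else float(pseudocount)
    return frequencies_from_rows(
        joint.rows, joint.row_weights, joint.q, lam, meff=joint.meff
    )


def split_intra_inter(
    scores: PairScoreMatrix | np.ndarray,
    protein_len: int,
    min_separation: int = 4,
    top_k: int | None = None,
) -> PairPartition:
    """Partition ranked pairs into intra-protein / inter-molecular / intra-ligand.

    The sequence-separation filter applies only within the protein block (and
    within the ligand block); inter-molecular pairs involve distinct chains
    and are never separation-filtered.
    """
    di = scores.di if isinstance(scores, PairScoreMatrix) else np.asarray(scores)
    L_total = di.shape[0]
    if protein_len >= L_total:
        raise ValueError("protein_len must be smaller than the joint column count")
    intra, inter, intra_lig = [], [], []
    for i in range(L_total - 1):
        for j in range(i + 1, L_total):
            entry = (i, j, float(di[i, j]))
            if j < protein_len:
                if j - i > min_separation:
                    intra.append(entry)
            elif i >= protein_len:
                if j - i > min_separation:
                    intra_lig.append(entry)
            else:
                inter.append(entry)
    key = lambda p: (-p[2], p[0], p[1])
    for bucket in (intra, inter, intra_lig):
        bucket.sort(key=key)
    if top_k is not None:
        intra, inter, intra_lig = intra[:top_k], inter[:top_k], intra_lig[:top_k]
    return PairPartition(
        intra=RankedPairs(intra, min_separation),
        inter=RankedPairs(inter, 0),
        intra_ligand=RankedPairs(intra_lig, min_separation),
    )
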