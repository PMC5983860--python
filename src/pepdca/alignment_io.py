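"""Readers and filters for alignments, ligand tables and per-site annotations.

All alignment data is held as an integer matrix over an explicit alphabet
string whose last-by-convention gap symbol is ``-``.  Columns are indexed
0-based internally; ``column_map`` carries 1-based reference (structure)
residue numbers when available.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO

#: canonical 21-state protein alphabet: 20 amino acids followed by the gap.
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"

#: characters normalized to the gap state (ambiguous/rare residue codes).
_UNKNOWN_RESIDUES = set("XBZUOJ*")

_GAP_CHARS = {"-", ".", "~"}


class AlignmentError(ValueError):
    """Raised for malformed or empty alignment input."""


@dataclass
class MSA:
    """A multiple sequence alignment over a fixed alphabet.

    Attributes
    ----------
    sequence_ids:
        Unique identifier per row.
    matrix:
        ``(M, L)`` integer matrix of alphabet indices.
    alphabet:
        Alphabet string; the gap character, when present, must be ``-``.
    species_labels:
        Optional species label per row.
    column_map:
        Optional 1-based, strictly increasing reference residue number per
        column (structure numbering).
    """

    sequence_ids: list[str]
    matrix: np.ndarray
    alphabet: str = PROTEIN_ALPHABET
    species_labels: list[str] | None = None
    column_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-dimensional")
        if self.matrix.shape[0] != len(self.sequence_ids):
            raise AlignmentError("sequence_ids length does not match matrix rows")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise AlignmentError("sequence identifiers must be unique")
        if self.n_columns < 1:
            raise AlignmentError("alignment must have at least one column")
        if self.matrix.min(initial=0) < 0 or self.matrix.max(initial=0) >= self.q:
            raise AlignmentError("matrix entries outside alphabet range")
        if self.species_labels is not None and len(self.species_labels) != self.n_sequences:
            raise AlignmentError("species_labels length does not match number of sequences")
        if self.column_map is not None:
            self.column_map = np.asarray(self.column_map, dtype=np.int64)
            if self.column_map.shape != (self.n_columns,):
                raise AlignmentError("column_map length does not match number of columns")
            if np.any(np.diff(self.column_map) <= 0):
                raise AlignmentError("column_map must be strictly increasing")

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def q(self) -> int:
        return len(self.alphabet)

    @property
    def gap_index(self) -> int | None:
        idx = self.alphabet.find("-")
        return idx if idx >= 0 else None

    def sequences(self) -> list[str]:
        """Decode the matrix back to strings."""
        lut = np.array(list(self.alphabet))
        return ["".join(row) for row in lut[self.matrix]]

    @classmethod
    def from_sequences(
        cls,
        sequence_ids: Sequence[str],
        sequences: Sequence[str],
        alphabet: str = PROTEIN_ALPHABET,
        species_labels: Sequence[str] | None = None,
        column_map: Sequence[int] | None = None,
    ) -> "MSA":
        """Build an MSA from raw strings, normalizing case and gap characters.

        Unknown residue codes (X, B, Z, U, O, J) and any character outside the
        alphabet are mapped to the gap state when the alphabet contains one,
        otherwise rejected.
        """
        if not sequences:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        gap_idx = alphabet.find("-")
        index = {c: i for i, c in enumerate(alphabet)}
        rows = np.empty((len(sequences), lengths.pop()), dtype=np.int64)
        for r, seq in enumerate(sequences):
            for c, ch in enumerate(seq.upper()):
                if ch in _GAP_CHARS:
                    ch = "-"
                code = index.get(ch)
                if code is None:
                    if gap_idx < 0:
                        raise AlignmentError(f"character {ch!r} outside alphabet and no gap state")
                    code = gap_idx
                rows[r, c] = code
        return cls(
            sequence_ids=list(sequence_ids),
            matrix=rows,
            alphabet=alphabet,
            species_labels=list(species_labels) if species_labels is not None else None,
            column_map=np.asarray(column_map) if column_map is not None else None,
        )


@dataclass
class LigandSet:
    """Fixed-length peptide ligands keyed by protein sequence id."""

    peptides: dict[str, list[str]]
    length: int

    def __post_init__(self) -> None:
        for sid, peps in self.peptides.items():
            if not peps:
                raise ValueError(f"sequence {sid!r} retained with zero ligands")
            for p in peps:
                if len(p) != self.length:
                    raise ValueError(f"ligand {p!r} for {sid!r} has length {len(p)} != {self.length}")

    @property
    def counts(self) -> dict[str, int]:
        """Ligand count ``N_a`` per sequence id."""
        return {sid: len(p) for sid, p in self.peptides.items()}


@dataclass
class SiteTable:
    """Per-alignment-column numeric annotations (stability, flags, ...)."""

    values: dict[str, dict[int, float]] = field(default_factory=dict)

    def add(self, name: str, column: int, value: float) -> None:
        col_values = self.values.setdefault(name, {})
        if column in col_values:
            raise ValueError(f"duplicate entry for column {column} in {name!r}")
        if column < 0:
            raise ValueError(f"negative column index {column}")
        col_values[column] = value

    def column_values(self, name: str, n_columns: int, default: float = math.nan) -> np.ndarray:
        out = np.full(n_columns, default, dtype=float)
        for col, val in self.values.get(name, {}).items():
            if col >= n_columns:
                raise ValueError(f"column {col} outside alignment of length {n_columns}")
            out[col] = val
        return out


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    alphabet: str = PROTEIN_ALPHABET,
    species_regex: str | None = None,
) -> MSA:
    """Read a FASTA or Stockholm alignment into an :class:`MSA`.

    Parameters
    ----------
    species_regex:
        Optional regex with one capture group applied to each identifier to
        extract a species label (identifier grammars vary between databases,
        so none is hard-coded).
    """
    fmt = format.lower()
    if fmt not in {"fasta", "stockholm"}:
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentError(f"could not parse {path}: {exc}") from exc
    ids = [rec.id for rec in aln]
    seqs = [str(rec.seq) for rec in aln]
    species = None
    if species_regex is not None:
        pattern = re.compile(species_regex)
        species = []
        for sid in ids:
            m = pattern.search(sid)
            species.append(m.group(1) if m else "")
    return MSA.from_sequences(ids, seqs, alphabet=alphabet, species_labels=species)


def assign_species(msa: MSA, mapping: Mapping[str, str]) -> MSA:
    """Attach species labels from a sidecar id->species mapping."""
    labels = [mapping.get(sid, "") for sid in msa.sequence_ids]
    return replace(msa, species_labels=labels)


def filter_gap_columns(msa: MSA, max_gap_fraction: float = 0.7) -> MSA:
    """Drop columns whose gap fraction strictly exceeds ``max_gap_fraction``.

    The surviving columns' original positions are recorded in ``column_map``:
    an existing map is subset, otherwise 1-based original column numbers are
    stored.
    """
    if not 0 < max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in (0, 1]")
    gap = msa.gap_index
    if gap is None:
        keep = np.ones(msa.n_columns, dtype=bool)
    else:
        gap_frac = (msa.matrix == gap).mean(axis=0)
        keep = gap_frac <= max_gap_fraction
    if not keep.any():
        raise AlignmentError("all columns removed by gap filtering")
    if msa.column_map is not None:
        new_map = msa.column_map[keep]
    else:
        new_map = np.flatnonzero(keep) + 1
    return replace(msa, matrix=msa.matrix[:, keep], column_map=new_map)


def subset_by_species(
    msa: MSA,
    include: Iterable[str] | None = None,
    exclude: Iterable[str] | None = None,
    max_per_species: int | None = None,
) -> MSA:
    """Filter rows by species label.

    Species whose row count exceeds ``max_per_species`` are dropped entirely
    (not down-sampled), matching the removal of over-represented clades.
    """
    if msa.species_labels is None:
        raise AlignmentError("species labels are required for species subsetting")
    include_set = set(include) if include is not None else None
    exclude_set = set(exclude) if exclude is not None else set()
    if include_set is not None and include_set & exclude_set:
        raise ValueError(f"species both included and excluded: {sorted(include_set & exclude_set)}")
    labels = np.asarray(msa.species_labels)
    keep = np.ones(msa.n_sequences, dtype=bool)
    if include_set is not None:
        keep &= np.isin(labels, sorted(include_set))
    if exclude_set:
        keep &= ~np.isin(labels, sorted(exclude_set))
    if max_per_species is not None:
        uniq, counts = np.unique(labels, return_counts=True)
        too_big = set(uniq[counts > max_per_species])
        if too_big:
            keep &= ~np.isin(labels, sorted(too_big))
    if not keep.any():
        raise AlignmentError("species subsetting removed every sequence")
    idx = np.flatnonzero(keep)
    return replace(
        msa,
        sequence_ids=[msa.sequence_ids[i] for i in idx],
        matrix=msa.matrix[idx],
        species_labels=[msa.species_labels[i] for i in idx],
    )


def retained_count(n: int, top_fraction: float) -> int:
    """Number of ligands kept per sequence: ``max(1, floor(f * n))``."""
    return max(1, math.floor(top_fraction * n))


def read_ligands(
    path: str | Path,
    format: str = "csv",
    length: int = 9,
    top_fraction: float | None = None,
    higher_is_better: bool = True,
) -> LigandSet:
    """Read a peptide-ligand table.

    Formats
    -------
    ``csv``
        Rows ``sequence_id,peptide[,score]``; a header row is detected and
        skipped.  Peptides whose length differs from ``length`` are dropped.
    ``scored``
        Same layout with the score column mandatory; required when
        ``top_fraction`` is given.

    With ``top_fraction`` the best-scoring ``max(1, floor(f*n))`` peptides are
    kept per sequence; ties at the cutoff are broken by peptide lexicographic
    order.
    """
    fmt = format.lower()
    if fmt not in {"csv", "scored"}:
        raise ValueError(f"unsupported ligand table format {format!r}")
    records: dict[str, list[tuple[str, float]]] = {}
    with open(path, newline="") as handle:
        reader = csv.reader(handle)
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            sid, pep = row[0].strip(), row[1].strip().upper()
            if sid.lower() in {"sequence_id", "id", "allele"}:
                continue
            score = float(row[2]) if len(row) > 2 and row[2].strip() else math.nan
            if len(pep) != length:
                continue
            records.setdefault(sid, []).append((pep, score))
    if top_fraction is not None:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        for sid, peps in records.items():
            if any(math.isnan(s) for _, s in peps):
                raise ValueError(f"top_fraction selection requires scores (sequence {sid!r})")
            sign = -1.0 if higher_is_better else 1.0
            peps.sort(key=lambda ps: (sign * ps[1], ps[0]))
            del peps[retained_count(len(peps), top_fraction):]
    peptides = {sid: [p for p, _ in peps] for sid, peps in records.items() if peps}
    if not peptides:
        raise ValueError(f"no ligands of length {length} found in {path}")
    return LigandSet(peptides=peptides, length=length)


def read_site_annotations(
    path: str | Path,
    kind: str = "column",
    name: str = "value",
    column_map: np.ndarray | None = None,
) -> SiteTable:
    """Read whitespace/TSV ``(index, value)`` records into a :class:`SiteTable`.

    ``kind='column'`` interprets indices as 0-based alignment columns;
    ``kind='residue'`` maps 1-based structure residue numbers through the
    inverse of ``column_map``.  Lines starting with ``#`` are skipped.
    """
    if kind not in {"column", "residue"}:
        raise ValueError(f"unsupported annotation kind {kind!r}")
    inverse: dict[int, int] | None = None
    if kind == "residue":
        if column_map is None:
            raise ValueError("residue-numbered annotations require a column_map")
        inverse = {int(res): col for col, res in enumerate(column_map)}
    table = SiteTable()
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[\s,;]+", line)
            idx = int(parts[0])
            value = float(parts[1]) if len(parts) > 1 and parts[1] else math.nan
            if inverse is not None:
                if idx not in inverse:
                    raise ValueError(f"residue number {idx} not present in column_map")
                idx = inverse[idx]
            table.add(name, idx, value)
    return table


def read_allele_frequencies(
    path: str | Path,
    min_frequency: float = 1e-5,
) -> dict[str, float]:
    """Read an ``allele,frequency`` table, keeping alleles above the floor.

    The default floor matches the convention of retaining alleles whose
    population frequency exceeds 0.00001.
    """
    freqs: dict[str, float] = {}
    with open(path, newline="") as handle:
        for row in csv.reader(handle):
            if not row or row[0].startswith("#"):
                continue
            allele = row[0].strip()
            if allele.lower() in {"allele", "id"}:
                continue
            f = float(row[1])
            if f < 0:
                raise ValueError(f"negative frequency for allele {allele!r}")
            if f > min_frequency:
                freqs[allele] = f
    return freqs


def write_pair_table(
    path: str | Path,
    pairs: Iterable[tuple[int, int, float]],
    column_map: np.ndarray | None = None,
    header_comment: str = "",
    protein_len: int | None = None,
) -> None:
    """Write a ranked pair table as TSV with a '#'-prefixed header.

    Columns are reported 1-based; when ``column_map`` exists, protein columns
    are translated to structure numbering.  Ligand-block columns (index >=
    ``protein_len``) are labeled ``P1..PK``.
    """

    def label(col: int) -> str:
        if protein_len is not None and col >= protein_len:
            return f"P{col - protein_len + 1}"
        if column_map is not None:
            return str(int(column_map[col]))
        return str(col + 1)

    with open(path, "w") as out:
        if header_comment:
            out.write(f"# {header_comment}\n")
        out.write("# i\tj\tscore\n")
        for i, j, score in pairs:
            out.write(f"{label(i)}\t{label(j)}\t{score:.10g}\n")
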