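"""Per-site scores: pair-score collapsing and entropy-based conservation.

Score direction caveat
----------------------
The per-column score computed here, ``1 + sum_A f log f / log 20`` over
non-gap frequencies, is a *conservation* measure: 1 for a perfectly
conserved column, 0 for a uniform 20-state column.  Downstream conventions
that call the below-threshold set "non-polymorphic" are nevertheless
supported as the default labeling rule (see :func:`classify_polymorphic`);
every output column of this module is named ``conservation_score`` to keep
the direction unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from pepdca.alignment_io import MSA
from pepdca.dca_core import RankedPairs

#: number of amino-acid states used to normalize the entropy (gaps excluded).
N_AMINO_ACIDS = 20


def pair_to_site_scores(ranked_pairs: RankedPairs, n_sites: int) -> np.ndarray:
    """Collapse a ranked pair list to per-site scores.

    Walking the list from the top, each site receives the score of the first
    (i.e. highest-scoring) pair that contains it; sites appearing in no pair
    keep score 0.  Because the list is sorted descending this equals the
    per-site maximum over all qualifying pairs.
    """
    scores = np.zeros(n_sites)
    assigned = np.zeros(n_sites, dtype=bool)
    for i, j, score in ranked_pairs:
        if not assigned[i]:
            scores[i] = score
            assigned[i] = True
        if not assigned[j]:
            scores[j] = score
            assigned[j] = True
    return scores


def conservation_scores(
    msa: MSA,
    sequence_weights: Mapping[str, float] | np.ndarray | None = None,
) -> np.ndarray:
    """Per-column conservation: one minus the normalized Shannon entropy.

    Gaps are omitted: non-gap frequencies are renormalized per column before
    the entropy is taken (natural log, normalized by ``log 20``).  With
    ``sequence_weights`` (e.g. allele population frequencies keyed by
    sequence id) counts are frequency-weighted.  All-gap columns are returned
    as NaN.
    """
    if sequence_weights is None:
        w = np.ones(msa.n_sequences)
    elif isinstance(sequence_weights, Mapping):
        w = np.array([float(sequence_weights.get(sid, 0.0)) for sid in msa.sequence_ids])
    else:
        w = np.asarray(sequence_weights, dtype=float)
        if w.shape != (msa.n_sequences,):
            raise ValueError("sequence_weights length must match the number of sequences")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("sequence weights must be non-negative with positive total")

    gap = msa.gap_index
    L, q = msa.n_columns, msa.q
    out = np.empty(L)
    for i in range(L):
        col = msa.matrix[:, i]
        counts = np.bincount(col, weights=w, minlength=q)
        if gap is not None:
            counts[gap] = 0.0
        total = counts.sum()
        if total == 0:
            out[i] = np.nan
            continue
        f = counts[counts > 0] / total
        out[i] = 1.0 + float(np.sum(f * np.log(f))) / np.log(N_AMINO_ACIDS)
    return out


# the spec of this pipeline historically calls the same quantity a
# "polymorphism score"; keep an explicit alias rather than a second code path.
polymorphism_scores = conservation_scores


@dataclass
class SiteLabels:
    """Binary site labels from thresholding a conservation-direction score.

    ``below_threshold`` marks sites with ``score < threshold``.  Two naming
    senses exist for this same set:

    * the quoted pipeline convention calls below-threshold sites
      "non-polymorphic" — this is the default hit set used by the enrichment
      stage (``non_polymorphic``);
    * read literally against the score direction (1 = conserved), the
      below-threshold set is the *least conserved* one (``low_conservation``).

    Both attributes are exposed so either sense can be fed downstream
    explicitly.
    """

    below_threshold: np.ndarray
    threshold: float
    defined: np.ndarray

    @property
    def non_polymorphic(self) -> np.ndarray:
        """Below-threshold set under the quoted pipeline convention."""
        return self.below_threshold

    @property
    def low_conservation(self) -> np.ndarray:
        """Below-threshold set read against the score's own direction."""
        return self.below_threshold

    @property
    def high_conservation(self) -> np.ndarray:
        return self.defined & ~self.below_threshold


def classify_polymorphic(scores: np.ndarray, threshold: float = 0.01) -> SiteLabels:
    """Threshold conservation-direction scores into binary site labels.

    Supported preset thresholds are 0.01 (default), 0.02 and 0.03.  Undefined
    (NaN) columns are excluded from both label sets with a warning.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    defined = ~np.isnan(scores)
    if not defined.all():
        warnings.warn(
            f"{int((~defined).sum())} undefined (all-gap) columns excluded from labeling",
            RuntimeWarning,
            stacklevel=2,
        )
    below = np.zeros(scores.shape, dtype=bool)
    below[defined] = scores[defined] < threshold
    return SiteLabels(below_threshold=below, threshold=threshold, defined=defined)
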