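"""Per-locus variability statistics and the p-distance barcode-gap analysis.

For each marker we report the counts a reader uses to judge its resolution —
unique sequences, distinct site patterns, parsimony-informative sites — and
the distribution of uncorrected pairwise distances (p-distances) partitioned
into within-clade and between-clade comparisons under a clade hypothesis.
A marker with a "barcode gap" has its within-clade range strictly below its
between-clade range; overlap means single-marker identification is unsafe.

Conventions (they matter for matching published counts):

* p-distances use pairwise deletion — a site enters a pair's comparison only
  when both rows carry an unambiguous base (gap, ``?`` and IUPAC ambiguity
  codes are treated as missing).
* site patterns distinguish every symbol, gaps and missing included;
* parsimony-informative sites count only unambiguous bases as states — a
  column is informative when at least two states each occur in two or more
  taxa.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .seqio import Alignment

logger = logging.getLogger(__name__)

#: strain → clade label
CladeHypothesis = Mapping[str, str]


@dataclass(frozen=True)
class LocusStats:
    """Row of the marker-variability table for one locus."""

    n_sequences: int
    n_unique_sequences: int
    aligned_bp: int
    n_patterns: int
    n_parsimony_informative: int


@dataclass
class DistanceMatrix:
    """Labeled symmetric matrix of pairwise distances.

    Undefined entries (pairs with no comparable site) are stored as NaN and
    excluded from every summary.  ``comparable_sites[i, j]`` is the number of
    sites the pair (i, j) was compared over.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        with np.errstate(invalid="ignore"):
            if not np.allclose(v, v.T, equal_nan=True):
                raise ValidationError("distance matrix is not symmetric")
            if np.nanmin(v) < 0:
                raise ValidationError("negative distances")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def has_undefined(self) -> bool:
        m = ~np.eye(self.n, dtype=bool)
        return bool(np.isnan(self.values[m]).any())


@dataclass(frozen=True)
class BarcodeGapSummary:
    """Within/between-clade p-distance summary for one locus."""

    within_mean: float
    within_min: float
    within_max: float
    within_n: int
    between_mean: float
    between_min: float
    between_max: float
    between_n: int
    overlap: bool


# Column-wise counts --------------------------------------------------------


def count_unique_sequences(aln: Alignment) -> int:
    """Number of distinct full rows (gaps and ``?`` significant)."""
    return len(set(aln.rows))


def count_alignment_patterns(aln: Alignment) -> int:
    """Number of distinct site patterns (columns as tuples over taxa)."""
    arr = aln.to_char_array()
    cols = np.ascontiguousarray(arr.T).view(
        np.dtype((np.void, arr.dtype.itemsize * aln.n_taxa))
    )
    return len(np.unique(cols))


def count_parsimony_informative_sites(aln: Alignment) -> int:
    """Columns with >=2 unambiguous states (A/C/G/T) each in >=2 taxa."""
    codes = aln.to_codes()
    n_informative = 0
    for j in range(aln.length):
        col = codes[:, j]
        counts = np.bincount(col[col < 4], minlength=4)
        if int((counts >= 2).sum()) >= 2:
            n_informative += 1
    return n_informative


def locus_stats(aln: Alignment) -> LocusStats:
    return LocusStats(
        n_sequences=aln.n_taxa,
        n_unique_sequences=count_unique_sequences(aln),
        aligned_bp=aln.length,
        n_patterns=count_alignment_patterns(aln),
        n_parsimony_informative=count_parsimony_informative_sites(aln),
    )


# p-distances ---------------------------------------------------------------


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Uncorrected p-distances with pairwise deletion.

    For each pair, comparable sites are the positions where both rows hold an
    unambiguous base; the distance is mismatches / comparable sites.  A pair
    with zero comparable sites gets NaN.
    """
    if aln.n_taxa < 2:
        raise ValidationError("p-distance needs at least 2 taxa")
    codes = aln.to_codes()
    base = codes < 4
    n = aln.n_taxa
    values = np.zeros((n, n))
    comparable = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = base[i] & base[i + 1 :]
        diff = (codes[i] != codes[i + 1 :]) & both
        nc = both.sum(axis=1)
        nd = diff.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(nc > 0, nd / np.maximum(nc, 1), np.nan)
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
        comparable[i, i + 1 :] = nc
        comparable[i + 1 :, i] = nc
    return DistanceMatrix(aln.taxa, values, comparable)


def barcode_gap_summary(
    dm: DistanceMatrix, hypothesis: CladeHypothesis
) -> BarcodeGapSummary:
    """Partition defined pairwise distances into within/between clade sets.

    Labels missing from the hypothesis are excluded with a logged warning; a
    single-member clade simply contributes no within pairs.  ``overlap`` is
    the closed-interval test ``within_max >= between_min``.
    """
    mapped = [t for t in dm.labels if t in hypothesis]
    dropped = [t for t in dm.labels if t not in hypothesis]
    if dropped:
        logger.warning("excluding %d unmapped taxa from barcode-gap summary", len(dropped))
    clades = {hypothesis[t] for t in mapped}
    if len(clades) < 2:
        raise ValidationError("barcode-gap summary needs at least 2 clades")
    within: list[float] = []
    between: list[float] = []
    idx = {t: i for i, t in enumerate(dm.labels)}
    for a, b in combinations(mapped, 2):
        d = dm.values[idx[a], idx[b]]
        if np.isnan(d):
            continue
        (within if hypothesis[a] == hypothesis[b] else between).append(float(d))
    if not between:
        raise ValidationError("no defined between-clade pairs")
    w = np.array(within) if within else np.array([np.nan])
    b = np.array(between)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return BarcodeGapSummary(
            within_mean=float(np.mean(w)),
            within_min=float(np.min(w)),
            within_max=float(np.max(w)),
            within_n=len(within),
            between_mean=float(np.mean(b)),
            between_min=float(np.min(b)),
            between_max=float(np.max(b)),
            between_n=len(between),
            overlap=bool(within and np.max(w) >= np.min(b)),
        )
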