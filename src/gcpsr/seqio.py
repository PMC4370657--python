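"""Alignment I/O and column bookkeeping for multi-locus data sets.

The central container is :class:`Alignment` — a rectangular block of DNA
characters over ``A C G T``, IUPAC ambiguity codes, the gap symbol ``-`` and
the missing-data symbol ``?``.  A :class:`LocusSet` holds one alignment per
locus; a taxon may be absent from some loci (e.g. a marker that failed to
sequence for part of the strains).  ``concatenate`` builds the supermatrix,
padding absent taxa with ``?`` runs, and ``trim_missing_columns`` removes
every column touched by ``?`` — the preprocessing required before haplotype
collapsing, where gaps are data but missing characters are not.

Coordinates are 0-based half-open throughout; the RAxML-style partition file
written by :func:`write_partitions` converts to the conventional 1-based
inclusive ranges on the way out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, FormatError, ValidationError

# Alphabet ------------------------------------------------------------------

UNAMBIGUOUS = "ACGT"
GAP = "-"
MISSING = "?"
IUPAC_AMBIGUOUS = "RYSWKMBDHVN"
ALPHABET = frozenset(UNAMBIGUOUS + IUPAC_AMBIGUOUS + GAP + MISSING)

#: integer codes used by the vectorised distance kernels:
#: A=0 C=1 G=2 T=3, gap=4, everything unresolvable (?, ambiguity)=5
CODE_GAP = 4
CODE_MISSING = 5
_CODE_TABLE = np.full(256, CODE_MISSING, dtype=np.uint8)
for _i, _b in enumerate(UNAMBIGUOUS):
    _CODE_TABLE[ord(_b)] = _i
_CODE_TABLE[ord(GAP)] = CODE_GAP


class Partition(NamedTuple):
    """Half-open column interval [start, end) belonging to one locus."""

    name: str
    start: int
    end: int


@dataclass(frozen=True)
class Alignment:
    """An immutable multiple sequence alignment.

    Parameters
    ----------
    taxa:
        Unique, non-empty strain identifiers, in file order.
    rows:
        One equal-length character string per taxon.
    partitions:
        Optional per-locus column intervals; must tile ``[0, length)``.
    """

    taxa: tuple[str, ...]
    rows: tuple[str, ...]
    partitions: tuple[Partition, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "rows", tuple(self.rows))
        if self.partitions is not None:
            object.__setattr__(
                self, "partitions", tuple(Partition(*p) for p in self.partitions)
            )
        if len(self.taxa) != len(self.rows):
            raise ValidationError("taxa and rows differ in count")
        if not self.taxa:
            raise ValidationError("alignment has no taxa")
        if any(not t for t in self.taxa):
            raise ValidationError("empty taxon identifier")
        if len(set(self.taxa)) != len(self.taxa):
            dup = next(t for t in self.taxa if self.taxa.count(t) > 1)
            raise ValidationError(f"duplicate taxon {dup!r}")
        length = len(self.rows[0])
        if length < 1:
            raise ValidationError("alignment length must be >= 1")
        for t, r in zip(self.taxa, self.rows):
            if len(r) != length:
                raise AlignmentError(f"ragged alignment at {t}")
            bad = set(r) - ALPHABET
            if bad:
                raise ValidationError(
                    f"row {t!r} contains unsupported symbols {sorted(bad)!r}"
                )
        if self.partitions is not None:
            pos = 0
            for p in self.partitions:
                if p.start != pos or p.end <= p.start:
                    raise ValidationError(
                        f"partitions must be ordered, non-overlapping and tile "
                        f"[0, {length}); got {p}"
                    )
                pos = p.end
            if pos != length:
                raise ValidationError(
                    f"partitions cover [0, {pos}) but alignment length is {length}"
                )

    # -- basic accessors ----------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(taxon) from None

    def to_char_array(self) -> np.ndarray:
        """(n_taxa, length) array of single-byte characters."""
        flat = "".join(self.rows).encode("ascii")
        return np.frombuffer(flat, dtype="S1").reshape(self.n_taxa, self.length)

    def to_codes(self) -> np.ndarray:
        """(n_taxa, length) uint8 codes: ACGT→0..3, '-'→4, other→5."""
        flat = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
        return _CODE_TABLE[flat].reshape(self.n_taxa, self.length)

    def select_columns(self, columns: Sequence[int] | np.ndarray) -> "Alignment":
        """New alignment restricted to ``columns`` (order preserved; partitions dropped)."""
        cols = np.asarray(columns, dtype=np.intp)
        arr = self.to_char_array()[:, cols]
        rows = tuple(arr[i].tobytes().decode("ascii") for i in range(self.n_taxa))
        return Alignment(self.taxa, rows, None)

    def subset_taxa(self, taxa: Iterable[str]) -> "Alignment":
        keep = tuple(taxa)
        return Alignment(keep, tuple(self.row(t) for t in keep), self.partitions)


@dataclass
class LocusSet:
    """Per-locus alignments keyed by locus name, in analysis order."""

    loci: dict[str, Alignment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValidationError("LocusSet needs at least one locus")

    @property
    def master_taxa(self) -> tuple[str, ...]:
        """Union of taxa over loci, ordered by first appearance."""
        seen: dict[str, None] = {}
        for aln in self.loci.values():
            for t in aln.taxa:
                seen.setdefault(t)
        return tuple(seen)

    def locus_names(self) -> tuple[str, ...]:
        return tuple(self.loci)


# Reading / writing ---------------------------------------------------------


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read one aligned FASTA file into an :class:`Alignment`.

    Rows are upper-cased and ``U`` is mapped to ``T``; record order is
    preserved.  Ragged rows, duplicate headers and empty files raise.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    taxa: list[str] = []
    rows: list[str] = []
    for rec in records:
        if rec.id in taxa:
            raise ValidationError(f"duplicate header {rec.id!r} in {path}")
        taxa.append(rec.id)
        rows.append(_normalize(str(rec.seq)))
    length = len(rows[0])
    for t, r in zip(taxa, rows):
        if len(r) != length:
            raise AlignmentError(f"ragged alignment at {t}")
    return Alignment(tuple(taxa), tuple(rows))


def write_fasta(aln: Alignment, path: str | Path, wrap: int = 80) -> None:
    """Write FASTA, wrapping sequence lines at ``wrap`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f">{t}\n")
            for i in range(0, len(r), wrap):
                fh.write(r[i : i + wrap] + "\n")


def write_phylip(aln: Alignment, path: str | Path) -> None:
    """Relaxed PHYLIP: header ``n_taxa n_cols``, full names, single space."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{aln.n_taxa} {aln.length}\n")
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f"{t} {r}\n")


def write_partitions(aln: Alignment, path: str | Path) -> None:
    """RAxML-style partition file, 1-based inclusive ranges."""
    if not aln.partitions:
        raise ValidationError("alignment has no partitions to write")
    with Path(path).open("w") as fh:
        for p in aln.partitions:
            fh.write(f"DNA, {p.name} = {p.start + 1}-{p.end}\n")


def read_partitions(path: str | Path) -> tuple[Partition, ...]:
    """Parse a RAxML-style partition file back to 0-based half-open intervals."""
    parts: list[Partition] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        try:
            _, rest = line.split(",", 1)
            name, span = rest.split("=")
            lo, hi = span.strip().split("-")
            parts.append(Partition(name.strip(), int(lo) - 1, int(hi)))
        except ValueError as exc:
            raise FormatError(f"bad partition line {line!r}") from exc
    return tuple(parts)


# Concatenation and trimming ------------------------------------------------


def concatenate(
    locus_set: LocusSet, taxon_order: Sequence[str] | None = None
) -> Alignment:
    """Build the supermatrix over ``taxon_order`` (default: master taxa).

    A taxon missing from a locus receives a run of ``?`` spanning that locus;
    partitions record each locus's column interval in input order.
    """
    order = tuple(taxon_order) if taxon_order is not None else locus_set.master_taxa
    order_set = set(order)
    for name, aln in locus_set.loci.items():
        stray = set(aln.taxa) - order_set
        if stray:
            raise ValidationError(
                f"taxa {sorted(stray)} of locus {name!r} not in taxon_order"
            )
    parts: list[Partition] = []
    chunks: dict[str, list[str]] = {t: [] for t in order}
    pos = 0
    for name, aln in locus_set.loci.items():
        for t in order:
            try:
                chunks[t].append(aln.row(t))
            except KeyError:
                chunks[t].append(MISSING * aln.length)
        parts.append(Partition(name, pos, pos + aln.length))
        pos += aln.length
    rows = tuple("".join(chunks[t]) for t in order)
    return Alignment(order, rows, tuple(parts))


class TrimResult(NamedTuple):
    """Outcome of ``trim_missing_columns``.

    ``empty`` flags the degenerate all-columns-removed case (the alignment
    then retains a single placeholder decision upstream must handle); it is
    metadata, not an exception.
    """

    alignment: "Alignment | None"
    kept_columns: tuple[int, ...]
    n_removed: int
    empty: bool


def trim_missing_columns(aln: Alignment) -> TrimResult:
    """Remove every column containing ``?`` in any row.

    Partition intervals are remapped onto the surviving columns; column order
    is preserved.  If no column survives, ``alignment`` is None and ``empty``
    is set.
    """
    arr = aln.to_char_array()
    keep_mask = ~(arr == MISSING.encode()).any(axis=0)
    kept = tuple(int(i) for i in np.nonzero(keep_mask)[0])
    n_removed = aln.length - len(kept)
    if not kept:
        return TrimResult(None, (), n_removed, True)
    trimmed = aln.select_columns(kept)
    new_parts: list[Partition] | None = None
    if aln.partitions is not None:
        new_parts = []
        cum = np.cumsum(keep_mask)  # survivors up to and including column i
        pos = 0
        for p in aln.partitions:
            width = int(cum[p.end - 1] - (cum[p.start - 1] if p.start else 0))
            if width > 0:
                new_parts.append(Partition(p.name, pos, pos + width))
                pos += width
        trimmed = replace(trimmed, partitions=tuple(new_parts) or None)
    return TrimResult(trimmed, kept, n_removed, False)
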