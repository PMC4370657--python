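"""Haplotype collapsing with the gap as a fifth character state.

Strains with byte-identical rows share a haplotype; a gap is a distinguishing
state, so ``ACT`` and ``A-T`` are different haplotypes.  The input must be
free of ``?`` — trim missing-data columns first (see
:func:`gcpsr.seqio.trim_missing_columns`), because a missing character would
otherwise silently split haplotypes.  Downstream summaries count singleton
haplotypes, cross-tabulate haplotypes against a clade hypothesis (a
haplotype spanning clades contradicts the hypothesis and is flagged), and
against strain geography.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import ValidationError
from .metrics import CladeHypothesis
from .seqio import MISSING, Alignment


@dataclass(frozen=True)
class Haplotype:
    haplotype_id: int
    members: tuple[str, ...]
    sequence: str

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HaplotypeTable:
    haplotypes: tuple[Haplotype, ...]
    n_sites: int
    n_variable_sites: int

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_singletons(self) -> int:
        return sum(1 for h in self.haplotypes if h.size == 1)

    def member_to_haplotype(self) -> dict[str, int]:
        return {m: h.haplotype_id for h in self.haplotypes for m in h.members}


@dataclass(frozen=True)
class GeographyTable:
    """Per-haplotype counts by region, with exclusivity calls."""

    counts: pd.DataFrame  # index: haplotype_id, columns: regions
    exclusive_region: dict[int, str | None] = field(default_factory=dict)


def collapse_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Group strains by exact row identity (gap = fifth state).

    Haplotype ids are numbered by first occurrence in input order.  Variable
    sites are columns with at least two distinct symbols.
    """
    if any(MISSING in r for r in aln.rows):
        raise ValidationError(
            "alignment contains '?'; run trim_missing_columns before collapsing"
        )
    groups: dict[str, list[str]] = {}
    for taxon, row in zip(aln.taxa, aln.rows):
        groups.setdefault(row, []).append(taxon)
    haps = tuple(
        Haplotype(i + 1, tuple(members), seq)
        for i, (seq, members) in enumerate(groups.items())
    )
    n_variable = sum(
        1 for j in range(aln.length) if len({r[j] for r in aln.rows}) > 1
    )
    return HaplotypeTable(haps, aln.length, n_variable)


def singleton_count(table: HaplotypeTable) -> int:
    return table.n_singletons


@dataclass(frozen=True)
class CladeHaplotypeCounts:
    counts: dict[str, int]
    spanning: tuple[int, ...]  # haplotype ids whose members cross clades


def haplotype_by_clade(
    table: HaplotypeTable, hypothesis: CladeHypothesis
) -> CladeHaplotypeCounts:
    """Distinct haplotypes intersecting each clade, flagging cross-clade ones."""
    unmapped = {
        m for h in table.haplotypes for m in h.members if m not in hypothesis
    }
    if unmapped:
        raise ValidationError(f"strains not in clade hypothesis: {sorted(unmapped)}")
    counts: dict[str, set[int]] = {}
    spanning: list[int] = []
    for h in table.haplotypes:
        clades = {hypothesis[m] for m in h.members}
        if len(clades) > 1:
            spanning.append(h.haplotype_id)
        for c in clades:
            counts.setdefault(c, set()).add(h.haplotype_id)
    return CladeHaplotypeCounts(
        {c: len(ids) for c, ids in counts.items()}, tuple(spanning)
    )


def haplotype_geography(
    table: HaplotypeTable, metadata: Mapping[str, str]
) -> GeographyTable:
    """Cross-tabulate haplotypes against strain regions.

    Strains absent from the metadata fall into an ``unknown`` bucket.  A
    haplotype whose members all share one (known) region is called exclusive
    to it.
    """
    records = [
        (h.haplotype_id, metadata.get(m, "unknown"))
        for h in table.haplotypes
        for m in h.members
    ]
    df = pd.DataFrame(records, columns=["haplotype_id", "region"])
    counts = (
        df.groupby(["haplotype_id", "region"]).size().unstack(fill_value=0)
    )
    exclusive: dict[int, str | None] = {}
    for h in table.haplotypes:
        regions = {metadata.get(m, "unknown") for m in h.members}
        exclusive[h.haplotype_id] = (
            next(iter(regions)) if len(regions) == 1 and "unknown" not in regions else None
        )
    return GeographyTable(counts, exclusive)
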