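"""Sex-chromosome assignment by modal alignment of marker tags.

Sex-linked tag sequences are mapped to a reference genome (either with
the built-in exact-seed ungapped mapper, or with externally produced
BLAST tabular hits), markers whose hits all fall on a single chromosome
are kept, and the chromosome attracting the most uniquely assigned
markers — the modal chromosome — is called as the sex chromosome.  A
reference-to-species chromosome correspondence map translates the call
into the study species' karyotype.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

import pandas as pd

from .model import AlignmentHit, DEFAULT_CHROM_MAP, Reference, natural_key

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def percent_1dp(count: int, total: int) -> float:
    """Exact percentage rounded half-up to one decimal (93.35 -> 93.4)."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = (Decimal(count) * 100) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# built-in mapper
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MapperParams:
    """Parameters of the exact-seed ungapped tag mapper.

    ``seed_k``: exact-match seed length in bp; ``min_identity``: minimum
    fraction of matching bases over the alignment; ``min_aln_length``:
    minimum alignable tag span in bp.
    """

    seed_k: int = 21
    min_identity: float = 0.90
    min_aln_length: int = 50

    def __post_init__(self) -> None:
        if not (1 <= self.seed_k <= self.min_aln_length):
            raise ValueError("require 1 <= seed_k <= min_aln_length")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")


def _index_reference(reference: Reference, k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for chrom in reference.chrom_ids:
        seq = reference.sequences[chrom]
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].append((chrom, i))
    return index


def map_tags(
    tags: Mapping[str, str],
    reference: Reference,
    params: MapperParams | None = None,
) -> list[AlignmentHit]:
    """Map tag sequences to a reference with exact k-mer seeding.

    Every seed match is extended without gaps over the full tag (clipped
    at chromosome ends); a hit is reported when identity >= min_identity
    over an alignment of >= min_aln_length bp.  Both strands are
    searched and all qualifying hits at all positions are returned, in
    deterministic (query, chromosome, start, strand) order.  Tags
    shorter than the seed length are skipped with a logged reason.
    """
    params = params or MapperParams()
    k = params.seed_k
    index = _index_reference(reference, k)
    hits: list[AlignmentHit] = []
    for query_id in sorted(tags, key=natural_key):
        tag = tags[query_id].upper()
        if len(tag) < k:
            logger.info("tag %s shorter than seed_k=%d, left unaligned",
                        query_id, k)
            continue
        for strand, q in (("+", tag), ("-", revcomp(tag))):
            candidates: set[tuple[str, int]] = set()
            for off in range(len(q) - k + 1):
                for chrom, pos in index.get(q[off : off + k], ()):
                    candidates.add((chrom, pos - off))
            for chrom, s0 in sorted(candidates, key=lambda c: (natural_key(c[0]), c[1])):
                seq = reference.sequences[chrom]
                a = max(s0, 0)
                b = min(s0 + len(q), len(seq))
                aln_len = b - a
                if aln_len < params.min_aln_length:
                    continue
                matches = sum(
                    1 for i in range(a, b) if q[i - s0] == seq[i]
                )
                identity = matches / aln_len
                if identity < params.min_identity:
                    continue
                hits.append(AlignmentHit(
                    query_id=query_id, chrom=chrom, start=a + 1, end=b,
                    strand=strand, identity=identity, aln_length=aln_len,
                ))
    hits.sort(key=lambda h: (natural_key(h.query_id), natural_key(h.chrom),
                             h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# unique-chromosome filtering and summary
# ---------------------------------------------------------------------------

@dataclass
class ChromAssignments:
    """Partition of loci into uniquely assigned / multi-chromosome / unaligned."""

    assigned: dict[str, str]
    multi_chrom: set[str]
    unaligned: set[str]


def unique_chromosome_assignments(
    hits: Iterable[AlignmentHit],
    locus_ids: Iterable[str] | None = None,
) -> ChromAssignments:
    """Assign each locus to a chromosome iff all its hits fall on one.

    Multiple hit positions on a single chromosome still count as
    assigned; hits on two or more chromosomes send the locus to the
    multi-chromosome set.  ``locus_ids``, when given, supplies the full
    locus universe so that loci without any hit populate the unaligned
    set.
    """
    chroms_by_locus: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        chroms_by_locus[h.query_id].add(h.chrom)
    assigned: dict[str, str] = {}
    multi: set[str] = set()
    for locus, chroms in chroms_by_locus.items():
        if len(chroms) == 1:
            assigned[locus] = next(iter(chroms))
        else:
            multi.add(locus)
    unaligned: set[str] = set()
    if locus_ids is not None:
        unaligned = {l for l in locus_ids if l not in chroms_by_locus}
    return ChromAssignments(assigned=assigned, multi_chrom=multi,
                            unaligned=unaligned)


@dataclass
class AssignmentSummary:
    """Per-chromosome counts of uniquely assigned sex-linked markers."""

    per_chrom_counts: dict[str, int]
    n_assigned: int
    n_multi_chrom: int = 0
    n_unaligned: int = 0
    modal_chrom: Optional[str] = None
    modal_fraction: Optional[float] = None
    modal_tie: bool = False

    @property
    def modal_percent_1dp(self) -> Optional[float]:
        """Modal fraction as a percentage, half-up rounded to 1 decimal."""
        if self.modal_chrom is None:
            return None
        return percent_1dp(self.per_chrom_counts[self.modal_chrom],
                           self.n_assigned)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"chromosome": c, "n_markers": n}
                for c, n in sorted(self.per_chrom_counts.items(),
                                   key=lambda kv: natural_key(kv[0]))]
        return pd.DataFrame(rows, columns=["chromosome", "n_markers"])


def assignment_summary(
    assignments: ChromAssignments | Mapping[str, str],
) -> AssignmentSummary:
    """Summarise unique assignments: counts, modal chromosome, fraction.

    A tie for the mode is broken toward the smaller chromosome id
    (numeric-aware ordering) and flagged; with zero assigned markers the
    modal fields stay undefined.
    """
    if isinstance(assignments, ChromAssignments):
        assigned = assignments.assigned
        n_multi = len(assignments.multi_chrom)
        n_unaligned = len(assignments.unaligned)
    else:
        assigned = dict(assignments)
        n_multi = n_unaligned = 0
    counts = Counter(assigned.values())
    n_assigned = sum(counts.values())
    if n_assigned == 0:
        logger.warning("no uniquely assigned markers; modal chromosome undefined")
        return AssignmentSummary(per_chrom_counts={}, n_assigned=0,
                                 n_multi_chrom=n_multi, n_unaligned=n_unaligned)
    best = max(counts.values())
    top = sorted((c for c, n in counts.items() if n == best), key=natural_key)
    modal = top[0]
    tie = len(top) > 1
    if tie:
        logger.warning("modal chromosome tie among %s; choosing %s", top, modal)
    return AssignmentSummary(
        per_chrom_counts=dict(counts),
        n_assigned=n_assigned,
        n_multi_chrom=n_multi,
        n_unaligned=n_unaligned,
        modal_chrom=modal,
        modal_fraction=counts[modal] / n_assigned,
        modal_tie=tie,
    )


# ---------------------------------------------------------------------------
# the sex-chromosome call
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SexChromosomeCall:
    reference_chrom: str
    species_chrom: str
    modal_fraction: float
    n_assigned: int
    confident: bool


def _map_chrom(chrom: str, chrom_map: Mapping[str, str]) -> str:
    if chrom in chrom_map:
        return chrom_map[chrom]
    stripped = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if stripped in chrom_map:
        return chrom_map[stripped]
    logger.info("chromosome %s absent from correspondence map; "
                "identity mapping used", chrom)
    return chrom


def call_sex_chromosome(
    summary: AssignmentSummary,
    chrom_map: Mapping[str, str] | None = None,
    min_fraction: float = 0.5,
    min_markers: int = 3,
) -> SexChromosomeCall:
    """Call the sex chromosome from the modal chromosome of the summary.

    The reference chromosome is translated to the study species'
    karyotype through ``chrom_map`` (default: reference 9 -> species 7,
    4 -> 3, 13 -> 13; identity for unmapped chromosomes).  The call is
    confident when the modal fraction reaches ``min_fraction`` and the
    modal count reaches ``min_markers``.
    """
    if summary.modal_chrom is None:
        raise ValueError("assignment summary has no modal chromosome")
    chrom_map = DEFAULT_CHROM_MAP if chrom_map is None else chrom_map
    modal_count = summary.per_chrom_counts[summary.modal_chrom]
    confident = (summary.modal_fraction >= min_fraction
                 and modal_count >= min_markers)
    return SexChromosomeCall(
        reference_chrom=summary.modal_chrom,
        species_chrom=_map_chrom(summary.modal_chrom, chrom_map),
        modal_fraction=summary.modal_fraction,
        n_assigned=summary.n_assigned,
        confident=confident,
    )
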