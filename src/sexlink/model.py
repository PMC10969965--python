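"""Core data model for reduced-representation sex-linkage analysis.

Genotyping-by-sequencing platforms such as DArTseq deliver two marker
classes: co-dominant SNP calls (homozygous reference / heterozygous /
homozygous alternate) and dominant presence/absence calls scored from
short (~69 bp) sequence tags.  Both are represented here as dense
loci x individuals matrices of small integer codes, annotated with the
phenotypic sex of each individual and, optionally, the tag sequence of
each locus.

Coordinate conventions follow BLAST tabular output: alignment positions
are 1-based and inclusive, and strand is encoded as "+" / "-".
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import ClassVar, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Sex",
    "SnpCall",
    "PACall",
    "GenotypeMatrix",
    "PAMatrix",
    "AlignmentHit",
    "Reference",
    "DEFAULT_CHROM_MAP",
    "natural_key",
]

_VALID_BASES = frozenset("ACGT")


class Sex(str, enum.Enum):
    """Phenotypic sex of an individual.

    Individuals of unknown sex are kept in the matrices but excluded
    from every sex-conditional statistic.
    """

    MALE = "M"
    FEMALE = "F"
    UNKNOWN = "U"


class SnpCall(enum.IntEnum):
    """Co-dominant SNP call states (integer codes used in matrices)."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


class PACall(enum.IntEnum):
    """Dominant presence/absence call states."""

    MISSING = -1
    ABSENT = 0
    PRESENT = 1


def natural_key(chrom: str) -> tuple:
    """Sort key that orders 'chr2' before 'chr10' (numeric-aware)."""
    parts = re.split(r"(\d+)", str(chrom))
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


def _check_tag(tag: str, locus_id: str) -> None:
    if not tag or not set(tag) <= _VALID_BASES:
        raise ValueError(
            f"tag for locus {locus_id!r} must be a nonempty A/C/G/T string"
        )


@dataclass
class _MarkerMatrix:
    """Shared structure of the SNP and presence/absence matrices.

    ``calls`` is an int8 array of shape (n_loci, n_individuals) using the
    codes of :class:`SnpCall` / :class:`PACall`.  ``tags`` when given is a
    list aligned with ``locus_ids`` (``None`` entries allowed for loci
    without a tag sequence).
    """

    locus_ids: list[str]
    individual_ids: list[str]
    sexes: list[Sex]
    calls: np.ndarray
    tags: list[str | None] | None = None

    _valid_codes: ClassVar[frozenset] = frozenset()
    marker_class: ClassVar[str] = ""

    def __post_init__(self) -> None:
        self.locus_ids = [str(x) for x in self.locus_ids]
        self.individual_ids = [str(x) for x in self.individual_ids]
        self.sexes = [Sex(s) for s in self.sexes]
        _check_unique(self.locus_ids, "locus")
        _check_unique(self.individual_ids, "individual")
        if len(self.sexes) != len(self.individual_ids):
            raise ValueError("sexes and individual_ids must have equal length")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.locus_ids), len(self.individual_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({len(self.locus_ids)}, {len(self.individual_ids)})"
            )
        bad = set(np.unique(self.calls)) - set(self._valid_codes)
        if bad:
            raise ValueError(f"invalid call codes in matrix: {sorted(bad)}")
        if self.tags is not None:
            if len(self.tags) != len(self.locus_ids):
                raise ValueError("tags must align with locus_ids")
            for lid, tag in zip(self.locus_ids, self.tags):
                if tag is not None:
                    _check_tag(tag, lid)
        self._locus_index = {lid: i for i, lid in enumerate(self.locus_ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def locus_index(self, locus_id: str) -> int:
        try:
            return self._locus_index[locus_id]
        except KeyError:
            raise KeyError(f"unknown locus id: {locus_id!r}") from None

    def sex_mask(self, sex: Sex) -> np.ndarray:
        return np.array([s is sex for s in self.sexes], dtype=bool)

    def tag_map(self) -> dict[str, str]:
        """Mapping locus id -> tag sequence for loci that have one."""
        if self.tags is None:
            return {}
        return {
            lid: t for lid, t in zip(self.locus_ids, self.tags) if t is not None
        }

    def subset_loci(self, keep: Iterable[str] | np.ndarray):
        """Return a new matrix restricted to the given loci (order kept)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            wanted = set(keep)
            idx = np.array(
                [i for i, lid in enumerate(self.locus_ids) if lid in wanted],
                dtype=int,
            )
        return type(self)(
            locus_ids=[self.locus_ids[i] for i in idx],
            individual_ids=list(self.individual_ids),
            sexes=list(self.sexes),
            calls=self.calls[idx],
            tags=None if self.tags is None else [self.tags[i] for i in idx],
        )

    def equals(self, other: "_MarkerMatrix") -> bool:
        return (
            type(self) is type(other)
            and self.locus_ids == other.locus_ids
            and self.individual_ids == other.individual_ids
            and self.sexes == other.sexes
            and np.array_equal(self.calls, other.calls)
            and (self.tags or None) == (other.tags or None)
        )


@dataclass
class GenotypeMatrix(_MarkerMatrix):
    """Loci x individuals matrix of co-dominant SNP calls."""

    _valid_codes: ClassVar[frozenset] = frozenset(int(c) for c in SnpCall)
    marker_class: ClassVar[str] = "SNP"


@dataclass
class PAMatrix(_MarkerMatrix):
    """Loci x individuals matrix of dominant presence/absence calls."""

    _valid_codes: ClassVar[frozenset] = frozenset(int(c) for c in PACall)
    marker_class: ClassVar[str] = "PA"


@dataclass(frozen=True)
class AlignmentHit:
    """A single tag-to-reference alignment (1-based inclusive coords)."""

    query_id: str
    chrom: str
    start: int
    end: int
    strand: str
    identity: float
    aln_length: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"require 1 <= start <= end, got {self.start}..{self.end}")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity outside [0,1]: {self.identity}")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class Reference:
    """A reference genome as an ordered set of chromosome sequences."""

    chrom_ids: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        _check_unique(self.chrom_ids, "chromosome")
        for cid in self.chrom_ids:
            seq = self.sequences.get(cid, "")
            if not seq or not set(seq) <= _VALID_BASES:
                raise ValueError(
                    f"sequence for {cid!r} must be nonempty over A/C/G/T"
                )

    def __len__(self) -> int:
        return len(self.chrom_ids)


# Reference-to-species chromosome correspondence used when the tags are
# aligned to the R. temporaria assembly: reference chromosomes 9, 4 and 13
# carry the material of study-species chromosomes 7, 3 and 13.
DEFAULT_CHROM_MAP: Mapping[str, str] = {"9": "7", "4": "3", "13": "13"}
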