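"""Sex-linked marker discovery by concordance filtering.

The discovery logic mirrors the standard reduced-representation workflow
for sexing markers in amphibians and fish:

1. drop loci whose call ratio (fraction of non-missing calls among
   individuals of known sex) is below a threshold (default 0.8);
2. score every remaining locus under both a male-heterogametic (XX/XY)
   and a female-heterogametic (ZZ/ZW) hypothesis.  A SNP locus conforms
   when heterogametic-sex individuals are heterozygous and
   homogametic-sex individuals are homozygous; a presence/absence locus
   conforms when the fragment is present in the sex it is limited to and
   absent in the other.  Concordance is the conforming fraction over all
   called individuals of known sex;
3. admit loci whose best-system concordance reaches the threshold
   (default 0.8 — the slack absorbs X/Y recombination, occasional sex
   reversal and genotyping error);
4. screen admitted SNP loci with a homozygosity false-positive test: a
   truly Y- (or W-) limited allele never occurs homozygously, so loci
   where the putative sex-limited allele appears in homozygous state in
   more than a small fraction of individuals (default 0.05) are flagged.

Flagged loci stay in the set but are excluded from the "true" counts of
the bookkeeping summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .model import GenotypeMatrix, PACall, PAMatrix, Sex, SnpCall, _MarkerMatrix

logger = logging.getLogger(__name__)

CATEGORIES = (
    "male_het_snp",
    "female_het_snp",
    "male_present_pa",
    "female_present_pa",
)


# ---------------------------------------------------------------------------
# per-locus call statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusCallStats:
    """Per-locus, per-sex call counts (unknown-sex individuals excluded)."""

    locus_id: str
    marker_class: str  # "SNP" or "PA"
    n_male: int
    n_female: int
    n_called_male: int
    n_called_female: int
    # SNP loci: (hom_ref, het, hom_alt) counts per sex
    male_geno: Optional[tuple[int, int, int]] = None
    female_geno: Optional[tuple[int, int, int]] = None
    # PA loci: (present, absent) counts per sex
    male_pa: Optional[tuple[int, int]] = None
    female_pa: Optional[tuple[int, int]] = None

    @property
    def n_called(self) -> int:
        return self.n_called_male + self.n_called_female

    @property
    def call_ratio(self) -> float:
        total = self.n_male + self.n_female
        return self.n_called / total if total else 0.0


def _count_arrays(matrix: _MarkerMatrix) -> dict[str, np.ndarray]:
    """Vectorised per-locus counts for every known-sex individual."""
    male = matrix.sex_mask(Sex.MALE)
    female = matrix.sex_mask(Sex.FEMALE)
    calls = matrix.calls
    out = {
        "n_male": int(male.sum()),
        "n_female": int(female.sum()),
        "called_male": (calls[:, male] >= 0).sum(axis=1),
        "called_female": (calls[:, female] >= 0).sum(axis=1),
    }
    if matrix.marker_class == "SNP":
        for name, code in (("hom_ref", SnpCall.HOM_REF), ("het", SnpCall.HET),
                           ("hom_alt", SnpCall.HOM_ALT)):
            out[f"male_{name}"] = (calls[:, male] == code).sum(axis=1)
            out[f"female_{name}"] = (calls[:, female] == code).sum(axis=1)
    else:
        for name, code in (("present", PACall.PRESENT), ("absent", PACall.ABSENT)):
            out[f"male_{name}"] = (calls[:, male] == code).sum(axis=1)
            out[f"female_{name}"] = (calls[:, female] == code).sum(axis=1)
    return out


def _stats_from_arrays(matrix, arrays, i) -> LocusCallStats:
    common = dict(
        locus_id=matrix.locus_ids[i],
        marker_class=matrix.marker_class,
        n_male=arrays["n_male"],
        n_female=arrays["n_female"],
        n_called_male=int(arrays["called_male"][i]),
        n_called_female=int(arrays["called_female"][i]),
    )
    if matrix.marker_class == "SNP":
        return LocusCallStats(
            **common,
            male_geno=(int(arrays["male_hom_ref"][i]), int(arrays["male_het"][i]),
                       int(arrays["male_hom_alt"][i])),
            female_geno=(int(arrays["female_hom_ref"][i]), int(arrays["female_het"][i]),
                         int(arrays["female_hom_alt"][i])),
        )
    return LocusCallStats(
        **common,
        male_pa=(int(arrays["male_present"][i]), int(arrays["male_absent"][i])),
        female_pa=(int(arrays["female_present"][i]), int(arrays["female_absent"][i])),
    )


def locus_call_stats(matrix: _MarkerMatrix, locus_id: str) -> LocusCallStats:
    """Compute call counts for one locus, excluding unknown-sex individuals."""
    i = matrix.locus_index(locus_id)
    arrays = _count_arrays(matrix)
    if arrays["n_male"] + arrays["n_female"] == 0:
        raise ValueError("matrix has no individuals of known sex")
    return _stats_from_arrays(matrix, arrays, i)


def call_ratios(matrix: _MarkerMatrix) -> np.ndarray:
    """Per-locus call ratio over individuals of known sex."""
    arrays = _count_arrays(matrix)
    total = arrays["n_male"] + arrays["n_female"]
    if total == 0:
        raise ValueError("matrix has no individuals of known sex")
    return (arrays["called_male"] + arrays["called_female"]) / total


def filter_call_ratio(matrix: _MarkerMatrix, min_call_ratio: float = 0.8):
    """Drop loci whose call ratio is strictly below the threshold.

    A locus at exactly the threshold is retained.  Input locus order is
    preserved; the number removed is logged.
    """
    if not (0.0 < min_call_ratio <= 1.0):
        raise ValueError("min_call_ratio must be in (0, 1]")
    keep = call_ratios(matrix) >= min_call_ratio
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "call-ratio filter (< %.3g): removed %d of %d %s loci",
            min_call_ratio, removed, matrix.n_loci, matrix.marker_class,
        )
    return matrix.subset_loci(keep)


# ---------------------------------------------------------------------------
# concordance scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceResult:
    """Concordance of one locus with one sex-linkage hypothesis."""

    locus_id: str
    marker_class: str
    system: str  # "XY" or "ZW"
    concordance: float
    n_conforming_heterogametic: int
    n_conforming_homogametic: int
    sex_limited_allele: Optional[str] = None  # "ref" / "alt"; SNP only
    allele_tie: bool = False


def _require_both_sexes_called(stats: LocusCallStats) -> None:
    if stats.n_called_male < 1 or stats.n_called_female < 1:
        raise ValueError(
            f"locus {stats.locus_id!r}: a sex has zero called individuals"
        )


def snp_concordance(stats: LocusCallStats, heterogametic_sex: Sex) -> ConcordanceResult:
    """Score a SNP locus under a chosen heterogamety hypothesis.

    Conforming calls are heterozygotes in the heterogametic sex and
    homozygotes (either class) in the homogametic sex.  The sex-limited
    allele is the heterozygote allele absent from the majority homozygote
    class of the homogametic sex; a tie between homozygote classes leaves
    it undefined.
    """
    if stats.marker_class != "SNP":
        raise ValueError("snp_concordance requires SNP call statistics")
    _require_both_sexes_called(stats)
    if heterogametic_sex is Sex.MALE:
        het_geno, hom_geno, system = stats.male_geno, stats.female_geno, "XY"
    else:
        het_geno, hom_geno, system = stats.female_geno, stats.male_geno, "ZW"
    conf_het = het_geno[1]                       # heterozygotes
    conf_hom = hom_geno[0] + hom_geno[2]         # either homozygote class
    concordance = (conf_het + conf_hom) / stats.n_called
    hom_ref_n, _, hom_alt_n = hom_geno
    if hom_ref_n > hom_alt_n:
        allele, tie = "alt", False
    elif hom_alt_n > hom_ref_n:
        allele, tie = "ref", False
    else:
        allele, tie = None, True
    return ConcordanceResult(
        locus_id=stats.locus_id, marker_class="SNP", system=system,
        concordance=concordance, n_conforming_heterogametic=conf_het,
        n_conforming_homogametic=conf_hom, sex_limited_allele=allele,
        allele_tie=tie,
    )


def pa_concordance(stats: LocusCallStats, limited_to_sex: Sex) -> ConcordanceResult:
    """Score a presence/absence locus as a fragment limited to one sex.

    Conforming calls are "present" in the limited-to sex and "absent" in
    the other sex.  A male-limited fragment indicates an XY system, a
    female-limited one a ZW system.
    """
    if stats.marker_class != "PA":
        raise ValueError("pa_concordance requires PA call statistics")
    _require_both_sexes_called(stats)
    if limited_to_sex is Sex.MALE:
        conf_het = stats.male_pa[0]      # present in males
        conf_hom = stats.female_pa[1]    # absent in females
        system = "XY"
    else:
        conf_het = stats.female_pa[0]
        conf_hom = stats.male_pa[1]
        system = "ZW"
    concordance = (conf_het + conf_hom) / stats.n_called
    return ConcordanceResult(
        locus_id=stats.locus_id, marker_class="PA", system=system,
        concordance=concordance, n_conforming_heterogametic=conf_het,
        n_conforming_homogametic=conf_hom,
    )


# ---------------------------------------------------------------------------
# classification and false-positive screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SexLinkedLocus:
    locus_id: str
    marker_class: str      # SNP / PA
    system: str            # XY / ZW
    category: str          # one of CATEGORIES
    concordance: float
    sex_limited_allele: Optional[str] = None
    allele_tie: bool = False
    fp_statistic: Optional[float] = None
    fp_flag: bool = False


@dataclass
class SexLinkedSet:
    """Classified sex-linked candidates plus the thresholds used."""

    members: list[SexLinkedLocus]
    concordance_threshold: float
    min_called_per_sex: int
    fp_threshold: Optional[float] = None

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[SexLinkedLocus]:
        return iter(self.members)

    def by_category(self, category: str) -> list[SexLinkedLocus]:
        return [m for m in self.members if m.category == category]

    def locus_ids(self, include_flagged: bool = True) -> list[str]:
        return [m.locus_id for m in self.members
                if include_flagged or not m.fp_flag]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "locus_id": m.locus_id, "marker_class": m.marker_class,
                "system": m.system, "category": m.category,
                "concordance": m.concordance,
                "sex_limited_allele": m.sex_limited_allele or "",
                "fp_statistic": m.fp_statistic,
                "fp_flag": m.fp_flag,
            } for m in self.members]
        )


_CATEGORY = {("SNP", "XY"): "male_het_snp", ("SNP", "ZW"): "female_het_snp",
             ("PA", "XY"): "male_present_pa", ("PA", "ZW"): "female_present_pa"}


def _classify_matrix(matrix, concordance_threshold, min_called_per_sex):
    members = []
    arrays = _count_arrays(matrix)
    score = snp_concordance if matrix.marker_class == "SNP" else pa_concordance
    for i in range(matrix.n_loci):
        stats = _stats_from_arrays(matrix, arrays, i)
        if (stats.n_called_male < min_called_per_sex
                or stats.n_called_female < min_called_per_sex):
            continue
        r_xy = score(stats, Sex.MALE)
        r_zw = score(stats, Sex.FEMALE)
        if max(r_xy.concordance, r_zw.concordance) < concordance_threshold:
            continue
        if r_xy.concordance == r_zw.concordance:
            logger.info("locus %s: XY/ZW concordance tie (%.4f), dropped as "
                        "ambiguous", stats.locus_id, r_xy.concordance)
            continue
        best = r_xy if r_xy.concordance > r_zw.concordance else r_zw
        members.append(SexLinkedLocus(
            locus_id=best.locus_id, marker_class=best.marker_class,
            system=best.system,
            category=_CATEGORY[(best.marker_class, best.system)],
            concordance=best.concordance,
            sex_limited_allele=best.sex_limited_allele,
            allele_tie=best.allele_tie,
        ))
    return members


def classify_sexlinked(
    snp: GenotypeMatrix | None,
    pa: PAMatrix | None = None,
    concordance_threshold: float = 0.8,
    min_called_per_sex: int = 3,
) -> SexLinkedSet:
    """Classify loci of both marker classes under the XY and ZW hypotheses.

    A locus joins the set when its better-scoring system reaches the
    concordance threshold (boundary included) and both sexes have at
    least ``min_called_per_sex`` called individuals.  An exact XY/ZW tie
    drops the locus as ambiguous.
    """
    if not (0.0 < concordance_threshold <= 1.0):
        raise ValueError("concordance_threshold must be in (0, 1]")
    if snp is not None and pa is not None:
        overlap = set(snp.locus_ids) & set(pa.locus_ids)
        if overlap:
            raise ValueError(
                f"SNP and PA matrices share locus ids: {sorted(overlap)[:5]}"
            )
    members: list[SexLinkedLocus] = []
    for matrix in (snp, pa):
        if matrix is not None and matrix.n_loci:
            members.extend(
                _classify_matrix(matrix, concordance_threshold, min_called_per_sex)
            )
    return SexLinkedSet(members=members,
                        concordance_threshold=concordance_threshold,
                        min_called_per_sex=min_called_per_sex)


def false_positive_test(
    sls: SexLinkedSet,
    snp: GenotypeMatrix,
    fp_threshold: float = 0.05,
) -> SexLinkedSet:
    """Flag SNP candidates whose sex-limited allele occurs homozygously.

    For each SNP member with a defined sex-limited allele b, the
    statistic is the fraction of called known-sex individuals (both
    sexes pooled) homozygous for b.  The member is flagged when the
    statistic exceeds ``fp_threshold`` or when b is undefined.
    Presence/absence members are exempt: homozygosity is undefined for a
    dominant marker.  Flagged loci remain in the set.
    """
    if not (0.0 <= fp_threshold <= 1.0):
        raise ValueError("fp_threshold must be in [0, 1]")
    known = snp.sex_mask(Sex.MALE) | snp.sex_mask(Sex.FEMALE)
    new_members = []
    for m in sls.members:
        if m.marker_class != "SNP":
            new_members.append(m)
            continue
        if m.sex_limited_allele is None:
            new_members.append(replace(m, fp_statistic=None, fp_flag=True))
            continue
        row = snp.calls[snp.locus_index(m.locus_id), known]
        called = row >= 0
        n_called = int(called.sum())
        hom_code = SnpCall.HOM_ALT if m.sex_limited_allele == "alt" else SnpCall.HOM_REF
        n_hom_b = int((row == hom_code).sum())
        stat = n_hom_b / n_called if n_called else 0.0
        new_members.append(replace(m, fp_statistic=stat,
                                   fp_flag=stat > fp_threshold))
    return SexLinkedSet(members=new_members,
                        concordance_threshold=sls.concordance_threshold,
                        min_called_per_sex=sls.min_called_per_sex,
                        fp_threshold=fp_threshold)


# ---------------------------------------------------------------------------
# bookkeeping summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryCounts:
    n_initial: int
    n_false_positive: int

    @property
    def n_true(self) -> int:
        return self.n_initial - self.n_false_positive


@dataclass
class DiscoverySummary:
    """Per-category initial / false-positive / true marker counts."""

    categories: dict[str, CategoryCounts]

    @property
    def n_true_total(self) -> int:
        return sum(c.n_true for c in self.categories.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in CATEGORIES:
            c = self.categories[cat]
            rows.append({"category": cat, "n_initial": c.n_initial,
                         "n_false_positive": c.n_false_positive,
                         "n_true": c.n_true})
        rows.append({"category": "total",
                     "n_initial": sum(c.n_initial for c in self.categories.values()),
                     "n_false_positive": sum(c.n_false_positive
                                             for c in self.categories.values()),
                     "n_true": self.n_true_total})
        return pd.DataFrame(rows)


def summarize_discovery(sls: SexLinkedSet) -> DiscoverySummary:
    """Tabulate initial / flagged / true counts per marker category."""
    cats = {}
    for cat in CATEGORIES:
        members = sls.by_category(cat)
        cats[cat] = CategoryCounts(
            n_initial=len(members),
            n_false_positive=sum(1 for m in members if m.fp_flag),
        )
    return DiscoverySummary(categories=cats)
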