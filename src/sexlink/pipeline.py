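"""End-to-end orchestration: discover, then assign.

Thin composition layer used by the command-line interface, the examples
and the acceptance checks.  All scientific behaviour lives in
:mod:`sexlink.discovery` and :mod:`sexlink.assignment`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .assignment import (
    AssignmentSummary,
    ChromAssignments,
    MapperParams,
    SexChromosomeCall,
    assignment_summary,
    call_sex_chromosome,
    map_tags,
    unique_chromosome_assignments,
)
from .discovery import (
    DiscoverySummary,
    SexLinkedSet,
    classify_sexlinked,
    false_positive_test,
    filter_call_ratio,
    summarize_discovery,
)
from .model import AlignmentHit, GenotypeMatrix, PAMatrix, Reference


@dataclass
class DiscoveryResult:
    sexlinked: SexLinkedSet
    summary: DiscoverySummary
    n_snp_input: int
    n_snp_pass_call_ratio: int
    n_pa_input: int
    n_pa_pass_call_ratio: int


def discover(
    snp: GenotypeMatrix,
    pa: PAMatrix | None = None,
    min_call_ratio: float = 0.8,
    concordance_threshold: float = 0.8,
    min_called_per_sex: int = 3,
    fp_threshold: float = 0.05,
) -> DiscoveryResult:
    """Run call-ratio filtering, concordance classification and the
    homozygosity false-positive screen."""
    snp_f = filter_call_ratio(snp, min_call_ratio)
    pa_f = filter_call_ratio(pa, min_call_ratio) if pa is not None else None
    sls = classify_sexlinked(snp_f, pa_f,
                             concordance_threshold=concordance_threshold,
                             min_called_per_sex=min_called_per_sex)
    sls = false_positive_test(sls, snp_f, fp_threshold=fp_threshold)
    return DiscoveryResult(
        sexlinked=sls,
        summary=summarize_discovery(sls),
        n_snp_input=snp.n_loci,
        n_snp_pass_call_ratio=snp_f.n_loci,
        n_pa_input=pa.n_loci if pa is not None else 0,
        n_pa_pass_call_ratio=pa_f.n_loci if pa_f is not None else 0,
    )


@dataclass
class AssignmentResult:
    partition: ChromAssignments
    summary: AssignmentSummary
    call: Optional[SexChromosomeCall]


def assign(
    locus_ids: Iterable[str],
    tags: Mapping[str, str] | None = None,
    reference: Reference | None = None,
    hits: Iterable[AlignmentHit] | None = None,
    mapper_params: MapperParams | None = None,
    chrom_map: Mapping[str, str] | None = None,
    min_fraction: float = 0.5,
    min_markers: int = 3,
) -> AssignmentResult:
    """Assign sex-linked markers to chromosomes and call the sex chromosome.

    Either precomputed ``hits`` (e.g. read from BLAST tabular output) or
    ``tags`` plus ``reference`` for the built-in mapper must be given.
    """
    locus_ids = list(locus_ids)
    if hits is None:
        if tags is None or reference is None:
            raise ValueError("provide either hits, or tags and a reference")
        subset = {lid: tags[lid] for lid in locus_ids if lid in tags}
        hits = map_tags(subset, reference, mapper_params)
    else:
        wanted = set(locus_ids)
        hits = [h for h in hits if h.query_id in wanted]
    partition = unique_chromosome_assignments(hits, locus_ids)
    summary = assignment_summary(partition)
    call = None
    if summary.modal_chrom is not None:
        call = call_sex_chromosome(summary, chrom_map=chrom_map,
                                   min_fraction=min_fraction,
                                   min_markers=min_markers)
    return AssignmentResult(partition=partition, summary=summary, call=call)
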