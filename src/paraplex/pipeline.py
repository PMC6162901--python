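"""End-to-end hybrid-capture workflow over one sample.

Ties the stages together the way the reflex screen runs them:
permissive emit-all alignment, four-rule pairing restricted to the gene
exon 12-15 span (which stacks genic and pseudogenic fragments into a
four-copy pileup), tetraploid calling there; distinguishing-base
partitioning and diploid calling in exon 11.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import (
    AlignParams,
    DEFAULT_PARAMS,
    SeAlignment,
    aggregate_exons12_15,
    align_reads,
    pair_all,
    partition_exon11_reads,
)
from .catalog import SiteCatalog
from .genotype import GenotypeCall, call_region
from .locus import ParalogLocusModel
from .reads import SimRead


@dataclass
class SmallVariantResult:
    exon11_calls: list[GenotypeCall]
    exons12_15_calls: list[GenotypeCall]
    n_pairs: int
    n_discarded_pairs: int
    exon11_partition: dict[str, list[SeAlignment]]
    aggregated: list[SeAlignment] = field(default_factory=list)


def exon12_15_span(model: ParalogLocusModel) -> tuple[int, int]:
    return (model.gene_exon(12)[0], model.gene_exon(15)[1])


def hybrid_capture_small_variants(
    reads: list[SimRead],
    model: ParalogLocusModel,
    catalog: SiteCatalog,
    params: AlignParams = DEFAULT_PARAMS,
    error_rate: float = 0.01,
    pair_margin: int = 700,
) -> SmallVariantResult:
    """Run the two-track small-variant workflow on one sample's reads.

    ``pair_margin`` widens the pairing region beyond the exon 12-15 span
    so that pairs whose mates fall in flanking introns still rescue.
    """
    aligned = align_reads(reads, model, params)

    span = exon12_15_span(model)
    region = (span[0] - pair_margin, span[1] + pair_margin)
    pairs, discarded = pair_all(aligned, region, params)
    aggregated = aggregate_exons12_15(pairs, model)
    tetra_calls = []
    for exon_label in (12, 13, 14, 15):
        tetra_calls.extend(
            call_region(
                aggregated, model.gene_exon(exon_label), 4, model.sequence, error_rate,
                catalog=catalog,
            )
        )

    exon11 = model.gene_exon(11)
    exon11_alns = []
    for by_mate in aligned.values():
        for alns in by_mate.values():
            for aln in alns:
                if aln.target_pos < exon11[1] and aln.target_end > exon11[0]:
                    exon11_alns.append(aln)
    partition = partition_exon11_reads(exon11_alns, catalog, exon11)
    diploid_calls = call_region(
        partition["gene_reads"], exon11, 2, model.sequence, error_rate
    )

    return SmallVariantResult(
        exon11_calls=diploid_calls,
        exons12_15_calls=tetra_calls,
        n_pairs=len(pairs),
        n_discarded_pairs=discarded,
        exon11_partition=partition,
        aggregated=aggregated,
    )
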