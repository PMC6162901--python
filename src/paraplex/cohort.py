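"""Cohort simulation: sample genomes over a paralog locus.

Each sample carries four haplotypes — ``gene_h1``, ``gene_h2``,
``pseudo_h1``, ``pseudo_h2`` — with small variants (SNVs/indels) drawn
from a site-frequency specification, plus optional gene-conversion
events that copy the partner paralog's allele at distinguishing bases,
and optional whole-exon copy-number events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .locus import BASES, ParalogLocusModel

HAPLOTYPES = ("gene_h1", "gene_h2", "pseudo_h1", "pseudo_h2")
GENE_HAPLOTYPES = ("gene_h1", "gene_h2")
PSEUDO_HAPLOTYPES = ("pseudo_h1", "pseudo_h2")


def paralog_of_haplotype(hap: str) -> str:
    return "gene" if hap.startswith("gene") else "pseudogene"


@dataclass(frozen=True)
class Variant:
    """A small variant in contig coordinates (VCF-style, anchor included
    for indels)."""

    position: int
    ref: str
    alt: str
    vtype: str = "SNV"  # SNV | indel

    def __post_init__(self):
        if self.vtype not in ("SNV", "indel"):
            raise ValueError(f"bad variant type {self.vtype}")
        if self.vtype == "SNV" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("SNV must be single-base")


@dataclass(frozen=True)
class CopyEvent:
    """Single-copy gain/loss of a contiguous exon span on one haplotype."""

    haplotype: str
    exon_labels: tuple[int, ...]  # gene-exon labels, contiguous
    delta: int  # -1 deletion, +1 duplication

    def __post_init__(self):
        if self.haplotype not in HAPLOTYPES:
            raise ValueError(f"unknown haplotype {self.haplotype}")
        if self.delta not in (-1, 1):
            raise ValueError("delta must be -1 or +1")
        labels = self.exon_labels
        if any(b - a != 1 for a, b in zip(labels, labels[1:])):
            raise ValueError("copy events must span contiguous exons")


@dataclass
class SampleGenome:
    sample_id: str
    haplotypes: dict[str, list[Variant]] = field(
        default_factory=lambda: {h: [] for h in HAPLOTYPES}
    )
    copy_events: list[CopyEvent] = field(default_factory=list)

    def validate(self, model: ParalogLocusModel) -> None:
        for hap, variants in self.haplotypes.items():
            lo, hi = model.region(paralog_of_haplotype(hap))
            seen = set()
            for v in variants:
                if not lo <= v.position < hi:
                    raise ValueError(f"{hap} variant at {v.position} outside its paralog")
                if v.position in seen:
                    raise ValueError(f"two variants at {v.position} on {hap}")
                seen.add(v.position)

    def variant_at(self, hap: str, position: int) -> Variant | None:
        for v in self.haplotypes[hap]:
            if v.position == position:
                return v
        return None

    def base_at(self, model: ParalogLocusModel, hap: str, gene_pos: int) -> str:
        """Allele carried by ``hap`` at the gene-coordinate position
        (pseudogene haplotypes are looked up via the homology map)."""
        pos = gene_pos
        if paralog_of_haplotype(hap) == "pseudogene":
            pos = model.gene_to_pseudogene(gene_pos)
        v = self.variant_at(hap, pos)
        return v.alt if v is not None else model.sequence[pos]


@dataclass(frozen=True)
class PolymorphicSite:
    """One entry of a site-frequency specification."""

    paralog: str  # gene | pseudogene
    position: int  # contig coordinate within that paralog's region
    ref: str
    alt: str
    frequency: float
    vtype: str = "SNV"

    def __post_init__(self):
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")
        if self.paralog not in ("gene", "pseudogene"):
            raise ValueError(f"unknown paralog {self.paralog}")


def random_site_spec(
    model: ParalogLocusModel,
    n_sites: int,
    rng: np.random.Generator,
    freq_range: tuple[float, float] = (0.02, 0.4),
    indel_fraction: float = 0.2,
    exonic_only: bool = True,
) -> list[PolymorphicSite]:
    """Draw a random polymorphic-site specification, avoiding
    distinguishing-base positions (those vary only via gene conversion)."""
    excluded = {db.gene_pos for db in model.distinguishing_bases}
    excluded |= {db.pseudogene_pos for db in model.distinguishing_bases}
    sites: list[PolymorphicSite] = []
    taken: set[int] = set()
    while len(sites) < n_sites:
        paralog = str(rng.choice(["gene", "pseudogene"]))
        exons = model.exons("gene" if paralog == "gene" else "pseudogene")
        if exonic_only:
            s, e = exons[int(rng.integers(len(exons)))]
        else:
            s, e = model.region(paralog)
        pos = int(rng.integers(s + 1, e - 1))
        if pos in excluded or pos in taken:
            continue
        taken.add(pos)
        ref = model.sequence[pos]
        freq = float(rng.uniform(*freq_range))
        if rng.random() < indel_fraction:
            if rng.random() < 0.5:  # deletion of the following base
                site = PolymorphicSite(
                    paralog, pos, model.sequence[pos : pos + 2], ref, freq, "indel"
                )
            else:  # insertion after the anchor
                ins = str(rng.choice(BASES))
                site = PolymorphicSite(paralog, pos, ref, ref + ins, freq, "indel")
        else:
            alt = str(rng.choice([b for b in BASES if b != ref]))
            site = PolymorphicSite(paralog, pos, ref, alt, freq, "SNV")
        sites.append(site)
    return sites


def generate_cohort(
    model: ParalogLocusModel,
    n_samples: int,
    site_frequency_spec: list[PolymorphicSite] | None = None,
    gene_conversion_rate: float | dict[int, float] = 0.0,
    seed: int = 0,
) -> list[SampleGenome]:
    """Sample ``n_samples`` genomes.

    Polymorphic-site alleles are drawn independently per haplotype at the
    specified frequencies.  Gene conversion is modelled per haplotype per
    distinguishing base: with the given rate the haplotype carries the
    *partner* paralog's allele at that base, which is what erodes the
    site's reliability in a large cohort.  ``gene_conversion_rate`` may
    be a scalar or a per-site map keyed by gene position.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    spec = site_frequency_spec or []
    rng = np.random.default_rng(seed)

    def conv_rate(gene_pos: int) -> float:
        if isinstance(gene_conversion_rate, dict):
            return gene_conversion_rate.get(gene_pos, 0.0)
        return float(gene_conversion_rate)

    cohort: list[SampleGenome] = []
    for i in range(n_samples):
        sample = SampleGenome(sample_id=f"S{i:04d}")
        for site in spec:
            haps = GENE_HAPLOTYPES if site.paralog == "gene" else PSEUDO_HAPLOTYPES
            for hap in haps:
                if rng.random() < site.frequency:
                    sample.haplotypes[hap].append(
                        Variant(site.position, site.ref, site.alt, site.vtype)
                    )
        for db in model.distinguishing_bases:
            rate = conv_rate(db.gene_pos)
            if rate <= 0.0:
                continue
            for hap in GENE_HAPLOTYPES:
                if rng.random() < rate:
                    sample.haplotypes[hap].append(
                        Variant(db.gene_pos, db.gene_allele, db.pseudogene_allele)
                    )
            for hap in PSEUDO_HAPLOTYPES:
                if rng.random() < rate:
                    sample.haplotypes[hap].append(
                        Variant(db.pseudogene_pos, db.pseudogene_allele, db.gene_allele)
                    )
        for hap in sample.haplotypes:
            sample.haplotypes[hap].sort(key=lambda v: v.position)
        sample.validate(model)
        cohort.append(sample)
    return cohort


def amplicon_truth_genotypes(
    cohort: list[SampleGenome],
    model: ParalogLocusModel,
    paralog: str,
    gene_positions: list[int],
) -> dict[tuple[str, int], tuple[int, str | None]]:
    """Idealized paralog-specific amplicon genotypes at gene-coordinate
    sites.

    For each (sample, gene position) returns ``(dosage, allele)`` where
    dosage counts the haplotype alleles of ``paralog`` that differ from
    the gene reference base at that position (as if the amplicon reads
    were aligned to the gene) and ``allele`` is the non-reference base
    observed, or ``None`` when dosage is 0.  A site carrying two distinct
    non-reference alleles gets allele ``"*"`` (mixed).
    """
    haps = GENE_HAPLOTYPES if paralog == "gene" else PSEUDO_HAPLOTYPES
    out: dict[tuple[str, int], tuple[int, str | None]] = {}

    def allele_of(sample: SampleGenome, hap: str, gene_pos: int) -> str:
        pos = gene_pos
        if paralog_of_haplotype(hap) == "pseudogene":
            pos = model.gene_to_pseudogene(gene_pos)
        v = sample.variant_at(hap, pos)
        if v is None:
            return model.sequence[pos]
        if v.vtype == "indel":
            return f"indel:{v.ref}>{v.alt}"
        return v.alt

    for sample in cohort:
        for gene_pos in gene_positions:
            ref = model.sequence[gene_pos]
            alts = [
                b for b in (allele_of(sample, h, gene_pos) for h in haps) if b != ref
            ]
            if not alts:
                out[(sample.sample_id, gene_pos)] = (0, None)
            elif len(set(alts)) == 1:
                out[(sample.sample_id, gene_pos)] = (len(alts), alts[0])
            else:
                out[(sample.sample_id, gene_pos)] = (len(alts), "*")
    return out
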