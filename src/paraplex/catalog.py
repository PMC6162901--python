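"""Distinguishing-base catalog, allele-frequency tables, probe design.

A candidate distinguishing site is *reliable* only if, in 100% of cohort
samples, the gene-specific amplicon is homozygous for the reference
(gene) allele and the pseudogene-specific amplicon is homozygous for the
same single alternate allele.  One heterozygous sample, a third allele,
or a no-call anywhere breaks reliability — reliability is monotone
non-increasing as the cohort grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import pandas as pd

from .locus import ParalogLocusModel


@dataclass
class CatalogSite:
    gene_pos: int
    pseudogene_pos: int
    gene_allele: str
    pseudogene_allele: str
    reliable: bool
    gene_alt_freq: float
    pseudogene_geneallele_freq: float
    n_samples: int


@dataclass
class SiteCatalog:
    sites: list[CatalogSite] = field(default_factory=list)

    def reliable_sites(self) -> list[CatalogSite]:
        return [s for s in self.sites if s.reliable]

    def n_reliable_in(self, interval: tuple[int, int]) -> int:
        return sum(1 for s in self.reliable_sites() if interval[0] <= s.gene_pos < interval[1])

    def counts_per_exon(self, model: ParalogLocusModel) -> dict[int, int]:
        """Reliable-site counts keyed by gene exon label."""
        return {
            label: self.n_reliable_in(iv)
            for label, iv in zip(model.gene_exon_labels, model.gene_exons)
        }

    def to_tsv(self, path) -> None:
        pd.DataFrame([vars(s) for s in self.sites]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SiteCatalog":
        df = pd.read_csv(path, sep="\t")
        return cls([CatalogSite(**row) for row in df.to_dict("records")])


def build_catalog(
    gene_amplicon_genotypes: dict[tuple[str, int], tuple[int, str | None]],
    pseudogene_amplicon_genotypes: dict[tuple[str, int], tuple[int, str | None]],
    candidate_sites,
) -> SiteCatalog:
    """Apply the 100%-of-samples reliability rule.

    Both genotype maps are keyed ``(sample_id, gene_pos)`` with values
    ``(dosage, allele)``: the dosage (0..2) of non-reference alleles
    observed in that paralog-specific amplicon as aligned to the gene,
    and the non-reference allele seen (``None`` when dosage is 0, ``"*"``
    for mixed alleles).  A missing or ``None``-dosage entry is a no-call
    and makes the site unreliable.  ``candidate_sites`` is an iterable of
    objects with ``gene_pos``, ``pseudogene_pos``, ``gene_allele`` and
    ``pseudogene_allele`` attributes (e.g. locus distinguishing bases).
    """
    gene_samples = {s for s, _ in gene_amplicon_genotypes}
    pseudo_samples = {s for s, _ in pseudogene_amplicon_genotypes}
    if gene_samples != pseudo_samples:
        raise ValueError("gene and pseudogene call sets cover different cohorts")
    if not gene_samples:
        raise ValueError("empty cohort")
    samples = sorted(gene_samples)
    n = len(samples)

    sites: list[CatalogSite] = []
    for cand in candidate_sites:
        pos = cand.gene_pos
        reliable = True
        gene_alt_haps = 0
        pseudo_genehap = 0
        for s in samples:
            g = gene_amplicon_genotypes.get((s, pos))
            p = pseudogene_amplicon_genotypes.get((s, pos))
            if g is None or p is None or g[0] is None or p[0] is None:
                reliable = False  # no-call fails the 100% rule
                continue
            g_dos, _ = g
            p_dos, p_allele = p
            gene_alt_haps += g_dos
            pseudo_genehap += 2 - p_dos
            if g_dos != 0:
                reliable = False
            if p_dos != 2 or p_allele != cand.pseudogene_allele:
                reliable = False
        sites.append(
            CatalogSite(
                gene_pos=pos,
                pseudogene_pos=cand.pseudogene_pos,
                gene_allele=cand.gene_allele,
                pseudogene_allele=cand.pseudogene_allele,
                reliable=reliable,
                gene_alt_freq=gene_alt_haps / (2 * n),
                pseudogene_geneallele_freq=pseudo_genehap / (2 * n),
                n_samples=n,
            )
        )
    return SiteCatalog(sites)


def allele_frequency_table(
    catalog: SiteCatalog,
    gene_amplicon_genotypes: dict[tuple[str, int], tuple[int, str | None]],
    pseudogene_amplicon_genotypes: dict[tuple[str, int], tuple[int, str | None]],
) -> pd.DataFrame:
    """Cohort allele-frequency table (site, paralog, allele, frequency, n).

    Frequencies are haplotype-allele counts over 2n per paralog; the two
    complementary alleles at a biallelic site sum to 1 within a paralog.
    """
    rows = []
    for site in catalog.sites:
        for paralog, genotypes, ref_allele, alt_allele in (
            ("gene", gene_amplicon_genotypes, site.gene_allele, site.pseudogene_allele),
            ("pseudogene", pseudogene_amplicon_genotypes, site.gene_allele, site.pseudogene_allele),
        ):
            dosages = [
                v[0]
                for (s, pos), v in genotypes.items()
                if pos == site.gene_pos and v[0] is not None
            ]
            n = len(dosages)
            if n == 0:
                alt_freq = 0.0
            else:
                alt_freq = sum(dosages) / (2 * n)
            rows.append(
                {"site": site.gene_pos, "paralog": paralog, "allele": alt_allele,
                 "frequency": alt_freq, "n": n}
            )
            rows.append(
                {"site": site.gene_pos, "paralog": paralog, "allele": ref_allele,
                 "frequency": 1.0 - alt_freq, "n": n}
            )
    return pd.DataFrame(rows, columns=["site", "paralog", "allele", "frequency", "n"])


def write_frequency_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_frequency_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def design_probes(
    model: ParalogLocusModel,
    variable_positions,
    probe_len: int = 40,
    stride: int = 20,
    pad: int = 20,
) -> pd.DataFrame:
    """Tile capture probes over gene exons, avoiding variable positions.

    ``variable_positions`` is any iterable of contig coordinates shown to
    differ or vary between the paralogs (distinguishing bases and
    cohort-variable sites; pseudogene coordinates are mapped onto the
    gene before checking).  Probes are ``probe_len``-mers placed every
    ``stride`` bases over each exon +/- ``pad``; any window overlapping a
    variable position is dropped.  Warns when an exon has uncovered
    bases (variable sites denser than the probe length allows).
    """
    plo, phi = model.pseudogene_region
    var: set[int] = set()
    for p in variable_positions:
        p = int(p)
        if plo <= p < phi:
            p = model.pseudogene_to_gene(p)
        var.add(p)

    rows = []
    for label, (es, ee) in zip(model.gene_exon_labels, model.gene_exons):
        lo = max(model.gene_region[0], es - pad)
        hi = min(model.gene_region[1], ee + pad)
        covered = set()
        for start in range(lo, hi - probe_len + 1, stride):
            window = range(start, start + probe_len)
            if any(p in var for p in window):
                continue
            covered.update(window)
            rows.append(
                {"chrom": model.contig_name, "start": start, "end": start + probe_len,
                 "name": f"probe_exon{label}_{start}"}
            )
        missing = [p for p in range(es, ee) if p not in covered]
        if missing:
            warnings.warn(
                f"exon {label}: {len(missing)} bases untileable around variable "
                f"positions (gap near {missing[0]})",
                stacklevel=2,
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def probes_to_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
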