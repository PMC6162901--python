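"""Synthetic paralog locus model.

A locus is a single contig carrying two homologous regions — a "gene"
region with exons labelled 11..15 and a "pseudogene" region with exons
labelled 2..6 (gene exon 11 corresponds to pseudogene exon 2, 12 to 3,
and so on).  The two regions are equal-length copies of each other that
differ only at a configurable set of *distinguishing bases*, so the
position homology map is a constant-offset bijection.  Sequence identity
per exon pair is therefore ``1 - n_distinguishing / exon_length``.

Coordinates are 0-based half-open throughout; they become 1-based only
on VCF/SAM output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = ("A", "C", "G", "T")

GENE_EXON_LABELS = (11, 12, 13, 14, 15)
PSEUDOGENE_EXON_LABELS = (2, 3, 4, 5, 6)


class ParameterError(ValueError):
    """Raised for infeasible or inconsistent locus configurations."""


@dataclass(frozen=True)
class DistinguishingBase:
    """A position where gene and pseudogene carry different alleles."""

    gene_pos: int
    pseudogene_pos: int
    gene_allele: str
    pseudogene_allele: str


@dataclass
class LocusConfig:
    """Parameters for :func:`generate_locus`.

    Defaults emulate the reference-genome-like configuration of the
    PMS2/PMS2CL 3' exons: five exon pairs whose hg19-style difference
    counts are 26, 0, 1, 1 and 0 bases (identity > 97% in every exon).
    """

    exon_lengths: tuple[int, ...] = (900, 160, 130, 180, 160)
    n_distinguishing: tuple[int, ...] = (26, 0, 1, 1, 0)
    identity_targets: tuple[float, ...] | None = None
    intron_length: int = 350
    flank: int = 250
    spacer: int = 800
    min_exon_length: int = 115  # exons must accommodate one read
    seed: int = 0


@dataclass
class ParalogLocusModel:
    contig_name: str
    sequence: str
    gene_exons: list[tuple[int, int]]
    pseudogene_exons: list[tuple[int, int]]
    gene_region: tuple[int, int]
    pseudogene_region: tuple[int, int]
    distinguishing_bases: list[DistinguishingBase]
    identity_per_exon: list[float]
    gene_exon_labels: tuple[int, ...] = GENE_EXON_LABELS
    pseudogene_exon_labels: tuple[int, ...] = PSEUDOGENE_EXON_LABELS

    # -- homology map -------------------------------------------------
    @property
    def homology_offset(self) -> int:
        return self.pseudogene_region[0] - self.gene_region[0]

    def gene_to_pseudogene(self, pos: int) -> int:
        if not self.gene_region[0] <= pos < self.gene_region[1]:
            raise ValueError(f"position {pos} outside gene region")
        return pos + self.homology_offset

    def pseudogene_to_gene(self, pos: int) -> int:
        if not self.pseudogene_region[0] <= pos < self.pseudogene_region[1]:
            raise ValueError(f"position {pos} outside pseudogene region")
        return pos - self.homology_offset

    def paralog_of(self, pos: int) -> str:
        if self.gene_region[0] <= pos < self.gene_region[1]:
            return "gene"
        if self.pseudogene_region[0] <= pos < self.pseudogene_region[1]:
            return "pseudogene"
        raise ValueError(f"position {pos} outside both paralog regions")

    def region(self, paralog: str) -> tuple[int, int]:
        return self.gene_region if paralog == "gene" else self.pseudogene_region

    def exons(self, paralog: str) -> list[tuple[int, int]]:
        return self.gene_exons if paralog == "gene" else self.pseudogene_exons

    def gene_exon(self, label: int) -> tuple[int, int]:
        return self.gene_exons[self.gene_exon_labels.index(label)]

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        n = len(self.gene_exons)
        if len(self.pseudogene_exons) != n or len(self.identity_per_exon) != n:
            raise ValueError("exon list length mismatch")
        for (gs, ge), (ps, pe) in zip(self.gene_exons, self.pseudogene_exons):
            if ge - gs != pe - ps:
                raise ValueError("paired exons must have equal length")
            if ps != gs + self.homology_offset:
                raise ValueError("pseudogene exon not at the homologous offset")
        for exons in (self.gene_exons, self.pseudogene_exons):
            for (a, b), (c, d) in zip(exons, exons[1:]):
                if not (a < b <= c < d):
                    raise ValueError("exon intervals must be sorted, non-overlapping")
        seq = self.sequence
        for db in self.distinguishing_bases:
            if db.pseudogene_pos != self.gene_to_pseudogene(db.gene_pos):
                raise ValueError("distinguishing base outside the homology map")
            if db.gene_allele == db.pseudogene_allele:
                raise ValueError("distinguishing base alleles must differ")
            if seq[db.gene_pos] != db.gene_allele or seq[db.pseudogene_pos] != db.pseudogene_allele:
                raise ValueError("distinguishing base alleles disagree with sequence")
        for i, ((gs, ge), stored) in enumerate(zip(self.gene_exons, self.identity_per_exon)):
            off = self.homology_offset
            diffs = sum(1 for p in range(gs, ge) if seq[p] != seq[p + off])
            computed = 1.0 - diffs / (ge - gs)
            if abs(computed - stored) > 1e-9:
                raise ValueError(f"identity_per_exon[{i}] stale: {stored} vs {computed}")

    # -- serialization ------------------------------------------------
    def to_json(self, path) -> None:
        doc = asdict(self)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParalogLocusModel":
        with open(path) as fh:
            doc = json.load(fh)
        doc["distinguishing_bases"] = [DistinguishingBase(**d) for d in doc["distinguishing_bases"]]
        for key in ("gene_exons", "pseudogene_exons"):
            doc[key] = [tuple(iv) for iv in doc[key]]
        for key in ("gene_region", "pseudogene_region", "gene_exon_labels", "pseudogene_exon_labels"):
            doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_fasta(self, path) -> None:
        rec = SeqRecord(Seq(self.sequence), id=self.contig_name, description="")
        SeqIO.write([rec], str(path), "fasta")

    def exons_to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for label, (s, e) in zip(self.gene_exon_labels, self.gene_exons):
                fh.write(f"{self.contig_name}\t{s}\t{e}\tgene_exon_{label}\n")
            for label, (s, e) in zip(self.pseudogene_exon_labels, self.pseudogene_exons):
                fh.write(f"{self.contig_name}\t{s}\t{e}\tpseudogene_exon_{label}\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def generate_locus(config: LocusConfig | None = None, **kwargs) -> ParalogLocusModel:
    """Build a synthetic two-paralog locus.

    The pseudogene region starts as an exact copy of the gene region and
    is then mutated at ``n_distinguishing[i]`` positions inside each exon
    pair.  When ``identity_targets`` is supplied it must be consistent
    with the requested difference counts (identity = 1 - n/len), else a
    :class:`ParameterError` is raised.
    """
    if config is None:
        config = LocusConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a LocusConfig or keyword overrides, not both")
    k = len(config.exon_lengths)
    if len(config.n_distinguishing) != k:
        raise ParameterError("n_distinguishing must match exon_lengths in length")
    for L in config.exon_lengths:
        if L < config.min_exon_length:
            raise ParameterError(f"exon length {L} below minimum {config.min_exon_length}")
    for L, nd in zip(config.exon_lengths, config.n_distinguishing):
        if nd < 0 or nd > 0.1 * L:
            raise ParameterError(
                f"{nd} distinguishing bases in a {L} nt exon leaves identity below 0.9"
            )
    if config.identity_targets is not None:
        if len(config.identity_targets) != k:
            raise ParameterError("identity_targets must match exon_lengths in length")
        for L, nd, t in zip(config.exon_lengths, config.n_distinguishing, config.identity_targets):
            if not 0.9 < t <= 1.0:
                raise ParameterError(f"identity target {t} outside (0.9, 1.0]")
            if round((1.0 - t) * L) != nd:
                raise ParameterError(
                    f"identity target {t} implies {round((1.0 - t) * L)} differences "
                    f"in a {L} nt exon but n_distinguishing = {nd}"
                )

    rng = np.random.default_rng(config.seed)

    # gene region layout: flank exon intron exon ... exon flank
    gene_exons: list[tuple[int, int]] = []
    pos = config.flank
    for L in config.exon_lengths:
        gene_exons.append((pos, pos + L))
        pos += L + config.intron_length
    region_len = pos - config.intron_length + config.flank
    gene_seq = list(_random_dna(rng, region_len))
    pseudo_seq = list(gene_seq)

    offset = region_len + config.spacer
    distinguishing: list[DistinguishingBase] = []
    for (gs, ge), nd in zip(gene_exons, config.n_distinguishing):
        if nd == 0:
            continue
        sites = np.sort(rng.choice(np.arange(gs, ge), size=nd, replace=False))
        for p in sites:
            p = int(p)
            g_allele = gene_seq[p]
            alts = [b for b in BASES if b != g_allele]
            p_allele = str(rng.choice(alts))
            pseudo_seq[p] = p_allele
            distinguishing.append(
                DistinguishingBase(p, p + offset, g_allele, p_allele)
            )

    spacer_seq = _random_dna(rng, config.spacer)
    sequence = "".join(gene_seq) + spacer_seq + "".join(pseudo_seq)

    model = ParalogLocusModel(
        contig_name="paralog_locus",
        sequence=sequence,
        gene_exons=gene_exons,
        pseudogene_exons=[(s + offset, e + offset) for s, e in gene_exons],
        gene_region=(0, region_len),
        pseudogene_region=(offset, offset + region_len),
        distinguishing_bases=distinguishing,
        identity_per_exon=[
            1.0 - nd / L for L, nd in zip(config.exon_lengths, config.n_distinguishing)
        ],
    )
    model.validate()
    return model
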