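"""Pileup construction and ploidy-aware SNV/indel calling.

The caller replaces local-assembly machinery with a transparent pileup
dosage model.  At a site with ploidy P (2 for the gene-partitioned
exon 11, 4 for the aggregated exons 12-15), the probability that a read
shows the alternate allele given alt dosage d is

    p_d = (d/P) * (1 - eps) + (1 - d/P) * (eps / 3)

with eps the per-base error rate spread uniformly over the three
alternative bases.  The genotype is the maximum-likelihood dosage under
a binomial model of the alt read count (uniform prior over dosages;
ties break toward the lower dosage).  Sites below the minimum depth of
20 reads are flagged LOW_DEPTH.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .align import SeAlignment

MIN_DEPTH = 20
DEFAULT_ERROR_RATE = 0.01


@dataclass
class PileupColumn:
    position: int
    ref_allele: str
    allele_counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.allele_counts.values())

    def top_alt(self) -> tuple[str | None, int]:
        """Most frequent non-reference allele and its count."""
        best, cnt = None, 0
        for allele, c in sorted(self.allele_counts.items()):
            if allele == self.ref_allele:
                continue
            if c > cnt:
                best, cnt = allele, c
        return best, cnt


@dataclass
class GenotypeCall:
    position: int
    ref: str
    alt: str
    ploidy: int
    dosage: int
    log_likelihoods: list[float]
    qual: float
    filter: str = "PASS"

    def normalized_likelihoods(self) -> np.ndarray:
        ll = np.asarray(self.log_likelihoods, dtype=float)
        w = np.exp(ll - ll.max())
        return w / w.sum()


def build_pileup(
    alignments: list[SeAlignment],
    region: tuple[int, int],
    reference: str,
) -> list[PileupColumn]:
    """Column counts over every position of ``region``.

    Substitutions are keyed by their base; indels are keyed at their
    anchor position as ``ins:<seq>`` / ``del:<length>`` (VCF-style, the
    anchor base itself still contributes its match/mismatch count at the
    anchor only through the indel key, not twice).
    """
    lo, hi = region
    counts: list[Counter] = [Counter() for _ in range(hi - lo)]

    def add(pos: int, allele: str) -> None:
        if lo <= pos < hi:
            counts[pos - lo][allele] += 1

    for aln in alignments:
        rp = aln.target_pos
        qp = aln.query_start
        ops = aln.cigar
        for k, (op, n) in enumerate(ops):
            if op == "M":
                seg_end = n
                # an immediately following indel claims the last matched
                # base as its anchor
                nxt = ops[k + 1] if k + 1 < len(ops) else None
                if nxt and nxt[0] == "I":
                    seg_end = n - 1
                    ins = aln.read_seq[qp + n : qp + n + nxt[1]]
                    add(rp + n - 1, f"ins:{ins}")
                elif nxt and nxt[0] == "D":
                    seg_end = n - 1
                    add(rp + n - 1, "del:%d" % nxt[1])
                for i in range(seg_end):
                    add(rp + i, aln.read_seq[qp + i])
                rp += n
                qp += n
            elif op == "I":
                qp += n
            elif op == "D":
                rp += n
    return [
        PileupColumn(lo + i, reference[lo + i], dict(c)) for i, c in enumerate(counts)
    ]


def dosage_log_likelihoods(
    alt_count: int, depth: int, ploidy: int, error_rate: float
) -> np.ndarray:
    d = np.arange(ploidy + 1)
    frac = d / ploidy
    p_d = frac * (1.0 - error_rate) + (1.0 - frac) * (error_rate / 3.0)
    return binom.logpmf(alt_count, depth, p_d)


def genotype_site(
    column: PileupColumn,
    ploidy: int,
    error_rate: float = DEFAULT_ERROR_RATE,
    min_depth: int = MIN_DEPTH,
    alt: str | None = None,
) -> GenotypeCall:
    """Maximum-likelihood alt dosage at one pileup column.

    ``alt`` defaults to the most frequent non-reference allele; all
    other alleles are pooled with the reference (multi-allelic sites are
    genotyped one alt at a time, best alt only).
    """
    if ploidy not in (2, 4):
        raise ValueError("ploidy must be 2 or 4")
    depth = column.depth
    if depth < 1:
        raise ValueError("cannot genotype an empty column")
    if alt is None:
        alt, alt_count = column.top_alt()
    else:
        alt_count = column.allele_counts.get(alt, 0)
    if alt is None:
        alt, alt_count = ".", 0
    ll = dosage_log_likelihoods(alt_count, depth, ploidy, error_rate)
    # argmax with ties toward the lower dosage (np.argmax already takes
    # the first maximum)
    dosage = int(np.argmax(ll))
    post = np.exp(ll - ll.max())
    post /= post.sum()
    p_err = max(1.0 - float(post[dosage]), 1e-300)
    qual = float(min(10_000.0, -10.0 * np.log10(p_err)))
    return GenotypeCall(
        position=column.position,
        ref=column.ref_allele,
        alt=alt,
        ploidy=ploidy,
        dosage=dosage,
        log_likelihoods=ll.tolist(),
        qual=qual,
        filter="PASS" if depth >= min_depth else "LOW_DEPTH",
    )


def call_region(
    alignments: list[SeAlignment],
    region: tuple[int, int],
    ploidy: int,
    reference: str,
    error_rate: float = DEFAULT_ERROR_RATE,
    min_depth: int = MIN_DEPTH,
    catalog=None,
) -> list[GenotypeCall]:
    """Genotype every position in a region; emit non-reference calls.

    Positions with zero coverage are skipped (they surface through CNV
    calling, not the small-variant caller); covered positions below the
    minimum depth still get calls but carry the LOW_DEPTH filter.

    When a site ``catalog`` is given, a tetraploid call that merely
    re-observes a known fixed gene/pseudogene difference — the catalog's
    pseudogene allele at dosage 2 (two pseudogene haplotypes stacked on
    the gene locus) — is suppressed rather than reported as a variant.
    """
    expected = {}
    if catalog is not None:
        expected = {s.gene_pos: s.pseudogene_allele for s in catalog.sites}
    calls = []
    for column in build_pileup(alignments, region, reference):
        if column.depth == 0:
            continue
        call = genotype_site(column, ploidy, error_rate, min_depth)
        if call.dosage == 0:
            continue
        if (
            ploidy == 4
            and call.position in expected
            and call.alt == expected[call.position]
            and call.dosage == 2
        ):
            continue
        calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

def write_vcf(calls: list[GenotypeCall], contig: str, contig_len: int, reference: str, path) -> None:
    """VCF 4.2 with a dosage-encoding GT (e.g. 0/0/0/1 at ploidy 4).

    Indel alleles are exported VCF-style with the anchor base included.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_len}>")
    header.add_line('##FILTER=<ID=LOW_DEPTH,Description="Depth below 20 reads">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Integer,Description="Alt dosage">')
    header.add_sample("SAMPLE")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            if call.alt.startswith("ins:"):
                ref = reference[call.position]
                alt = ref + call.alt[4:]
                pos = call.position
            elif call.alt.startswith("del:"):
                n = int(call.alt[4:])
                pos = call.position
                ref = reference[pos : pos + n + 1]
                alt = reference[pos]
            else:
                pos, ref, alt = call.position, call.ref, call.alt
            rec = out.new_record(
                contig=contig,
                start=pos,
                alleles=(ref, alt),
                filter="PASS" if call.filter == "PASS" else "LOW_DEPTH",
            )
            rec.qual = round(call.qual, 2)
            gt = tuple([0] * (call.ploidy - call.dosage) + [1] * call.dosage)
            rec.samples["SAMPLE"]["GT"] = gt
            rec.samples["SAMPLE"]["DS"] = call.dosage
            out.write(rec)
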