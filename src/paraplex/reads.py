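"""Paired-end short-read simulation over a paralog locus.

Two modes mirror the two assays being emulated:

* ``hybrid_capture`` — fragments drawn from all four haplotypes
  (gene + pseudogene, two copies each), i.e. capture that is agnostic to
  genic/pseudogenic origin.
* ``amplicon_gene`` / ``amplicon_pseudogene`` — fragments drawn from the
  two haplotypes of one paralog only, emulating a paralog-specific
  long-range PCR amplicon, with optional allelic dropout (relative
  under-amplification of one allele).

Every read carries a truth origin label (its source haplotype) and a
truth reference placement, so alignment and partitioning can be scored
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam

from .cohort import (
    GENE_HAPLOTYPES,
    HAPLOTYPES,
    PSEUDO_HAPLOTYPES,
    SampleGenome,
    paralog_of_haplotype,
)
from .locus import BASES, ParalogLocusModel

_COMP = str.maketrans("ACGTN", "TGCAN")

MODES = ("hybrid_capture", "amplicon_gene", "amplicon_pseudogene")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ReadSimConfig:
    mode: str = "hybrid_capture"
    read_length: int = 115
    paired: bool = True
    mean_depth: float = 500.0
    error_rate: float = 0.001
    dropout_fraction: float = 1.0  # 1.0 = no dropout (amplicon modes only)
    fragment_range: tuple[int, int] = (250, 600)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode}")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 < self.dropout_fraction <= 1.0:
            raise ValueError("dropout_fraction must be in (0, 1]")


@dataclass
class SimRead:
    """One sequenced read with truth annotations.

    ``seq`` is in sequencing orientation (mate 2 is the reverse
    complement of the fragment's 3' end).  ``ref_start``/``cigar``
    describe the read's true placement on the locus reference in
    forward-reference orientation.
    """

    read_id: str
    mate: int
    seq: str
    origin: str  # source haplotype
    strand: str  # + for mate 1, - for mate 2
    ref_start: int
    cigar: list[tuple[str, int]]
    sample_id: str

    @property
    def aligned_seq(self) -> str:
        """Read bases in forward-reference orientation."""
        return self.seq if self.strand == "+" else revcomp(self.seq)


def _haplotype_sequence(
    model: ParalogLocusModel, sample: SampleGenome, hap: str
) -> tuple[str, np.ndarray]:
    """Apply a haplotype's variants to its paralog region.

    Returns the mutated sequence and an int array mapping each haplotype
    base to its reference coordinate (-1 for inserted bases).
    """
    lo, hi = model.region(paralog_of_haplotype(hap))
    pieces: list[str] = []
    refpos: list[np.ndarray] = []
    cur = lo
    for v in sorted(sample.haplotypes[hap], key=lambda v: v.position):
        if v.position < cur:
            raise ValueError(f"overlapping variants on {hap} at {v.position}")
        pieces.append(model.sequence[cur : v.position])
        refpos.append(np.arange(cur, v.position))
        pieces.append(v.alt)
        rp = np.full(len(v.alt), -1, dtype=np.int64)
        # shared anchor/substituted bases keep their reference coordinate
        n_anchor = min(len(v.ref), len(v.alt))
        rp[:n_anchor] = np.arange(v.position, v.position + n_anchor)
        refpos.append(rp)
        cur = v.position + len(v.ref)
    pieces.append(model.sequence[cur:hi])
    refpos.append(np.arange(cur, hi))
    return "".join(pieces), np.concatenate(refpos)


def _truth_cigar(refpos: np.ndarray) -> tuple[int, list[tuple[str, int]]]:
    """CIGAR of a haplotype slice against the reference, from its
    reference-coordinate map.  Returns (ref_start, cigar)."""
    ops: list[tuple[str, int]] = []
    start = -1
    prev = -1
    for rp in refpos:
        rp = int(rp)
        if rp < 0:
            op = "I"
        elif prev < 0 or start < 0:
            op = "M"
        else:
            gap = rp - prev - 1
            if gap > 0:
                ops.append(("D", gap))
            op = "M"
        if rp >= 0 and start < 0:
            start = rp
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
        if rp >= 0:
            prev = rp
    if start < 0:
        raise ValueError("read consists only of inserted bases")
    # leading insertions are soft artifacts of the truth map; fold into M
    return start, ops


def _event_ref_span(model: ParalogLocusModel, hap: str, exon_labels) -> tuple[int, int]:
    first = model.gene_exon(exon_labels[0])
    last = model.gene_exon(exon_labels[-1])
    span = (first[0], last[1])
    if paralog_of_haplotype(hap) == "pseudogene":
        off = model.homology_offset
        span = (span[0] + off, span[1] + off)
    return span


def simulate_reads(
    sample: SampleGenome, model: ParalogLocusModel, config: ReadSimConfig
) -> list[SimRead]:
    """Simulate paired 115 bp (by default) reads from a sample genome.

    Fragment midpoints are uniform over each source haplotype; fragment
    lengths are uniform over ``fragment_range``.  ``mean_depth`` is the
    per-paralog-region coverage (each haplotype contributes half), so in
    hybrid-capture mode aggregating both paralogs onto one locus yields
    roughly twice ``mean_depth``.  Copy events modulate fragment
    sampling: deletions drop fragments whose midpoint falls in the event
    span on that haplotype; duplications emit an extra copy of such
    fragments.
    """
    rng = np.random.default_rng(config.seed)
    if config.mode == "hybrid_capture":
        haps = list(HAPLOTYPES)
    elif config.mode == "amplicon_gene":
        haps = list(GENE_HAPLOTYPES)
    else:
        haps = list(PSEUDO_HAPLOTYPES)

    read_len = config.read_length
    reads: list[SimRead] = []
    serial = 0
    for hap in haps:
        hapseq, refpos = _haplotype_sequence(model, sample, hap)
        L = len(hapseq)
        n_frag = int(round(config.mean_depth / 2.0 * L / (2.0 * read_len)))
        events = [e for e in sample.copy_events if e.haplotype == hap]

        dropped_allele = False
        if config.mode != "hybrid_capture":
            # a deletion removing the primer-proximal exon kills the allele
            primer_label = model.gene_exon_labels[0]
            for e in events:
                if e.delta == -1 and primer_label in e.exon_labels:
                    warnings.warn(
                        f"{sample.sample_id}/{hap}: primer-site exon deleted; "
                        "allele drops out of the amplicon",
                        stacklevel=2,
                    )
                    dropped_allele = True
        if dropped_allele:
            continue

        retain = 1.0
        if config.mode != "hybrid_capture" and hap.endswith("_h2"):
            retain = config.dropout_fraction

        frag_lo, frag_hi = config.fragment_range
        mids = rng.integers(0, L, size=n_frag)
        flens = rng.integers(frag_lo, min(frag_hi, L) + 1, size=n_frag)
        starts = np.clip(mids - flens // 2, 0, L - flens)
        keep = np.ones(n_frag, dtype=bool)
        if retain < 1.0:
            keep &= rng.random(n_frag) < retain
        copies = np.ones(n_frag, dtype=np.int64)
        for e in events:
            s, t = _event_ref_span(model, hap, e.exon_labels)
            # fragment spans in reference coordinates (via the map); a
            # deleted span removes the DNA, so any overlapping fragment
            # goes with it
            frag_ref_lo = refpos[starts]
            frag_ref_hi = refpos[np.minimum(starts + flens, L) - 1] + 1
            overlaps = (frag_ref_lo < t) & (frag_ref_hi > s)
            if e.delta == -1:
                keep &= ~overlaps
            else:
                copies = copies + overlaps.astype(np.int64)

        for i in np.nonzero(keep)[0]:
            flen = int(flens[i])
            start = int(starts[i])
            for _ in range(int(copies[i])):
                rid = f"{sample.sample_id}.{serial}"
                serial += 1
                r1_slice = (start, start + read_len)
                pieces = [(1, "+", r1_slice)]
                if config.paired:
                    r2_slice = (start + flen - read_len, start + flen)
                    pieces.append((2, "-", r2_slice))
                for mate, strand, (a, b) in pieces:
                    sub = hapseq[a:b]
                    ref_start, cigar = _truth_cigar(refpos[a:b])
                    if strand == "-":
                        sub = revcomp(sub)
                    if config.error_rate > 0.0:
                        sub = _apply_errors(sub, config.error_rate, rng)
                    reads.append(
                        SimRead(rid, mate, sub, hap, strand, ref_start, cigar, sample.sample_id)
                    )
    return reads


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    out = list(seq)
    for i in np.nonzero(mask)[0]:
        out[i] = str(rng.choice([b for b in BASES if b != out[i]]))
    return "".join(out)


def realized_depth(reads, region: tuple[int, int]) -> float:
    """Mean per-base coverage over ``region``.

    Accepts simulated reads (truth placements) or alignments (anything
    with ``target_pos``/``cigar``).
    """
    lo, hi = region
    cov = np.zeros(hi - lo, dtype=np.int64)
    for r in reads:
        pos = r.ref_start if hasattr(r, "ref_start") else r.target_pos
        for op, n in r.cigar:
            if op == "M":
                a = max(pos, lo)
                b = min(pos + n, hi)
                if b > a:
                    cov[a - lo : b - lo] += 1
                pos += n
            elif op == "D":
                pos += n
    return float(cov.mean())


# ---------------------------------------------------------------------------
# Text-format output
# ---------------------------------------------------------------------------

def write_fastq(reads: list[SimRead], r1_path, r2_path=None) -> None:
    """Phred+33 FASTQ; constant Q40 qualities (errors are already in the
    base calls)."""
    handles = {1: open(r1_path, "w")}
    if r2_path is not None:
        handles[2] = open(r2_path, "w")
    try:
        for r in reads:
            fh = handles.get(r.mate)
            if fh is None:
                continue
            fh.write(f"@{r.read_id}/{r.mate}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
    finally:
        for fh in handles.values():
            fh.close()


def write_truth_sam(reads: list[SimRead], model: ParalogLocusModel, path) -> None:
    """SAM with truth placements and an ``XO`` origin tag per read."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": model.contig_name, "LN": len(model.sequence)}],
    }
    _cig = {"M": 0, "I": 1, "D": 2}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.aligned_seq
            flag = 0
            if r.mate:
                flag |= 1  # paired
                flag |= 64 if r.mate == 1 else 128
            if r.strand == "-":
                flag |= 16
            a.flag = flag
            a.reference_id = 0
            a.reference_start = r.ref_start
            a.mapping_quality = 60
            a.cigartuples = [(_cig[op], n) for op, n in r.cigar]
            a.set_tag("XO", r.origin)
            a.set_tag("XS", r.sample_id)
            out.write(a)
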