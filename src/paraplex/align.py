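"""Permissive seed-and-extend alignment and paralog-aware read pairing.

The alignment stage deliberately emits *all* plausible placements of a
read (both the genic and the pseudogenic location of a homologous
fragment); downstream pairing and aggregation decide what to keep.  The
scoring scheme is match +1 / mismatch -1 / gap open -2 / gap extend -1
with an alignment score threshold of 20 and exact 11-mer seeds; a gap of
length L costs open + (L-1)*extend.

Short queries (<= ``_EXACT_QUERY_LEN``) are aligned with a full
affine-gap Smith-Waterman on each seeded window, which is exact.
Production-length reads use a fast path: local max-subarray scoring on
each seed diagonal, with a two-diagonal combination step that handles a
single indel exactly; this is what the read simulator can produce.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np

from .locus import ParalogLocusModel
from .reads import SimRead, revcomp

_EXACT_QUERY_LEN = 60  # full-DP path for queries up to this length


@dataclass(frozen=True)
class AlignParams:
    seed_len: int = 11
    match: int = 1
    mismatch_penalty: int = 1
    gap_open: int = 2
    gap_extend: int = 1
    min_score: int = 20
    emit_all: bool = True
    max_pair_sep: int = 1000


DEFAULT_PARAMS = AlignParams()


@dataclass
class SeAlignment:
    """Single-end local alignment of one read mate."""

    read_id: str
    mate_index: int
    target: str
    target_pos: int  # 0-based start of the aligned reference span
    cigar: list[tuple[str, int]]
    strand: str
    score: int
    query_start: int
    query_end: int
    read_seq: str  # full read in forward-reference orientation
    origin: str | None = None  # truth tag when available

    @property
    def target_end(self) -> int:
        return self.target_pos + sum(n for op, n in self.cigar if op in "MD")

    def consumed_query(self) -> int:
        return sum(n for op, n in self.cigar if op in "MI")

    def base_at(self, ref_pos: int) -> str | None:
        """Read base aligned over ``ref_pos`` (None if not covered or
        deleted)."""
        rp = self.target_pos
        qp = self.query_start
        for op, n in self.cigar:
            if op == "M":
                if rp <= ref_pos < rp + n:
                    return self.read_seq[qp + (ref_pos - rp)]
                rp += n
                qp += n
            elif op == "D":
                if rp <= ref_pos < rp + n:
                    return None
                rp += n
            elif op == "I":
                qp += n
        return None


@dataclass
class PairedAlignment:
    read_id: str
    alignment_1: SeAlignment
    alignment_2: SeAlignment
    pair_score: int


def recompute_score(aln: SeAlignment, reference: str, params: AlignParams = DEFAULT_PARAMS) -> int:
    """Score of an alignment recomputed from its CIGAR (invariant check)."""
    score = 0
    rp, qp = aln.target_pos, aln.query_start
    for op, n in aln.cigar:
        if op == "M":
            for i in range(n):
                if aln.read_seq[qp + i] == reference[rp + i]:
                    score += params.match
                else:
                    score -= params.mismatch_penalty
            rp += n
            qp += n
        else:
            score -= params.gap_open + (n - 1) * params.gap_extend
            if op == "D":
                rp += n
            else:
                qp += n
    return score


# ---------------------------------------------------------------------------
# Exact affine-gap local DP (small queries and seeded windows)
# ---------------------------------------------------------------------------

def smith_waterman(
    query: str, ref: str, params: AlignParams = DEFAULT_PARAMS
) -> tuple[int, int, int, int, int, list[tuple[str, int]]]:
    """Best local alignment (score, qstart, qend, rstart, rend, cigar).

    Full O(nm) affine-gap DP with traceback.  E = gap consuming the
    reference (D), F = gap consuming the query (I).
    """
    n, m = len(query), len(ref)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = (0, 0, 0)
    go, ge, ma, mi = params.gap_open, params.gap_extend, params.match, params.mismatch_penalty
    for i in range(1, n + 1):
        qi = query[i - 1]
        Hi, Hp = H[i], H[i - 1]
        Ei, Fi, Fp = E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            e = max(Hi[j - 1] - go, Ei[j - 1] - ge)
            f = max(Hp[j] - go, Fp[j] - ge)
            d = Hp[j - 1] + (ma if qi == ref[j - 1] else -mi)
            h = max(0, d, e, f)
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best[0]:
                best = (h, i, j)
    score, i, j = best
    if score == 0:
        return 0, 0, 0, 0, 0, []
    # traceback
    ops: list[str] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            d = H[i - 1][j - 1] + (ma if query[i - 1] == ref[j - 1] else -mi)
            if h == d:
                ops.append("M")
                i -= 1
                j -= 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")
            if E[i][j] == H[i][j - 1] - go:
                state = "H"
            j -= 1
        else:
            ops.append("I")
            if F[i][j] == H[i - 1][j] - go:
                state = "H"
            i -= 1
    qstart, rstart = i, j
    _, qi, rj = best
    cigar: list[tuple[str, int]] = []
    for op in reversed(ops):
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return score, qstart, qi, rstart, rj, cigar


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

class SeedIndex:
    """Exact k-mer index of one reference sequence (all k-mers, no
    sampling — loci are tiny, exhaustiveness beats speed)."""

    def __init__(self, name: str, seq: str, k: int = 11):
        self.name = name
        self.seq = seq
        self.k = k
        idx: dict[str, list[int]] = defaultdict(list)
        for i in range(len(seq) - k + 1):
            idx[seq[i : i + k]].append(i)
        self.index = {kmer: np.asarray(v, dtype=np.int64) for kmer, v in idx.items()}
        self.arr = np.frombuffer(seq.encode(), dtype=np.uint8)

    def diagonals(self, query: str) -> np.ndarray:
        k = self.k
        hits: list[np.ndarray] = []
        for q in range(len(query) - k + 1):
            pos = self.index.get(query[q : q + k])
            if pos is not None:
                hits.append(pos - q)
        if not hits:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(hits))


def _cluster_diagonals(diags: np.ndarray, band: int = 30) -> list[np.ndarray]:
    if diags.size == 0:
        return []
    splits = np.nonzero(np.diff(diags) > band)[0] + 1
    return np.split(diags, splits)


def _diagonal_local(query_arr, ref_arr, d, ma, mi):
    """Best gapless local segment on diagonal d.

    Returns (score, qstart, qend); reference span is [qstart+d, qend+d).
    """
    n, m = len(query_arr), len(ref_arr)
    qa = max(0, -d)
    qb = min(n, m - d)
    if qb - qa <= 0:
        return 0, 0, 0
    s = np.where(query_arr[qa:qb] == ref_arr[qa + d : qb + d], ma, -mi)
    p = np.concatenate(([0], np.cumsum(s)))
    runmin = np.minimum.accumulate(p[:-1])
    gains = p[1:] - runmin
    best = int(np.argmax(gains))
    score = int(gains[best])
    end = best + 1
    start = int(np.argmin(p[: end]))
    return score, qa + start, qa + end


def _two_diagonal_local(query_arr, ref_arr, d1, d2, params):
    """Best single-indel alignment using prefix on d1 and suffix on d2.

    d2 > d1 means a deletion (reference bases skipped); d2 < d1 an
    insertion (query bases skipped).  Returns (score, qstart, qend,
    cigar, rstart) or None.
    """
    ma, mi = params.match, params.mismatch_penalty
    n, m = len(query_arr), len(ref_arr)
    gap = abs(d2 - d1)
    gap_cost = params.gap_open + (gap - 1) * params.gap_extend

    def diag_scores(d):
        qa = max(0, -d)
        qb = min(n, m - d)
        if qb - qa <= 0:
            return None, qa, qb
        return np.where(query_arr[qa:qb] == ref_arr[qa + d : qb + d], ma, -mi), qa, qb

    s1, a1, b1 = diag_scores(d1)
    s2, a2, b2 = diag_scores(d2)
    if s1 is None or s2 is None:
        return None
    # bestP[i]: best suffix-free local prefix on d1 ending exactly at query i
    p1 = np.concatenate(([0], np.cumsum(s1)))
    runmin = np.minimum.accumulate(p1)
    bestP = p1 - runmin  # index i-a1
    startP = np.array([int(np.argmin(p1[: i + 1])) for i in range(len(p1))])
    # bestS[i]: best local suffix on d2 starting exactly at query i
    p2 = np.concatenate(([0], np.cumsum(s2)))
    runmax = np.maximum.accumulate(p2[::-1])[::-1]
    bestS = runmax - p2
    endS = np.array(
        [len(p2) - 1 - int(np.argmax(p2[::-1][: len(p2) - i])) for i in range(len(p2))]
    )

    best = None
    if d2 > d1:  # deletion: query split point shared
        lo = max(a1 + 1, a2)
        hi = min(b1, b2 - 1) + 1
        for i in range(lo, hi):
            sc = bestP[i - a1] + bestS[i - a2] - gap_cost
            if bestP[i - a1] <= 0 or bestS[i - a2] <= 0:
                continue
            if best is None or sc > best[0]:
                best = (int(sc), i)
        if best is None:
            return None
        sc, i = best
        qs = a1 + startP[i - a1]
        qe = a2 + endS[i - a2]
        cigar = [("M", i - qs), ("D", gap), ("M", qe - i)]
        return sc, qs, qe, cigar, qs + d1
    else:  # insertion: query skips `gap` bases between the parts
        lo = max(a1 + 1, a2 - gap)
        hi = min(b1, b2 - gap - 1) + 1
        for i in range(lo, hi):
            j = i + gap
            sc = bestP[i - a1] + bestS[j - a2] - gap_cost
            if bestP[i - a1] <= 0 or bestS[j - a2] <= 0:
                continue
            if best is None or sc > best[0]:
                best = (int(sc), i)
        if best is None:
            return None
        sc, i = best
        qs = a1 + startP[i - a1]
        qe = a2 + endS[i + gap - a2]
        cigar = [("M", i - qs), ("I", gap), ("M", qe - (i + gap))]
        return sc, qs, qe, cigar, qs + d1


def _align_to_index(
    query: str, index: SeedIndex, params: AlignParams
) -> list[tuple[int, int, int, int, list[tuple[str, int]]]]:
    """All seeded local alignments of ``query`` (one orientation) against
    one reference.  Returns tuples (score, qstart, qend, rstart, cigar)."""
    diags = index.diagonals(query)
    if diags.size == 0:
        return []
    q_arr = np.frombuffer(query.encode(), dtype=np.uint8)
    results = []
    for cluster in _cluster_diagonals(diags):
        if len(query) <= _EXACT_QUERY_LEN:
            pad = 8
            lo = max(0, int(cluster.min()) - pad)
            hi = min(len(index.seq), int(cluster.max()) + len(query) + pad)
            score, qs, qe, rs, re, cigar = smith_waterman(query, index.seq[lo:hi], params)
            if score >= params.min_score and cigar:
                results.append((score, qs, qe, lo + rs, cigar))
            continue
        best = None
        for d in cluster:
            sc, qs, qe = _diagonal_local(q_arr, index.arr, int(d), params.match, params.mismatch_penalty)
            cand = (sc, qs, qe, qs + int(d), [("M", qe - qs)])
            if best is None or sc > best[0]:
                best = cand
        if len(cluster) > 1:
            ds = [int(d) for d in cluster]
            for i in range(len(ds)):
                for j in range(len(ds)):
                    if i == j:
                        continue
                    out = _two_diagonal_local(q_arr, index.arr, ds[i], ds[j], params)
                    if out is not None and out[0] > best[0]:
                        sc, qs, qe, cigar, rstart = out
                        best = (sc, qs, qe, rstart, cigar)
        if best is not None and best[0] >= params.min_score:
            results.append(best)
    return results


def seed_and_extend(
    read, references, params: AlignParams = DEFAULT_PARAMS, indexes=None
) -> list[SeAlignment]:
    """Emit all alignments of a read with score >= the threshold.

    ``read`` may be a :class:`~paraplex.reads.SimRead`, an
    ``(id, sequence)`` pair, or a bare sequence string.  ``references``
    is a mapping ``name -> sequence`` (or a single string).  Both
    orientations of the read are tried.
    """
    if isinstance(read, SimRead):
        rid, seq, mate, origin = read.read_id, read.seq, read.mate, read.origin
    elif isinstance(read, str):
        rid, seq, mate, origin = "read", read, 1, None
    else:
        rid, seq = read
        mate, origin = 1, None
    if isinstance(references, str):
        references = {"ref": references}
    if not references or any(len(s) == 0 for s in references.values()):
        raise ValueError("empty reference")
    if len(seq) < params.seed_len:
        raise ValueError("read shorter than the seed length")
    if indexes is None:
        indexes = {name: SeedIndex(name, s, params.seed_len) for name, s in references.items()}

    alignments: list[SeAlignment] = []
    seen: set[tuple[str, int, str]] = set()
    for name, index in indexes.items():
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            for score, qs, qe, rstart, cigar in _align_to_index(oriented, index, params):
                key = (name, rstart, strand)
                if key in seen:
                    continue
                seen.add(key)
                alignments.append(
                    SeAlignment(
                        read_id=rid,
                        mate_index=mate,
                        target=name,
                        target_pos=rstart,
                        cigar=cigar,
                        strand=strand,
                        score=score,
                        query_start=qs,
                        query_end=qe,
                        read_seq=oriented,
                        origin=origin,
                    )
                )
    alignments.sort(key=lambda a: -a.score)
    if not params.emit_all and alignments:
        return alignments[:1]
    return alignments


def align_reads(
    reads: list[SimRead],
    model: ParalogLocusModel,
    params: AlignParams = DEFAULT_PARAMS,
) -> dict[str, dict[int, list[SeAlignment]]]:
    """Align a batch of simulated reads against the locus contig.

    Returns ``{read_id: {mate: [alignments]}}``.
    """
    index = {model.contig_name: SeedIndex(model.contig_name, model.sequence, params.seed_len)}
    out: dict[str, dict[int, list[SeAlignment]]] = defaultdict(dict)
    for read in reads:
        alns = seed_and_extend(read, {model.contig_name: model.sequence}, params, indexes=index)
        out[read.read_id][read.mate] = alns
    return out


# ---------------------------------------------------------------------------
# Pairing (four-rule pair rescue) and aggregation
# ---------------------------------------------------------------------------

def _in_region(aln: SeAlignment, region: tuple[int, int]) -> bool:
    return region[0] <= aln.target_pos < region[1]


def pair_alignments(
    alignments_mate1: list[SeAlignment],
    alignments_mate2: list[SeAlignment],
    region: tuple[int, int],
    params: AlignParams = DEFAULT_PARAMS,
    copy_regions: list[tuple[int, int]] | None = None,
) -> list[PairedAlignment]:
    """Pair two mates' alignment lists under the four rules: same read
    name, both inside ``region``, starts within 1000 bp, and the
    highest-scoring pair wins.  On an exact score tie between different
    locus copies (``copy_regions``), one pair per copy is kept — this is
    what stacks four copies at one locus.
    """
    candidates: list[PairedAlignment] = []
    for a1 in alignments_mate1:
        for a2 in alignments_mate2:
            if a1.read_id != a2.read_id:
                continue
            if not (_in_region(a1, region) and _in_region(a2, region)):
                continue
            if abs(a1.target_pos - a2.target_pos) > params.max_pair_sep:
                continue
            candidates.append(PairedAlignment(a1.read_id, a1, a2, a1.score + a2.score))
    if not candidates:
        return []
    best = max(c.pair_score for c in candidates)
    winners = [c for c in candidates if c.pair_score == best]
    if len(winners) == 1:
        return winners
    if copy_regions:
        kept: list[PairedAlignment] = []
        used: set[int] = set()
        for c in winners:
            for i, reg in enumerate(copy_regions):
                if i not in used and _in_region(c.alignment_1, reg):
                    kept.append(c)
                    used.add(i)
                    break
        if kept:
            return kept
    return winners[:1]


def pair_all(
    aligned: dict[str, dict[int, list[SeAlignment]]],
    region: tuple[int, int],
    params: AlignParams = DEFAULT_PARAMS,
    copy_regions: list[tuple[int, int]] | None = None,
) -> tuple[list[PairedAlignment], int]:
    """Apply pairing across a batch; returns (pairs, n_discarded_reads)."""
    pairs: list[PairedAlignment] = []
    discarded = 0
    for rid, by_mate in aligned.items():
        got = pair_alignments(
            by_mate.get(1, []), by_mate.get(2, []), region, params, copy_regions
        )
        if got:
            pairs.extend(got)
        else:
            discarded += 1
    return pairs, discarded


def aggregate_exons12_15(
    pairs: list[PairedAlignment], model: ParalogLocusModel
) -> list[SeAlignment]:
    """Stack paired alignments onto the gene copy.

    Alignments already at the gene locus pass through; any positioned in
    the pseudogene region are translated to the homologous gene
    coordinate.  Truth origin tags are preserved for evaluation.
    """
    off = model.homology_offset
    plo, phi = model.pseudogene_region
    out: list[SeAlignment] = []
    for pair in pairs:
        for aln in (pair.alignment_1, pair.alignment_2):
            if plo <= aln.target_pos < phi:
                aln = replace(aln, target_pos=aln.target_pos - off)
            out.append(aln)
    return out


def partition_exon11_reads(
    alignments: list[SeAlignment],
    catalog,
    exon11: tuple[int, int],
) -> dict[str, list[SeAlignment]]:
    """Partition gene-positioned exon-11 reads by distinguishing bases.

    A read (pair) is kept only if it overlaps at least one *reliable*
    distinguishing site and every overlapped reliable site carries the
    same paralog's allele on every mate; conflicts and site-free reads
    are discarded.  Raises if the catalog has no reliable exon-11 site.
    """
    sites = [
        s
        for s in catalog.sites
        if s.reliable and exon11[0] <= s.gene_pos < exon11[1]
    ]
    if not sites:
        raise ValueError("no reliable distinguishing site in exon 11; "
                         "gene-specific exon-11 calling is impossible")
    by_read: dict[str, list[SeAlignment]] = defaultdict(list)
    for aln in alignments:
        by_read[aln.read_id].append(aln)
    out = {"gene_reads": [], "pseudogene_reads": [], "discarded": []}
    for rid, alns in by_read.items():
        votes: set[str] = set()
        covered = False
        for aln in alns:
            for s in sites:
                base = aln.base_at(s.gene_pos)
                if base is None:
                    continue
                covered = True
                if base == s.gene_allele:
                    votes.add("gene")
                elif base == s.pseudogene_allele:
                    votes.add("pseudogene")
                else:
                    votes.add("other")
        if not covered or len(votes) != 1 or "other" in votes:
            out["discarded"].extend(alns)
        elif votes == {"gene"}:
            out["gene_reads"].extend(alns)
        else:
            out["pseudogene_reads"].extend(alns)
    return out
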