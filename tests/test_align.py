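import numpy as np
import pytest

from paraplex import (
    AlignParams,
    ReadSimConfig,
    SampleGenome,
    Variant,
    pair_alignments,
    partition_exon11_reads,
    seed_and_extend,
    simulate_reads,
    smith_waterman,
)
from paraplex.align import SeAlignment, aggregate_exons12_15, recompute_score

BASES = "ACGT"


def sw_oracle_score(query, ref, match=1, mismatch=1, gap_open=2, gap_extend=1):
    """Independent full-matrix affine local-alignment score (numpy,
    scoring only).  Gap of length L costs open + (L-1)*extend."""
    n, m = len(query), len(ref)
    NEG = -(10**9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            sub = match if q[i - 1] == r[j - 1] else -mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
    return int(H.max())


def mutate(seq, rng, n_sub=0, indel=None):
    s = list(seq)
    for _ in range(n_sub):
        i = int(rng.integers(len(s)))
        s[i] = BASES[(BASES.index(s[i]) + 1 + int(rng.integers(3))) % 4]
    if indel == "del":
        i = int(rng.integers(5, len(s) - 5))
        del s[i : i + int(rng.integers(1, 4))]
    elif indel == "ins":
        i = int(rng.integers(5, len(s) - 5))
        s[i:i] = rng.choice(list(BASES), size=int(rng.integers(1, 4)))
    return "".join(s)


def test_scores_match_smith_waterman_oracle():
    """Seeded emit-all alignment scores equal exhaustive local-DP scores
    on small instances wherever an exact 11-mer seed exists."""
    rng = np.random.default_rng(2024)
    params = AlignParams(min_score=12)
    for trial in range(60):
        ref = "".join(rng.choice(list(BASES), size=int(rng.integers(60, 300))))
        qlen = int(rng.integers(20, 51))
        start = int(rng.integers(0, len(ref) - qlen))
        kind = ("exact", "subs", "del", "ins")[trial % 4]
        query = ref[start : start + qlen]
        if kind == "subs":
            query = mutate(query, rng, n_sub=int(rng.integers(1, 4)))
        elif kind in ("del", "ins"):
            query = mutate(query, rng, indel=kind)
        if len(query) < 12:
            continue
        has_seed = any(query[i : i + 11] in ref for i in range(len(query) - 10))
        if not has_seed:
            continue
        oracle = sw_oracle_score(query, ref)
        got = seed_and_extend(query, {"r": ref}, params)
        got_plus = [a.score for a in got if a.strand == "+"]
        if oracle >= params.min_score:
            assert got_plus and max(got_plus) == oracle
        else:
            assert not got_plus


def test_internal_dp_agrees_with_oracle():
    rng = np.random.default_rng(7)
    for _ in range(25):
        ref = "".join(rng.choice(list(BASES), size=120))
        query = mutate(ref[20:70], rng, n_sub=2, indel="del")
        score, qs, qe, rs, re, cigar = smith_waterman(query, ref)
        assert score == sw_oracle_score(query, ref)


def test_read_identical_to_both_paralogs_gets_two_full_score_alignments(default_locus):
    # exon 12 has no distinguishing bases: the read sits in both copies
    gs, _ = default_locus.gene_exon(12)
    read = default_locus.sequence[gs : gs + 115]
    alns = seed_and_extend(read, {default_locus.contig_name: default_locus.sequence})
    full = [a for a in alns if a.score == 115]
    assert len(full) == 2
    positions = sorted(a.target_pos for a in full)
    assert positions == [gs, gs + default_locus.homology_offset]


def test_alignment_score_threshold_boundary():
    rng = np.random.default_rng(1)
    ref = "".join(rng.choice(list(BASES), size=200))
    # best local segment scores 19 -> suppressed
    query19 = ref[50:69] + ("A" if ref[69] != "A" else "C") * 6
    assert sw_oracle_score(query19, ref) == 19
    assert seed_and_extend(query19, {"r": ref}) == []
    # 21 clean matches -> emitted
    query21 = ref[50:71]
    alns = seed_and_extend(query21, {"r": ref})
    assert any(a.score == 21 for a in alns)


def test_single_mismatch_read_scores_113(default_locus):
    gs, _ = default_locus.gene_exon(12)
    read = list(default_locus.sequence[gs : gs + 115])
    read[57] = "A" if read[57] != "A" else "G"
    alns = seed_and_extend("".join(read), {default_locus.contig_name: default_locus.sequence})
    assert max(a.score for a in alns) == 113


def test_emitted_scores_recompute_from_cigar(default_locus):
    gs, _ = default_locus.gene_exon(13)
    read = default_locus.sequence[gs : gs + 80] + default_locus.sequence[gs + 82 : gs + 117]
    for a in seed_and_extend(read, {default_locus.contig_name: default_locus.sequence}):
        assert recompute_score(a, default_locus.sequence) == a.score
        assert a.query_end - a.query_start == a.consumed_query()


def test_empty_reference_rejected():
    with pytest.raises(ValueError):
        seed_and_extend("ACGTACGTACGTACGT", {"r": ""})


def _aln(read_id, pos, score, mate=1):
    return SeAlignment(read_id, mate, "ref", pos, [("M", 100)], "+", score, 0, 100, "A" * 100)


class TestPairing:
    REGION = (0, 5000)

    def test_mates_within_1000bp_pair(self):
        pairs = pair_alignments([_aln("r", 100, 100)], [_aln("r", 400, 100, 2)], self.REGION)
        assert len(pairs) == 1
        assert pairs[0].pair_score == 200

    def test_mates_1500bp_apart_do_not_pair(self):
        assert pair_alignments([_aln("r", 100, 100)], [_aln("r", 1600, 100, 2)], self.REGION) == []

    def test_highest_scoring_pair_wins(self):
        m1 = [_aln("r", 100, 115), _aln("r", 2100, 110)]
        m2 = [_aln("r", 400, 110, 2), _aln("r", 2400, 100, 2)]
        pairs = pair_alignments(m1, m2, self.REGION)
        assert len(pairs) == 1
        assert pairs[0].pair_score == 225
        assert pairs[0].alignment_1.target_pos == 100

    def test_outside_region_discarded(self):
        assert pair_alignments([_aln("r", 100, 100)], [_aln("r", 400, 100, 2)], (1000, 2000)) == []

    def test_score_tie_keeps_one_pair_per_locus_copy(self):
        m1 = [_aln("r", 100, 115), _aln("r", 3100, 115)]
        m2 = [_aln("r", 400, 115, 2), _aln("r", 3400, 115, 2)]
        pairs = pair_alignments(
            m1, m2, self.REGION, copy_regions=[(0, 3000), (3000, 5000)]
        )
        assert len(pairs) == 2
        assert sorted(p.alignment_1.target_pos for p in pairs) == [100, 3100]


class TestPartition:
    def _read_over_site(self, site, allele, model, read_id="r1"):
        pos = site.gene_pos - 50
        seq = list(model.sequence[pos : pos + 115])
        seq[50] = allele
        return SeAlignment(read_id, 1, model.contig_name, pos, [("M", 115)], "+", 113, 0, 115, "".join(seq))

    def test_gene_allele_read_goes_to_gene(self, small_locus, small_catalog):
        site = small_catalog.reliable_sites()[0]
        aln = self._read_over_site(site, site.gene_allele, small_locus)
        out = partition_exon11_reads([aln], small_catalog, small_locus.gene_exon(11))
        assert out["gene_reads"] == [aln]

    def test_pseudogene_allele_read_goes_to_pseudogene(self, small_locus, small_catalog):
        site = small_catalog.reliable_sites()[0]
        aln = self._read_over_site(site, site.pseudogene_allele, small_locus)
        out = partition_exon11_reads([aln], small_catalog, small_locus.gene_exon(11))
        assert out["pseudogene_reads"] == [aln]

    def test_read_over_no_reliable_site_discarded(self, small_locus, small_catalog):
        gs, _ = small_locus.gene_exon(12)  # exon 12 has no sites
        aln = SeAlignment(
            "r2", 1, small_locus.contig_name, gs, [("M", 115)], "+", 115, 0, 115,
            small_locus.sequence[gs : gs + 115],
        )
        out = partition_exon11_reads([aln], small_catalog, small_locus.gene_exon(11))
        assert out["discarded"] == [aln]

    def test_conflicting_sites_discarded(self, small_locus, small_catalog):
        sites = sorted(small_catalog.reliable_sites(), key=lambda s: s.gene_pos)
        s1, s2 = sites[0], sites[1]
        pos = s1.gene_pos - 10
        span = s2.gene_pos - pos + 10
        seq = list(small_locus.sequence[pos : pos + span])
        seq[s1.gene_pos - pos] = s1.gene_allele
        seq[s2.gene_pos - pos] = s2.pseudogene_allele
        aln = SeAlignment("r3", 1, small_locus.contig_name, pos, [("M", span)], "+", span - 4, 0, span, "".join(seq))
        out = partition_exon11_reads([aln], small_catalog, small_locus.gene_exon(11))
        assert out["discarded"] == [aln]

    def test_no_reliable_sites_is_an_error(self, small_locus, small_catalog):
        from paraplex.catalog import SiteCatalog
        import dataclasses

        dead = SiteCatalog(
            [dataclasses.replace(s, reliable=False) for s in small_catalog.sites]
        )
        with pytest.raises(ValueError, match="exon"):
            partition_exon11_reads([], dead, small_locus.gene_exon(11))


def test_aggregate_translates_pseudogene_pairs_to_gene_coords(small_locus):
    from paraplex.align import PairedAlignment

    off = small_locus.homology_offset
    ps, _ = small_locus.pseudogene_exons[1]
    a1 = SeAlignment("r", 1, small_locus.contig_name, ps, [("M", 115)], "+", 115, 0, 115, "A" * 115)
    a2 = SeAlignment("r", 2, small_locus.contig_name, ps + 200, [("M", 115)], "-", 115, 0, 115, "A" * 115)
    out = aggregate_exons12_15([PairedAlignment("r", a1, a2, 230)], small_locus)
    assert sorted(a.target_pos for a in out) == [ps - off, ps + 200 - off]
    assert aggregate_exons12_15([], small_locus) == []


def test_error_free_pairs_from_exons12_15_survive_pairing(small_locus):
    """>= 99.9% of error-free hybrid-capture pairs whose fragments lie
    in the exon 12-15 span survive the four pairing rules."""
    from paraplex.align import align_reads, pair_all
    from paraplex.pipeline import exon12_15_span

    cfg = ReadSimConfig(mean_depth=120, error_rate=0.0, seed=21)
    reads = simulate_reads(SampleGenome("P0"), small_locus, cfg)
    span = exon12_15_span(small_locus)
    off = small_locus.homology_offset

    def frag_in_span(r1, r2):
        lo = min(r1.ref_start, r2.ref_start)
        hi = max(r1.ref_start + 115, r2.ref_start + 115)
        if lo >= small_locus.pseudogene_region[0]:
            lo, hi = lo - off, hi - off
        return span[0] <= lo and hi <= span[1]

    by_id = {}
    for r in reads:
        by_id.setdefault(r.read_id, {})[r.mate] = r
    target_ids = {
        rid for rid, mates in by_id.items()
        if len(mates) == 2 and frag_in_span(mates[1], mates[2])
    }
    assert len(target_ids) > 200
    aligned = align_reads([r for r in reads if r.read_id in target_ids], small_locus)
    pairs, _ = pair_all(aligned, (span[0] - 700, span[1] + 700))
    paired_ids = {p.read_id for p in pairs}
    assert len(paired_ids & target_ids) / len(target_ids) >= 0.999
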