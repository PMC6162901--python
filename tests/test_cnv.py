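import itertools
import math

import numpy as np
import pytest

from paraplex import DepthMatrix, bin_depths, call_cnv, call_cnv_exon11, make_bins, normalize
from paraplex.align import SeAlignment
from paraplex.cnv import RETURN_TO_BASELINE, estimate_sigma, viterbi_path


def brute_force_best_path(row, sigma, baseline, p_cnv):
    """Exhaustive enumeration over all 3^n copy-state paths using an
    independently written joint log-probability."""
    def trans(a, b):  # states as copy numbers
        if a == baseline:
            return 1 - p_cnv if b == baseline else p_cnv / 2
        if b == baseline:
            return RETURN_TO_BASELINE
        if b == a:
            return 1 - RETURN_TO_BASELINE - p_cnv / 2
        return p_cnv / 2

    def emit(copy, x, s):
        mu = copy / baseline
        return -0.5 * ((x - mu) / s) ** 2 - math.log(s) - 0.5 * math.log(2 * math.pi)

    states = (baseline - 1, baseline, baseline + 1)
    best = (-math.inf, None)
    for path in itertools.product(states, repeat=len(row)):
        ll = math.log(trans(baseline, path[0])) + emit(path[0], row[0], sigma[0])
        for i in range(1, len(row)):
            ll += math.log(trans(path[i - 1], path[i])) + emit(path[i], row[i], sigma[i])
        if ll > best[0]:
            best = (ll, path)
    return best


@pytest.mark.parametrize("baseline", [2, 4])
def test_viterbi_matches_exhaustive_enumeration(baseline, rng):
    for trial in range(6):
        n = int(rng.integers(4, 9))
        row = 1.0 + rng.normal(0, 0.12, size=n)
        if trial % 2:
            a, b = sorted(rng.choice(n, size=2, replace=False))
            row[a : b + 1] -= 0.25
        sigma = np.full(n, 0.07)
        states, ll = viterbi_path(row, sigma, baseline, 0.01)
        bll, bpath = brute_force_best_path(row, sigma, baseline, 0.01)
        assert ll == pytest.approx(bll, rel=1e-12)
        assert tuple(states) == bpath


class TestNormalize:
    def test_constant_matrix_becomes_all_ones(self):
        m = DepthMatrix([(i, i + 50) for i in range(0, 500, 50)], list("abcde"),
                        np.full((5, 10), 500.0))
        normalize(m)
        assert np.allclose(m.normalized, 1.0)

    def test_global_depth_scale_removed_in_stage_one(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(300, 700, size=10)
        raw = np.tile(base, (5, 1))
        raw[2] *= 2.0  # one sample sequenced twice as deep
        m = DepthMatrix([(i, i + 50) for i in range(0, 500, 50)], list("abcde"), raw)
        normalize(m)
        assert np.allclose(m.normalized[2], 1.0)

    def test_hand_computed_two_stage_medians(self):
        """5x10 matrix with one sample at 0.75 in three bins: those
        cells land at ~0.75, everything else at ~1.0 (oracle: explicit
        median arithmetic below)."""
        raw = np.full((5, 10), 400.0)
        raw[1, 3:6] = 300.0
        # oracle, computed the long way
        stage1 = raw / np.array([np.median(r) for r in raw])[:, None]
        expected = stage1 / np.array([np.median(stage1[:, j]) for j in range(10)])
        m = DepthMatrix([(i, i + 50) for i in range(0, 500, 50)], list("abcde"), raw)
        normalize(m)
        assert np.allclose(m.normalized, expected)
        assert np.allclose(m.normalized[1, 3:6], 0.75)
        assert np.allclose(m.normalized[0], 1.0)

    def test_per_bin_median_is_one_after_normalization(self):
        rng = np.random.default_rng(1)
        raw = rng.poisson(600, size=(9, 20)).astype(float)
        m = DepthMatrix([(i, i + 50) for i in range(0, 1000, 50)],
                        [f"s{i}" for i in range(9)], raw)
        normalize(m)
        assert np.allclose(np.median(m.normalized, axis=0), 1.0)

    def test_zero_median_bin_masked(self):
        raw = np.full((4, 6), 500.0)
        raw[:, 2] = 0.0
        m = DepthMatrix([(i, i + 50) for i in range(0, 300, 50)], list("abcd"), raw)
        normalize(m)
        assert not m.bin_mask[2]
        assert np.isnan(m.normalized[:, 2]).all()

    def test_requires_cohort(self):
        m = DepthMatrix([(0, 50), (50, 100)], ["a", "b"], np.full((2, 2), 10.0))
        with pytest.raises(ValueError, match="cohort"):
            normalize(m)


class TestBinDepths:
    def _aln(self, pos, length=100):
        return SeAlignment("r", 1, "ref", pos, [("M", length)], "+", length, 0, length, "A" * length)

    def test_no_reads_gives_zero_row(self):
        assert bin_depths([], [(0, 50), (50, 100)]).tolist() == [0, 0]

    def test_read_spanning_two_bins_increments_both(self):
        counts = bin_depths([self._aln(30, 40)], [(0, 50), (50, 100)])
        assert counts.tolist() == [1, 1]

    def test_start_mode_counts_once(self):
        counts = bin_depths([self._aln(30, 40)], [(0, 50), (50, 100)], mode="start")
        assert counts.tolist() == [1, 0]

    def test_counts_follow_poisson_expectation(self, small_locus):
        """Uniform 500x simulation: per-bin counts within 4 SD of the
        Poisson rate implied by the simulator's own geometry."""
        from paraplex import ReadSimConfig, SampleGenome, simulate_reads
        from paraplex.align import SeAlignment as A

        cfg = ReadSimConfig(mode="amplicon_gene", mean_depth=500, seed=13)
        reads = simulate_reads(SampleGenome("S"), small_locus, cfg)
        alns = [
            A(r.read_id, r.mate, "c", r.ref_start, r.cigar, r.strand, 115, 0, 115, r.aligned_seq)
            for r in reads
        ]
        # exon 13 sits away from the fragment-clamping edge zone
        gs, ge = small_locus.gene_exon(13)
        bins = make_bins([(gs, ge)], 50)
        counts = bin_depths(alns, bins)
        # read starts are ~uniform at density depth/read_len (both mates);
        # a read overlaps a 50 bp bin iff its start is in a 164 bp window
        lam = 500 / 115 * (50 + 115 - 1)
        assert np.all(np.abs(counts - lam) < 4 * np.sqrt(lam))


class TestCallCnv:
    BINS = [(i * 50, (i + 1) * 50) for i in range(12)]

    def test_flat_row_is_negative(self):
        calls = call_cnv(np.ones(12), 4, bins=self.BINS, sigma=0.05)
        assert [c.status for c in calls] == ["NEGATIVE"]

    def test_single_copy_deletion_on_tetraploid_background(self):
        row = np.ones(12)
        row[4:8] = 0.75
        calls = call_cnv(row, 4, bins=self.BINS, sigma=0.05)
        events = [c for c in calls if c.status == "CALL"]
        assert len(events) == 1
        assert events[0].called_copy == 3
        assert events[0].delta == -1
        assert events[0].bin_span == (4, 8)
        assert events[0].interval == (200, 400)

    def test_single_copy_deletion_on_diploid_background(self):
        row = np.ones(12)
        row[3:6] = 0.5
        calls = call_cnv(row, 2, bins=self.BINS, sigma=0.05)
        events = [c for c in calls if c.status == "CALL"]
        assert [e.called_copy for e in events] == [1]

    def test_duplication_detected_with_positive_delta(self):
        row = np.ones(12)
        row[0:4] = 1.25
        events = [c for c in call_cnv(row, 4, bins=self.BINS, sigma=0.05) if c.status == "CALL"]
        assert [e.delta for e in events] == [1]

    def test_marginal_event_is_no_call(self):
        """An event decoded on the Viterbi path but with log-odds inside
        (0, q_min) is reported as NO_CALL rather than CALL."""
        row = np.ones(12)
        row[4:8] = 0.85  # weak drop: decoded, but with low confidence
        calls = call_cnv(row, 4, bins=self.BINS, sigma=0.05, q_min=3.0)
        non_neg = [c for c in calls if c.status != "NEGATIVE"]
        assert non_neg and all(c.status == "NO_CALL" for c in non_neg)
        assert all(0.0 < c.quality < 3.0 for c in non_neg)
        # the same event with decisive evidence is a confident CALL
        row[4:8] = 0.75
        calls = call_cnv(row, 4, bins=self.BINS, sigma=0.05, q_min=3.0)
        assert any(c.status == "CALL" for c in calls)

    def test_deletion_quality_monotone_in_depth_drop(self):
        quals = []
        for ratio in (0.95, 0.9, 0.85, 0.8, 0.75):
            row = np.ones(12)
            row[4:8] = ratio
            calls = call_cnv(row, 4, bins=self.BINS, sigma=0.05)
            dels = [c for c in calls if c.delta == -1 and c.status != "NEGATIVE"]
            quals.append(max((c.quality for c in dels), default=0.0))
        assert all(b >= a for a, b in zip(quals, quals[1:]))
        assert quals[-1] > quals[0]

    def test_short_row_rejected(self):
        with pytest.raises(ValueError):
            call_cnv(np.ones(1), 4)
        with pytest.raises(ValueError):
            call_cnv(np.ones(6), 3)


class TestExon11:
    def test_gene_deletion_detected_at_baseline_two(self, rng):
        mat = rng.poisson(400, size=(20, 7)).astype(float)
        mat[3] = rng.poisson(200, size=7)
        panel = np.full(20, 400.0)
        calls = call_cnv_exon11(mat, 3, list(range(100, 170, 10)), panel_scale=panel)
        assert [(c.called_copy, c.status) for c in calls] == [(1, "CALL")]

    def test_unmutated_sample_is_negative(self, rng):
        mat = rng.poisson(400, size=(20, 7)).astype(float)
        calls = call_cnv_exon11(mat, 5, list(range(100, 170, 10)),
                                panel_scale=np.full(20, 400.0))
        assert [c.status for c in calls] == ["NEGATIVE"]

    def test_too_few_usable_sites_is_no_call(self):
        calls = call_cnv_exon11(np.full((5, 1), 100.0), 0, [42])
        assert [c.status for c in calls] == ["NO_CALL"]
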