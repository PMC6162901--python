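import numpy as np
import pytest

from paraplex import (
    contiguous_spans,
    indel_sensitivity,
    inject_cnv,
    merge_diploid_to_tetraploid,
    simulate_depth_cohort,
    weighted_aggregate_sensitivity,
)
from paraplex.align import SeAlignment
from paraplex.evalsim import cnv_sensitivity_sweep, inject_cnv_counts, round_percent


class TestInjection:
    def test_deletion_ratio_75_in_span_100_outside(self, rng):
        row = np.full(200, 1000.0)
        mask = np.zeros(200, dtype=bool)
        mask[60:120] = True
        out = inject_cnv_counts(row, mask, "deletion", rng)
        assert out[mask].mean() / 1000 == pytest.approx(0.75, abs=0.01)
        assert np.all(out[~mask] == 1000)

    def test_duplication_ratio_125(self, rng):
        row = np.full(200, 1000.0)
        mask = np.zeros(200, dtype=bool)
        mask[:80] = True
        out = inject_cnv_counts(row, mask, "duplication", rng)
        assert out[mask].mean() / 1000 == pytest.approx(1.25, abs=0.01)
        assert np.all(out[~mask] == 1000)

    def test_injection_preserves_depth_outside_span(self, rng):
        row = rng.poisson(800, size=300).astype(float)
        mask = np.zeros(300, dtype=bool)
        mask[100:150] = True
        out = inject_cnv_counts(row, mask, "deletion", rng)
        assert out[~mask].mean() / row[~mask].mean() == pytest.approx(1.0, abs=0.02)

    def test_read_level_injection(self, rng):
        alns = [
            SeAlignment(f"r{i}", 1, "c", p, [("M", 100)], "+", 100, 0, 100, "A" * 100)
            for i, p in enumerate(rng.integers(0, 5000, size=4000))
        ]
        span = (1000, 2000)
        n_in = sum(1 for a in alns if span[0] <= a.target_pos < span[1])
        dels = inject_cnv(alns, span, "deletion", 7)
        n_in_del = sum(1 for a in dels if span[0] <= a.target_pos < span[1])
        assert n_in_del / n_in == pytest.approx(0.75, abs=0.05)
        dups = inject_cnv(alns, span, "duplication", 7)
        n_in_dup = sum(1 for a in dups if span[0] <= a.target_pos < span[1])
        assert n_in_dup / n_in == pytest.approx(1.25, abs=0.05)
        assert len({a.read_id for a in dups}) == len(dups)  # fresh ids

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValueError):
            inject_cnv_counts(np.ones(10), np.ones(10, dtype=bool), "inversion", rng)


class TestSweep:
    def test_span_enumeration(self):
        assert len(contiguous_spans(4)) == 10
        assert contiguous_spans(2) == [(0, 1), (0, 2), (1, 2)]

    def test_replicate_count_honored_exactly(self):
        matrix, exon_bins = simulate_depth_cohort(n_samples=12, seed=0)
        res = cnv_sensitivity_sweep(matrix, exon_bins, n_replicates=219, seed=1)
        assert res.table["n"].sum() == 219

    def test_sweep_is_deterministic_under_fixed_seed(self):
        matrix1, eb = simulate_depth_cohort(n_samples=10, seed=2)
        matrix2, _ = simulate_depth_cohort(n_samples=10, seed=2)
        t1 = cnv_sensitivity_sweep(matrix1, eb, 60, seed=9).table
        t2 = cnv_sensitivity_sweep(matrix2, eb, 60, seed=9).table
        assert t1.equals(t2)

    def test_high_depth_sweep_is_sensitive(self):
        """On a clean 700-count cohort every injected event class is
        detected at high sensitivity, multi-exon at least as well as
        single-exon."""
        matrix, exon_bins = simulate_depth_cohort(n_samples=25, seed=3)
        res = cnv_sensitivity_sweep(matrix, exon_bins, n_replicates=300, seed=4)
        per = res.per_size().set_index(["kind", "size"])
        assert (per["sensitivity"] >= 0.85).all()
        multi = per[per.index.get_level_values("size") > 1]["sensitivity"].mean()
        single = per[per.index.get_level_values("size") == 1]["sensitivity"].mean()
        assert multi >= single - 0.05


class TestWeightedAggregate:
    def test_published_style_table_gives_96_7(self):
        sens = [88.9, 99.2, 100.0, 100.0, 100.0, 93.8]
        weights = [0.26, 0.21, 0.08, 0.15, 0.26, 0.04]
        assert weighted_aggregate_sensitivity(sens, weights) == 96.7

    def test_all_perfect_gives_100(self):
        assert weighted_aggregate_sensitivity([100.0, 100.0], [0.5, 0.5]) == 100.0

    def test_uniform_weights_average(self):
        assert weighted_aggregate_sensitivity([80.0, 100.0], [0.5, 0.5]) == 90.0

    def test_validation(self):
        with pytest.raises(ValueError):
            weighted_aggregate_sensitivity([100.0], [0.5, 0.5])
        with pytest.raises(ValueError):
            weighted_aggregate_sensitivity([100.0, 90.0], [0.5, 0.4])

    def test_rounding_is_half_up(self):
        assert round_percent(96.65) == 96.7
        assert round_percent(99.949) == 99.9


class TestMerge:
    def _reads(self, rng, n, pos_range=(100, 200), prefix="r"):
        return [
            SeAlignment(f"{prefix}{i}", 1, "c", int(rng.integers(*pos_range)),
                        [("M", 100)], "+", 100, 0, 100, "A" * 100)
            for i in range(n)
        ]

    def test_het_plus_homref_expects_dosage_one(self, rng):
        a = self._reads(rng, 100, prefix="a")
        b = self._reads(rng, 100, prefix="b")
        merged, expected = merge_diploid_to_tetraploid(a, b, 200, 1, 0, seed=1)
        assert expected == 1

    def test_het_plus_homalt_expects_dosage_three(self, rng):
        a = self._reads(rng, 100, prefix="a")
        b = self._reads(rng, 100, prefix="b")
        _, expected = merge_diploid_to_tetraploid(a, b, 200, 1, 2, seed=1)
        assert expected == 3

    def test_equal_depth_skips_downsampling(self, rng):
        a = self._reads(rng, 120, prefix="a")
        b = self._reads(rng, 120, prefix="b")
        merged, _ = merge_diploid_to_tetraploid(a, b, 200, 1, 1, seed=1)
        assert len(merged) == 240

    def test_deeper_sample_is_downsampled_in_window(self, rng):
        a = self._reads(rng, 400, prefix="a")
        b = self._reads(rng, 200, prefix="b")
        merged, _ = merge_diploid_to_tetraploid(a, b, 200, 1, 0, seed=1)
        n_a = sum(1 for x in merged if x.read_id.startswith("a"))
        assert n_a == pytest.approx(200, abs=60)

    def test_uncovered_site_rejected(self, rng):
        a = self._reads(rng, 50, prefix="a")
        b = self._reads(rng, 50, pos_range=(4000, 4100), prefix="b")
        with pytest.raises(ValueError, match="covered"):
            merge_diploid_to_tetraploid(a, b, 200, 1, 0)


class TestIndelSensitivity:
    def test_all_found(self):
        out = indel_sensitivity([(1, 1), (2, 2), (3, 3)])
        assert out["presence_sensitivity"] == 1.0
        assert out["dosage_concordance"] == 1.0

    def test_one_miss_in_250(self):
        results = [(1, 1)] * 249 + [(1, 0)]
        out = indel_sensitivity(results)
        assert round_percent(100 * out["presence_sensitivity"]) == 99.6

    def test_dosage_errors_counted_separately(self):
        out = indel_sensitivity([(3, 2), (2, 2)])
        assert out["presence_sensitivity"] == 1.0
        assert out["dosage_concordance"] == 0.5

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            indel_sensitivity([])
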