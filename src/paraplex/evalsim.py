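"""CNV-injection and tetraploid-indel simulation drivers.

Single-copy events on a tetraploid background are emulated directly on
read counts: a deletion subsamples a span's reads to 75% (3/4 copies),
a duplication rescales to 125% (5/4 copies).  The sweep enumerates every
contiguous exon combination, injects events into randomly drawn
CNV-negative background samples, and scores the caller's detections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .align import SeAlignment
from .cnv import (
    DEFAULT_P_CNV,
    DEFAULT_Q_MIN,
    DepthMatrix,
    call_cnv,
    estimate_sigma,
    normalize,
    normalize_row,
)

DELETION_RETAIN = 0.75
DUPLICATION_SCALE = 1.25


def round_percent(x: float, digits: int = 1) -> float:
    """Half-up rounding of a percentage, as printed in reports."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Injection
# ---------------------------------------------------------------------------

def inject_cnv_counts(
    row: np.ndarray, span_mask: np.ndarray, kind: str, rng: np.random.Generator
) -> np.ndarray:
    """Inject a single-copy event into a raw depth-count row.

    Deletion: binomial subsampling of in-span counts at p = 0.75.
    Duplication: add a binomial resample of 25% of in-span counts
    (sampling reads with replacement at the count level).
    """
    if kind not in ("deletion", "duplication"):
        raise ValueError(f"unknown CNV kind {kind}")
    out = np.asarray(row, dtype=float).copy()
    counts = out[span_mask].astype(np.int64)
    if kind == "deletion":
        out[span_mask] = rng.binomial(counts, DELETION_RETAIN)
    else:
        out[span_mask] = counts + rng.binomial(counts, DUPLICATION_SCALE - 1.0)
    return out


def inject_cnv_reads(
    alignments: list[SeAlignment],
    span: tuple[int, int],
    kind: str,
    rng: np.random.Generator,
) -> list[SeAlignment]:
    """Read-level injection: Bernoulli-retain span reads at 0.75
    (deletion) or duplicate 25% of them with fresh ids (duplication)."""
    if kind not in ("deletion", "duplication"):
        raise ValueError(f"unknown CNV kind {kind}")
    lo, hi = span
    out: list[SeAlignment] = []
    extra = 0
    for aln in alignments:
        in_span = lo <= aln.target_pos < hi
        if not in_span:
            out.append(aln)
            continue
        if kind == "deletion":
            if rng.random() < DELETION_RETAIN:
                out.append(aln)
        else:
            out.append(aln)
            if rng.random() < DUPLICATION_SCALE - 1.0:
                from dataclasses import replace

                extra += 1
                out.append(replace(aln, read_id=f"{aln.read_id}#dup{extra}"))
    return out


def inject_cnv(sample, span, kind: str, seed: int | np.random.Generator = 0):
    """Dispatch on input type: a numpy row with a boolean span mask, or a
    list of alignments with a coordinate span."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(sample, np.ndarray):
        return inject_cnv_counts(sample, span, kind, rng)
    return inject_cnv_reads(sample, span, kind, rng)


def simulate_depth_cohort(
    n_samples: int = 30,
    exon_labels: tuple[int, ...] = (12, 13, 14, 15),
    bins_per_exon: int = 4,
    n_background_bins: int = 32,
    mean_count: float = 1400.0,
    sample_scale_sd: float = 0.2,
    bin_efficiency_sd: float = 0.15,
    bin_size: int = 50,
    seed: int = 0,
) -> tuple[DepthMatrix, dict[int, tuple[int, int]]]:
    """Simulate a CNV-negative cohort depth matrix for a capture panel.

    The default ``mean_count`` matches a tetraploid-aggregate locus:
    ~500x per paralog stacks to ~1000x at the gene locus, which with
    115 bp reads puts about 1400 read starts in the 164 bp window
    overlapping a 50 bp bin.  Counts are Poisson around ``mean_count``
    modulated by a lognormal
    per-sample library scale and a lognormal per-bin capture efficiency
    (the two nuisance effects the two-stage median normalization is
    designed to remove).  The panel carries the target exons' 50 bp bins
    plus background bins from elsewhere on the panel, so that a CNV
    spanning every target exon cannot drag the sample's own median.
    Returns the matrix and a map exon label -> half-open bin-index span.
    """
    rng = np.random.default_rng(seed)
    n_exon_bins = bins_per_exon * len(exon_labels)
    n_bins = n_exon_bins + n_background_bins
    sample_scale = rng.lognormal(0.0, sample_scale_sd, size=(n_samples, 1))
    bin_eff = rng.lognormal(0.0, bin_efficiency_sd, size=(1, n_bins))
    raw = rng.poisson(mean_count * sample_scale * bin_eff).astype(float)
    bins = [(i * bin_size, (i + 1) * bin_size) for i in range(n_bins)]
    matrix = DepthMatrix(bins=bins, samples=[f"S{i:03d}" for i in range(n_samples)], raw=raw)
    exon_bins = {
        label: (k * bins_per_exon, (k + 1) * bins_per_exon)
        for k, label in enumerate(exon_labels)
    }
    return matrix, exon_bins


# ---------------------------------------------------------------------------
# Sensitivity sweep
# ---------------------------------------------------------------------------

def contiguous_spans(n_exons: int) -> list[tuple[int, int]]:
    """All contiguous exon-index spans, e.g. 4 exons -> 10 spans."""
    return [(i, j) for i in range(n_exons) for j in range(i + 1, n_exons + 1)]


@dataclass
class SweepResult:
    table: pd.DataFrame  # kind, first_exon, size, n, detected, sensitivity

    def per_size(self) -> pd.DataFrame:
        g = self.table.groupby(["kind", "size"], as_index=False)[["n", "detected"]].sum()
        g["sensitivity"] = g["detected"] / g["n"]
        return g

    def overall(self) -> float:
        return float(self.table["detected"].sum() / self.table["n"].sum())


def cnv_sensitivity_sweep(
    matrix: DepthMatrix,
    exon_bins: dict[int, tuple[int, int]],
    n_replicates: int,
    seed: int = 0,
    baseline: int = 4,
    p_cnv: float = DEFAULT_P_CNV,
    q_min: float = DEFAULT_Q_MIN,
) -> SweepResult:
    """Inject CNVs over every contiguous exon combination and measure
    sensitivity.

    ``matrix`` holds raw depth counts for a CNV-negative cohort;
    ``exon_bins`` maps exon label -> half-open bin-index range.
    ``n_replicates`` is the total number of simulated samples, spread
    uniformly over the size/position/kind grid (remainders go to the
    first combinations).  A replicate counts as detected when the caller
    emits a confident event of the correct sign overlapping the injected
    span.
    """
    normalize(matrix)
    sigma = estimate_sigma(matrix)
    rng = np.random.default_rng(seed)
    labels = sorted(exon_bins)
    spans = contiguous_spans(len(labels))
    combos = [(kind, s) for kind in ("deletion", "duplication") for s in spans]
    per = n_replicates // len(combos)
    extra = n_replicates % len(combos)
    n_bins = matrix.raw.shape[1]
    bins = matrix.bins

    rows = []
    for ci, (kind, (i, j)) in enumerate(combos):
        n_rep = per + (1 if ci < extra else 0)
        first_bin = exon_bins[labels[i]][0]
        last_bin = exon_bins[labels[j - 1]][1]
        span_mask = np.zeros(n_bins, dtype=bool)
        span_mask[first_bin:last_bin] = True
        want_copy = baseline + (1 if kind == "duplication" else -1)
        detected = 0
        for _ in range(n_rep):
            k = int(rng.integers(matrix.raw.shape[0]))
            injected = inject_cnv_counts(matrix.raw[k], span_mask, kind, rng)
            row = normalize_row(matrix, injected)
            calls = call_cnv(row, baseline, bins=bins, sigma=sigma, p_cnv=p_cnv, q_min=q_min)
            for c in calls:
                if (
                    c.status == "CALL"
                    and c.called_copy == want_copy
                    and c.bin_span[0] < last_bin
                    and c.bin_span[1] > first_bin
                ):
                    detected += 1
                    break
        rows.append(
            {
                "kind": kind,
                "first_exon": labels[i],
                "size": j - i,
                "n": n_rep,
                "detected": detected,
                "sensitivity": detected / n_rep if n_rep else math.nan,
            }
        )
    return SweepResult(pd.DataFrame(rows))


def weighted_aggregate_sensitivity(per_size_sensitivities, weights) -> float:
    """Frequency-weighted aggregate sensitivity, in percent to one
    decimal (half-up).

    Inputs are percentages and fractional weights; weights must sum
    to 1 (+/- 1e-9).
    """
    s = np.asarray(per_size_sensitivities, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.shape != w.shape:
        raise ValueError("sensitivities and weights differ in length")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {w.sum()}, not 1")
    return round_percent(float(np.dot(s, w)))


# ---------------------------------------------------------------------------
# Tetraploid indel merges
# ---------------------------------------------------------------------------

def merge_diploid_to_tetraploid(
    alignments_a: list[SeAlignment],
    alignments_b: list[SeAlignment],
    indel_site: int,
    dosage_a: int,
    dosage_b: int,
    seed: int | np.random.Generator = 0,
    window: int = 100,
) -> tuple[list[SeAlignment], int]:
    """Merge two diploid alignment sets into a synthetic tetraploid one.

    The deeper sample is binomially downsampled (per-read Bernoulli) so
    both contribute about equally many reads in the ``window`` bp region
    centered on the indel; the expected tetraploid dosage is the sum of
    the two diploid dosages.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = indel_site - window // 2, indel_site + window // 2

    def in_window(aln: SeAlignment) -> bool:
        return aln.target_pos < hi and aln.target_end > lo

    n_a = sum(1 for a in alignments_a if in_window(a))
    n_b = sum(1 for a in alignments_b if in_window(a))
    if n_a == 0 or n_b == 0:
        raise ValueError("indel site not covered in both samples")

    def thin(alignments, p):
        kept = []
        for aln in alignments:
            if in_window(aln) and rng.random() >= p:
                continue
            kept.append(aln)
        return kept

    if n_a > n_b:
        alignments_a = thin(alignments_a, n_b / n_a)
    elif n_b > n_a:
        alignments_b = thin(alignments_b, n_a / n_b)
    merged = list(alignments_a) + list(alignments_b)
    return merged, dosage_a + dosage_b


def indel_sensitivity(results: list[tuple[int, int]]) -> dict[str, float]:
    """Sensitivity over merged tetraploid samples.

    ``results`` holds (expected_dosage, called_dosage) per merge with
    expected_dosage >= 1.  Presence-level sensitivity counts any call
    with dosage >= 1; dosage-level concordance requires the exact
    dosage.
    """
    if not results:
        raise ValueError("empty merged cohort")
    n = len(results)
    present = sum(1 for exp, got in results if got >= 1)
    exact = sum(1 for exp, got in results if got == exp)
    return {
        "n": n,
        "presence_sensitivity": present / n,
        "dosage_concordance": exact / n,
    }
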