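"""Read-depth CNV calling with a three-state HMM.

Depth is counted in bins (50 bp tiles for amplicon data; exon tiles for
capture panels), normalized in two stages — each sample's row by its
median bin depth, then each bin by its cross-sample median — and decoded
with a hidden Markov model over copy states {baseline-1, baseline,
baseline+1}.  Emissions are Gaussian around copy/baseline with a per-bin
sigma estimated from the cohort's median absolute deviation.  The
transition out of the baseline state is p_cnv (0.01 by default, split
evenly between loss and gain), chosen for high CNV sensitivity; CNV
states return to baseline with probability 0.1.

Event quality is the log-odds of the Viterbi path against the same path
with the event's bins forced back to baseline.  Events in the open
interval (0, q_min) are NO_CALL; q_min defaults to 3 log-odds units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import SeAlignment

DEFAULT_P_CNV = 0.01
DEFAULT_Q_MIN = 3.0
RETURN_TO_BASELINE = 0.1


@dataclass
class DepthMatrix:
    bins: list[tuple[int, int]]
    samples: list[str]
    raw: np.ndarray  # samples x bins
    normalized: np.ndarray | None = None
    bin_mask: np.ndarray | None = None  # True = usable bin

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (len(self.samples), len(self.bins)):
            raise ValueError("raw matrix shape does not match samples x bins")


@dataclass
class CnvCall:
    interval: tuple[int, int]
    baseline: int
    called_copy: int
    quality: float
    status: str  # CALL | NO_CALL | NEGATIVE
    bin_span: tuple[int, int] = (0, 0)  # half-open bin index range

    @property
    def delta(self) -> int:
        return self.called_copy - self.baseline


def make_bins(intervals, bin_size: int = 50) -> list[tuple[int, int]]:
    """Equal-sized bins tiling each interval (last bin may be short)."""
    bins = []
    for s, e in intervals:
        for b in range(s, e, bin_size):
            bins.append((b, min(b + bin_size, e)))
    return bins


def bin_depths(
    alignments: list[SeAlignment],
    bins: list[tuple[int, int]],
    mode: str = "overlap",
) -> np.ndarray:
    """Raw counts per bin.

    ``overlap`` counts a read in every bin its aligned span overlaps
    (50 bp amplicon tiles); ``start`` counts a read only in the bin
    containing its alignment start (one-bin-per-target capture panels).
    """
    for (a, b), (c, d) in zip(bins, bins[1:]):
        if not (a < b and b <= c):
            raise ValueError("bins must be sorted and non-overlapping")
    starts = np.asarray([b[0] for b in bins])
    ends = np.asarray([b[1] for b in bins])
    counts = np.zeros(len(bins), dtype=np.int64)
    for aln in alignments:
        if mode == "start":
            i = np.searchsorted(starts, aln.target_pos, side="right") - 1
            if i >= 0 and aln.target_pos < ends[i]:
                counts[i] += 1
        else:
            lo, hi = aln.target_pos, aln.target_end
            i = np.searchsorted(ends, lo, side="right")
            while i < len(bins) and starts[i] < hi:
                counts[i] += 1
                i += 1
    return counts


def normalize(matrix: DepthMatrix) -> DepthMatrix:
    """Two-stage median normalization.

    Stage one divides each sample's bins by that sample's median bin
    depth (making rows scale-free); stage two divides each bin by its
    cross-sample median (flattening bin-specific capture efficiency).
    Bins whose cross-sample median is zero are masked out.
    """
    if matrix.raw.shape[0] < 3:
        raise ValueError("normalization needs a cohort of >= 3 samples")
    sample_med = np.median(matrix.raw, axis=1, keepdims=True)
    if np.any(sample_med == 0):
        raise ValueError("a sample has zero median depth")
    stage1 = matrix.raw / sample_med
    bin_med = np.median(stage1, axis=0)
    mask = bin_med > 0
    normalized = np.full_like(stage1, np.nan)
    normalized[:, mask] = stage1[:, mask] / bin_med[mask]
    matrix.normalized = normalized
    matrix.bin_mask = mask
    return matrix


def normalize_row(matrix: DepthMatrix, raw_row: np.ndarray) -> np.ndarray:
    """Normalize one (possibly modified) sample row against an already
    normalized cohort's bin medians — used by injection sweeps."""
    if matrix.bin_mask is None:
        raise ValueError("normalize the cohort matrix first")
    stage1 = raw_row / np.median(raw_row)
    bin_med = np.median(matrix.raw / np.median(matrix.raw, axis=1, keepdims=True), axis=0)
    out = np.full(stage1.shape, np.nan)
    out[matrix.bin_mask] = stage1[matrix.bin_mask] / bin_med[matrix.bin_mask]
    return out


def estimate_sigma(matrix: DepthMatrix, floor: float = 0.02) -> np.ndarray:
    """Per-bin noise scale: 1.4826 * MAD of the normalized bin values."""
    if matrix.normalized is None:
        raise ValueError("normalize first")
    med = np.nanmedian(matrix.normalized, axis=0)
    mad = np.nanmedian(np.abs(matrix.normalized - med), axis=0)
    return np.maximum(1.4826 * mad, floor)


# ---------------------------------------------------------------------------
# HMM decoding
# ---------------------------------------------------------------------------

def _log_transition_matrix(p_cnv: float) -> np.ndarray:
    # state order: loss (baseline-1), baseline, gain (baseline+1)
    ret = RETURN_TO_BASELINE
    t = np.array(
        [
            [1.0 - ret - p_cnv / 2.0, ret, p_cnv / 2.0],
            [p_cnv / 2.0, 1.0 - p_cnv, p_cnv / 2.0],
            [p_cnv / 2.0, ret, 1.0 - ret - p_cnv / 2.0],
        ]
    )
    return np.log(t)


def _emission_logpdf(row: np.ndarray, sigma: np.ndarray, baseline: int) -> np.ndarray:
    """(3, n_bins) Gaussian log-densities at copy ratios around the
    baseline."""
    copies = np.array([baseline - 1, baseline, baseline + 1], dtype=float)
    means = copies[:, None] / baseline
    sig = np.broadcast_to(sigma, row.shape)[None, :]
    return -0.5 * ((row[None, :] - means) / sig) ** 2 - np.log(sig) - 0.5 * np.log(2 * np.pi)


def viterbi_path(
    row: np.ndarray,
    sigma: np.ndarray,
    baseline: int,
    p_cnv: float = DEFAULT_P_CNV,
) -> tuple[np.ndarray, float]:
    """Most likely copy-state path; returns (states, log-likelihood).

    States are copy numbers in {baseline-1, baseline, baseline+1}.
    Initial state distribution matches the baseline row of the
    transition matrix.
    """
    emit = _emission_logpdf(row, sigma, baseline)
    logt = _log_transition_matrix(p_cnv)
    init = logt[1]
    n = row.shape[0]
    dp = np.zeros((n, 3))
    bt = np.zeros((n, 3), dtype=np.int64)
    dp[0] = init + emit[:, 0]
    for i in range(1, n):
        scores = dp[i - 1][:, None] + logt
        bt[i] = np.argmax(scores, axis=0)
        dp[i] = scores[bt[i], np.arange(3)] + emit[:, i]
    states = np.zeros(n, dtype=np.int64)
    states[-1] = int(np.argmax(dp[-1]))
    for i in range(n - 1, 0, -1):
        states[i - 1] = bt[i, states[i]]
    ll = float(dp[-1].max())
    return states + baseline - 1, ll


def path_loglik(
    states: np.ndarray,
    row: np.ndarray,
    sigma: np.ndarray,
    baseline: int,
    p_cnv: float = DEFAULT_P_CNV,
) -> float:
    """Joint log-likelihood of an explicit copy-state path."""
    idx = states - (baseline - 1)
    emit = _emission_logpdf(row, sigma, baseline)
    logt = _log_transition_matrix(p_cnv)
    ll = logt[1, idx[0]] + emit[idx[0], 0]
    for i in range(1, len(idx)):
        ll += logt[idx[i - 1], idx[i]] + emit[idx[i], i]
    return float(ll)


def call_cnv(
    row: np.ndarray,
    baseline: int,
    bins: list[tuple[int, int]] | None = None,
    sigma: np.ndarray | float = 0.05,
    p_cnv: float = DEFAULT_P_CNV,
    q_min: float = DEFAULT_Q_MIN,
) -> list[CnvCall]:
    """Decode one normalized depth row into CNV events.

    Contiguous runs of a non-baseline Viterbi state merge into one event
    whose quality is the log-odds of the decoded path against the same
    path with the run reverted to baseline.  Returns one NEGATIVE call
    spanning the row when no event is found.  NaN bins (masked during
    normalization) are dropped before decoding.
    """
    row = np.asarray(row, dtype=float)
    if baseline not in (2, 4):
        raise ValueError("baseline must be 2 or 4")
    if row.size < 2:
        raise ValueError("need at least 2 bins to decode")
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), row.shape).copy()
    keep = ~np.isnan(row)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 usable bins")
    orig_idx = np.nonzero(keep)[0]
    row_k = row[keep]
    sig_k = sigma[keep]
    if bins is None:
        bins = [(i, i + 1) for i in range(row.size)]

    states, ll = viterbi_path(row_k, sig_k, baseline, p_cnv)
    calls: list[CnvCall] = []
    i = 0
    n = len(states)
    while i < n:
        if states[i] == baseline:
            i += 1
            continue
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        alt_states = states.copy()
        alt_states[i:j] = baseline
        quality = ll - path_loglik(alt_states, row_k, sig_k, baseline, p_cnv)
        a, b = int(orig_idx[i]), int(orig_idx[j - 1])
        interval = (bins[a][0], bins[b][1])
        status = "CALL" if quality >= q_min else "NO_CALL"
        calls.append(
            CnvCall(
                interval=interval,
                baseline=baseline,
                called_copy=int(states[i]),
                quality=float(quality),
                status=status,
                bin_span=(a, b + 1),
            )
        )
        i = j
    if not calls:
        calls.append(
            CnvCall(
                interval=(bins[0][0], bins[-1][1]),
                baseline=baseline,
                called_copy=baseline,
                quality=0.0,
                status="NEGATIVE",
                bin_span=(0, row.size),
            )
        )
    return calls


def call_cnv_exon11(
    site_depth_rows: np.ndarray,
    sample_index: int,
    site_positions: list[int],
    panel_scale: np.ndarray | None = None,
    p_cnv: float = DEFAULT_P_CNV,
    q_min: float = DEFAULT_Q_MIN,
    sigma_floor: float = 0.02,
) -> list[CnvCall]:
    """Exon-11 CNV call at baseline 2 from gene-partitioned read depth.

    Because pseudogenic reads are filtered out of exon 11, gene depth is
    only well defined at positions overlapping reliable distinguishing
    sites.  ``site_depth_rows`` is a cohort matrix (samples x sites) of
    gene-assigned read counts at those positions.

    ``panel_scale`` is each sample's overall depth scale (e.g. its
    median bin depth across the whole capture panel).  It anchors the
    stage-one normalization: the usable exon-11 positions all sit inside
    the one exon, so normalizing by the row's own median would erase a
    whole-exon event.  Without it the row's own median is used, which
    can only detect events not spanning every usable site.  Fewer than
    2 usable sites yields a NO_CALL for the exon.
    """
    site_depth_rows = np.asarray(site_depth_rows, dtype=float)
    n_sites = site_depth_rows.shape[1]
    if n_sites < 2:
        return [
            CnvCall(
                interval=(min(site_positions, default=0), max(site_positions, default=0) + 1),
                baseline=2,
                called_copy=2,
                quality=0.0,
                status="NO_CALL",
            )
        ]
    bins = [(p, p + 1) for p in site_positions]
    if panel_scale is not None:
        scale = np.asarray(panel_scale, dtype=float).reshape(-1, 1)
        if np.any(scale <= 0):
            raise ValueError("panel_scale must be positive")
        stage1 = site_depth_rows / scale
    else:
        stage1 = site_depth_rows / np.median(site_depth_rows, axis=1, keepdims=True)
    bin_med = np.median(stage1, axis=0)
    mask = bin_med > 0
    normalized = np.full_like(stage1, np.nan)
    normalized[:, mask] = stage1[:, mask] / bin_med[mask]
    med = np.nanmedian(normalized, axis=0)
    mad = np.nanmedian(np.abs(normalized - med), axis=0)
    sigma = np.maximum(1.4826 * mad, sigma_floor)
    row = normalized[sample_index]
    return call_cnv(row, baseline=2, bins=bins, sigma=sigma, p_cnv=p_cnv, q_min=q_min)
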