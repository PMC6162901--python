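"""Dosage-aware concordance, exact binomial intervals, dropout QC.

Tetraploid hybrid-capture calls are compared against paired diploid
gene- and pseudogene-amplicon truth in a 5x5 dosage matrix (hybrid
dosage 0-4 by combined amplicon dosage 0-4).  Cells where alternate
alleles are detected on both sides but with discordant counts are
*permissible dosage errors*: the presence signal alone suffices to
trigger reflex disambiguation, which corrects the dosage.  True
negatives are counted only at sites polymorphic in the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta

from .evalsim import round_percent

CLASSES = ("TN", "TP", "PermissibleDosageError", "FP", "FN")


def classify_cell(hybrid_dosage: int, truth_dosage: int) -> str:
    if hybrid_dosage == 0 and truth_dosage == 0:
        return "TN"
    if hybrid_dosage > 0 and truth_dosage > 0:
        return "TP" if hybrid_dosage == truth_dosage else "PermissibleDosageError"
    if hybrid_dosage > 0:
        return "FP"
    return "FN"


@dataclass
class ConcordanceMatrix:
    cells: np.ndarray  # 5x5: rows hybrid dosage, cols truth dosage

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.shape != (5, 5):
            raise ValueError("concordance matrix must be 5x5")

    def class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for h in range(5):
            for t in range(5):
                out[classify_cell(h, t)] += int(self.cells[h, t])
        return out

    @property
    def total(self) -> int:
        return int(self.cells.sum())

    def presence_sensitivity(self) -> float:
        c = self.class_counts()
        denom = c["FN"] + c["TP"] + c["PermissibleDosageError"]
        return 1.0 - c["FN"] / denom if denom else float("nan")


@dataclass
class RateEstimate:
    point: float
    ci_low: float
    ci_high: float
    level: float
    n: int
    k: int

    def __post_init__(self):
        if not (0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0):
            raise ValueError("interval must satisfy 0 <= low <= point <= high <= 1")

    def percent(self, digits: int = 1) -> tuple[float, float, float]:
        return (
            round_percent(100 * self.point, digits),
            round_percent(100 * self.ci_low, digits),
            round_percent(100 * self.ci_high, digits),
        )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact central binomial interval via the beta-quantile
    formulation; (k=0 -> low=0, k=n -> high=1)."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return low, high


def rate_estimate(k: int, n: int, level: float = 0.95) -> RateEstimate:
    low, high = clopper_pearson(k, n, level)
    return RateEstimate(point=k / n, ci_low=low, ci_high=high, level=level, n=n, k=k)


def concordance(
    hybrid_calls: dict[tuple[str, int], int],
    gene_amplicon_calls: dict[tuple[str, int], int],
    pseudogene_amplicon_calls: dict[tuple[str, int], int],
    polymorphic_sites,
    samples,
) -> ConcordanceMatrix:
    """Build the 5x5 dosage concordance matrix.

    All three call sets are ``(sample, gene_pos) -> alt dosage`` maps
    (missing entries mean dosage 0); amplicon dosages are diploid (0-2)
    and combine additively into the 0-4 truth axis.  Evaluation runs
    over ``samples`` x ``polymorphic_sites`` so that concordant-negative
    cells are counted only where the cohort is polymorphic.
    """
    sites = sorted(set(int(p) for p in polymorphic_sites))
    for key in list(hybrid_calls) + list(gene_amplicon_calls) + list(pseudogene_amplicon_calls):
        if int(key[1]) not in sites:
            raise ValueError(f"call at site {key[1]} outside the evaluated site set")
    cells = np.zeros((5, 5), dtype=np.int64)
    for s in samples:
        for pos in sites:
            g = int(gene_amplicon_calls.get((s, pos), 0))
            p = int(pseudogene_amplicon_calls.get((s, pos), 0))
            if not (0 <= g <= 2 and 0 <= p <= 2):
                raise ValueError("amplicon dosages must be diploid (0..2)")
            h = int(hybrid_calls.get((s, pos), 0))
            cells[min(h, 4), g + p] += 1
    return ConcordanceMatrix(cells)


def sens_spec(
    counts,
    treat_permissible_as: str = "TP",
    level: float = 0.95,
) -> dict[str, RateEstimate | None]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) with exact
    intervals.

    ``counts`` is a ConcordanceMatrix or a dict with keys tp/fp/tn/fn
    (and optionally permissible).  Permissible dosage errors count as
    detections when ``treat_permissible_as='TP'`` (presence-level, the
    default — the alt-presence signal is what matters clinically);
    with ``'separate'`` they are excluded from both numerator and
    denominator and reported on their own.  An undefined ratio yields
    ``None``, not 0/0.
    """
    if treat_permissible_as not in ("TP", "separate"):
        raise ValueError("treat_permissible_as must be 'TP' or 'separate'")
    if isinstance(counts, ConcordanceMatrix):
        c = counts.class_counts()
        tp, fp, tn, fn = c["TP"], c["FP"], c["TN"], c["FN"]
        perm = c["PermissibleDosageError"]
    else:
        tp, fp = int(counts["tp"]), int(counts["fp"])
        tn, fn = int(counts["tn"]), int(counts["fn"])
        perm = int(counts.get("permissible", 0))
    if any(v < 0 for v in (tp, fp, tn, fn, perm)):
        raise ValueError("negative counts")
    if treat_permissible_as == "TP":
        tp += perm
        perm_rate = None
    else:
        total_pos = tp + perm + fn
        perm_rate = rate_estimate(perm, total_pos, level) if total_pos else None
    sens = rate_estimate(tp, tp + fn, level) if tp + fn else None
    spec = rate_estimate(tn, tn + fp, level) if tn + fp else None
    return {"sensitivity": sens, "specificity": spec, "permissible": perm_rate}


def qc_allelic_dropout(
    het_allele_balances,
    threshold: float = 0.2,
) -> str:
    """Amplicon dropout QC from heterozygous-site allele balances.

    Returns ``review_no_hets`` when no heterozygous site exists (cannot
    exclude dropout), ``dropout_suspected`` when every het balance is
    below ``threshold`` (well under the expected ~50%), otherwise
    ``pass``.
    """
    balances = [float(b) for b in het_allele_balances]
    if not balances:
        return "review_no_hets"
    if all(b < threshold for b in balances):
        return "dropout_suspected"
    return "pass"
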