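"""Reflex-testing decision engine and reflex-rate estimation.

A called variant maps deterministically to one of three actions:

* ``no_report`` — benign or likely-benign variants are neither reported
  nor reflexed;
* ``reflex`` — non-benign CNVs anywhere in the five terminal exons, and
  non-benign SNVs/indels in exons 12-15, need orthogonal (long-range
  PCR / MLPA) disambiguation of their gene-vs-pseudogene origin;
* ``report_no_reflex`` — non-benign SNVs/indels in exon 11, where
  distinguishing-base read partitioning already localizes the variant.

A CNV no-call is treated as unresolved and reflexed by default; set
``nocall_retest`` to model the retest-first practice in which repeat
sequencing typically resolves it to a confident negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import RateEstimate
from .evalsim import round_percent

CLASSIFICATIONS = ("Benign", "LikelyBenign", "VUS", "LikelyPathogenic", "Pathogenic")
BENIGN = ("Benign", "LikelyBenign")
EXON_LABELS = (11, 12, 13, 14, 15)
VARIANT_TYPES = ("SNV", "indel", "CNV")


@dataclass(frozen=True)
class VariantRecord:
    variant_type: str
    location: int  # exon label 11..15
    classification: str
    cnv_status: str = "n/a"  # n/a | CALL | NO_CALL

    def __post_init__(self):
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant type {self.variant_type}")
        if self.location not in EXON_LABELS:
            raise ValueError(f"unknown exon label {self.location}")
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification}")
        if (self.cnv_status != "n/a") != (self.variant_type == "CNV"):
            raise ValueError("cnv_status applies exactly to CNV records")


@dataclass(frozen=True)
class ReflexDecision:
    action: str  # report_no_reflex | reflex | no_report
    reason: str


def decide(record: VariantRecord, nocall_retest: bool = False) -> ReflexDecision:
    """Map one variant record to a reflex decision (total and
    deterministic over the record grid)."""
    if record.variant_type == "CNV" and record.cnv_status == "NO_CALL":
        if nocall_retest:
            return ReflexDecision("no_report", "CNV no-call resolved by retest policy")
        return ReflexDecision("reflex", "CNV no-call is unresolved; disambiguate")
    if record.classification in BENIGN:
        return ReflexDecision("no_report", "benign variants are neither reported nor reflexed")
    if record.variant_type == "CNV":
        return ReflexDecision("reflex", "non-benign CNV in the terminal exons needs disambiguation")
    if record.location == 11:
        return ReflexDecision(
            "report_no_reflex", "exon-11 reads map uniquely; report without reflex"
        )
    return ReflexDecision("reflex", "non-benign SNV/indel in exons 12-15 needs disambiguation")


def component_of(record: VariantRecord) -> str:
    if record.variant_type != "CNV":
        return "snv_indel"
    return "cnv_nocall" if record.cnv_status == "NO_CALL" else "cnv_call"


def cohort_reflex_rate(
    sample_records: dict[str, list[VariantRecord]],
    component_denominators: dict[str, int] | None = None,
    nocall_retest: bool = False,
) -> dict[str, dict]:
    """Per-component reflex rates over a cohort.

    A sample counts at most once per component (snv_indel, cnv_call,
    cnv_nocall) regardless of how many of its variants reflex.
    Component denominators default to the cohort size but may differ
    (e.g. when only a subset was assessed for CNV no-calls).
    """
    if not sample_records:
        raise ValueError("empty cohort")
    reflexed: dict[str, set[str]] = {"snv_indel": set(), "cnv_call": set(), "cnv_nocall": set()}
    for sample, records in sample_records.items():
        for rec in records:
            if decide(rec, nocall_retest).action == "reflex":
                reflexed[component_of(rec)].add(sample)
    n_default = len(sample_records)
    out: dict[str, dict] = {}
    overall_pct = 0.0
    for comp, samples in reflexed.items():
        n = (component_denominators or {}).get(comp, n_default)
        k = len(samples)
        pct = round_percent(100.0 * k / n)
        out[comp] = {"k": k, "n": n, "percent": pct}
        overall_pct += 100.0 * k / n
    out["overall"] = {"percent": round_percent(overall_pct)}
    return out


def estimate_reflex_rate(
    components: list[tuple[int, int]],
    cohort_size: int = 13_000,
    n_draws: int = 100_000,
    seed: int = 0,
) -> RateEstimate:
    """Extrapolate the overall reflex rate by Monte-Carlo posterior
    sampling.

    Each observed component count (k, n) gets an independent
    Beta(k+1, n-k+1) posterior (uniform prior); the overall rate is the
    sum of component draws, clipped at 1.  The posterior mean of the sum
    equals the sum of (k+1)/(n+2) analytically, which the Monte-Carlo
    mean converges to.  ``cohort_size`` only frames the report — under
    this beta-binomial model the rate itself is scale-free.
    """
    if n_draws < 10_000:
        raise ValueError("n_draws must be >= 10^4")
    for k, n in components:
        if not 0 <= k <= n or n < 1:
            raise ValueError(f"invalid component counts ({k}, {n})")
    rng = np.random.default_rng(seed)
    total = np.zeros(n_draws)
    for k, n in components:
        total += rng.beta(k + 1, n - k + 1, size=n_draws)
    total = np.clip(total, 0.0, 1.0)
    low, high = np.percentile(total, [2.5, 97.5])
    return RateEstimate(
        point=float(total.mean()),
        ci_low=float(low),
        ci_high=float(high),
        level=0.95,
        n=n_draws,
        k=-1,
    )
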