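# Methods

This note documents the models behind `paraplex`, the choices made
where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## The problem being modelled

A gene's terminal exons (labelled 11–15) are nearly identical to a
pseudogene's corresponding region (labelled 2–6). Hybrid-capture short
reads from either paralog align to both; paralog-specific long-range
PCR (LR-PCR) can attribute variants but is costly to run on every
sample. The workflow modelled here screens everything with short
reads — diploid calling in exon 11 after distinguishing-base read
partitioning, tetraploid calling in exons 12–15 after stacking both
paralogs at the gene locus — and reflexes only the samples whose
findings need disambiguation.

## Synthetic locus and cohort

`generate_locus` builds one contig with two equal-length homologous
regions separated by a spacer, so the position homology map is a
constant-offset bijection. All gene/pseudogene differences are the
*distinguishing bases*; per-exon identity is `1 − n/len` and a supplied
identity target must agree with the requested difference count to
within one base, otherwise a `ParameterError` is raised. Defaults
(exons of 900/160/130/180/160 nt with 26/0/1/1/0 differences) emulate
the reference-genome-like configuration with >97% identity per exon;
the fully degraded configuration (no differences in exons 12–15) is a
one-line config change. Real gene/pseudogene pairs have small length
differences and structural divergence outside the exons; those are
deliberately out of scope to keep the homology map bijective.

`generate_cohort` draws each haplotype's alleles independently at the
specified site frequencies (no linkage) and models gene conversion as
an independent per-haplotype, per-site event that copies the partner
paralog's allele. That is the minimal generative process with the one
property that matters downstream: any positive exchange rate will, in a
large cohort, place the partner allele on at least one haplotype and
break the site's reliability.

`simulate_reads` draws fragment midpoints uniformly (lengths uniform in
250–600 nt, a narrower band than real sonication so that pairing under
the 1000 bp rule stays exercised but unambiguous), sequences 115 nt
paired ends, and applies independent per-base substitution errors
uniform over the three alternatives; no indel errors, no GC or
capture-efficiency bias, no duplicates, no quality-score model
(qualities are written as constant Q40 and ignored by the aligner).
`mean_depth` is per-paralog-region coverage, so the tetraploid stack at
the gene locus runs at about twice it. Copy events drop (or duplicate)
fragments *overlapping* the event span on the affected haplotype — a
deletion removes the DNA, so midpoint-based thinning would understate
the depth drop for exons shorter than a fragment. Allelic dropout in
amplicon mode is per-fragment Bernoulli thinning of the second
haplotype at retention `dropout_fraction` (the relative amplification
of that allele), giving expected het allele balance `r/(1+r)`; the
generative process behind the real signature is unknown, only the
signature itself matters for the QC flag. Consequently, passing tests
show the pipeline's logic is correct under idealized noise; they say
nothing about robustness to capture bias, indel sequencing errors or
alignment ambiguity beyond the paralog pair.

## Alignment

Scoring is match +1, mismatch −1, gap open −2, gap extend −1 (a gap of
length L costs `open + (L−1)·extend`), exact 11-mer seeds without
sampling, emit-all, and a score threshold of 20. The stated penalties
and threshold leave the match reward and extension penalty open; +1/−1
keeps the threshold meaningful for 115 nt reads. Queries up to 60 nt
are aligned by full affine-gap local DP on each seeded window (exact).
Longer reads use a fast path: the best local segment on each seed
diagonal (max-subarray), plus a two-diagonal combination that handles a
single indel exactly — the only gapped structure the read simulator
produces. Oracle equivalence against full Smith–Waterman is asserted on
small instances wherever an exact seed exists.

Pairing applies the four rules (same name, both in the exon 12–15
region, within 1000 bp, highest pair score wins); an exact score tie
across locus copies keeps one pair per copy. Exon-11 partitioning is
joint over the read pair: every overlapped *reliable* site must carry
the same paralog's allele, conflicts and site-free reads are discarded
(conservative; the source procedure does not address conflicts). A
base-call error at a read's only informative site can still flip its
assignment, so partition purity is exactly 100% only at error rate 0
and bounded by the error rate otherwise.

## Genotyping

A pileup dosage model replaces third-party local-assembly callers: the
concordance surface being reproduced (dosage agreement) is
model-agnostic, and an explicit likelihood is testable. At ploidy P,
error rate ε (default 0.01), and alt dosage d, a read shows the alt
with probability `p_d = (d/P)(1−ε) + (1−d/P)(ε/3)`; the call is the
ML dosage of the binomial alt count (uniform prior, ties to the lower
dosage). Depth below 20 reads flags `LOW_DEPTH`. Indels are VCF-style
left-anchored alleles counted at their anchor column. Multi-allelic
columns are genotyped against the best single alt. A known fixed
gene/pseudogene difference observed at dosage 2 in the tetraploid
track is suppressed when a catalog is supplied — it is the expected
signature of the two stacked pseudogene haplotypes, not a variant.
A single diploid caller serves exon 11 (the source workflow ran two
and left the merge rule unstated).

## CNV calling

Depth is counted in 50 bp bins (any-overlap) for amplicon-style data or
per-target (start-in-bin) for capture panels, then normalized by each
sample's median bin depth and each bin's cross-sample median. The
decoder is a 3-state HMM over copies {b−1, b, b+1} at baseline b ∈
{2, 4}: Gaussian emissions centred at copy/b with per-bin σ =
1.4826·MAD of the normalized cohort (floor 0.02), baseline
self-transition 1−p_CNV with p_CNV = 0.01 split between loss and gain,
CNV-state return-to-baseline 0.1. The published workflow cites an
in-house caller whose internals are not in the text; this HMM is a
declared stand-in fixed to every stated fact (bins, normalization,
baselines, p_CNV). Viterbi decoding is hand-written because event
quality is defined bespoke — the log-odds of the decoded path against
the same path with the event reverted to baseline — and events with
quality in (0, 3) are NO_CALL (the no-call criterion is not specified
at the source; 3 log-odds units is this package's choice). States
beyond ±1 copy are out of scope (documented limitation: a homozygous
deletion would be reported as a single loss).

Exon 11 depth is only defined at reliable distinguishing sites (the
positions partitioned gene reads must overlap). Because those sites all
sit in one exon, stage-one normalization accepts an external per-sample
panel scale; without it a whole-exon event is invisible by
construction.

## Simulation drivers and problem sizes

CNV injection subsamples span reads to 75% (deletion) or adds a 25%
resample with fresh ids (duplication); at the depth-count level this is
`Binomial(n, 0.75)` and `n + Binomial(n, 0.25)`. The sweep enumerates
all 10 contiguous spans of the last four exons per event kind and
spreads the replicate budget uniformly (the source total of 2186 is
honored when requested; its distribution across sizes was unstated).
Detection requires a confident call of the correct sign overlapping the
injected span. Cohort depth matrices default to 30 samples × (16 exon +
32 background) bins at a mean count of 1400 — the tetraploid-aggregate
scale: ~500× per paralog stacks to ~1000×, which with 115 nt reads
yields ~1400 reads overlapping a 50 bp bin — with lognormal per-sample
(σ=0.2) and per-bin (σ=0.15) nuisance factors that the two-stage
normalization exists to remove. Background bins matter: without them a
CNV spanning every target exon drags the sample's own median and
normalizes itself away. Test and acceptance runs use 200 genotype
samples, 300 specificity samples and 600 sweep replicates; these sizes
make the binomial uncertainty on each estimate small relative to the
thresholds asserted.

Tetraploid indel merges combine two diploid alignment sets, binomially
downsampling the deeper one over the 100 bp window centred on the
indel; expected dosage is the sum of the diploid dosages.

## Metrics and reflex estimation

Concordance is a 5×5 matrix of hybrid-capture dosage (0–4) against
combined gene+pseudogene amplicon dosage; equal positive dosages are
TP, unequal positive dosages are *permissible dosage errors* (the
presence signal already triggers reflex, which corrects the count), and
true negatives are counted only at cohort-polymorphic sites. Permissible
errors count toward sensitivity by default and are always reported as
their own class. Intervals are exact Clopper–Pearson via beta
quantiles. Reported percentages round half-up to one decimal. The
dropout QC flag uses a het allele-balance threshold of 0.2
("significantly less than 50%" quantified as a configurable default).

Reflex-rate extrapolation places independent Beta(k+1, n−k+1)
posteriors (uniform priors) on each component rate and sums draws,
clipped at 1. The analytic posterior mean Σ(k+1)/(n+2) of the observed
components (41/707, 2/707, 1/144) is 7.72%, which both the Monte-Carlo
mean and the published-scale figure agree with — supporting the model
choice, which the source (naming only its MCMC tool) leaves open.
CNV no-calls reflex by default; `nocall_retest=True` models the
retest-first practice under which repeat sequencing usually resolves
them. Cohort size enters reporting only; the summed rate is scale-free
under this model.

## Known limitations

No linkage or haplotype structure in cohorts; no capture bias, indel
errors or base qualities in reads; single-indel alignment fast path;
±1 copy states only; no MLPA probe modelling; variant classifications
are inputs, never computed.
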