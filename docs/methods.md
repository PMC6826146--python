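# Methods

## Model and assumptions

The pipeline quantifies point substitutions on a single mtDNA strand in the
D-loop window rCRS 16,560 → 279 (289 positions, wrapping the circular
16,569-bp coordinate frame; 1-based inclusive coordinates throughout).  Its
central assumption is the primer-ID premise: a random 19-base tag is attached
to each template molecule *before* exponential amplification, so a true
template substitution segregates with the tag and reaches near-unanimous
support within its read group, while post-extension PCR errors and sequencing
errors are scattered independently across reads.  A single-PID design cannot
distinguish a genuine single-strand mutation from a chemical lesion copied in
the extension step; results are therefore "substitutions on the sequenced
strand".  Insertions and deletions are excluded from calling: gaps are
tracked through alignment so columns stay in frame, but a gap never emits a
variant.

Eligibility thresholds (group size ≥ 5, support ≥ 75% inclusive, ≥ 100 groups
per sample, 2% somatic/heteroplasmic cutoff, 100-bp MID search window) are
assay constants, exposed in config but defaulted to the established values.
The error-suppression guarantee is binomial: with per-read-base error rate e
and group size n = 5, a non-template base reaches 75% support with
probability at most Σ_{k≥4} C(5,k) e^k (1−e)^{5−k} ≈ 5e⁴ — about 5 × 10⁻⁸
per column at e = 0.01, which is what makes single-molecule mutation counting
feasible at all.

## Key parameters

| parameter | default | units / meaning |
|---|---|---|
| `region.start`, `region.end` | 16,560, 279 | 1-based rCRS bounds, wrapping |
| `demux.search_window` | 100 | bp; MID must start before this offset |
| `pid.length` | 19 | bases after the MID |
| `consensus.min_group_size` | 5 | reads per PID group |
| `consensus.support_threshold` | 0.75 | inclusive support fraction |
| `consensus.min_participant_groups` | 100 | groups per sample (QC) |
| `heteroplasmy.cutoff` | 0.02 | inclusive somatic upper bound |
| `align.min_identity` | 0.70 | identity floor for projection |

`n_somatic` counts **group-level events**: a somatic allele observed in 2 of
300 groups contributes 2 to the numerator, consistent with the frequency
being per template molecule.  Heteroplasmic variants are aggregated by
(position, alternate allele) — two different alleles at one site are distinct
molecular events; `heteroplasmy.by_position_only` restores aggregation by
position alone.  Heteroplasmic events never enter the somatic numerator, and
the control background is reported but never subtracted from sample burdens.

## Alignment

Each payload is projected onto region coordinates independently with an
affine-gap global aligner (Biopython `PairwiseAligner`; match +1, mismatch
−1, gap open −4, gap extend −1, free end gaps), rather than through one
multiple alignment: per-read pairwise projection is deterministic, per-group
independent, and the calling rules only need reference-frame columns.
Payloads whose length equals the region's and whose direct identity is ≥ 0.9
skip dynamic programming (substitution-only reads, the dominant case).  A DP
alignment must engage ≥ 50% of the shorter sequence; otherwise a random
payload could pass the identity floor on a few-base terminal overlap.  The
"reaches position 279" filter is evaluated as alignment *coverage* of that
position, not read length, so indels do not break it.  Reads below the
identity floor are dropped with a logged reason.

Ties in the participant-consensus plurality vote resolve to the reference
base (never fabricating a variant from a 50/50 split), and a reference N
disables calling at that position.  Sub-threshold PID-consensus columns carry
a no-call marker — the participant base is assumed — because the mutation
definition only fires at ≥ 75% support.

## Simulator

`mitopid.simulate` emulates the assay's generative process: n templates
(default 2,000, the template bottleneck) copied from the reference region;
heteroplasmic variants applied to a Bernoulli(f) — or, for exact
dose-response work, a round(f·n) — subset; Poisson(μ) somatic substitutions
per template at distinct uniform positions (default μ = 0.015 per template,
which reproduces a realistic burden of ≈ 0.5 per 10,000 bp); transition
probability `ti_weight` = 0.8 for planted and error substitutions, matching
the observed transition dominance; reads per template Poisson with mean 6
(≈ 10,000 reads over ≈ 2,000 templates, with a realistic fraction of groups
clearing the ≥ 5 threshold); and i.i.d. per-read-base substitution errors at
rate ε = 0.003 merging post-extension PCR and sequencing error into one
scattered process.

What it deliberately does **not** model: PCR lineage correlation of errors (a
jackpot error early in amplification is more correlated than i.i.d.; the
caller's discriminating signal — scattered vs consistent within groups — is
conservative against i.i.d. errors but lineage-correlated errors could defeat
a single-PID design), homopolymer indel errors (the platform's dominant mode,
irrelevant here because indels are excluded), amplification-efficiency bias
between templates, quality scores, and chimeric reads.  PID collisions (two
templates drawing the same 19-mer) are possible but expected < 10⁻⁵ per pair
set at 2,000 templates over 4¹⁹; they are logged when they occur and accepted
as noise.  Passing tests therefore demonstrate correctness of the algorithm
under independent scattered error, not robustness to correlated artefacts in
real libraries.

The cohort generator works **on the transformed scale only**: ln(x+1) burden
is linear in age/smoking/HIV with Gaussian noise, and heteroplasmy is
logistic with an age × smoking interaction (defaults: intercept −3, age
+0.05/yr, smoking +2.0, interaction −0.08/yr — prevalence rising with age in
never smokers and falling in current smokers, at ≈ 24% overall).  Ages are
uniform on 2–72; 35% smokers; 56% HIV-positive of whom 43% with high peak
viral load.  Because the Gaussian is not truncated, the implied raw frequency
can dip slightly below zero at young ages; this is an accepted artefact of
emulating the regression layer rather than deriving burden from reads.

## Statistical layer

The ANCOVA is ordinary least squares on ln(x+1) burden with treatment coding
against never-smoker and HIV-negative references; a rank check names aliased
terms, and a guard requires n ≥ 10 per model term.  The logistic model
reports Wald 95% intervals and Nagelkerke pseudo-R² (McFadden alongside,
since "R²" for logistic fits is flavour-ambiguous), refuses single-class
outcomes, and flags complete separation instead of returning unstable
estimates.  Covariate selection is two-stage: univariate p < .1, then the
candidate must lower the multivariable AIC ("improves the fit" needed an
operational criterion; AIC was chosen).  The assay CV uses the sample (n−1)
standard deviation over replicate runs.  Missing covariates are handled by
complete-case deletion per model with n reported.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` seeds; identical
seed and config give byte-identical outputs, and results are independent of
read order.  Support and fraction comparisons are inclusive (≥ 0.75, ≤ 0.02)
so printed-threshold arithmetic like 6/8 = 75% or 4/200 = 2% lands on the
intended side.  Test and validation simulations use 150–600 templates per
sample and 20–50 seeded replicates; coverage checks of confidence intervals
use 200–1,000 replicate cohorts of n = 500–1,000 — sizes chosen so binomial
noise in the checked proportion is small against the margin being asserted.
The acceptance script runs one full-scale sample (2,000 templates), twelve
800-template plasmid controls, and three replicate runs.

## Known limitations

Single-strand, single-PID design (no duplex confirmation); no NUMT filtering
(the D-loop target largely avoids it); no chimera detection; exact MID
matching (no mismatch tolerance by default — `mid.max_mismatch` exists in
config but relaxation is not recommended since a mis-assigned sample is worse
than a lost read); the bundled reference genome is synthetic (random sequence
of rCRS length — coordinates, not bases, drive the logic), so analyses of
real data must supply the true rCRS FASTA.
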