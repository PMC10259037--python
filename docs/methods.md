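# Methods

This note documents the models, rules, and numerical choices behind
occc-molpro, and what the synthetic cohort does and does not establish.

## Variant interpretation

A variant is deleterious (class 4/5) when its annotated consequence is
truncating — frameshift, nonsense, no-start, no-stop, or a consensus
(±1/±2) splice-site change — regardless of any database classification, or
when it is a missense variant recorded as pathogenic or likely pathogenic in
the ClinVar-style knowledge base.  Synonymous, in-frame indel, promoter and
other non-coding calls never qualify.  Classification is a pure function of
the record and the knowledge base; permuting input order cannot change any
gene status, and gene-level counting is sample-level (two qualifying
variants in one gene of one sample set one cell).

Splice classification trusts the upstream consequence annotation rather than
re-deriving it from sequence: this pipeline starts from called, annotated
variants by design.

One recurrent *POLE* nonsense variant (NM_006231.2:c.3961A>T, p.(R1321X))
does not produce the ultramutated phenotype and therefore never contributes
to *POLE* driver status; the classifier returns a dedicated
`excluded_pole_nonsense` rule so the exclusion is visible downstream.  The
variant still counts toward TMB, which is classification-blind.

TERT promoter positivity is an exact HGVS c. match against a hotspot set
that defaults to c.-124C>T, c.-124C>A and c.-146C>T; no classification rule
contributes to TERTp status.  Knowledge-base lookups (polymorphism, driver,
known-fusion, family tables) are offline TSV snapshots so runs are
reproducible; there are no live database queries.

Molecular subtypes follow the TCGA-style hierarchy POLEmut > MSI-High >
p53abn > NSMP.  POLEmut requires a class 4/5 *POLE* variant outside the
excluded set; p53abn is operationalized as ≥ 1 class 4/5 *TP53* mutation
(no immunohistochemistry is in scope); a sample missing any input status is
not-evaluable, never silently NSMP.

## TMB

TMB = countable variants / coding megabases.  Countable: coding consequence
(synonymous or nonsynonymous), allele frequency ≥ 10% (inclusive), and —
under the default `exclude_polymorphisms` germline policy — not flagged in a
population polymorphism database unless also a known/probable driver.  The
denominator defaults to the capture panel's 1.708 Mb of coding territory
and is configurable.  Samples need ≥ 40% tumor cells to be evaluable;
missing purity is an explicit not-evaluable reason.  TMB-High is ≥ 10
mut/Mb with the comparison on the unrounded value (reporting uses two
decimals).  Because counts are integers over a fixed 1.708 Mb denominator,
reported TMB values live on a 1/1.708 grid: a cohort whose counts cluster at
5 per sample has median 2.93 mut/Mb, the closest realizable value to the
integer 3 that such a cohort rounds to.

## MSI

Up to 17 microsatellite markers per sample, each stable / unstable /
not-evaluated.  The instability fraction uses evaluated markers only; the
sample is MSI-High when the fraction strictly exceeds 20% (4/17 = 23.5% is
MSI-High; 2/10 = 20% is MSS).  Zero evaluated markers yields a
not-evaluable result, never MSS by default.

## Fusion filtering

All criteria must hold simultaneously: both partners protein-coding; the 5'
breakpoint within ± 15 bp (inclusive) of an exon 3' edge and the 3'
breakpoint within ± 15 bp of an exon 5' edge in transcript coordinates;
crossing reads ≥ 10% (inclusive) of reads at the breakpoint location;
expression support; and no artifact screen.  Unknown transcripts make a
candidate unevaluable, which is a rejection with an explicit reason — a
cohort run never aborts on one candidate.

Parameters the assay describes qualitatively were fixed as documented
defaults, all configurable:

* *Expression support* — reads at the breakpoint location must be at least
  2× the cohort median coverage of that region.  The median ships as a
  per-candidate input column (`region_median_reads`) because a
  candidate-only table cannot reproduce region-level cohort coverage.
* *Readthrough* — same chromosome and strand, partners within 200 kb, with
  the 5' partner genomically upstream in the direction of transcription.
* *Recurrent artifact* — the same gene pair in more than 20% of cohort
  samples, unless the pair is in the known-fusion table (recurrence of a
  documented fusion is biology, not artifact).

Reading frame: with the 5' transcript retaining CDS length L up to its
breakpoint and the 3' breakpoint at codon phase p within its CDS, the
junction is in-frame iff L ≡ p (mod 3); breakpoints outside either CDS give
`unknown`.  Novelty is a pure known-fusion-pair lookup.  Breakpoints are
transcript (r.) coordinates; genomic positions are carried only for
readthrough geometry.

## Expression

Two normalization schemes serve different outputs, as in the assay's own
workflow.  Clustering consumes TMM-normalized data: normalization factors
follow the trimmed-mean-of-M-values algorithm (reference sample chosen by
upper-quartile closest to the cohort mean; genes zero in either sample
dropped; 30% two-sided trim on M, 5% on A; precision-weighted mean of
retained M values; factors rescaled to geometric mean 1) — verified against
an external reference implementation to 1e-5 on a fixture — followed by
log2 CPM with prior count 1 over TMM-adjusted library sizes and per-gene
Z-scores (population sd; constant genes become zero rows with a warning).
Samples are clustered on Manhattan (L1) distance with complete linkage,
cutting the tree at k = 2 because the study design asks for the two main
clusters; the cut count is a parameter.  Cluster labels are assigned by
descending size, and the input is canonically ordered first so the result is
invariant to sample and gene order.

The cluster-comparison table instead uses RPKM (count × 10⁹ / (library size
× gene length)) divided per sample by the geometric mean of the three
stable reference genes *VCP*, *SF3B1*, *ATP5F1B*; the geometric mean is the
standard choice for ratio-scale reference normalization.  Samples with a
zero reference RPKM are flagged and excluded.

Differential expression fits, per gene, a negative binomial GLM of counts on
a two-level group indicator with a log effective-library-size offset.
Dispersion is estimated by method of moments within groups and moderated
toward the cohort mean dispersion with a prior weight of 10 observations —
a simple squeeze that stabilizes small-group estimates.  Group effects are
tested by Wald statistics and adjusted by Benjamini–Hochberg.  All-zero
genes are excluded with a note.

## Cohort statistics and survival

RFS runs from diagnosis to recurrence or death of disease (a disease death
without a recorded recurrence date is an event at death); OS runs from
diagnosis to any recorded death — deaths of treatment complications,
uncertain, or other causes included, because the endpoint is defined by the
death record, not its cause.  Such deaths censor RFS at the death date.
Records without follow-up are excluded with a logged count, and percentages
throughout the package use non-missing denominators.

Categorical associations use Fisher's exact test when any expected cell is
≤ 5 (the boundary counts as small) and Pearson's chi-squared without
continuity correction otherwise; the method used is recorded.  Cox
proportional-hazards fits use Efron tie handling (via lifelines).  The
multivariable strategy screens covariates univariably at Wald p < 0.05,
fits the full model, and removes the highest-p term until all remaining
terms are significant, recording the trace.  Monotone likelihood is
detected by scanning few-level covariates for levels with zero events and
flagged on the fit rather than reported as a clean convergence.

## Synthetic cohort generator

The generator emulates the study inputs with exactly planted marginals:
carrier samples per gene are assigned by exact-count (hypergeometric)
sampling rather than Bernoulli draws, so cohort percentages reproduce
exactly.  Defaults: 100 DNA samples with ARID1A 51, PIK3CA 47, KRAS 18,
TP53 12, ATM 10, PPP2R1A 7, PTEN 6, NF1 6, POLE 4 carriers and 27
TERTp-positive samples; KRAS and TP53 carriers disjoint; 7 MSI-High samples
of which one is also POLE-mutated; 105 RNA samples with 14 filter-passing
fusions (13 distinct breakpoint events) plus one decoy per rejection class
and a recurrent artifact pair in 25 samples; a 93/12 expression structure;
87 samples with follow-up, with POLEmut/MSI-High samples planted event-free.

TMB is planted as per-sample countable-variant loads — target density ×
1.708 Mb, rounded half-up — never as a stored number, so the reported
burden always flows through the real counting path.  The hypermutated group
has densities 24–86 (POLE-mutated), 14–26 (MSI-High) and one 13 mut/Mb
MSS/POLE-wild-type sample; the 91 remaining samples use a density list
whose realized cohort median is 5 counts = 2.93 mut/Mb and whose low end is
0.  Non-qualifying decoys (VUS missense, synonymous, polymorphism-flagged,
low-AF, non-coding) exercise every exclusion rule.

Fusion transcript models are miniature synthetic annotations: exon
boundaries are anchored exactly at the planted breakpoints and 5' CDS
starts are solved so each fusion realizes its intended reading frame.
Expression counts are negative binomial (dispersion 0.05; reference genes
0.02) with library-size factors spanning an exact 3.5-fold range; minority
markers are shifted 2.5× up / 0.4× down by default — comfortably past the
2-fold reporting threshold so realized group ratios do not straddle it at
n = 12.

A self-check pass re-derives every rule-derivable truth label (gene counts,
TERTp, TMB counts and calls, MSI calls, fusion verdicts with frames and
junctions) from the generated raw tables and fails generation on any
disagreement.  Identical spec and seed give byte-identical output
directories.

**What the synthetic cohort does not show.**  It contains no sequence
context, no read-level evidence, no copy-number events, and no germline/
somatic distinction; variant positions and alleles are schematic.  Clinical
covariate effects are planted qualitatively (R0 resection lowers recurrence
risk), not calibrated to the study's effect sizes.  Passing tests therefore
demonstrate that the pipeline's rules, counters, filters, and statistics are
implemented correctly and recover known structure through their real
computation paths — not that the upstream callers or the biological claims
are reproduced on real data.

## Problem sizes

The default cohort (100 DNA samples, ~1,400 variants; 105 RNA samples, 147
genes; 45 fusion candidates) runs end-to-end in a few seconds.  Simulation
tests use n = 400–500 for Cox parameter recovery and 1,000 randomized
candidates for the filter-oracle equivalence check.

## Known limitations

* The expected-cell rule, backward-elimination criterion (Wald p, α = 0.05),
  dispersion moderation weight, and fusion-screen defaults are documented
  conventions, not values the assay specifies; all are parameters.
* The NB dispersion trend is a global mean, not a fitted mean–dispersion
  curve; adequate at panel scale (147 genes), coarse for genome-wide use.
* Fisher's exact branch is implemented for 2×2 tables; larger sparse tables
  raise rather than silently switching methods.
* The Cox separation screen inspects categorical covariates only;
  continuous-covariate monotone likelihood surfaces through the fit note.
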