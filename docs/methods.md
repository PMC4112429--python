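# Methods

## The burden statistic

For one gene, let `k_case` and `k_control` be the numbers of qualifying
carrier events (one sample carrying one qualifying variant counts once; a
variant carried by two samples counts twice) in `n_case` cases and
`n_control` controls.  Conditional on the pooled total `n = k_case +
k_control`, each event lands in a case with probability
`π = n_case / (n_case + n_control)` under the null of equal per-sample
carrier rates in the two arms.  The reported p value is the exact one-sided
upper tail

    p = P(X ≥ k_case),  X ~ Binomial(n, π),

computed with `scipy.stats.binom.sf` and verified in the test suite against
an exact rational tail summation for all pooled totals up to 50.  `k_case =
0` returns p = 1.  This conditional construction ignores the (tiny)
within-sample dependence of events across variants and treats per-event
case membership as independent; with per-gene carrier rates of order 10⁻³
and at most a handful of events per gene that approximation is what makes
the test tractable, and the null-calibration experiment shows it is
conservative in the relevant regime (discreteness keeps the realised
type-I rate an order of magnitude below the nominal threshold).

Boundaries are strict everywhere, matching the design readings: exactly
four control events is still tested ("more than four" excludes), p exactly
at the threshold is not flagged ("lower than" flags), a score exactly at
the cutoff is not polygenic ("above" classifies), a panel frequency exactly
0.5% is not rare ("below" qualifies).

No multiple-testing correction is applied; the 4×10⁻³ threshold is a
triage device for follow-up, not a claim of exome-wide significance.  A
Bonferroni-adjusted column (threshold × number of tested genes) is emitted
for information only.

### Gene-level filters

* Genes with more than `max_control_variants = 4` qualifying control
  events are excluded before testing.  The limit follows from disease
  prevalence: at 1/500, a 1926-sample control panel is expected to contain
  `1926/500 ≈ 4` undiagnosed carriers, so a true dominant FH gene can
  show a few control events but not more.
* Sex chromosomes and the mitochondrion are excluded by default (`X`
  always; `Y`/`MT` configurable).  The binomial comparison assumes equal
  diploid opportunity in both arms, which a cohort of unstated sex
  composition cannot guarantee outside the autosomes.
* Candidate-gene-list mode (`run_gene_list_burden`) applies no filters:
  the list is the hypothesis, every member is tested, and a pooled test
  over the listed genes is reported alongside.

## Variant flags

Frequency aggregation over reference panels uses the **maximum**: a
variant common in any panel is not rare, and a panel in which the variant
is unobserved contributes zero.  *Novel* means frequency zero in every
panel.  Novelty is judged against reference panels only — presence in the
study's own controls does not revoke it; control presence enters the
analysis through the burden counts instead.  *Functional* is a fixed
consequence-class set (missense, stop gain/loss, frameshift ins/del,
splice site) taken from the annotation file as-is; no distance-from-exon
recomputation is attempted, so "splice site" means whatever the upstream
annotator called splice-affecting.

Variant identity is a normalized key: alleles upper-cased, shared suffix
then shared prefix trimmed (advancing the position), `chr` prefixes
stripped.  This collapses right-shifted indel spellings whose reference
spans overlap; full left-alignment against a reference genome is out of
scope for exome call sets and would require the FASTA.

## Gene score

`S = Σᵢ wᵢ dᵢ + APOE(h₁,h₂)`, with the APOE diplotype component a fixed
lookup (ε2ε2 −0.9, ε2ε3 −0.4, ε2ε4 −0.2, ε3ε3 0, ε3ε4 +0.1, ε4ε4 +0.2).
The diplotype is derived from rs429358/rs7412 allele counts; the one
ambiguous unphased configuration (both SNPs heterozygous) is resolved as
ε2/ε4, the phase consistent with the essentially unobserved ε1 haplotype
not existing, and allele counts only an ε1 could produce are a data error.
Any missing score SNP or APOE genotype leaves the sample unscored —
classification is then `unscored`, never polygenic, and the pipeline keeps
such samples in the discovery cohort.  Group comparisons use the Welch
unequal-variance two-sample t test pairwise and one-way ANOVA across
groups, both from scipy; they are reported, not thresholded.

Default cutoff 1.16 (healthy-population top decile); 1.08 (9th decile) is
available as a more permissive alternative via `--score-cutoff`.

## Pipeline precedence and arithmetic

Exclusions satisfy `n_remaining = n_total − n_tier1 − n_polygenic` with
disjoint exclusion sets: a sample that is both mutation-positive and
high-score counts once, under Tier-1.  `unknown_effect` catalogue entries
(e.g. novel APOB variants of untested pathogenicity) are reported on match
but never exclude.  Reports are deterministic: fixed sample and gene
ordering, p-then-gene sorting, no uncontrolled randomness.

## Synthetic cohort generator

The generator produces cohorts with the statistical structure the
analysis assumes, at the study scale (125 cases, 1926 controls), with every
planted signal recorded in a truth table:

* **Carrier events.**  Per (gene, sample), at most one qualifying
  novel-functional event, Bernoulli with per-gene rate; case rates may be
  multiplied for enriched genes.  The default 500-gene panel log-spaces
  rates between 5×10⁻⁵ and 2×10⁻³ per sample (expected control counts
  ~0.1–4), cycling chromosomes with every 23rd gene on X so the chromosome
  filter is exercised.  Decoy calls (novel synonymous, common missense)
  are added at a low rate so the filters have something to remove.
* **Tier-1 spikes.**  25 of 125 cases receive a dominant catalogued
  mutation (the synthetic catalogue mimics curated FH-database rows, with
  padded VCF spellings retained so emitted VCFs stay valid while keys
  still normalize onto the catalogue); one further case is a
  heterozygous carrier of the recessive *LDLRAP1* entry — reported by the
  screen but, correctly, never explained.
* **Scores.**  12 independent SNPs in Hardy–Weinberg proportions plus an
  APOE diplotype from haplotype frequencies (ε2 0.08, ε3 0.77, ε4 0.15).
  The weight/frequency table is calibrated so the control score
  distribution has mean 0.90 and 90th percentile 1.16: the mean is matched
  analytically; the percentile via a normal approximation refined by a
  Monte Carlo fixed point, because the lumpy APOE component (13% of mass
  at −0.4 or below) skews the distribution left and shifts the true upper
  decile boundary.  The calibrated model lands at a score SD of ≈0.23.
  No linkage disequilibrium is modelled — sufficient for testing score
  arithmetic and decile logic, not for LD-sensitive questions.
* **Aetiology structure.**  16 of 125 cases are unscorable (one score SNP
  dropped, emulating DNA-quality failure).  Polygenic cases are planted
  among score-attainable mutation-negative cases at 27% of the scored
  cases (29 of 109), drawn conditional on score > 1.16; other scored
  mutation-negatives are drawn conditional on ≤ 1.16.  Spiked mutation
  carriers draw unconditional background scores, so carriers above the
  cutoff arise at the population rate (~10%, i.e. ~2 of the ~21 scored
  carriers) — monogenic and polygenic aetiologies coincide only by
  chance.  A consequence of these planted fractions is that the cascade
  removes exactly 25 + 29 samples and scans 71, for any seed.

What the generator does **not** emulate: realistic site-frequency spectra,
LD, sequencing error, variable coverage, population stratification or
relatedness.  Tests passing on synthetic cohorts therefore validate the
*logic and calibration* of the pipeline, not its robustness to real-data
artefacts.

## Experiment sizes

The null-calibration experiment uses 200 replicate scans of a 500-gene
panel at 71 vs 1926 samples (per-gene counts simulated directly, p values
cached per count pair), which bounds the flagged-gene fraction tightly
while completing in seconds.  The recovery experiment runs the full
generator once at study scale.  The tail-sum oracle covers all pooled
totals up to 50 — beyond any count a 125-case exome can produce per gene.

## Known limitations and open points

* The burden test counts carrier events, not alleles; a homozygote counts
  once.  Per-gene evidence tables list each variant once per carrier.
* "Novel" depends entirely on the supplied panel columns; an annotation
  file with missing frequency columns silently makes everything novel.
* The recessive compound-heterozygote rule cannot verify phase; two
  distinct heterozygous catalogue hits in *LDLRAP1* are assumed to be in
  trans.
* Score weights shipped with the generator are synthetic placeholders
  calibrated to distribution summaries, not the published per-SNP values;
  real analyses must supply the consortium weight table.
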