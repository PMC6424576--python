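# Methods

This note documents the statistical model implemented by `strainflow`, the
assumptions of the bundled cohort simulator, the defaults of every
parameter that matters, and the numerical and design choices made where
more than one reasonable option existed.

## Data model

Strain populations are represented as ternary SNV incidence profiles per
species: each cell of the allele × sample matrix is `1` (allele present),
`0` (position covered by at least one read, allele absent) or `-1`
(position uncovered). The distinction between covered-absent and uncovered
is load-bearing: absence of an allele is only evidence when the position
was observable, and every downstream statistic — incidence frequencies,
pair likelihoods, gained-allele calls — conditions on coverage. The
readers enforce this contract at load time (`PRESENT`/`ABSENT` both imply
coverage) and it cannot be violated downstream because no operation writes
back into profiles.

Alleles are keyed `taxon:position:ref>alt` with 1-based positions on the
representative genome; the identity of an allele is the (position, alt
base) pair, so two alternate bases at one position are distinct alleles.
Multi-allelic positions are therefore treated as independent alleles in
all overlap computations — a choice the score's per-allele factorization
requires, and one that may differ from analyses that collapse positions.

All tables are TSV with `#` comments permitted; result writers emit floats
at 17 significant digits so tables round-trip bit-exactly.

## Filtering

A taxon is analyzable in a sample when three conditions hold
simultaneously: horizontal coverage (genome breadth) ≥ 0.05, vertical
coverage (mean depth) ≥ 0.25, and relative abundance ≥ 1e-6. Taxa are kept
when this conjunction holds in ≥ 10% of all samples pooled across sites;
per-site prevalences are reported separately to support the
prevalent-in-both vs single-site categorization. An SNV is *informative*
when its position is covered in ≥ 10 oral and ≥ 10 gut samples and the
allele is present in ≥ 1 sample of each site; counts are over all samples
of each site in the dataset, consistent with the background frequencies
being global quantities. Oral–gut sample pairs enter scoring only with
shared coverage at ≥ 20 positions; source/sink/sink triplets enter
longitudinal tests only with shared coverage at ≥ 100 positions. All
thresholds are exposed as function arguments and config keys.

## Transmission score

Background incidences `f_oral(i)`, `f_gut(i)` are presence fractions over
covered samples per site. To keep all four cell log-probabilities finite
they are clamped to `[1/(2n), 1 − 1/(2n)]`, where `n` is the site-specific
covered-sample count for that allele — a half-count (Anscombe-style)
pseudofrequency. With the ≥ 10-sample coverage filter the clamp is at most
0.05 from the raw value and only binds for alleles present in no or all
covered samples.

`L_obs` adds agreement log-probabilities and subtracts disagreement
log-probabilities; `L_min` sums the per-allele minimum of the two
agreement log-probabilities. Natural logarithms throughout (the base
cancels in the ratio but is pinned for reported `L` values). Since every
agreement term is ≥ its least-likely counterpart and disagreement terms
enter `L_obs` with positive sign, `L_obs ≥ L_min` always, hence
`P_raw = L_obs / L_min ≤ 1` with equality exactly at the least-likely
full-agreement configuration. The production implementation evaluates all
oral × gut pairs of a taxon with four weighted matrix products; tests pin
it against a per-allele loop written independently.

Backgrounds: four modes are available — `global` (all inter-individual
oral×gut pairs), `cohort` (restricted to the focal subject's cohort;
the default and the mode used for headline results), `subject_global` and
`subject_cohort` (only pairs involving the focal subject's own samples).
Pairs whose two samples share a subject (any timepoints), a family or a
village are excluded from all backgrounds. `μ_raw` and `σ_raw` are the
mean and SD (n−1 denominator) of background `P_raw`; a subject's score is
flagged unavailable with fewer than 10 background pairs or `σ_raw = 0`.
For subjects with several timepoints the intra-individual pair uses the
earliest timepoint with both sites present and eligible.

Classification: the frequent-transmitter test is a one-sample, one-sided
(greater) Wilcoxon signed-rank of subject-level `S_T` against 0 — the
scores are already background-standardized, so the one-sample form is the
natural reading; a two-sample Mann–Whitney of intra vs background `P_raw`
is available as a config option. It requires ≥ 5 scored subjects and is
BH-corrected across taxa. The occasional branch computes an upper-tail
normal p per subject and BH-corrects within taxon across subjects — the
correction family is a design choice (the alternative, correcting across
all taxon×subject pairs, is stricter and would only shrink the occasional
set). Classification is applied to every taxon passing the prevalence
filter, not only those prevalent in both sites.

## Longitudinal analyses

"Gained" fecal alleles require gut coverage at both timepoints (ABSENT at
t0, PRESENT at t1); alleles uncovered at t0 are excluded rather than
treated as absent, because absence is only observable under coverage. The
coupling test forms the 2×2 table {gained vs not} × {present in source at
t0 vs not} over alleles covered in all three samples, uses a two-sided
Fisher exact p with the direction requirement OR > 1 imposed separately
(one-sided available via config), and BH-corrects across the full family
of (taxon, subject, transition, direction) tests. Tables with a zero
gained margin have an undefined odds ratio and are flagged degenerate, not
coupled. Three-timepoint subjects contribute the consecutive transitions
t0→t1 and t1→t2 independently.

The transmission rate is `|gained ∩ oral_t0-present| / |gained|` — a
conservative lower estimate of oral-sourced turnover, since constant
dispersal could also stabilize existing fecal alleles, which sparse
longitudinal sampling cannot quantify. Rates are Z-standardized against
two randomized backgrounds built by permuting samples among subjects
within the same cohort and transition: shuffling gut-t1 samples
(*longitudinal* background, randomizing fecal turnover) and shuffling
oral-t0 samples (*coupled* background, randomizing the reservoir). The
default is 100 seeded shuffles; permutations may map a subject to itself,
which is slightly conservative. A Z score requires ≥ 10 defined shuffled
rates and non-zero shuffled SD.

## Quantification

The classifiable denominator of a sample is the summed relative abundance
of the filtered taxon panel in that sample. The *potential* transmitted
fraction sums frequent and occasional transmitters over that denominator.
The *realized* fraction keeps frequent transmitters detected (by the same
three-way detection conjunction as filtering) in both of the subject's
paired samples, plus occasional transmitters that are individually
significant in the focal subject, and multiplies each species' classified
relative abundance by the subject's oral–gut SNV Jaccard overlap for that
species. Multiplication is the minimal interpretation of adjusting
abundance for partial strain-population overlap; since every factor is in
[0, 1], realized ≤ potential ≤ 1 holds for every sample. The Jaccard
overlap is computed over mutually covered positions only, and an empty
present-set union is defined as overlap 0.

The passive-translocation expectation
`swallowed_per_day · 10^(−log10_reduction) / gut_cells` defaults to
1.5e12 cells/day swallowed, a 5-order-of-magnitude reduction on gastric
passage (the conservative end of the 5–6 range; the parameter is exposed)
and 3.8e13 gut bacteria, giving ≈ 3.9e-7 — the relative fecal abundance
ingestion alone could sustain. Observed transmitted fractions orders of
magnitude above this level indicate active colonization rather than
passive carry-through.

Rarefied richness draws `depth` (default 1000) multinomial observations
from the renormalized abundance vector, `reps` (default 100) times, and
averages the number of species hit at least once. Cohen's d uses the
pooled-variance denominator with n−1 weights.

## Cohort simulator

The generator emulates the *shape* of multi-cohort paired oral/gut SNV
data with known transmission structure:

* Per species, each allele draws an incidence `q_i ~ Beta(a, b)` with
  defaults a = 0.7, b = 3.0 (mean ≈ 0.19, right-skewed — most alleles
  rare, a few common, matching the incidence spectra the score is designed
  around).
* A subject's oral population carries allele *i* with probability `q_i`.
  For transmitter species the gut population copies the oral *state* of
  each allele with probability τ and otherwise redraws from
  `Bernoulli(q_i)`; non-transmitters redraw every allele. Copying the
  state (rather than only carried alleles) keeps the marginal gut
  incidence exactly `q_i` for every class, so transmitter status leaks
  into oral–gut agreement only, never into the background frequencies.
  Defaults: τ = 0.8 for frequent transmitters; occasional transmitters
  apply τ in a random 25% subject subset and behave independently
  elsewhere; `oral_only`/`gut_only` species are undetected (uncovered,
  near-zero abundance, sub-threshold coverage layers) at the other site.
* Coverage dropout is independent Bernoulli per (allele, sample), default
  0.1. Real coverage is read-depth-driven and spatially correlated;
  independence suffices to exercise the UNCOVERED logic and the coverage
  filters but understates the variance of per-pair shared-position counts.
* Between consecutive timepoints a fraction θ (default 0.2) of the gut
  allele set is replaced. Each gained allele is copied from the subject's
  baseline oral set minus the current gut set with probability r (default
  0.5) or else drawn from an environmental pool of alleles carried by
  neither the current gut set nor the baseline oral set. Keeping the pool
  disjoint from the oral reservoir makes r identifiable as the oral
  fraction of gained alleles; exhausted oral reservoirs fall back to the
  pool and the fallback is recorded in the truth record. Oral populations
  are constant over time.
* Abundances are per-(species, sample) log-normal draws (σ = 1.0),
  normalized per sample to 0.95 with a 5% unclassified remainder;
  single-site specialists are further enriched 4-fold at their home site.
  Detected taxa draw breadth in [0.3, 0.95] and depth in [0.5, 5];
  undetected taxa fall below every filtering threshold.
* Families are optional subject pairs whose later member copies the
  earlier member's oral state with a configurable probability — enough
  structure to exercise the family-exclusion paths in background
  construction. Village grouping is accepted in metadata but not
  simulated.

One integer seed fully determines every output byte. The truth record
stores each species' class, each subject's baseline oral–gut shared-allele
fraction, and the source label of every gained allele.

What passing tests on this simulator do *not* show: robustness to
read-depth-correlated coverage, to site-specific incidence spectra
(`f_oral ≠ f_gut` systematically), to shared evolutionary history between
subjects (the simulator's alleles are exchangeable tokens without linkage
or phylogeny), or to compositional noise in abundance estimates. The
simulator is a correctness and calibration harness, not a realism claim.

## Problem sizes and calibration behaviour

Simulation-based checks run at 30–50 subjects with species of 200 alleles
(null-calibration sweeps use 20 species × 20 seeds; the distributional
null check uses 200 subjects), sizes at which every property of interest
is measurable while the full test suite stays fast.

One behaviour worth knowing when reading classification output at small
cohort sizes: all subjects of a taxon share the same estimated background
(μ_raw, σ_raw), so subject-level scores are positively correlated within
taxon, and the effective information in the background is set by the
number of background *subjects*, not pairs. On fully null cohorts the
frequent-transmitter call rate stays well under the 5% BH level, but in
mixed cohorts — where BH's step-up threshold is relaxed by genuine
positives — an unlucky background draw can occasionally push a null taxon
over the line. With ~50 subjects this costs a point of specificity in a
minority of random replicates; it shrinks with cohort size as the
background mean stabilizes. The per-subject occasional branch is
unaffected.

## Known limitations

* The score treats alleles as independent; linkage between SNVs of one
  strain makes effective evidence smaller than the allele count, so
  `S_T` magnitudes are comparable between taxa only loosely.
* Background incidences are estimated from the same dataset being scored;
  in very small datasets the focal subject's own contribution to
  `f_oral`/`f_gut` is not removed.
* The frequent/occasional boundary is a continuum: a species transmitting
  strongly in a sufficiently large subject subset will satisfy the
  cohort-wide rank test and be called frequent.
* Transmission rates are lower bounds (gained alleles only) and undefined
  for subject/taxon pairs without fecal turnover.
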