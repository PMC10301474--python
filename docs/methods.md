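# Methods

## The inference model

The caller formalizes a judgement clinical reviewers make visually on
TaqMan Genotyper plots. Its premise is purely allelic-ratio: with two
gene copies a heterozygote produces balanced allele-specific signal
(variant fraction ≈ 0.5); with three copies the ratio is 2:1, so the
endpoint lands near fraction 1/3 or 2/3 depending on which haplotype
carries the extra copy. Everything else is calibration and decision
rules.

**Fraction coordinate.** Each endpoint (VIC, FAM) is projected onto
f = FAM/(VIC+FAM). This deliberately discards the radial (total signal)
dimension of the 2-D plot: the duplication signal lives entirely in the
allelic ratio, and total fluorescence varies with amplitude and lot
effects that the projection cancels. This is a documented divergence
from the visual method, which sees both dimensions.

**Cluster model.** Per assay and run, 2-copy samples with known class
(controls from prior lots plus concurrently run patients) give each
class a center (median fraction) and robust spread
(MAD × 1.4826, floored at `floor_sd = 0.005` so that noise-free runs do
not produce infinite z). Fitting per run absorbs lot-to-lot channel
scaling, which moves all clusters of a run coherently. Classification
zones are center ± 0.12, kept for reporting; the shift statistic uses
the heterozygous center and spread only. Calibration requires ≥ 2
points in each represented class and a heterozygous class.

**Shift statistic and votes.** For a query heterozygote with replicate
fractions f₁, f₂: zᵢ = (fᵢ − center)/spread, z = mean. A shift is
*confident* when both replicates fall on the same side and each
|zᵢ| ≥ `z_min = 3`. A confident shift toward the variant axis votes for
the haplotype carrying the variant at that assay; toward the reference
axis, for the other haplotype — the direction→haplotype mapping goes
through the allele-definition table, never the assumption that the
variant allele is the minor one (a reference-ward shift at a
*41-tagging site is evidence for duplication of *1).

**Decision rule.** Name the duplicated allele only when all confident
votes agree, at least `min_votes = 2` exist, and the three CNV probes
agree on exactly 3 copies. Otherwise defer to sequencing with explicit
reasons (too few informative SNVs, weak shift, replicate discordance,
conflicting votes, low comparator count, CNV inconsistency). Ties and
conflicts always defer: the clinical value of the method rests on 100%
accuracy among attempted calls, with ambiguity routed to sequencing.
With these defaults single-SNV cases always defer and clean multi-SNV
cases are called, mirroring the reviewers' deferral pattern; all three
thresholds are exposed in configuration.

**Why conflicts matter (dropout guard).** A rare variant under a primer
can suppress one allele at one assay and fake a shift. In the modeled
scenario — a *1×2/*41 carrier with wild-type dropout at c.886C>T — that
assay votes *41 while c.985+39G>A and c.1457G>C vote *1; the caller
returns DEFER(conflicting_votes) rather than a wrong call. This is why
`min_votes` ≥ 2 and unanimity are non-negotiable defaults.

## Copy-number interpretation

The three probes (promoter, intron 6, exon 9, normalized to a control
gene) see hybrid alleles differently: *68-like hybrids contribute
(1,0,0), *36-like (1,1,0), *13-like (0,1,1), full copies (1,1,1),
deletions nothing. `enumerate_structures` solves the resulting integer
equation exhaustively (closed form over the free hybrid counts) and
sorts solutions by parsimony: fewest hybrid copies, then more full
copies. All solutions are always reported — the ordering is a
heuristic, not a probability model — and `consistency_check` filters
them by the full-copy count implied by the SNV side; anything but a
single survivor recommends sequencing. The hybrid basis is restricted
to the three probe-signature classes; at three-probe resolution other
hybrids collapse onto these signatures.

Rounding: a probe estimate maps to the nearest integer when within
`ambiguity_halfwidth = 0.35`, else AMBIGUOUS (chosen so a plateau at
x.5 ± replicate noise is always flagged). All three probes ambiguous at
the *same* half-integer raises `suspect_control_gene_variant`: one
suppressed control-gene copy scales every estimate by 2/(1+η), and a
2-copy sample with η = 0.6 reads exactly 2.5 everywhere. Estimates above
`validated_max = 6` raise `exceeds_validated_range`; the assay's true
validated ceiling is not published, so 6 is a configurable choice.

## Activity scores and phenotypes

Scores are data, not code: a per-allele table (*1 = *2 = *2A = *27 =
*35 = 1.0; *9 = *17 = *29 = *41 = *59 = 0.5; *10 = 0.25; nulls, hybrids
and the deletion 0) shipped as JSON and user-replaceable. The score is
the sum over all gene copies; phenotype cutpoints are the consensus
boundaries 0 / ≤1 / ≤2.25 / >2.25 (Poor/Intermediate/Normal/Ultrarapid).
A ×N term (unknown multiplicity ≥ 2) is represented distinctly from a
numeric count and scores as an open bound — the score with N set to 3,
reported ">k" — which resolves to a phenotype only when the entire
admissible range falls in one band. Two printed reference rows
(*4×2/*29×2 and *1×2/*36+*10) are inconsistent with *any* per-allele
value table that fits the remaining rows; they are marked
`score_consistent = 0` in the packaged cohort fixture and excluded from
golden comparisons as probable typos.

Canonical diplotype strings order the higher-activity haplotype first
(ties by numeric star order); comparisons in tests are order-insensitive
because published strings do not follow a single consistent ordering.
Unphaseable extra copies (e.g. a sequencing-identified *2 in a 4-copy
*2A/*17 case) are reported as an alternatives pair
(`*2A×2/*2+*17 or *2A×2+*2/*17`); both phasings are required to share
one activity score, so the phenotype is unaffected.

## The simulator

The generator emulates one run of an endpoint-genotyping panel plus the
CNV assay; it is the package's definition of the study conditions, not a
tuning knob.

* Per sample × assay, the true fraction follows from the diplotype's
  per-assay allele counts, restricted to each allele's CYP2D6-derived
  segment (a *68-like hybrid amplifies only promoter–exon 1 assays, a
  *13-like only intron 1 onward). Gaussian noise with
  `sigma_f = 0.02` is applied per replicate in the fraction coordinate,
  clipped to [0,1], then mapped back to (VIC, FAM) via a radial gain
  with lognormal amplitude jitter (sd 0.1) and per-run lognormal lot
  scale factors (sd 0.1) on each channel. σ_f = 0.02 puts the 0.167
  duplication shift at ≈ 8σ, consistent with most cases being visually
  unambiguous. PCR kinetics and trajectory traces are not modeled —
  endpoint geometry only.
* Allelic dropout is a continuous efficiency η ∈ [0,1] scaling one
  allele's effective copy count at a chosen assay, so full dropout and
  partial skew are both reachable.
* CNV estimates are true probe copies × 2/(1+η_ctrl) + N(0, σ_c = 0.1),
  floored at zero, two replicates; η_ctrl applies to
  interference-flagged samples (default 0.6, the minimal ratio model
  producing non-integer plateaus like 2.5 from 2 copies).
* Qualitative genotype calls are emitted from truth: the instrument
  software's calls are an *input* to the method. Dropout skews signal,
  not call labels.
* Comparator samples are synthetic 2-copy samples heterozygous (or
  homozygous) at every assay — an abstraction: real concurrent patients
  are heterozygous at a genotype-dependent subset. Defaults (4 controls
  per class, 6 concurrent heterozygotes) give 10 het comparators per
  assay.

The packaged cohort fixture reproduces the reference study composition:
73 three-copy cases over 30 genotypes (mode *1/*4×2, n = 11), 11
hybrid/multicopy cases with their probe triples, 3 ambiguous-CNV cases
flagged for control-gene interference. The fixture's printed
informative-SNV counts (range 1–5, median 3) are stored as metadata;
they cannot all be derived from fixed per-allele definitions (two
printed rows assign different counts to the same allele pair), so the
simulator derives counts from the packaged definitions instead, which
agree for 25 of 30 main genotypes. The one ×N record expands to N = 4
for simulation. What passing simulations do *not* show: performance on
real instrument exports with asymmetric cluster shapes, cross-assay
signal correlation, or rare alleles off the panel.

## Evaluation

Accuracy counts only attempted (non-deferred) cases. Cohen's kappa
(p_o − p_e)/(1 − p_e) is computed per rater pair and averaged;
identical rating vectors score 1.0 by convention, covering the
degenerate single-category case. Correctness agreement restricts each
pair to cases both raters attempted; report-vs-defer agreement uses all
cases.

## Problem sizes and numerical choices

Tests and the acceptance script use the 73-case packaged cohort and a
200-case resampled cohort (seeded draws from the main-genotype mix) —
sizes chosen to match the reference composition while keeping the whole
suite in seconds. Degenerate inputs: zero total fluorescence is a
non-amplification error; zero spread is floored; z = 0 has direction
"none"; missing CNV probes mark the copy number unresolved (deferral)
rather than guessing.

## Known limitations

* The panel ships only the star alleles resolvable on it and appearing
  in the reference cohorts; it is not a PharmVar catalog.
* Hybrid tandem attachment uses canonical partners (*68 with *4, *36
  with *10) and otherwise the duplicated haplotype — a heuristic;
  three-probe data cannot phase hybrids.
* Multi-run pooling of comparator samples is deliberately unsupported;
  calibration is per run.
* Whether control-gene interference can co-occur with a true
  duplication is unresolved; the interference fingerprint simply defers.
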