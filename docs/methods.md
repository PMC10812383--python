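# Methods

This note documents the models, rules and numerical choices behind
`polestrat`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the design was genuinely open.

## Variant model

Variant calls are short-form protein HGVS labels. The parser accepts an
optional `p.` prefix, is case-insensitive, and normalizes stop codons
(`X` or `*`) to `*` internally. Supported kinds: missense, nonsense,
frameshift (`fs`, with optional `*n` tail), delins, in-frame
deletion/insertion, duplication, and splice annotations (any label
containing "splice"; the residue is taken from the first digit run when
present). Multi-residue events are positioned by their start residue.
Full HGVS (intronic, UTR, complex rearrangements) is out of scope.

The POLE protein is modeled as 2,286 residues with two interval tiers:

* **Lobes** (must tile the protein exactly): N-terminal lobe (NTL)
  residues 1–1,183, C-terminal lobe (CTL) 1,184–2,286.
* **Domains** (non-overlapping, gaps allowed): NTD 1–267, ExoD 268–471,
  palm 528–950, fingers 951–1,075, thumb 1,076–1,183, CTD 1,184–2,286.

The ExoD interval and the polymerase subdomain boundaries are
configurable defaults, not measurements: they were chosen to contain the
20 driver residues (275–465) and the standard subdomain assignments of
reference residues (palm 680, thumb 1,125, CTD beyond 1,183). Analyses
sensitive to whether a boundary variant is "ExoD" or not should treat
these intervals as a tunable input (`domain_map.json`).

The driver catalog ships as shorthand
(`D275G, P286R, S297F/Y, F367C/L/V, V411L, L424F, P436R/S/Y, M444K/L,
A456P, S459F/Y, S461L/P, A465V`) and expands to exactly 20 alleles.
Driver matching is exact on (reference residue, position, alternate):
M444I is not a driver (the catalog holds M444K/L), and a delins spanning
a driver residue is never a driver.

## Stratification

A tumor enters the cohort if it carries at least one POLE variant and has
a TMB value. With the default threshold t = 10 mut/Mb (inclusive on the
high side):

| group | TMB | drivers | additional variants |
|-------|-----|---------|---------------------|
| G1 | < t | — | any |
| G2 | ≥ t | ≥ 1 | 0 |
| G3 | ≥ t | ≥ 1 | ≥ 1 |
| G4 | ≥ t | 0 | ≥ 1 |

Driver *presence*, not count, separates G2/G3 from G4; tumors with two
drivers and no extra variant are G2. A TMB-low tumor that contains a
driver is kept in G1 and flagged (`driver_with_low_tmb`) rather than
reclassified — the taxonomy is TMB-first. MSI vocabulary is collapsed to
MSS / MSI-H; MSI-low and unrecognized values count as MSS for the
substatus (with a warning for unrecognized input), since the group tables
dichotomize. Group medians use the midpoint convention (even n: mean of
the two central order statistics), which is how values like 264.5 arise.

## Signature context engine

A coding SNV is typed by its trinucleotide context read from the coding
sequence at position − 1 / position + 1 and normalized to a
pyrimidine reference (purine-reference contexts are reverse-complemented),
giving one of 96 channels. Normalization is an involution under reverse
complement and idempotent on normalized input; non-SNVs (frameshift,
delins, splice) have no channel.

For each POLE-proofreading signature (SBS10a, SBS10b, SBS14, SBS28) the
*context set* is every channel whose probability exceeds the inclusion
threshold (default 1%, strict); its coverage is the exact sum of the
included probabilities, monotone non-increasing in the threshold. Hotspot
channels are fixed per signature: T[C>A]T (SBS10a), T[C>T]G (SBS10b),
N[C>A]T i.e. all four 5′ bases (SBS14), T[T>G]T (SBS28). A variant is "in
a POLE ExoD context" if its channel lies in the union of the four sets;
multi-signature matches count once in the fraction and are itemized in
the per-signature breakdown.

Because the denominator convention for context percentages is a genuine
choice, both are always reported: the SNV-resolvable denominator
(non-SNVs excluded, the default `fraction`) and the all-variants
denominator (`fraction_all_variants`). An empty denominator yields an
explicit undefined result, not zero.

### Bundled reference fixtures are synthetic stand-ins

The shipped signature table (`data/sbs_pole_synthetic.tsv`) is **not**
the COSMIC v3 release; it is a constructed stand-in that reproduces the
documented structure of those vectors: each hotspot dominates its
signature, the known minor channels are above the 1% rule (G[C>T]G in
both SBS10a and SBS10b; C[C>T]G in SBS14), the >1% channels jointly
carry 88.5% of each signature's mass (the real vectors' >1% channels
carry 88–89%), and the remaining mass is spread uniformly below the
threshold. Likewise `data/pole_cds_synthetic.fasta` is a deterministic
2,286-codon random coding sequence (all 32 reference trinucleotide
contexts realizable, no internal stops), not the NM_006231 sequence.
Consequences: the context *engine* and all its invariants are fully
exercised, but absolute in-context percentages computed against these
fixtures characterize the stand-ins, not the genome-derived references.
Both files are drop-in replaceable (COSMIC-format TSV; FASTA) via
`RunConfig.signature_path` / `transcript_path`, and the signature source
is recorded in the run manifest.

## Cohort statistics

Mann–Whitney U uses midranks for ties. The exact permutation null is
used when both arms have ≤ 20 observations and the pooled sample is
tie-free; otherwise a tie-corrected normal approximation with continuity
correction. Comparisons with ≤ 2 datapoints in either arm are refused
with an explicit status — not reported as p = 1. Significance stars:
\*\*\* p < 0.001, \*\* p < 0.01, \* p < 0.05, NS otherwise.
Benjamini–Hochberg adjustment is the standard step-up with monotonicity
enforcement, input order preserved; the comparison family is whatever
list the caller passes — no implicit pooling. Spearman uses midranks with
the t approximation. The implementations delegate to scipy/statsmodels;
the test suite checks them against independent brute-force enumeration
and the step-up formula directly.

## Annotation rules

* **Stability**: ΔΔG ≥ +1.45 kcal/mol destabilizing, ≤ −1.45
  stabilizing, else neutral; boundaries inclusive; classification is
  mirror-symmetric under ΔΔG → −ΔΔG. The cutoff corresponds to roughly
  three standard deviations of decoy-set score differences in the
  upstream energy protocol; the structure modeling itself is out of
  scope — records arrive as (variant, model, ΔΔG) rows, with the
  DNA-bound model meaningful only for NTL variants. The census
  cross-tabulates class × lobe × model and conserves totals per model.
* **Neoantigens**: categories from (MHC binding, T-cell reactivity)
  scores in [0,1] with inclusive 0.5 thresholds — (≥,≥) immunogenic,
  (≥,<) nonimmunogenic, (<,≥) no biological significance, (<,<) none —
  a partition of the unit square. The modified neoantigen burden is the
  per-tumor count of immunogenic calls.
* **Group-3 exclusivity**: keep (gene, protein-change) keys with ≤ 1
  occurrence in Group 2 and ≥ 2 in Group 3; anti-monotone in G2 counts,
  monotone in G3 counts.

## Synthetic cohort generator

The generator's defaults are the study conditions the analysis assumes:
group sizes per cancer type (CRC 36/11/24/21, EC 95/37/57/118,
OC 24/12/8/4), per-group TMB medians and ranges (e.g. CRC G3 264.5,
114–414; EC G3 219, 53–520), MSI fractions, under-50 age fractions and
sex composition, all taken from the group-table structure the pipeline
summarizes.

**TMB sampling.** Only a median and a range are specified per group, so
the default sampler is a median-anchored two-piece log-uniform: with
probability ½ log-uniform on [min, median], otherwise on [median, max].
This makes the configured median the exact distribution median while
keeping the support equal to the configured range; a plain log-uniform
(whose median is the geometric mid-range and can miss the target by >20%)
and a range-truncated log-normal are available as alternatives. Samples
are rounded to 0.1 mut/Mb. Configs whose G1 range reaches the TMB
threshold (or whose G2–G4 ranges start below it) are rejected as
infeasible rather than silently clipped.

**Drivers.** Driver-bearing tumors draw their allele with weights
P286R 0.40, V411L 0.27, remainder equal over the other 18 alleles, so
P286R+V411L cover ≈ 67% of driver-bearing tumors; a second distinct
driver is added with probability 0.01 (such tumors stay G2/G3 by the
presence rule). G3 additional-variant counts follow
{1: 0.55, 2: 0.25, 3: 0.12, 4: 0.05, 5: 0.03}; G1/G4 variant counts
{1: 0.7, 2: 0.2, 3: 0.1}.

**Passenger variants.** Each passenger picks a mixture component
(default SBS10a 0.20, SBS10b 0.35, SBS14 0.15, SBS28 0.08, uniform noise
0.22), then a channel from that component's 96-channel vector (uniform
for noise), then uniformly one of the CDS positions realizing that
channel (directly or by reverse complement), yielding a concrete coding
change and its derived protein label. Synonymous draws, stop-codon
positions and accidental collisions with catalog driver alleles are
re-sampled; for distributional tests the synonymous filter can be
disabled so the channel distribution matches the mixture closed form.
Under the default mixture the expected Group-3 in-context fraction is
≈ 0.76 (signature components contribute ≈ their coverage, the noise
component the union's channel share), in the 60–80% band the group
structure implies; it is an emergent property of the mixture, not a
fitted constant. A single seeded NumPy generator is threaded through all
sampling — no global state — so identical (config, seed) reproduces the
cohort record-for-record.

**What the generator does not emulate:** MSI mutational processes,
comutation landscapes, panel-specific TMB measurement error, germline
contamination, and any correlation between TMB and the number or context
of POLE variants beyond the group structure itself. Passing tests
therefore validate the pipeline's logic and its statistical machinery on
cohorts with the assumed structure; they are not evidence about any real
cohort.

## Problem sizes and tolerances

The default test suite and the acceptance script use the full default
cohort (447 tumors), k = 1000 draws for mixture-recovery checks (3
binomial standard errors), k = 5000 × 5 seeds for the chi-square
goodness-of-fit (α = 0.01, ≤ 1 rejection allowed), 20 replicate cohorts
for median recovery (±15%), and complete permutation enumeration for
Mann–Whitney samples up to n_a + n_b = 10. The acceptance script averages
per-group medians over 10 replicate cohorts because a sample median over
n = 8 tumors (OC Group 3) is otherwise dominated by sampling noise.
Exact-test p-values are compared to enumeration at 1e-12; probability
sums are validated at 1e-6; context-set coverage is reported exactly.

## Known limitations

* The bundled signature vectors and transcript are synthetic stand-ins
  (above); swap in genome-derived files for production analyses.
* Domain boundaries are literature-style defaults; boundary variants can
  change ExoD/non-ExoD tallies.
* Splice labels without a digit run carry no residue and cannot be
  domain-annotated.
* The BH step-up is not idempotent (no multiple-testing adjustment is);
  adjusted p-values must not be re-adjusted.
* The exclusivity filter matches protein-change strings after HGVS
  normalization; it does not resolve transcript-level synonyms across
  annotation sources.
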