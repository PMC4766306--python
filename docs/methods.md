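# Methods

## The screening problem

`cypscreen` implements a bait-gene comparative co-expression screen for
candidate biosynthetic enzymes in non-model plants, together with the
enzymology used to validate such candidates. The motivating setting is
Amaryllidaceae alkaloid biosynthesis: the only validated pathway gene,
norbelladine 4′-*O*-methyltransferase (N4OMT), sits immediately upstream
of the C–C phenol-coupling step, so transcripts that track N4OMT's
tissue-expression pattern across several independently assembled
transcriptomes — and that encode cytochrome P450s, the enzyme family
expected to catalyse phenol coupling — are strong candidates for the
coupling enzyme.

The screen runs per "assembly" (a species × assembler combination) and
then intersects across assemblies:

1. **Bait selection.** The transcript encoding the closest homolog of the
   bait reference protein is identified by local protein alignment.
2. **Co-expression.** Every transcript's three-tissue expression vector
   (leaf, inflorescence, bulb) is matched against the assembly's bait
   model (see below).
3. **P450 classification.** In the reference assembly, co-expressing
   transcripts are kept when their predicted peptide hits a reference
   P450 protein set at E ≤ 10⁻⁴.
4. **Cross-assembly linking.** Each reference candidate is aligned, at
   the nucleotide level, against the *co-expressing transcript lists* of
   the other assemblies; presence means a best hit at E ≤ 10⁻⁵⁰ among
   those list members (not anywhere in the assembly — membership in the
   co-expression list is part of the evidence).
5. **Intersection.** A candidate present in all lists (its own reference
   list counts) is flagged top priority. The required presence count is
   configurable; the default is all assemblies.

## Expression-model matching

A transcript with tissue vector *v* matches the bait model *m* when all
of the following hold (defaults in parentheses):

* Pearson correlation r(v, m) ≥ corr_cutoff (0.8);
* background = max(v) ≥ background_cutoff (1, in the matrix's own
  expression units);
* fold = max(v) / max(min(v), background_cutoff) ≥ fold_cutoff (4);
* two-sided p ≤ p_cutoff (0.05), from t = r·√((n−2)/(1−r²)) on n−2
  degrees of freedom (optional, on by default).

Two numerical points deserve emphasis. First, with n = 3 tissues the
parametric p-criterion requires |r| ≥ 0.9969 at p ≤ 0.05, so whenever it
is enabled it dominates the 0.8 correlation cutoff. A permutation test
over three tissue labels cannot get below p = 1/3! ≈ 0.17, so the
parametric form is the only reading under which near-perfect profiles
can pass at 0.05; it is the one implemented. Second, the fold-change
denominator is floored at the background cutoff because bait models
legitimately contain near-zero entries (0.01 RPM in leaf), which would
otherwise make folds explode.

Correlation is computed on raw abundances by default; a `log_transform`
flag (log1p on both vectors) is available since quantification pipelines
differ in whether pattern matching is done on a log scale. Matching is
invariant under positive rescaling of *v* except for the background
criterion, which is intentionally scale-bearing.

## Homology search and significance

Pairwise search is optimal Smith–Waterman local alignment with affine
gaps (no seeding heuristics — exact DP is affordable at the scales this
package targets; an optional shared-8-mer prefilter is provided as a
speed flag). Scoring defaults: BLOSUM62 with gap open 11 / extend 1 for
peptides; +1/−2 with gap open 5 / extend 2 for nucleotides. Significance
uses the Karlin–Altschul expectation E = K·m·n·e^(−λS) with the classic
gapped-search constants (protein K = 0.041, λ = 0.267; nucleotide
K = 0.46, λ = 1.28). These are configurable; the cutoffs used by the
screen (10⁻⁴ permissive protein stage, 10⁻⁵⁰ stringent nucleotide
linking stage) are the screen's defining constants. E-values that
underflow double precision are clamped to the smallest positive double
so they remain positive and orderable.

Ties in best-hit selection are broken by higher raw score, then
lexicographic subject id, making results independent of subject order.

Peptides are predicted as the longest ATG-initiated open reading frame
over six frames (stop excluded; an ORF may run off the end of its frame,
as is common for incomplete de novo assemblies). This replaces a trained
ORF predictor: it is deterministic, dependency-free and adequate for
synthetic coding transcripts; it will under-call peptides on real
assemblies with 5′-truncated ORFs lacking an ATG.

P450 annotation reports the four consensus motifs — EXXR, PXRX (canonical
instance PERF), the heme-binding FXXGXRXCXG decapeptide and the oxygen
binding and activation motif (A/G)GX(D/E)TT — as advisory hits;
classification itself is purely homology-based. Motif positions are
0-based half-open internally and reported 1-based where the P450
literature convention applies.

## Synthetic data: what it emulates and what it does not

The generator produces, per assembly: a bait transcript whose expression
equals the assembly's bait model exactly; one planted P450 orthogroup
(optional) with expression proportional to the bait model times
multiplicative log-normal noise (log-scale sd `expression_noise_sigma`);
decoy P450s and non-P450 background transcripts with per-tissue means
drawn uniformly on [0.1, 200] — spanning the dynamic range of the real
bait models — times the same noise; and optionally a bait-correlated
*non-P450* transcript as a negative control for the classification gate.
Default bait models are the five published N4OMT models (relative RT-PCR
units for the reference *Narcissus* assembly; RPM/TPM for the *Galanthus*
assemblies).

Sequences are built from two deterministic synthetic templates (a
500-residue P450-like peptide carrying the four consensus motifs, and a
360-residue motif-scrubbed bait peptide), reverse-translated with random
codons and framed by short UTRs. Orthogroup members in non-reference
assemblies are substitution-mutated from the reference member at exactly
`homolog_identity` (default 0.95), with the start codon protected and
in-frame stops rejected; decoys are independent draws at 50–65% peptide
identity from the template, so they classify as P450s but cannot link
across assemblies at the stringent nucleotide cutoff.

**Choice of the default noise level.** Because the three-tissue
p-criterion demands r ≥ 0.9969, planted-signal noise must be small
relative to the model's dynamic range for the planted candidate to pass
in *every* assembly. The default `expression_noise_sigma = 0.02` keeps
the per-assembly failure probability of the worst-conditioned model
(1/30/45) below ~10⁻³, consistent with the near-perfect correlations
observed for genuine pathway co-expression; by σ ≈ 0.05 the five-of-five
recovery probability falls to roughly 85% per seed, and tests document
recovery at the default rather than at that boundary.

What the generator does **not** emulate: realistic transcriptome scale
(~10² transcripts per assembly versus ~10⁵ in real assemblies — the
published transcript counts are not reproducible from synthetic data and
are out of scope), isoform redundancy, indels and assembly chimerism,
count-based sampling noise in expression estimates, or mean–variance
relationships of RNA-seq quantification. Passing tests therefore
demonstrate correctness of the screen's logic and statistics under its
own assumptions, not performance on real transcriptomes.

## Kinetics

Velocity follows the standard uncompetitive substrate-inhibition law

    v(S) = kcat·[E]·S / (Km + S + S²/Ki),

which reduces to Michaelis–Menten as Ki → ∞ and peaks at S* = √(Km·Ki).
Units: S, Km, Ki in µM; kcat in 1/min; [E] in nM; hence v in nM/min and
kcat/Km in 1/(µM·min).

Fitting is damped least squares (trust-region reflective with positivity
bounds) with an analytic Jacobian, relative tolerances 10⁻¹⁰, at most 500
function evaluations. Initialisation: kcat ← max(v)/[E]; Km ← S at
half-maximal observed velocity on the rising limb; Ki ← 10 × max(S) —
robust starting points for inhibition-shaped curves. Standard errors are
asymptotic (from the Jacobian at the optimum, residual variance on n − p
degrees of freedom); they are reported as such, without claiming they
match any particular published uncertainty convention. Under model
`"auto"`, a finite Ki is reported only when the substrate-inhibition fit
reduces the residual sum of squares by ≥ 5% relative to the
Michaelis–Menten fit — the rule that operationalises "no substrate
inhibition observed" for poor substrates.

The kinetics simulator draws v = model(S)·(1 + ε), ε ~ N(0, cv), clipped
at zero, on a 12-point geometric grid spanning 0.25–200 µM in triplicate
by default, with [E] = 2.5 nM and 5% noise — the assay geometry used by
the recovery analyses. Default generating constants are the published
values for the preferred substrate (Km 1.13 µM, kcat 15.0 min⁻¹,
Ki 64.3 µM).

Two closed-form assay calculators round out the module: the −2 m/z rule
for C–C phenol-coupled product precursors (oxidative coupling of two
phenol rings loses two hydrogens; note that published MRM tables may
show small deviations from the rule for individual compounds, e.g.
286.20 monitored where the rule gives 286.30 — the rule's output is not
forced to match instrument-tuned values), and molar ratios from tissue
contents in mg/g with molar masses of 301.34 g/mol (haemanthamine) and
287.35 g/mol (galanthamine).

## Assembly statistics

N50 uses the descending-cumulative-sum convention: the first length at
which the running total reaches half the assembly total. Median of an
even-count set is the mean of the central pair. All residues, including
N, count toward lengths. An optional minimum-length reader filter mirrors
assembler-style cutoffs (100/201 bp in the emulated datasets) and is off
by default.

## Problem sizes and determinism

Default scenario sizes (5 assemblies × 123 transcripts, 100 kinetics
datasets × 36 points) were chosen so a full test run plus the acceptance
computation completes in well under a minute on one core while leaving
every stage statistically meaningful. All stochastic operations take
explicit seeds; the screen itself is deterministic given its inputs.

## Known limitations

* Karlin–Altschul constants are not re-estimated for the implemented
  aligner; E-values are calibrated in the BLAST sense, not empirically.
* No composition-based statistics or edge-effect corrections.
* The packaged reference P450 set is synthetic (template-derived); real
  classification should substitute a curated P450 protein FASTA.
* The parametric correlation p-value on three tissues is a modelling
  convention, not a guarantee of calibrated error rates at n = 3.
* Whether published "±" uncertainties are SEs or SDs is not modelled;
  asymptotic SEs are reported.
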