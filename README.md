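# cypscreen

Bait-gene comparative co-expression screening for cytochrome P450
discovery in non-model plants, with the enzymology to back it up.

When a metabolic pathway has exactly one validated gene, the tissue
expression pattern of that gene is itself a search query: transcripts
that reproduce the pattern across several independently assembled
transcriptomes, and that belong to the right enzyme family, are prime
candidates for the neighbouring pathway steps. `cypscreen` implements
that screen end-to-end for the Amaryllidaceae-alkaloid setting — bait
N4OMT (norbelladine 4′-*O*-methyltransferase), target family cytochrome
P450 — plus the substrate-inhibition kinetics and mass bookkeeping used
to characterise the enzyme a screen like this turns up.

## What it computes

**Co-expression matching.** Transcript vector *v* (leaf, inflorescence,
bulb) matches the bait model *m* when

r(v, m) ≥ 0.8, max(v) ≥ 1, max(v)/max(min(v), 1) ≥ 4, and p ≤ 0.05,

where p is the two-sided parametric test on r with n − 2 df. With three
tissues the p-criterion is the sharp one: it requires r ≥ 0.9969.

**Homology.** Exact Smith–Waterman local alignment (BLOSUM62 11/1 for
peptides, +1/−2 with 5/2 gaps for nucleotides) scored with
Karlin–Altschul E-values E = K·m·n·e^(−λS). The screen uses E ≤ 10⁻⁴
for P450 classification against a reference protein set and E ≤ 10⁻⁵⁰
for stringent cross-assembly nucleotide linking; candidates present in
five of five co-expression lists are top priority.

**Kinetics.** v(S) = kcat·[E]·S / (Km + S + S²/Ki) — uncompetitive
substrate inhibition, reducing to Michaelis–Menten as Ki → ∞ — fitted by
damped least squares with analytic Jacobian; catalytic efficiency
kcat/Km; the −2 m/z rule for C–C phenol-coupled products; molar ratios
from tissue contents.

**Synthetic data.** A seeded generator produces multi-assembly datasets
with a planted bait-correlated P450 orthogroup among decoys, and noisy
substrate-inhibition assays, so every stage is testable without
downloads. See `docs/methods.md` for the model and its limits.

## Worked example

Simulate a five-assembly dataset with one planted orthogroup, then run
the screen:

```
$ cypscreen simulate --seed 3 --out demo
wrote 5 assemblies to demo
$ cypscreen screen --config demo/screen_config.yaml --out demo/report.tsv
...
narcissus_abyss_mira: 2 co-expressing P450 candidates
1 top-priority candidates
2 candidates (1 top priority) -> demo/report.tsv
```

The report's top line is the planted candidate, recovered in all five
assemblies with a near-perfect bait correlation and the P450 consensus
motifs at their canonical residue positions:

```
candidate_id                 r       fold   background  p        n_assemblies_present  top_priority  motifs
narcissus_abyss_mira|t0070   0.9999  44.05  53.96       0.0096   5                     True          ...EXXR@387;PXRX@430;heme_FXXGXRXCXG@464;oxygen_binding@320
```

Fit a simulated substrate-inhibition assay (Km 1.13 µM, kcat 15 min⁻¹,
Ki 64.3 µM, enzyme 2.5 nM, 5% noise):

```
$ cypscreen simulate-rates --seed 2 --out rates.csv
$ cypscreen kinetics-fit rates.csv --enzyme-conc 2.5
{
  "model": "substrate_inhibition",
  "km_uM": 1.1639,
  "kcat_per_min": 14.993,
  "ki_uM": 67.049,
  "efficiency_per_uM_min": 12.88,
  ...
}
```

The fitted constants land on the generating values within their
uncertainties; the efficiency of ~13 µM⁻¹·min⁻¹ is what marks the
preferred substrate. The small calculators:

```
$ cypscreen mz --coupled 274.30          # phenol-coupled product precursor
272.30
$ cypscreen molar-ratio --content-a 2.23 --mw-a 301.34 --content-b 0.246 --mw-b 287.35
8.644                                    # haemanthamine : galanthamine, molar
```

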