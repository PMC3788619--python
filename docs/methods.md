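# Methods

## pSNV annotation

A phosphosite is an S/T/Y residue with a 15-mer window (position 8 central,
±7 flanks, `_`-padded at protein termini). A missense variant within the
window is a pSNV; its class is a total function of the offset and the
substitution: offset 0 is *direct* unless the exchange is S↔T (kinases
phosphorylate serine and threonine interchangeably, so the acceptor
survives; such variants are kept as *proximal*), |offset| ≤ 2 is *proximal*,
3–7 is *distal*. Windows of nearby sites are merged into continuous regions
(closed 1-based intervals, overlap-or-abut rule), which makes residue
exposures and region-level counts additive: a variant inside two
overlapping windows yields one annotation per window but is counted once in
every tally, keyed by (protein, position, ref, alt, sample). Variants whose
reference amino acid disagrees with the protein sequence are excluded and
reported rather than force-applied — a deterministic, auditable choice.
Mutation tables are protein-level; genome-coordinate translation and
isoform selection are upstream of this package, and the readers enforce one
sequence per protein rather than choosing isoforms. The hypermutated-sample
filter is a plain per-sample mutation cap, off by default, because no
principled threshold is bundled with the package.

## Kinase models and the Matrix Similarity Score

Binding specificity is a 20 × 15 probability matrix estimated from aligned
15-mer binding peptides with a per-cell pseudocount (default 0.01) so no
probability is zero; terminal pads contribute no count and each column
normalizes over the peptides observed there. Column information weights use
the motif-scanning convention adapted to the 20-letter alphabet,
I(i) = Σ_a p·ln(20p); a configuration switch (`use_info_weights=False`)
makes all weights 1 for sensitivity checks.

The MSS of a peptide is (Current − Min)/(Max − Min) over the 14 flanking
columns, where Current sums I(i)·p_i(a_i) and Min/Max substitute the column
minimum/maximum. The central column is never scored, so the score is
invariant to the acceptor residue by construction. Pad positions contribute
the uniform expectation I(i)/20 to all three sums and hence drop out of the
normalization — the unbiased treatment of unknown flanks. A fully uniform
model has Max = Min and raises a degenerate-model error rather than
returning an arbitrary score.

Significance is empirical: p = (# background ≥ score)/N against the
phosphosites annotated to other kinases. p may be exactly 0 under this
fraction definition; a (k+1)/(N+1) smoothed variant sits behind a config
flag, default off. Background score distributions are computed once per
model and shared.

Refinement iterates: build the PWM from the current training set, score
every member, compute each member's empirical p against the kinase-disjoint
background, drop members with p > 0.2, repeat until no member drops. The
reference distribution for the outlier cutoff is the same background used
everywhere else (one consistent p-value definition); members are scored
against the PWM of the full current set, with leave-one-out available as an
option. The loop terminates in at most n iterations because the set
strictly shrinks. Models keeping fewer than 20 peptides are flagged
non-retained. Retained models are validated by ten-fold cross-validation —
fold assignment is seeded, each fold's PWM scores its held-out positives
and all negatives, and the pooled scores give a midrank-tie AUROC — with
retention requiring AUROC ≥ 0.75. Negatives are the refined peptides of the
other retained kinases minus any peptide also annotated to the focal
kinase.

## Rewiring calls

For each flanking pSNV and each retained model, the reference and mutated
windows are scored and converted to empirical p-values. Loss requires
pRef < 0.05 and pMut > 0.1; gain requires pRef > 0.1 and pMut < 0.05. The
two regions are disjoint, so a (variant, kinase) pair yields at most one
event; a variant with at least one loss and one gain (necessarily different
kinases) is a switch. All retained models are scanned genome-wide, with
`kinase_known` flagging experimentally annotated pairs; a `--known-only`
mode restricts to annotated kinases. Direct pSNVs bypass scoring entirely —
the MSS cannot see the central column — and are emitted as unconditional
losses attributed to the site's known kinases, or to `unknown`. The
high-confidence filter keeps losses only for experimentally annotated
kinases and, per variant, the single gain with the highest mutant MSS
(ties: smaller pMut, then kinase name); "top-scoring" is interpreted
per-variant because no sharper definition is available, and the filter is
idempotent and only removes edges.

## Enrichment statistics

All count tests are one-tailed Poisson exact tail probabilities with
λ = background rate × exposure, evaluated through the regularized
incomplete gamma function (exact, never a normal approximation). Robust
expected ranges are the median ± MAD of seeded Poisson draws.

* **Sequence context.** Structured and disordered phospho-region pSNV
  counts are each tested against the SNV rate of the matching non-phospho
  sequence; direct pSNVs are tested for depletion against the overall
  non-phospho rate applied to the acceptor residues. Because the background
  rate is a plug-in estimate from the same cohort, the context test is
  mildly anticonservative (measured type-I ≈ 6% at nominal 5% on null
  cohorts); the pooled calibration across context, domain and pathway units
  stays well under 8%.
* **Domains.** Domains in < 3 proteins, or with domain-specific pSNVs in
  < 3 proteins, are filtered before testing. Observed = distinct pSNVs in
  the domain ∩ phospho-region intersection, exposure = its residue count,
  background = pSNVs per residue of all phospho-associated sequence; BH-FDR
  at 0.05, with a display flag at ≥ 25 pSNVs.
* **Pathways.** Gene sets of 3–1000 genes are tested per stratum
  (source × mutation type × cancer type, plus pan-cancer); a set whose
  in-stratum mutations come from a single gene or single sample is
  discarded there. Expected = member-gene count × mean mutations per gene
  of the stratum's universe — all genes for the SNV analysis, phosphosite
  genes for pSNVs; "mean mutations per gene" (not per residue) matches the
  exposure being a gene count. BH-FDR runs separately per stratum, never
  globally. The final pSNV-specific list needs pan-cancer pSNV FDR < 0.01
  with the pan-cancer and every per-cancer SNV FDR > 0.1. Depletion-only
  directions are carried on every result so driver-like summaries can drop
  them.
* **PPI groups.** With mean degree d̄ over the analyzed network, a group G
  expects |G|·d̄/2 internal edges; a pair (A, B) expects min(|A|,|B|)·d̄
  cross edges. The between-group expectation is under-specified in the
  underlying design; the min-size form is documented here and kept in one
  place so it can be swapped.
* Impact bins (low = 0–1 damaging calls of five predictors, moderate =
  2–4, high = 5) use a two-sided binomial test against the other-SNV bin
  frequencies; score comparisons use a seeded label-permutation test with
  (k+1)/(n_perm+1) smoothing.

## The synthetic world

The generator emulates the statistical structure of the real inputs, not
their biology in detail. Sequences are uniform over the 20 amino acids
(isolating algorithmic behavior from composition effects); disorder is laid
down in contiguous 20–60-residue blocks hitting a target fraction of 0.37,
the canonical disordered share of the human proteome. Phosphosites sit on a
16-residue grid so windows never collide, which makes planted motifs exact
and region merging trivial to reason about.

Each synthetic kinase has an obligate anchor residue (strength 0.98 —
e.g. the +1 proline of proline-directed kinases) and four moderate
preferences (strength 0.9) at offsets disjoint between kinases. Twenty
target sites per kinase carry the full consensus and the kinase's
annotation. Every other site is labelled with a background kinase name and
shares the anchor at frequency 0.45 and each moderate preference at 0.5 —
the motif overlap across kinase families that makes the empirical
background realistic. These rates were sized analytically so that a target
site is a significant match (pRef ≈ 0.02–0.04), a single anchor-destroying
substitution lands in the background bulk (pMut ≈ 0.15–0.2), and a
motif-neutral substitution moves the score only through near-zero-weight
columns. Truth-labelled cohorts add anchor-destroying and motif-neutral
variants at target sites for sensitivity/false-call measurement.

Mutation cohorts draw a Poisson total at 2 × 10⁻³ mutations per residue per
sample (40 samples in the demo — a desk-scale stand-in for cohort-scale
missense burdens) and place mutations multinomially. Planted enrichments
multiply local rates: `phospho_window[_structured]` and `domain:<name>`
inflate the region class; `geneset_snv:<name>` inflates whole member genes;
`geneset_psnv:<name>` *redistributes* each member gene's burden into its
phospho windows at the stated multiplier while scaling the rest of the gene
down to keep the gene-level total unchanged — the generative picture of
site-directed selection, and the only construction under which a
"pSNV-specific" pathway is genuinely invisible to the SNV analysis.
Planted gene sets are pairwise disjoint so multipliers never stack.

What the generator does not emulate: residue composition biases,
trinucleotide mutational signatures, correlated site placement,
copy-number or structural variation, and kinase expression context.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under the stated generative model, not performance on real
cohorts.

## Problem sizes and numerical choices

The demo study uses 150 proteins of 360–520 residues (~66k residues,
~360 sites, ~5k mutations), backgrounds of ~300 windows, and 60 training
peptides per kinase; the pathway power experiment uses 300 proteins at one
site each (phospho fraction ≈ 0.03) with 50 samples, sized from the ratio
z_pSNV/z_SNV ≈ 1/√(phospho fraction) so the planted set clears pSNV FDR
0.01 with margin; the null calibration pools context, domain and pan-cancer
pathway units over 20 seeds. Ties in empirical p-values are counted in the
"equal or greater" direction; BH-FDR enforces step-up monotonicity and
restores input order; all stochastic operations take explicit seeds and are
bit-reproducible given (inputs, seed).

## Known limitations

Only protein-level missense variants are considered. The refinement
cutoff's reference distribution and the high-confidence "top-scoring"
definition are interpretations of under-specified design points (documented
above and kept behind single functions). The context test's plug-in
background is mildly anticonservative. Kinase coverage in any real
application is limited to kinases with enough curated binding sites to
survive the 20-sequence and AUROC gates.
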