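# Methods

## Coordinate system and reference annotation

All coordinates are 1-based inclusive positions on the 16,569-bp circular
human mitochondrial genome (the rCRS coordinate convention). The control
region (D-loop, 16,024–576) wraps the replication origin and is stored as
a single feature with a wrap flag. The gene model bundled in
`data/features.tsv` is the standard rCRS/MITOMAP annotation: 13
protein-coding genes, 22 tRNAs, 2 rRNAs and the D-loop. Counting each
base once per region class (overlapping ORF bases once), the class sizes
are D-loop 1,122 bp, protein-coding 11,341 bp, rRNA 2,513 bp and tRNA
1,504 bp; ~89 bases are intergenic spacers. When a single label per base
is needed, overlaps resolve by the priority D-loop > protein > rRNA >
tRNA (no cross-class overlaps exist in the bundled model, so the priority
is only a guard for user-supplied annotations).

**Synthetic reference sequence.** The bundled sequence
(`data/rcrs_synthetic.fa`) is a stand-in, not the true reference: the raw
cohort data and their licence-restricted companions are unavailable, and
a reference FASTA cannot be shipped from third-party packages. Bases are
drawn from a mitochondrial-like composition with these pinned exceptions:
the two published 123-bp assay context fragments centred on positions
1,888 (G) and 16,093 (T); the ACA codon at 10,398–10,400 (so 10398A>G is
a nonsynonymous first-codon-position change in MT-ND3, as for the real
genome); and poly-C/AC-repeat tracts at the four classical homopolymer
trouble spots. Every algorithm is sequence-agnostic; all sequence-derived
tests (codon effects, CpG symmetry, contexts) are exact properties of
whichever sequence is loaded, and a user analysing real data should load
the true reference with `GenomeAnnotation.from_files`.

**Codon effects.** Translation uses the vertebrate mitochondrial genetic
code (NCBI table 2). MT-ND6 and the eight light-strand tRNAs are read
from the reverse complement; alleles are always given on the heavy strand
(VCF convention) and complemented internally. Genes ending in incomplete
stop codons (completed by mRNA polyadenylation in vivo) are padded with A
for the trailing codon. For the two overlapping ORF pairs (ATP8/ATP6,
ND4L/ND4) an effect is reported per gene and the collapsed label prefers
nonsynonymous — conservative for dN/dS numerators.

**D-loop sub-regions.** The 17-element control-region table
(`data/dloop_subregions.tsv`) follows the standard MITOMAP control-region
model (hypervariable segments, conserved sequence blocks, TFAM binding
sites, promoters, termination-associated sequences), including MT-HSP1,
MT-TFH and MT-TAS2. The exact identities of the remaining 14 elements
are a documented assumption — the published analysis names only those
three — and the table is user-overridable.

## Variant I/O

One `VariantCall` is one alternate allele at one position in one sample
with HL (alt reads / depth), a 95% CI and the depth. Multi-allelic VCF
records are split into per-allele calls flagged `multiallelic_site`;
indels are left-aligned against the loaded reference (origin-crossing
indels are rejected; none occur in practice). The FORMAT/HF field takes
precedence over allelic depths when both are present. Where the caller
supplies no CI, the Wilson score interval at the call's depth is used:
it is the standard binomial interval at these depths and the choice is
isolated behind one function. HL and CI values are rounded to six
decimals on read and write so a write/read cycle is lossless despite VCF
single-precision floats.

## Refinement rules

Rules run in the fixed order R1–R5 described in the README, after an
initial plasmy assignment from the caller's heteroplasmy window
(HL ≤ 0.90 heteroplasmic, HL > 0.90 homoplasmic); R3 is the only
promotion path from the heteroplasmic label to homoplasmic below that
threshold. Two deliberately exposed ambiguities:

- **Rule 1 mode.** Read literally, the source criterion *retains* calls
  whose CI lower bound is below 1%, which contradicts its evident QC
  purpose (the criteria it adapts are exclusion filters). The default
  `discard_below_floor` removes them; `literal_retain_below_floor`
  preserves the literal wording. Both are one flag apart and audited.
- **Rule 2 order.** Low-HL alleles (< 5%) are pruned first; a site is
  discarded only if more than one alternate allele *still* remains. The
  alternative reading (discard any multi-allelic site outright) would
  make the prune clause vacuous.

Indels are retained under their own plasmy label and pass only through
R2/R4; the depth and CI rules address heteroplasmic SNVs. The audit
satisfies retained + removed = input per profile, refinement is
idempotent on its own output, and tightening the depth thresholds never
enlarges the retained set (property-tested).

## Pair classification

Matching is exact on (position, ref, alt); a site heteroplasmic for
different alternates in the two tissues yields one de novo plus one lost
record, never a germline one (allele-level semantics of heteroplasmy).
The default scope is heteroplasmic-only; a call homoplasmic in one tissue
and heteroplasmic in the other therefore contributes only its
heteroplasmic side (use `scope="all"` to see the pairing). Because
germline heteroplasmy levels differ by tissue, the category summary
reports germline HL means per tissue rather than pooled.

## Statistics

All ratios are plain count ratios: no per-site opportunity normalisation
for dN/dS (codon-opportunity-corrected ω is out of scope), and spectra
use the pyrimidine-centred six-class (or raw twelve-class) convention.
Ti/Tv has two modes because the reduced footnote definition (counting
only A/C and T/G exchanges as transversions) cannot be distinguished from
the standard four-pair definition in the source material; the standard
mode is the default.

Region rate comparisons model counts with an exposure of region length ×
sample count. The default `exact_conditional` method conditions the two
Poisson counts on their sum, giving an exact binomial test that matches
the Poisson GLM asymptotically but stays exact at the small counts this
genome produces; `poisson_glm` (IRLS log-linear fit) is provided for
fidelity to the named method. The shift-direction test is an exact
two-sided binomial sign test excluding zero shifts (a sign test is
undefined for ties); regions with no nonzero shift are skipped.
Sub-region enrichment builds, for each control-region element, the 2×2
table of heteroplasmic events versus non-event base-pair opportunities
(length × number of samples − events) inside versus outside the element,
restricted to the D-loop; this events-vs-opportunities construction is
the most plausible reading of the published odds ratios and is isolated
behind the `exposure` parameter. Bonferroni correction multiplies each
raw p by the number of tests, capped at 1.

Wilcoxon rank-sum comparisons are exact for tie-free samples of ≤ 50 per
group and use the tie-corrected normal approximation otherwise; fully
tied input returns p = 1 with the degenerate flag.

## Association

Crude ORs are (a·d)/(b·c) with a log-scale Wald 95% CI; any zero cell
triggers the Haldane–Anscombe 0.5 correction, flagged. Adjusted ORs come
from maximum-likelihood logistic regression (IRLS, convergence tolerance
1e-8, ≤ 100 iterations) with categorical covariates expanded against
their lowest level and binary covariates against absence. Separation is
reported as an error naming the term (|log-OR| > 15), rank-deficient
designs as a collinearity error. The published crude CIs are
arithmetically symmetric around their estimates and inconsistent with any
standard log-scale interval computable from the printed counts; this
package reproduces the point estimates and reports Wald intervals, and
makes no claim of matching the printed CI bounds.

## Synthetic cohorts

The pair generator's defaults are the study conditions: 50 pairs,
category HL distributions as beta laws moment-matched to the reported
mean/SD pairs (germline blood 10.7% ± 23.1%, germline biopsy
14.1% ± 24.6%, de novo 9.9% ± 20.3%, lost 3.8% ± 9.6%), depths normal
around 1,105× (biopsy) and 1,218× (blood), a transition-dominated
spectrum (85% transitions, giving Ti/Tv > 5), homoplasmies near fixation
at ~1.1 × 10⁻³ events/bp/sample (~18 per sample), and a five-fold
control-region rate excess. Event rates per category
(germline 2.4 × 10⁻⁴, de novo 1.6 × 10⁻⁴, lost 6 × 10⁻⁵ events/bp/sample)
were chosen once to land the per-pair heteroplasmy counts in the reported
range; HL draws are truncated to a window (default 0.03–0.88) so planted
calls fall inside the resolvable heteroplasmy band. Germline HLs are
comonotone across tissues (one uniform driving both beta quantiles),
giving correlated levels with the tissue-specific means. Observed calls
re-draw alt reads binomially at the sampled depth, so HL, reads, depth
and the Wilson CI are mutually consistent.

Genuine events avoid the homopolymer blacklist intervals, because the
refinement removes calls there unconditionally; planting real signal
there would be planting unrecoverable truth. Artifacts are planted
explicitly instead — extra sub-5% alleles at called sites (targets of
R2) and calls inside the homopolymer tracts (targets of R4) — and carry
artifact categories in the truth table so their removal is verifiable.

When a de novo coding dN/dS target is configured (default 2.0), the
generator draws each coding event's effect from Bernoulli(target/(1+target))
and keeps the event at a coding position where that effect is achievable,
so the realized nonsynonymous:synonymous ratio is an unbiased binomial
draw around the target.

The `noise_free()` preset (no artifacts, no homoplasmies, HL window
0.06–0.80) defines the regime in which category recovery is exact: there
the pipeline's category confusion matrix is diagonal by construction of
the rules, and the tests assert exactly that. Under the full default
conditions a handful of boundary calls (HL near the CI floor) can
legitimately be filtered, so recovery there is asserted only up to those
documented channels.

What the generator does *not* emulate: read-level errors and alignment
artifacts beyond the planted channels, phylogenetic (haplogroup)
structure among samples, position-specific mutational hotspots other
than the configurable sub-region hotspot, and covariate-outcome
confounding unless explicitly configured. Passing tests therefore
demonstrate correctness of the algorithms under the stated sampling
model, not robustness to upstream calling errors in real data.

The case-control generator assigns carrier status at the control
prevalence (default 0.08), draws the outcome from a logistic model whose
exposure coefficient is ln(true OR) (default ln 1.67) and whose intercept
is solved (Brent's method) so the expected case fraction matches
304/663, and draws HLs so dichotomization at 10% reproduces carrier
status exactly. Covariates are independent of exposure and outcome
unless given explicit log-odds effects.

## Problem sizes and numerical choices

Simulation-based checks use 200 pairs (category recovery, dN/dS
recovery), 200 replicates (logistic CI coverage), 500–1,000 randomized
profiles (refinement properties) and exhaustive enumeration for the
exact tests on tables with small totals — sizes at which binomial
sampling error is small relative to the asserted effects while the whole
suite remains quick on a single core. Seeds are fixed in tests and
routed through a single `--seed` in the acceptance script. Ratio
denominators of zero are reported as degenerate flags rather than raised;
p-values of skipped tests are NaN, never silently 1.

## Known limitations

- The bundled sequence is synthetic; absolute CpG density, trinucleotide
  context frequencies and per-gene codon usage do not match the real
  mitochondrial genome, only their invariant properties do.
- dN/dS is a raw count ratio; comparisons between regions with different
  codon composition inherit that convention's biases.
- The enrichment exposure model treats base-pair opportunities as
  independent Bernoulli trials, ignoring recurrent mutation at a site.
- Unconditional logistic models only; matched designs needing conditional
  likelihood are out of scope, as are survival models.
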