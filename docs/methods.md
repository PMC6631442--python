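# Methods

## Quantities and conventions

All coordinates are 0-based, half-open internally; GFF3 and VCF inputs
(1-based) are converted on read. Motifs, reference and alternate bases
are expressed on the transcript's sense (transcribed) strand, so the 5′
and 3′ flank directions always refer to transcription; for − strand
genes the genomic slice is reverse-complemented and the flanks swapped.
"Exon" always means the CDS portion; UTRs are labelled separately, and
the analysis pools 5′- and 3′-UTR into one UTR group. Region labels
partition every transcript span. Each variant is assigned to exactly one
transcript; where transcripts overlap, the transcript with the longest
CDS wins, ties broken by lexicographic id. This priority is a convention,
not an inference, and is configurable at the annotation layer.

The normalized SBS frequency of motif *m* in region *R* is
ν(m) = (c_SBS(m)/N_SBS)/(c_R(m)/N_R). The denominator is counted over
*every* position of the region across all assigned transcripts, on the
same sense-strand convention as the numerator, so the two are directly
comparable. Flanking bases of a motif may cross exon/intron or
transcript boundaries: only the position of the substituted base (the
pattern's X) decides the region label, and the flank is taken from the
contiguous genomic sequence. Motifs containing an ambiguous base (N) or
truncated by a contig end are excluded from both numerator and
denominator. By construction the region-frequency-weighted mean of ν
over motifs present in the background equals 1 exactly; the test suite
asserts this to 1e-9 on every run.

Motifs whose background count is zero have no defined ν and are omitted
from downstream correlations (and reported); motifs observed zero times
among SBSs but present in the background keep ν = 0. Each motif
contributes one unweighted point to a correlation, matching a
one-point-per-motif scatter.

## vIP tables and composition

Single-base vIPs default to the experimental values (G 8.20, A 8.42,
C 8.85, T 9.10 eV); computed alternatives can be loaded from TSV or an
XLSX workbook whose sheets map to motif lengths. Doublet-to-quadruplet
vIPs are inputs — this package performs no quantum chemistry. A
quintuplet's vIP is the mean of its two overlapping quadruplet windows
and a sextuplet's the mean of its three; motifs longer than six
generalize to the mean over all contiguous quadruplet windows, a natural
extension of the same rule (outputs are labelled with the composition
method via the table's `source_label`). An additive estimate — the mean
of the constituent single-base vIPs — is exposed separately for
comparison. Composition arithmetic is validated to 1e-9.

## Statistics

Pearson correlations are tested with the Fisher z-transformation:
z = atanh(r), statistic z·√(n−3), two-sided against the standard normal.
Differences of two correlations use
(atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)). Sidedness is a choice
(two-sided throughout), as is the difference statistic; both are the
standard textbook forms. Fisher-z confidence intervals are exposed as
well. No multiple-testing correction is applied — raw p-values are
reported against α = 0.05 and the full p list is available for external
correction.

The non-linear correlation fits f(X) = a + bX⁻¹ + cX⁻² + dX⁻³, which is
linear in (a,b,c,d); it is solved by ordinary least squares after
standardizing the three inverse-power basis columns (the inverse powers
of X ≈ 8–9 eV are nearly collinear, and standardization keeps the system
well conditioned), then back-transforming the coefficients. r_nonlinear
is the Pearson correlation between fitted and observed values; data
exactly in the model space are recovered to 1e-9. Duplicate X values
make the basis rank-deficient; the minimum-norm solution is used and a
warning emitted. With exactly 4 distinct points the fit interpolates and
r_nonlinear = 1 is expected, which is why correlation rows with fewer
than ~5 points deserve skepticism; rows under 4 usable motifs are
flagged not-computable rather than dropped.

Degenerate inputs (constant x or y, n below the minimum, |r| = 1) raise
or are flagged explicitly: perfect correlations report p = 0 with an
exactness flag instead of an atanh overflow.

## The synthetic-data generator

The generator is first-class, tested code; it defines the study
conditions under which the pipeline's statistical guarantees are stated.

Genome and genes: one contig of i.i.d. bases at GC content 0.45 (between
the ~40% genome-wide and ~50–55% exomic figures for human; an i.i.d.
model cannot have both), carrying 80 genes by default, alternating
strands, each utr5–exon(–intron–exon)*–utr3 with in-frame CDS; default
length ranges give ≈1.1 Mb. The vIP table is the additive single-base
mean minus 0.15 eV per GpG dinucleotide step plus N(0, 0.02 eV) seeded
noise; the GpG bonus guarantees G-runs (GGG, GGGG) are the strict
minimum-vIP motifs of their length, echoing the expected stack ordering,
and the noise decorrelates the table from pure composition.

Substitutions: region totals follow the mix exon 0.75 / intron 0.10 /
5′-UTR 0.03 / 3′-UTR 0.12, rescaled from the composition of the real
catalogue the analysis targets (~3/4 exonic of ~190k variants, with
introns and UTRs splitting the remainder roughly 25k : 38k and the UTR
mass 8k : 30k between 5′ and 3′). Within a region, a site is drawn with
probability ∝ exp(−β·vIP(motif_k)) — exponential tilting toward low-vIP
contexts — without replacement (one substitution per site), implemented
as Gumbel top-k on the log-weights. β defaults to 0.5 eV⁻¹ with k = 3
(pattern NXN); any supported pattern may drive the rate instead, e.g.
`rate_pattern="XN"` makes the rate depend only on the base and its 3′
neighbour, planting a 5′–3′ asymmetry. The alternate base is a
transition with weight κ = 4 against 1 per transversion, giving
R = κ/2 = 2. One third of records get a clinical label; a labelled
record is pathogenic with probability
logistic(α₀ + α₁·|ΔvIP| + α₂·(mean base vIP − motif vIP)), defaults
α₀ = 0, α₁ = α₂ = 2 eV⁻¹ — a minimal construction making pathogenicity
increase with the vIP jump of the base change and with low-vIP context,
the two dependencies the pathogenicity statistics are designed to
detect. All randomness flows through one seeded generator; identical
configs give byte-identical files, and every generative parameter is
echoed in a JSON sidecar for recovery tests.

What the generator does *not* emulate: CpG-methylation deamination
chemistry, APOBEC/UV signatures, selection, recurrent hits, isochore or
GC-content structure, overlapping transcripts, and real vIP tables
(motif vIPs here are additive-plus-GpG by construction, whereas computed
stack vIPs deviate from additivity more richly). Passing tests therefore
demonstrate that the pipeline recovers the planted rate→spectrum
coupling at realistic scale and calibration — not that the biological
hypothesis is true, nor how strong the coupling is in real catalogues.

## Problem sizes used by the checks

Parameter recovery runs 20 seeds at the default scale (≈1.1 Mb genome,
50 000 SBSs, β = 0.5 eV⁻¹, k = 3) and requires a negative triplet
correlation at p < 0.001 in ≥ 19/20. Null calibration runs 200
replicates at a reduced scale (6 genes, 1 500 SBSs each, β = 0) chosen
so a replicate takes well under a second; the Fisher-z rejection rate at
α = 0.05 must stay within 0.05 ± 0.02 (the binomial standard error at
200 replicates is ≈0.015, so this band is a meaningful but not
overstrict check). The planted-asymmetry check uses 20 seeds at 20
genes / 10 000 SBSs with the 3′-driven rate and requires r(XN) < r(NX)
in ≥ 80% of seeds. The counting engine is verified against an
independent brute-force window scan (pure string slicing) on 100 random
sequences up to 2 kb, all patterns, both strands, with Ns present.

## Known limitations

- The coding-effect classifier handles SBSs only (no indels/MNVs) and
  classifies stop-loss as missense; nonsense variants are a separate
  class excluded from "missense" by default.
- Background counting tallies each genomic position once per assigned
  transcript region; with heavily overlapping annotations a position can
  legitimately contribute to two transcripts' backgrounds.
- Δν uses per-group normalization (each group's motif share divided by
  the region background) and then differences; normalizing the
  difference of raw shares instead would scale, but not re-rank, the
  values when group sizes are equal, and the per-group form keeps each ν
  interpretable on its own.
- The Fisher-z test treats per-motif points as independent; multinomial
  counting induces weak negative dependence, visible only marginally in
  the null calibration.
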