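# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `plastoflux`, in the order the pipeline runs.

## Synthetic organelle genomes (`plastoflux.simulate`)

The generator emulates a pair of sister plant species whose common
ancestor acquired plastid-derived blocks (MTPTs) in its mitochondrial
genome.

**Timeline.** The ancestral plastid exists at `t_flux` years before
present, when `n_mtpt_blocks` contiguous blocks totalling
`mtpt_fraction` of the plastid are copied (each in random orientation)
into a random mitochondrial background. Both organelle lineages then
evolve to `t_split`, split into species A and B, and evolve
independently to the present. All mutation processes draw from one
`numpy` SeedSequence rooted at the scenario seed, so identical scenarios
are byte-identical.

**Mutation model.** Coding sequences accumulate *synonymous-only*
single-base substitutions: the event count is Poisson with mean
`rate × years × S`, where S is the NG86 synonymous-site count of the
sequence, and each event picks a codon with probability proportional to
its current number of synonymous one-step options. This makes the Ks
estimator directly checkable against `λ·t`. Intergenic sequence (tRNA
and rRNA included) evolves under Jukes–Cantor substitutions at 3× the
synonymous rate, a neutral proxy that keeps the identity-threshold scan
meaningful without modelling selection. No insertion/deletion process
runs by default; InDels are planted explicitly where marker tests need
them, because no usable rate for organelle InDel accumulation is
available to calibrate one.

**Defaults as study conditions.** Plastid length 160 kb with 75
protein-coding genes, `mtpt_fraction` 0.35, λ_pt = 2×10⁻⁹ and
λ_mt = 0.6×10⁻⁹ substitutions/site/year, `t_split` = 2 My,
`t_flux` = 10.7 My, and an 88% plastid share of organelle reads — the
regime reported for the *Cynanchum* system this package models. Block
sizes are log-uniform on 0.3–20 kb (multi-fragment MTPTs are observed;
no size law is published), then rescaled so the planted total matches
`mtpt_fraction`. Tests and the validation suite use scaled-down genomes
(10–62 kb plastids, 10–50 genes) chosen so each property is measured in
seconds; the properties checked (recall, score equivalence, clock
recovery) do not depend on genome length beyond seed statistics.

Genotype tables draw per-marker off-type alleles at configurable
frequencies, with an option to force an exact number of heterogeneous
collections (used to reconstruct published error patterns); allele
depths at diagnostic sites are Binomial(total_depth, copy_fraction_pt)
per site, with the mitochondrial depth as the remainder.

## MTPT scan (`plastoflux.scan`)

A seed-and-extend local aligner with BLAST-like structure:

1. exact word seeds on both strands (`word_size` 8);
2. a vectorized window prefilter keeps seeds that extend by ≥ 8 net
   score within ±24 bp;
3. seeds on one diagonal within 100 bp chain together and extend
   ungapped with an X-drop of 20;
4. HSPs above the gapped trigger (18) are clustered across nearby
   diagonals (≤ `band_pad` 32 apart, query gap ≤ 200) and joined by a
   banded affine-gap local DP, then extended from both ends by a banded
   gapped X-drop extension (X-drop 40, the customary looser bound for
   the gapped phase);
5. scoring is +1/−2 with gap cost 5 + 2k; E-values use the ungapped
   Karlin–Altschul constants λ = 1.33, K = 0.621 for that scheme.

Segments must pass identity ≥ 0.70, length ≥ 30 bp and E ≤ 1e-10 —
these thresholds, not the scoring internals, are the scientific filter —
and survive the plastid tRNA/rRNA mask (those genes are conserved across
compartments and are not evidence of transfer). A segment more than half
inside the mask is dropped; a straddler is split into its unmasked runs,
re-scored from its stored alignment columns, and re-filtered.

**Why word size 8.** With substitution-only divergence, any block of
length L ≥ 50 at ≥ 90% identity has at most ⌊L/10⌋ mismatches, leaving a
longest exact run of at least ⌈0.9·L/(L/10+1)⌉ ≥ 8 by pigeonhole — so an
8-mer seed always exists inside the minimum block the scan claims to
recover, and 100% recall of such blocks is a guarantee rather than a
probability. The conventional 11 would make recall of 50 bp blocks
stochastic. The parameter remains configurable.

The scanner's scores are held to *exact* equality with an independent
full Smith–Waterman implementation (Biopython's `PairwiseAligner` under
the same scoring) on random pairs up to 200 bp whenever the optimum
clears the E-value bar; planted-block recall, filter monotonicity and
strand symmetry are separate suites. Backbone projection counts each
species at most once per position; a gene is "identified in" a species
when that species' segment union covers ≥ 50% of the gene span
(frequency classes: > 20 species most_frequent, > 10 moderate, else
rare; thresholds configurable for small simulated panels).

## Ks estimation and dating (`plastoflux.ks`)

Coding sequences are aligned through their translations (BLOSUM62,
affine gaps −10/−1, exact matrix immaterial for near-identical organelle
genes) and back-projected so gaps are whole codons; codon columns with
gaps and terminal stops are trimmed. NG86 counting: per-codon synonymous
sites are the fraction of one-step changes preserving the amino acid
(changes to stops count as nonsynonymous); per-codon-pair differences
average over all minimal substitution paths, discarding paths through
stop codons. pS = Sd/S is Jukes–Cantor corrected,
Ks = −(3/4)·ln(1 − (4/3)·pS), undefined ("saturated") at pS ≥ 3/4. The
61×61 pair table is precomputed at import and verified against an
independent path-enumeration oracle in the tests. A counting method was
chosen over a maximum-likelihood estimator because it is self-contained
and exactly testable; below Ks ≈ 0.13 (the relevant organelle range) the
two agree closely.

Two summaries of a gene set are provided. `ks_mode` — Gaussian KDE with
Silverman bandwidth on a 5×10⁻⁴ grid, ties broken toward the smaller
value, median fallback below 5 values — matches how organelle Ks
distributions are usually summarized and is robust to a contaminating
mode. `ks_pooled` — ΣSd/ΣS before the correction — is the right
combined estimate when individual genes carry only a handful of
synonymous differences (at Ks ≈ 0.008 a 300-codon gene holds Sd ≈ 2, so
per-gene Ks and its mode are coarsely discrete); the pipeline dates from
the pooled value and reports both.

Dating: T = Ks/2λ with the compartment's rate. For plastid-vs-MTPT the
copies evolve at different rates after insertion, so the default clock
divides by λ_pt + λ_mt; `2pt` and `2mt` readings are exposed
(`flux_clock`) since the published treatment does not state which λ its
flux date used — the rate-sum reading is the one consistent with the
reported ~10.7 My.

## Marker evaluation (`plastoflux.markers`)

Whole-plastid variant calling aligns the two genomes on a collinear
chain of unique shared 20-mers and aligns inter-anchor gaps with an
affine-gap aligner. The anchoring matters: a unit-cost edit-distance
alignment scatters a 348 bp deletion across chance matches, while the
affine segment aligner keeps it one contiguous InDel, which the > 20 bp
marker rule needs. Balanced insertion/deletion runs are reported as
substitutions.

Design filters (all configurable): sites with heterogeneous genotypes in
more than 3% of either accession's read depth are eliminated (strictly
greater — 3.0% survives), since minor-allele reads at a plastid site are
the signature of a co-mapping MTPT copy; InDels qualify only above 20 bp
(codominant size markers whose two amplicon lengths differ by exactly
the InDel length); SNPs qualify only with no other variant within 150 bp,
read as a distance rule because the amplicon length is fixed separately
to 100–150 bp. Primers are unique GC-balanced (40–60%) 20-mers.

In-silico PCR: a primer binds with ≤ 2 mismatches and an exact
3′-terminal 3-mer; every convergent plus/minus pair within 5 kb yields an
amplicon. These defaults mimic permissive lab PCR; they are deliberately
simple (no melting temperature, dimers or hairpins). A marker is PARADOX
when a mitochondrial amplicon is predicted or its plastid amplicon
overlaps a detected MTPT segment, else SAFE. Copy fractions are
d_pt/(d_pt+d_mt) with percentages reconciled to 100 by largest
remainder. `band_visibility` is a deliberately minimal semi-quantitative
model — product = copies·2^cycles, capped at a plateau, visible above a
threshold — sufficient to show why an 88:12 template ratio needs three
extra cycles to surface the minor band.

## Authentication rules (`plastoflux.authenticate`)

Positive rule: genuine iff ≥ 1 marker shows the target allele. Negative
rule: counterfeit iff ≥ 1 marker shows an off-type allele. Missing calls
are ignored by default (conservative toward genuine products;
`strict_missing` treats them as off-type); a locus showing both alleles
counts as target-present *and* off-present. Since "no target allele
anywhere" implies "some off allele somewhere" for any classifiable
profile, the positive rule's counterfeit set is a subset of the negative
rule's — power(negative) ≥ power(positive) and fpr(negative) ≥
fpr(positive). The tests verify this per profile and exhaustively over
all 3-marker tables with up to 6 collections.

## Validation design

The synthetic generator produces substitution-only, selection-free,
single-chromosome genomes with uniform base composition. Passing tests
therefore demonstrate correctness of the algorithms under the stated
model, not performance on real organelle data, which adds InDel
polymorphism, repeat-mediated mitochondrial rearrangement,
multi-chromosome structures, rate heterogeneity across genes and
compositional bias. Planted-block recall fixtures keep the outer 4 bp of
each block unmutated: a mutated edge erodes the block's *detectable*
boundary (any local aligner trims a net-negative tail), so intact ends
make the ≤ 5 bp coordinate tolerance a measure of the scanner rather
than of mutation placement. Similarly, the paradox-marker fixture sites
its primers where the MTPT copy is conserved, which is exactly the
condition under which real co-amplifying markers fail.

Known limitations: no InDel mutation process by default; the
mitochondrial multi-chromosome structure of real plant mitochondria is
collapsed to one chromosome (whether recombination between chromosome
types affects MTPT detection is untested); Ka/ω, codon-frequency and
transition/transversion-corrected distances are out of scope; the
scanner approximates but does not replicate any specific search tool's
output, so published whole-genome coverage percentages tied to one
tool's internals are not acceptance targets.
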