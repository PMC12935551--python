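# Methods

This note documents the models and procedures implemented in strmosaic,
their assumptions, the parameters that matter, and what the simulator does
and does not emulate.

## Motif classes and repeat purity

A repeat motif of length k (2–6 bp) is identified with its *class*: the k
rotations of the motif together with the k rotations of its reverse
complement, named by the lexicographically smallest member (canonical
form).  Reads sequenced from either strand, starting at any phase, then map
to one class.  *Purity* of a read against a class is the maximum over all
class variants of the fraction of read positions matching a tiling of that
variant from offset 0; ties between variants go to the earliest variant in
canonical rotation order, for determinism.  Purity counts substitutions
only: a read whose best explanation requires an internal indel scores low
rather than being realigned.  This keeps the primitive O(len·k) and makes
"fraction of explained positions" exactly interpretable.  Non-ACGT bases
(N) count as mismatches.

A read is an **in-repeat read (IRR)** when purity ≥ τ.  Default τ = 0.95
(~7 tolerated mismatches in a 151 bp read) operationalises "almost
entirely repeat"; it is a configurable knob, not an external constant.  At
this threshold, random 151-mers essentially never qualify (measured
specificity ≥ 0.999), while error-free in-repeat reads always do.  Note a
consequence tested explicitly: reads with up to ~τ·R bp of flank overhang
also pass, so the purity-based IRR count slightly exceeds the strict
"wholly inside the tract" count; oracle tests of the IRR-count estimator
therefore count reads by tract geometry, and the detector's operating
characteristics are verified separately.

## Locus assignment and IRR pairs

IRRs align unreliably inside repeats, so the locus of origin is recovered
from the *mate*: an IRR is assigned to the unique catalog locus of its
motif class whose tract lies within `window_bp` (default 500 bp) of the
mate's aligned interval.  Zero or multiple candidates leave the read
unassigned with the reason recorded (`mate-unmapped`,
`no-locus-in-window`, `ambiguous-locus`); assignment never crosses motif
classes.  A fragment whose two mates are both IRRs of one class (an **IRR
pair**) implies the fragment fits inside the repeat — evidence of a very
long allele.  Pairs inherit the unique locus at which the same sample has
anchored single IRRs of that class, else they are reported ambiguous.

## Spanning calls and genotypes

A spanning call requires an exact substring match of ≥ `min_anchor_bp`
(default 10) to the left flank immediately before the tract and the right
flank immediately after it, tried in both read orientations.  The unit
count is the number of complete motif copies between anchors; per-unit
substitutions are recorded as interruptions (1-based unit index plus
observed bases), capped at 3 interrupted units per read — beyond that the
call is rejected.  Indels inside the tract need no special handling: length
is measured between anchors, so a slipped molecule is simply a different
length observation.  Spanning takes precedence over IRR classification for
the same read.

Genotypes per sample × locus take the top-supported length, plus a second
allele when its support is ≥ max(`min_support`, `minor_frac` × top
support) (defaults 2 and 0.2).  Remaining lengths stay available as
candidate somatic observations.  Genotyping is invariant to read order.

## Stutter filter

PCR slippage during bridge amplification yields a polyclonal cluster of
molecules with and without one repeat unit.  The read reports the majority
species; base qualities collapse where the species disagree.  For a read
whose called length differs by δ = ±1 from its nearest germline allele, the
filter locates the junction where the *shorter* species' tract ends (one
unit before the called repeat end for δ = +1; the called end for δ = −1),
constructs the two expected downstream sequences — right flank directly,
versus one phase-correct motif unit then the right flank — and takes the
offsets where they differ as the signature set.  When the flank itself
begins repeat-like, the first informative offset falls later; a junction
within 10 bp of the read end, or an empty signature, makes the read
not-applicable.  Only the 3′ junction in read orientation is used; whether
a 5′-side or mate-based signature would add power is left open
deliberately.

Verdict: *artifact* iff mean signature quality ≤ `q_low` (default 25) or
≤ mean quality of all other read positions − `q_drop` (default 10);
otherwise *retained*.  |δ| > 1 is logged unclassified (the package
quantifies single-unit somatic steps).  The rule is deterministic and
monotone: lowering signature qualities can only move a read toward
artifact.  Thresholds are package defaults exposed as CLI parameters — the
mechanism is principled, the numbers are tunable knobs.

## Somatic phenotypes

**Expansion fraction.**  For allele a and direction d ∈ {+1, −1}, f =
n(a+d) / (n(a) + n(a+d)) over retained spanning reads, with a 95% Wilson
score interval.  Eligibility: the sample carries a, carries no germline
allele at a+d, and the other germline allele is ≥ 3 units away (exact a/a
homozygotes allowed, interpreted per allele copy) — this attribution gap
prevents cross-contamination between adjacent-length alleles.  Pooling
across individuals sums counts before the ratio (unbiased under varying
coverage), never averages ratios.  Contraction (−1) is supported
symmetrically; in an expansion-only simulated world the −1 estimates are
consistent with zero, which the tests verify as an estimator property.

**Age trends and screening.**  Weighted least squares of the metric on age
(weights = attributable read counts); the screening test regresses a
phenotype on age or a 0/1/2 genotype dosage and reports the slope z and
two-sided p (flag threshold configurable; 1e-4 is the convention used for
candidate-instability screens).

**Long alleles.**  A read is an IRR only if it starts in the L − R + 1
positions interior to an L bp tract, so E[IRR count] = c·max(0, L − R + 1)
with c the haploid read-start density (≈ depth/R; estimable genome-wide as
(mapped bases / 2·genome size)/R).  Inversion gives L̂ = (R − 1) + count/c;
zero IRRs censors at L < R.  Under mosaicism L̂ estimates the cell-averaged
expanded length.  The fragment metric divides the IRR-pair count by the
per-bp fragment-start density, estimating the eligible-start span
E[max(0, L − F + 1)] integrated over the fragment-length distribution —
monotone in L and better-powered for very long alleles.  How to combine
the two metrics into one optimised phenotype is exposed as a parameter
rather than fixed.

**Inherited-allele calibration.**  Within groups sharing the same
inherited allele (group labels are an input column; the simulator emits
the inherited length), metrics are z-scored ((x − mean)/sd, sample sd) and
rank inverse-normal transformed with offset (r − 0.5)/n, ties by average
rank.  Groups smaller than 10 or with zero variance are dropped with
logged reasons.

## Germline rates from IBD

Haplotypes sharing a tract IBD should share the repeat allele; length
discordances are germline mutations on the separating meioses.  Under the
exponential tract-length model the total separating meioses are m̂ =
max(2, 100 / length_cM); externally supplied per-branch meioses override.
Each member contributes its branch meioses (pairwise: m̂/2) of exposure,
attributed to the ancestral allele; exposure is conserved regardless of
concordance pattern.  The ancestral allele is the strict modal allele among
members; ties — including any discordant pair with no third member — are
unpolarizable by consensus.  Because pairs dominate real sharing data, the
cluster table accepts an optional externally imputed ancestral allele
(standing in for imputation from more-distantly shared haplotypes, which
is upstream of this package); the simulator emits it from truth.  Members
differing by >1 unit contribute their event at the observed step, with no
multi-step path inference.

Rates are events/exposure per (allele, direction) with exact (Garwood)
Poisson 95% intervals; zero events yield rate 0 with upper bound
3.689/exposure.  Interrupted alleles are distinct states keyed by (length,
interruption signature), so interrupted and pure alleles of equal length
accrue separate rates, enabling their comparison via the rate ratio:
conditional on total events, the numerator count is binomial, and a
Clopper–Pearson interval on its proportion maps to the ratio.  Alleles
observed on < 25 haplotypes can be pooled into same-signature neighbours
for reporting.

## Simulator: the stated world

Defaults: 151 bp paired reads at 30x haploid depth; fragments normal
400 ± 60 bp truncated below at the read length; substitution error 1e-3;
baseline Q37.  Germline expansion 5e-4 per meiosis with a 3:1
expansion:contraction asymmetry (the upper range of common trinucleotide
repeats, whose per-locus means span roughly 1e-4 to 1e-3 and which often
expand more than they contract).  Somatic: the single-step model — a
fraction f = r_s(a)·age of cells carry a+1, the rest a — with r_s = 2e-4
per year, so a 25-unit carrier reaches ~1% expanded cells by age 50, the
regime reported for the most blood-unstable common repeats.  Stutter hits
2% of repeat-overlapping reads, re-extracting the read from a ±1-unit
molecule and redrawing qualities at the positions where the two species
differ from N(15, 5) clipped to [2, 37].  The signature is constructed by
direct sequence comparison of the two species, while the filter
reconstructs it from catalog flanks: a fair but not information-identical
target.  IBD branches mutate stepwise per meiosis; tract lengths are
exponential with mean 100/m cM.

Fragment starts are uniform at exactly the configured per-bp density;
fragments overrunning the simulated region are dropped, an edge effect
confined to the far flank.  All randomness flows from one seeded
generator; identical config + seed reproduce SAM and truth tables
byte-identically.

Not emulated: instrument-specific quality profiles, GC bias, duplicate
fragments, indel sequencing errors, multi-step somatic ladders,
interruption-bearing simulated tracts, and alignment ambiguity (simulated
reads carry their true coordinates).  A green end-to-end test therefore
establishes correctness of the estimators under the stated generative
model, not robustness to aligner artifacts or library-specific noise.

## Numerical and design choices

* Coordinates are 0-based half-open throughout (BED convention); SAM
  positions convert on ingest.
* Wilson intervals via statsmodels; exact Poisson bounds via chi-square
  quantiles; WLS/OLS fits via statsmodels; ranks and normal quantiles via
  scipy.
* Nearest-germline-allele ties (equidistant alleles) resolve to the
  shorter allele; purity ties resolve by canonical rotation order; equal
  genotype support resolves by shorter length first — all for determinism.
* Read-heavy test scenarios shrink fragments/flanks (250 ± 30 bp, 340 bp)
  to keep runtimes desk-scale; geometry and error model are unchanged.
* Outputs are sorted (sample, locus, read id); results are independent of
  input read order and of thread count (the implementation is
  single-threaded; the CLI `--threads` contract is trivially met and the
  flag is therefore not exposed).

## Known limitations

* Locus assignment assumes the mate maps; loci whose flanks are themselves
  repetitive will accumulate `ambiguous-locus` skips.
* The stutter filter addresses bridge-amplification stutter with its
  quality signature; slippage during library PCR (before flow-cell
  loading) produces clean-quality artifacts it cannot detect, which
  inflates apparent mosaicism equally at all ages.
* Germline-rate estimation consumes IBD clusters as input; detecting IBD
  tracts, parent-of-origin effects and parental-age effects are out of
  scope (the latter require de novo designs).
* Spanning-based somatic estimation covers alleles up to ~(R − 2·anchor)/k
  units; longer alleles fall back to the IRR-count and fragment metrics,
  which have coarser resolution.
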