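# Methods

`pepseq` analyses peptide self-editing screens: pooled libraries of peptide–
prime-editor (PE2) fusions in which every cell carries one library member
that installs a fixed 6-nt substitution (CCTCTG → GAATTC) at a target site
adjacent to its own peptide barcode. Paired-end amplicon sequencing links
peptide identity (read 1) to editing outcome (read 2); the analysis turns
those reads into per-peptide editing efficiencies, effect estimates, and
hit calls. This note records the models, the defaults, and the choices made
where the design was open.

## Library design

Proteins are tiled into 85-residue peptides stepping by 45 residues, so
interior residues are covered about twice; if the last regular tile falls
short of the C-terminus an extra tile is anchored at `length − 85`, keeping
every peptide the same length and every residue covered. Phosphomimetic
variants replace exactly one serine or threonine with glutamate; one
variant per S/T site, no multi-site combinations (the combinatorial space
would dwarf any practical library, and the single-substitution count is
what a variant-per-site expansion yields).

Nucleotide encoding samples codons independently per position, weighted by
a user-supplied usage table (uniform over synonymous codons by default —
the analysis is insensitive to codon choice; any organism-specific table
can be passed in). The demultiplexing contract is that the first eight
nucleotides are unique across the library; on collision the first three
codons are resampled up to 200 times. This can be genuinely unattainable:
peptides sharing their first three residues draw prefixes from the codon
wobble of those residues only, and e.g. an `MQH` amino terminus admits just
two distinct 8-nt prefixes. The error then reports the colliding records so
the designer can drop or re-tile them — and this limitation is exactly why
phosphomimetic variants additionally carry a unique 9-nt tag. The tag is
placed downstream of the open reading frame, outside the translated frame,
so the amino-acid sequence is untouched; the assay description says only
that tags aid sequence mapping, not where they sit.

Coordinates are 0-based and half-open throughout.

## Read processing

**Demultiplexing.** Exact string matching of the first eight nucleotides of
read 1 against the designed prefixes. No error tolerance: one mismatch
leaves the read unassigned (tallied, never counted).

**Alignment.** Read 2 is aligned globally (Needleman–Wunsch) to the
reference amplicon with match +1, mismatch −1, gap open −5, gap extension
0 — read literally, a gap of any length costs 5. End gaps are scored like
internal gaps. Traceback ties are broken diagonal > up (gap in reference) >
left (gap in query); the choice is documented because it fixes where
equivalent gaps land, though never the score. The implementation is a
three-state Gotoh dynamic program written here because downstream filters
need per-column events with reference coordinates and query qualities plus
a pinned tie-break; scores are cross-checked in the tests against both an
exhaustive enumeration oracle and `Bio.Align.PairwiseAligner`. A gap-free
fast path is taken for equal-length read/reference pairs with at most five
mismatches, where the gap-free alignment is provably strictly optimal
(a gapped alternative scores at most `L − d − 10 < L − 2h` for `h ≤ 5`).

**Filtering.** Reads with mean PHRED quality below 30 are dropped (the
mean-quality rule is applied to the target-site read only; read 1 is used
solely for prefix matching, and the source description ties the filters to
sequenced target sites). Mismatches at bases with quality below 30 are
masked, i.e. treated as reference. Indels are masked unless the three
alignment columns immediately flanking each side are matches with quality
≥ 30; "three matching nucleotides on both sides" is read as the adjacent
columns, the strictest interpretation and the one that makes the 2-match
counterexample unambiguous. Masked indels are removed from the event list
before classification.

**Classification.** A kept read's *effective sequence* is rebuilt from the
masked alignment (masked mismatches contribute the reference base, masked
deletions restore the reference, masked insertions are dropped). Then:
effective sequence equal to the fully edited amplicon → `prime_edited`;
otherwise any unmasked indel → `indel`; otherwise equal to the reference
(or differing only through masked events) → `unedited`; anything else —
including reads carrying only part of the programmed edit — → `other`.
Edit calling is all-or-nothing. Checking full equality with the edited
amplicon first (rather than the indel branch first) is behaviourally
identical for a same-length substitution and lets the same rule score
programmed insertions or deletions.

## Synthetic data

The generator mirrors the inference model exactly: peptide i has
Beta(α_i, β_i) parameters, replicate j realises p_ij ~ Beta(α_i, β_i), and
the edited count is Bin(n_j, p_ij). Defaults are chosen to look like the
screen this pipeline is built for: control mean editing rate 0.2 (screens
of this design report roughly 16–28% edited alleles), concentration
α + β = 100 (a replicate-level CV of ~20% in the editing rate, consistent
with the modest replicate correlations such screens show), enhancer fold
1.5, indel fraction 0.005 among non-edited alleles (reported indel rates
are 0.3–0.7%), partial-edit fraction 0.005 of edited alleles, per-base
substitution error 0.001. Sequencing depth is constant per peptide × 
replicate cell; nothing downstream depends on depth jitter, and constant
depth keeps truth tables exact. Replicates can share a rate draw through a
batch map, emulating replicates that share a library integration.

Reads are rendered with a two-level quality model (high 37; error positions
and an optional random fraction at 15). The random low-quality fraction
defaults to 0 so that an error-free simulation is classified exactly as
planted — low-quality positions adjacent to a planted indel would
legitimately mask it. Indel alleles carry a 1–3 nt insertion or deletion
placed uniformly within ±6 nt of the edit region (a stand-in spectrum;
real nick-proximal indel spectra are editor- and site-specific). Partial
edits carry a proper prefix of the alternate allele. Output is
byte-identical given identical inputs and seed.

What the generator does *not* emulate: sequencer-specific error and
quality profiles, PCR duplicates and jackpotting, chimeric reads, uneven
library representation, and cell-biological covariates (expression,
fitness). Passing the end-to-end tests therefore demonstrates correctness
of the accounting and inference under the assumed model, not robustness to
every artefact of real NGS data.

## Effect inference

Peptides with fewer than 100 kept reads in any replicate are excluded
(strict inequality; 100 everywhere is retained).

The per-peptide MLE of (α, β) solves the digamma score equations of the
beta-binomial log-likelihood

    ℓ(α, β) = Σ_j [ln B(y_j + α, n_j − y_j + β) − ln B(α, β)]

via `scipy.optimize.root` in log-parameter space, started from the
moment-matching estimate; a solution is accepted only if the solver
converges to positive finite parameters that do not lower the likelihood.
Moment matching follows the overdispersed-binomial view: with
`obsvar = var_j(y_j/n_j)` (sample variance, k−1 denominator, preferred for
small k) and `expvar = m(1−m)/mean(n_j)`, the concentration is
`(mean(n_j) − 1)/(obsvar/expvar − 1) − 1` and `α = m·(α+β)`. Degenerate
regimes: mean exactly 0 or 1 adds a half-count pseudocount (y+½, n+1);
underdispersed samples (`obsvar ≤ expvar`), where the formula has no
positive solution and the likelihood peaks at infinite concentration, clamp
the concentration to `10·mean(n_j)` preserving the mean; overdispersion so
extreme the formula turns non-positive clamps to a floor of 0.01. A single
replicate is unidentifiable and uses the clamp. Note the likelihood can
peak on the infinite-concentration boundary even for samples that look
mildly overdispersed by the unweighted moment criterion (unequal n_j,
k = 2); the fallback covers those too.

Ranking against controls uses `P(Y_pep > Y_ctrl) + ½·P(Y_pep = Y_ctrl)`
with both counts beta-binomial at a common reference depth (median observed
n by default): exact pmf-product enumeration up to n_ref = 5000, seeded
Monte Carlo beyond. Controls are pooled into a single (α, β) fit for the
comparison distribution, matching the singular "control effect parameters"
framing. Hit calling normalises each peptide's per-replicate edited
fraction by the mean control fraction in that replicate (replicates with
zero control editing are excluded with a warning), applies a two-sided
paired t-test against the control means, and corrects with
Benjamini–Hochberg (the named FDR procedure is not specified upstream; BH
is the field default). The composite rank orders by exceedance probability,
then higher fitted mean, then lower fitted variance — a documented
composite, not a claimed reproduction of the original prioritisation
weighting, which additionally admitted high-mean/high-variance peptides by
judgement.

## Dual-peptide additive model

Dual fusions are modelled as `observed(i, j) = baseline + a_i + b_j` with
*position-specific* effect vectors (an N-terminal peptide may act
differently from the same peptide placed C-terminally; the screen design
distinguishes orientation). The observed quantity per pair is the median
normalised fraction across replicates. The least-squares fit includes an
intercept and anchors the control peptide's effect at 0 in each position;
predictions are invariant to the anchoring. Additivity is quantified as the
Pearson r between predicted and observed per-pair medians (over pairs, not
replicates); zero-variance inputs make r undefined and NaN is returned.
Disconnected pair designs are rejected as unidentifiable.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so each
stage is exercised meaningfully: alignment oracle on 1000 random short
pairs; a 50-peptide, depth-500, 3-replicate noise-free FASTQ round trip
(75,000 read pairs) checked exactly against truth; 200 random
overdispersed instances for the MLE/grid comparison; 100 peptides at k = 8,
n = 2000 for parameter recovery; a 200-peptide screen with ten planted
1.5× enhancers at depth 1000, k = 3 for ranking recovery; and 10×10 dual
grids. The acceptance script simulates a ~60-peptide screen at depth 400
with five replicates — hit calling with a paired t-test needs the
five-replicate design the validation screens used — plus a noisy 10×10
dual grid.

## Known limitations

- The aligner is quadratic pure Python; it is fast enough for amplicon
  work because nearly all reads take the gap-free fast path and repeated
  (sequence, quality) pairs are memoised, but it is not a general-purpose
  NGS aligner.
- The MLE is per-peptide; no shrinkage across peptides, no batch-effect
  regression, no Bayesian posterior beyond the point estimate.
- The composite ranking is one reasonable reading of an under-specified
  prioritisation; the t-test and the exceedance probability are both
  reported so users can rank by either.
- The dual model fits main effects only; interaction-term selection and
  epistasis classification are out of scope.
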