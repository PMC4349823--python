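# Methods

`srnaseg` implements two independent procedures for nominating bacterial small
non-coding RNA (sRNA) candidates, originally developed for *Wolbachia* (the
wMel strain and its comparison with wPip), plus the synthetic-data generators
needed to exercise both end to end. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic tests do
and do not establish.

## The conservation arm

### Alignment encoding

A pairwise whole-genome alignment (colinear blocks, e.g. progressiveMauve
output in XMFA) is converted into a single symbol sequence over a 16-letter
alphabet `a..p`: each gap-free aligned column maps its ordered base pair
(reference, query) row-major, so `(A,A)→a`, `(A,C)→b`, …, `(T,T)→p`.
Identical bases land on `{a, f, k, p}`; the fraction of those symbols in a
window is the local conservation level. Columns containing a gap or any
ambiguity code emit nothing — their reference coordinates are simply absent
from the coordinate map, which later turns into coordinate gaps in the
profile rather than zero values. Ambiguity codes are treated like indels
because neither carries a usable ordered base pair; soft-masked lowercase
input is upper-cased before encoding. Blocks are joined with `#`, which the
model treats as a mandatory change-point; blocks on the reverse reference
strand are reverse-complemented into forward orientation first so all output
lives on one reference coordinate axis. Masked regions (prophages, known
horizontal transfers, supplied as BED) are removed column-wise before
encoding, splitting blocks where the removal is internal, and blocks whose
reference span falls under `min_block` (default 500 nt) are dropped.

All genomic coordinates in the package are 1-based inclusive; interval length
is `end − start + 1`.

### The change-point model

The encoded sequence is modelled as piecewise homogeneous: an unknown set of
change-points partitions it into segments; each segment carries one of `k`
latent classes; symbols within a segment are i.i.d. categorical draws from the
class's 16-dimensional emission simplex θ. Priors are conjugate:

- θ_c ~ Dirichlet(α = 1) per class (`dirichlet_alpha`);
- each eligible inter-symbol boundary is a change-point independently with
  probability `cp_prior_p` = 0.005, i.e. a geometric prior mean segment length
  of 200 nt — the scale of the conserved elements being sought;
- segment labels are i.i.d. from a mixture π with a symmetric Dirichlet(1)
  prior (`class_prior`).

Boundaries at `#` separators are fixed (probability 1, never toggled).

### Sampler

Inference is by Metropolis-free Gibbs sampling. One sweep:

1. **Boundary toggles.** For every eligible boundary, in left-to-right order,
   the indicator is resampled with the labels of the affected segments
   marginalised out given the current (θ, π):
   `P(on) ∝ cp_prior_p · [Σ_c π_c L(left|θ_c)] · [Σ_c π_c L(right|θ_c)]` and
   `P(off) ∝ (1 − cp_prior_p) · Σ_c π_c L(merged|θ_c)`; the affected labels
   are then redrawn from their conditional. Segment likelihoods are ratios of
   per-class prefix sums of log θ, so each toggle costs O(k); a forward
   pointer to the next active boundary makes the whole pass O(N·k) (toggling
   a boundary never changes boundaries to its right).
2. **Label resampling** for every segment, `P(c) ∝ π_c L(segment|θ_c)`.
3. **Conjugate draws**: θ_c ~ Dirichlet(α + symbol counts in class c),
   π ~ Dirichlet(1 + segment counts).
4. The data log-likelihood under the fresh θ is recorded along with the full
   state.

The sweep kernel is compiled with numba; a 25 kb sequence runs 1,000
iterations in a few seconds. A single seeded generator drives the chain; the
seed is recorded in every output and identical inputs reproduce bit-identical
sample lists. Defaults are 1,000 iterations with the first 150 discarded as
burn-in and no thinning.

Empty classes are allowed (their θ is then a prior draw); they are the
signature of an over-fitted class count and feed the selection rule below.

**Label switching.** The prior is symmetric in class labels, so raw label
identities are meaningless across draws. Classes are identified by
*conservation rank*: within each draw, classes are ordered by
E(θ) = θ_a + θ_f + θ_k + θ_p (descending; for unnormalized frequency vectors
the statistic divides by Σθ). Raw samples keep their sampled labels;
re-ranking happens only at reporting time.

### Model selection

Models are fitted independently for k = 1..12 (the analysis default) and
compared by trace-based criteria with p = 15k + (k − 1) free parameters and
L̂ the maximum sampled log-likelihood:

- AIC = −2L̂ + 2p
- BIC = −2L̂ + p·ln n (n = encoded symbols)
- DICV = mean(D) + var(D) over the post-burn-in deviance trace D = −2·logL,
  i.e. D̄ + 2·p_D with the variance-based effective-parameter estimate
  p_D = var(D)/2.

The working k is the smallest joint local minimum of AIC and DICV (a boundary
point needs only its single neighbour to be larger); a candidate whose fitted
model contains a class with mean mixture proportion below `min_mixture`
(default 0.01) is treated as over-fitted and skipped. If no admissible joint
local minimum exists the AIC argmin over non-over-fitted models is returned
with a warning flag (plain argmin only when every model is over-fitted) — the
under-populated-class rule governs the decision in either path. BIC is
reported but never drives selection: its ln(n) penalty dominates at genomic n
and it behaves unlike the other two criteria. Convergence is checked the same
way it is checked in practice for this model family: by the log-likelihood
and per-class E(θ) traces, summarised with a split-half comparison of the
post-burn-in log-likelihood means (flagged if the halves differ by more than
3 pooled standard errors).

### Profiles and candidates

The profile of class rank r assigns each encoded reference position the Monte
Carlo posterior probability, over post-burn-in draws, that its segment carries
the class ranking r-th by E(θ) in that draw. Because ranks partition the
classes in every draw, the k rank-profiles sum to one at every position.
Profiles are written as UCSC fixedStep wiggle tracks (step 1, span 1, four
decimals), with a new declaration block at every coordinate gap.

Candidate regions are maximal runs of profiled positions with value ≥ `p_min`
(default 0.5), broken at coordinate gaps, kept only if strictly longer than
`len_min` (default 50 nt — "longer than 50" is read strictly; the shortest
published region, 53 nt, is consistent with either reading). Runs overlapping
a CDS by even 1 nt are rejected (candidates must lie entirely in intergenic
space); runs fully inside an annotated non-coding feature (rRNA, tRNA, tmRNA,
ncRNA, pseudogene) are reported separately as already-annotated; the rest are
reported with their nearest flanking features, strand ignored. A FASTA export
of candidates supports external screening (e.g. the post hoc horizontal
transfer check by BLAST against A- and B-group genomes, which is outside this
package's scope).

## The RNA-Seq arm

Reads are quality-filtered the way the original data were: trailing bases
with quality < 30 are trimmed, reads shorter than 40 nt after trimming are
discarded, and losing either mate discards the pair. Mapping itself is out of
scope; mapped pairs arrive as SAM (primary records only; mates paired by
query name; spans from POS plus the reference-consuming CIGAR length).
Multi-mapped pairs are assumed pre-resolved to a single recorded location,
mirroring random assignment at the mapping stage; the package does not
re-randomize.

Counting assigns a pair to every feature its fragment span (leftmost mate
start to rightmost mate end) overlaps by ≥ 1 nt, against a modified
annotation in which explicit intergenic features (`IG-n`) fill the maximal
gaps left by the union of all annotated features — so overlapping or nested
genes collapse, and the intergenic features plus the annotation union tile
the genome exactly.

The specificity filter is deliberately conservative. For each intergenic
region, with its nearest non-intergenic neighbours as flanks:

- *inside* pairs have both mate spans fully contained in the region;
- *straddling* pairs have one mate overlapping the region and the other
  overlapping a flank by ≥ 1 nt.

One straddling pair suffices for a `readthrough` verdict (the exclusion rule
is "any pair"); otherwise `specific` requires at least `min_pairs` inside
pairs (default 10 — the screening threshold for "high transcription" is not
published; 10 echoes the per-CDS "> 10 reads" reporting convention);
otherwise `untranscribed`. Strand is ignored throughout, as the library
preparation this models was unstranded. Pairs lying entirely in flanking
genes carry no evidence either way.

## Synthetic data

`simulate_alignment` draws symbols independently per planted segment: a match
symbol (uniform over {a,f,k,p}) with the class's match probability m, else a
mismatch symbol from the class's mismatch distribution (uniform over the 12
non-match symbols by default; a transition/transversion-structured
distribution can be supplied but is not exploited downstream). Planted `#`
breaks and an optional indel rate (realised as coordinate gaps) complete the
structure. The generator returns the true segmentation and compositions for
recovery tests. The default study condition for recovery experiments is two
classes with match fractions 0.95 and 0.60 — the conservation levels of the
most conserved class and a typical background class in the wMel–wPip
comparison — in 20 segments of 500–2,000 nt (≥ 20 kb total).

`simulate_reads` builds a random genome with annotated CDS intervals and
samples fragments (normal length, default 300 ± 30 nt, floored at the read
length; fragments longer than their transcript are redrawn and counted) from
transcripts of three kinds: intergenic-specific (contained in a gap),
polycistronic (spanning gene–gap–gene), and UTR read-through (starting in a
gap and running into a gene). Mates are the first and last 72 nt of the
fragment (mate 2 reverse-complemented), with constant base quality;
sequencing error is off by default because the filter under test is
positional, not base-level. Truth verdicts per gap follow the planted
transcript kinds and the sampled pair counts. All outputs (FASTQ, SAM of true
alignments, GFF3, truth tables) are byte-identical under a fixed seed.

What passing on synthetic data shows — and does not. The generators match the
model's assumptions exactly (piecewise-i.i.d. composition; exact mate
positions; no mapping error, coverage bias, or rRNA contamination). Tests
therefore establish correctness of the inference and filtering machinery, not
robustness to real-data violations such as compositional drift within
segments, mapping ambiguity, or fragment-size tails.

## Verification against exact enumeration

For instances with ≤ 14 symbols and ≤ 3 classes, `exact_posterior_small`
enumerates every segmentation and labeling with θ and π integrated out
analytically (Dirichlet-multinomial predictives), giving exact change-point
marginals. Raw per-position label marginals are uniform by label symmetry, so
the identifiable quantity checked is rank membership: within one enumerated
configuration, E(θ) of class c under its conditional Dirichlet is
Beta(4α + matches, 12α + mismatches), classes are independent, and rank
probabilities are order statistics of independent Betas computed by
quadrature. The sampler estimates the same functional by ranking each draw's
sampled θ, so the two sides share a single definition. Agreement is asserted
within 3 Monte-Carlo standard errors, with the SE estimated by batch means
and floored by the binomial SE at the exact value (a lower bound under
positive autocorrelation). The exhaustive check runs over all two-symbol
sequences up to length 5 plus a seeded sample of lengths 8–10; longer
exhaustive sweeps grow as 2^n × 3^(n−1) enumeration states and add nothing
structurally new.

## Problem sizes and defaults

| parameter | default | meaning |
|---|---|---|
| `min_block` | 500 nt | minimum reference span of an aligned block |
| `dirichlet_alpha` | 1.0 | emission prior pseudo-count per symbol |
| `cp_prior_p` | 0.005 | prior change-point probability per boundary |
| `class_prior` | 1.0 | mixture prior pseudo-count per class |
| `iterations` / `burn_in` | 1000 / 150 | sweeps recorded / discarded |
| k range | 1–12 | class counts swept for selection |
| `min_mixture` | 0.01 | over-fit disqualification threshold |
| `p_min` | 0.5 | profile threshold for candidate runs |
| `len_min` | 50 nt | candidates must be strictly longer |
| `q_min` / `read_len_min` | 30 / 40 nt | read trimming and length filter |
| `min_pairs` | 10 | inside pairs needed for a `specific` verdict |
| fragment / read length | 300 ± 30 / 72 nt | read simulator geometry |

Recovery experiments in the tests and the acceptance script use 10 seeded
replicates of the two-class condition with k swept over 1–4, 1,000 iterations
each; the oracle comparison uses 5,000 post-burn-in draws per instance. These
sizes make the complete run reproducible on a single CPU in a few minutes
while leaving the statistical conclusions unchanged at larger sizes.

## Known limitations

- The concrete prior and move set are this package's own design; results from
  other implementations of this model family (such as the changept program)
  are comparable at the level of the model and decision rules, not draw by
  draw.
- Analysis of a full genome pair (~1 Mb encoded, k up to 12) is supported by
  the same code paths but is an hours-scale run; packaged experiments run at
  tens of kilobases.
- Only pairwise encodings are implemented; the 16-letter code does not extend
  to 3-way alignments.
- Secondary-structure-level conservation is invisible to a composition-based
  segmentation; candidates conserved in structure but not sequence will be
  missed.
- The specificity filter inherits fragment-scale blindness: an intergenic
  region shorter than the fragment size cannot yield inside pairs and can
  never be called specific, regardless of its true transcription.
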