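# srnaseg

Discovery of candidate small non-coding RNAs (sRNAs) in bacterial genomes by
two independent routes, packaged as a tested Python library with a CLI.

Bacterial sRNAs — typically 50–500 nt, often regulatory, frequently
trans-encoded from intergenic loci — are easy to miss with annotation
pipelines built around open reading frames. Two orthogonal signals reveal
them anyway:

1. **Conservation.** Functional intergenic elements evolve under purifying
   selection, so between two moderately diverged strains they stand out as
   unusually conserved islands in otherwise drifting intergenic sequence.
   `srnaseg` encodes a pairwise whole-genome alignment column-by-column into
   a 16-letter alphabet (ordered base pair `(ref, qry)` → one of `a..p`;
   identities land on `{a,f,k,p}`), then fits a Bayesian multiple
   change-point model: unknown change-points cut the sequence into segments,
   each segment belongs to one of *k* latent classes with its own emission
   simplex θ over the 16 symbols, with conjugate priors throughout
   (Dirichlet(α) emissions, Bernoulli(p) boundaries, Dirichlet mixture over
   labels). A Gibbs sampler yields posterior draws; the number of classes is
   chosen by the first joint local minimum of AIC and a deviance-variance DIC
   (DICV), skipping over-fitted models; classes are identified across draws
   by their conservation level E(θ) = θ_a + θ_f + θ_k + θ_p. The posterior
   probability that each reference position belongs to the most conserved
   class becomes a wiggle track, and runs of positions with probability
   ≥ 0.5 longer than 50 nt that touch no CDS are the candidates.

2. **Intergenic-specific transcription.** RNA-Seq coverage in an intergenic
   region can be read-through from an operon or UTR rather than an
   independent transcript. With paired-end reads the two are separable:
   `srnaseg` calls a region *specifically transcribed* only when enough pairs
   map with both mates fully inside it and not a single pair straddles into a
   flanking gene.

The package was built around the *Wolbachia* wMel genome (with the wMel–wPip
alignment for the conservation arm) and ships the published coordinates of
the 19 highly conserved intergenic regions of wMel for coordinate arithmetic
and filter checks — but every stage runs on any bacterial genome, and a
synthetic-data module generates complete ground-truthed inputs for both arms
so that the whole pipeline is testable without downloads.

## Worked example

Fit the change-point model to a synthetic two-class alignment (match
fractions 0.95 and 0.60 in 20 planted segments, ~26 kb):

```python
import numpy as np
from srnaseg import (AlignmentSimSpec, ClassSpec, simulate_alignment,
                     sweep_classes)

rng = np.random.default_rng(0)
lengths = rng.integers(500, 2001, size=20)
segments = [(int(n), 1 + i % 2) for i, n in enumerate(lengths)]
spec = AlignmentSimSpec(segments=segments,
                        classes={1: ClassSpec(0.95), 2: ClassSpec(0.60)},
                        seed=0)
encoded, truth_seg, truth_comps = simulate_alignment(spec)

sweep = sweep_classes(encoded, range(1, 5), iterations=1000, burn_in=150, seed=11)
selection = sweep.select()
results = sweep.results[selection.k]
print(results.summary())
```

```
Change-point segmentation results
=================================
classes (k):            2
sequence length:        26112 symbols
iterations / burn-in:   1000 / 150
seed:                   11002
max log-likelihood:     -54387.04
AIC / BIC / DICV:       108836.1 / 109089.3 / 109106.4
mean internal cuts:     90.1

class  mean E(theta)  mean mixture prop.
    2        0.9466             0.4931
    1        0.5951             0.5069
```

The sweep selects k = 2 and recovers the planted conservation levels: the
most conserved class's posterior mean E(θ) is 0.947 against the planted 0.95,
at about half the positions, as planted. `results.profile(class_rank=1)`
returns the per-position membership probability of that class, writable as a
wiggle track with `srnaseg.write_wig`, and
`srnaseg.conserved_segments(profile)` extracts the candidate runs.

The same pipeline from the shell, on any alignment + annotation:

```bash
srnaseg simulate --out-dir fixtures --seed 5        # synthetic inputs
srnaseg conserve --alignment aln.xmfa --gff ann.gff3 --mask prophages.bed \
                 --out-dir conserve_out --seed 1    # conservation arm
srnaseg txn --sam mapped.sam --gff ann.gff3 --out-dir txn_out  # RNA-Seq arm
srnaseg intersect --candidates conserve_out/candidates.tsv \
                  --verdicts txn_out/verdicts.tsv --out joint.tsv
```

`conserve` writes `criteria.tsv` (the AIC/BIC/DICV table), trace plots, the
rank-1 wiggle track, candidates as TSV/BED, and a manifest with the seed and
configuration; `txn` writes per-feature counts and per-intergenic-region
verdicts (`specific` / `readthrough` / `untranscribed`).

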