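# linmotif

Robust, unsupervised deconvolution of linear amino-acid motifs around
post-translationally modified sites.

## The problem

Protein-modifying enzymes recognize short linear sequence contexts — a
kinase that prefers a proline right after the phospho-serine, a ligase
that needs acidic residues three positions upstream.  Given a set of
fixed-width peptide windows centered on modified sites (the
*foreground*) and a reference window population (the *background*,
typically every same-width, same-center-residue subsequence of a
proteome), motif deconvolution decomposes the foreground into
independent motifs, each a set of fixed (position, residue) pairs.

The classic greedy strategy (Motif-X lineage) repeatedly fixes the
single most-enriched position/residue pair and removes the matching
sequences.  When two pairs are *statistically identical* — same residue,
same count, same background frequency — the greedy choice is arbitrary,
and because the chosen subset removes shared sequences, the runner-up
can drop below the support threshold and vanish.  The result is a
positional bias: motifs reported for a dataset differ from those
reported for the same dataset read backwards, or reordered.

`linmotif` removes this bias by **tie branching**: every maximally
enriched pair is selected simultaneously, the foreground is partitioned
into possibly *overlapping* subsets (a window matching several pairs
joins all of them) plus a remainder, the background is recompiled for
each subset, and the procedure recurses.  The output is a pure function
of the foreground/background *counts* — invariant under input
permutation, noise placement, and sequence reversal.

## The statistic

For foreground windows `n` at offset `i` with `k` occurrences of token
`t` (a residue, or a compound physicochemical group such as acidic
`{D,E}`), and background probability `p0 = f_bg(i, t)`:

    p = P(X >= k),  X ~ Binomial(n, p0)

evaluated exactly (term summation for small `n`, regularized incomplete
beta otherwise).  A pair is significant when `p <= alpha / m` with
Bonferroni family size `m = width x (20 + #groups)`, recomputed at every
scan.  Defaults: `alpha = 0.001`, minimum support 20 sequences, window
width free (11/13/15 are typical), position-specific background
frequencies.  Motifs are labelled Class I (central residue plus flanking
fixations), II (central only) or III (flanking only — no fixed central
residue is ever required).

For multi-sample studies, motifs extracted per sample are pooled into a
non-redundant set; every sample is matched against every motif, match
counts are binomially tested against the product of per-offset
background frequencies, significant counts become percentages of the
sample size, and the matrix is ln(x+1)-transformed, row-centered/scaled
and ordered by average-linkage Euclidean clustering for heatmap export.

## Worked example

The positional-bias demonstration set: 39 windows of width 15, all
serine-centered; 19 with aspartate at the first position, 19 at the
last, and one with aspartate at both — two statistically identical
enrichments coupled through one shared sequence.

```
$ linmotif simulate --kind bias-demo --seed 11 --out-dir .
$ linmotif extract --fg bias_demo_fg.txt --bg bias_demo_bg.txt --out-dir results
loaded 39 foreground windows (width 15), background of 5000 windows
extracted 2 motifs in 0.02s

$ cat results/motifs.tsv
pattern	fixed_pairs	support	class	pair_pvalues	matched_count
..............D	D@+7	20	III	1.827354e-15	20
D..............	D@-7	20	III	1.827354e-15	20
```

Both motifs are recovered, each supported by 20 sequences (the dual-D
window counts for both), with *identical* p-values — the tie that a
greedy selector would break arbitrarily, losing one motif when the
shared sequence is captured first.  The central serine is correctly not
reported: against the serine-centered background its frequency is 1.

The robustness battery on the same files:

```
$ linmotif validate --fg bias_demo_fg.txt --bg bias_demo_bg.txt
permutation_invariance: PASS
head_tail_noise_symmetry: PASS
reversal_equivariance: PASS
```

Library use mirrors the CLI:

```python
from linmotif import EngineConfig, build_background, extract_motifs, synthgen

fg, bg_windows = synthgen.generate_bias_demo(seed=11)
motifs = extract_motifs(fg, build_background(bg_windows, 15), EngineConfig())
for m in motifs:
    print(m.pattern, m.support, m.complexity_class)
```

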