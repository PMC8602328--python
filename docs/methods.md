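# Methods

## Model and procedure

`linmotif` operates on fixed-width, odd-length aligned peptide windows.
Columns are addressed by offset relative to the central (modified)
position, `-(w-1)/2 .. +(w-1)/2`.  A *motif* is a set of fixed
(offset, token) pairs with unique offsets, where a token is a single
residue or a compound residue group; a window matches a motif when its
residue at every fixed offset equals the token or belongs to the group.

One deconvolution run proceeds as:

1. **Scan.** For every offset and every token with at least one
   foreground occurrence, compute the one-sided exact binomial survival
   probability `P(X >= k)` with `X ~ Binomial(n, p0)`, where `k` is the
   foreground occurrence count at that offset, `n` the number of
   foreground windows with a counted residue at that offset, and `p0`
   the background probability of the token there.  A pair is significant
   when `p <= alpha/m`, `m = w * (20 + #groups)` (Bonferroni; the family
   is recomputed for every scan, since each subset is a fresh family of
   tests).
2. **Select.** All significant pairs whose p-value ties the minimum are
   selected simultaneously.  Ties are decided on log p-values with
   relative tolerance 1e-9, so mathematically identical configurations
   reached by different summation orders still tie; exact-zero p-values
   compare equal to each other only.  If a single residue and a group
   containing it are both maximal with identical `k`, the group adds no
   sequences and only the single residue is kept.
3. **Partition.** One subset per selected pair (subsets may overlap — a
   window matching several pairs joins all of them) plus a remainder of
   windows matching none.  Subsets below the minimum support are
   dropped.
4. **Recurse.** Each pair subset recurses with the pair appended to its
   prefix and the background *recompiled* (restricted to background
   windows matching the pair).  The remainder recurses with the
   unchanged prefix and background.  When a scan finds nothing
   significant, a pair-extension branch emits its prefix as a motif
   (support = subset size); remainder branches emit nothing on their own
   termination, so each prefix is emitted exactly once per distinct
   extension path.  A branch whose recompiled background would be empty
   terminates and emits its prefix including the pair that exhausted it.

The recursion never re-fixes an offset already present in the prefix
(candidates at fixed offsets are removed before maximal selection).
This enforces unique offsets per motif and guarantees termination; in
particular, a compound-group fixation is not later "refined" by one of
its member residues at the same offset.

Identical pair sets reached through different branch orders are emitted
once (they necessarily carry identical matched sets and support).
Output order is deterministic: candidates are scanned offset-ascending
with singles alphabetical before groups; motifs are sorted by support
descending, then pattern.

## Statistical background

Backgrounds are built from a proteome (one window per residue position,
termini padded with `-`, optionally restricted to a given central
residue) or from user-supplied pre-aligned windows.  Padded `-` cells
and ambiguous `X` cells (to which all nonstandard codes are normalized)
are excluded from the numerator *and* denominator of every frequency,
in foreground and background alike, so probabilities remain
well-defined near termini.  Frequencies are position-specific by
default; pooled (position-independent) frequencies are available as a
configuration switch.  A compound group's probability is the sum of its
disjoint members' probabilities.

A token that never occurs in the (current, possibly recompiled)
background has `p0 = 0`; any foreground occurrence would then be
"infinitely significant".  Such pairs are *untestable* and are excluded
from the scan rather than claimed enriched — with small recompiled
backgrounds this is a sparsity artifact, not evidence, and admitting it
would both inflate the false-positive rate and hijack recursion
branches.  Reported p-values therefore always lie in (0, 1].

No default background is fabricated: a run without an explicit
background (or proteome to derive one from) is an error, because using
the foreground as its own background corrupts every p-value.

## Numerical choices

* Binomial survival: for `n <= 64`, direct term summation with a
  multiplicative recurrence starting from the log-evaluated first term
  (all terms positive; relative error ~`n * eps`, comfortably within
  1e-12).  For larger `n`, the survival function via the regularized
  incomplete beta (scipy).  Edge cases: `P(X >= 0) = 1`; `p0 = 1` gives 1;
  `p0 = 0` with `k > 0` gives 0 (reachable only through the scalar
  function, never through a scan).
* The tie tolerance (1e-9 relative on log p) is far wider than summation
  noise (~1e-14) and far narrower than any genuine enrichment
  difference at the default threshold.
* Zero-variance rows in the ln(x+1)/center/scale transform become
  all-zero rows rather than NaN, keeping matrix shapes stable.  Scaling
  uses the sample standard deviation (ddof = 1, as R's `scale`).
* Non-significant cells of the percentage match matrix are exported as
  NaN; for clustering they are filled with 0 and flagged in a parallel
  boolean mask.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.001 | familywise significance level per scan (Bonferroni-corrected) |
| `min_support` | 20 | minimum sequences matching a motif; sub-threshold subsets are not pursued |
| `width` | input width | odd window width; 11–15 typical for modification-site studies |
| `position_specific_background` | true | per-offset vs pooled background frequencies |
| `compound_groups` | off | physicochemical residue groups screened as single tokens |
| `require_central_residue` | unset | optional central-residue restriction; unset analyzes all windows together |
| `dedup_sequences` | off | plain-sequence-level redundancy elimination (used for tissue-level comparisons) |
| `tie_strategy` | `"all"` | `"first"` is a deliberate greedy ablation reproducing the positional-bias failure mode |

The defaults (`alpha` 0.001, support 20) follow the Motif-X-compatible
convention so results are comparable across tools.  The built-in
compound groups are a standard physicochemical partition — acidic DE,
basic KRH, polar-uncharged STNQ, nonpolar-aliphatic AVLIM, aromatic
FWY, tiny GPC — overridable by a `name:RESIDUES` definition file.

Site extraction is 1-based at the protein level; windows are the site
residue plus `(w-1)/2` flanks each side, `-`-padded past termini.
Sites are de-duplicated on (accession, position, modification); a site
whose stated residue disagrees with the protein sequence is rejected
and counted, not an error.  Pan-modification studies retain only
modifications with at least 50 occurrences (configurable).

## Synthetic data

The generators produce the validation datasets so that every claim is
testable without downloads:

* **Bias demo** — 39 serine-centered 15-mers: 19 with D at offset −7,
  19 with D at +7, one with D at both; uniform-random filler that never
  places a stray D at the opposite anchor, so each anchor has exactly
  20 supporting sequences.  The background is 5,000 serine-centered
  windows with uniform filler, generated in mirror pairs (each window
  plus its reverse) so mirror offsets are exactly equifrequent — the
  demo's premise is that the two anchors are *statistically identical*,
  and symmetrization makes that exact rather than approximate.
* **Random proteomes** — i.i.d. residues, uniform by default, standing
  in for a reference proteome at desk scale.
* **Null samples** — foregrounds drawn uniformly *without replacement*
  from a background window pool (optionally central-residue-stratified).

What the generators do not emulate: real proteome composition biases,
protein-abundance weighting, correlated positions, or modification
prevalence distributions.  Passing the null experiment on uniform
proteomes therefore bounds the procedure's intrinsic false-positive
behaviour, not its behaviour under compositional confounding; the
robustness battery (permutation, noise placement, reversal), however,
holds for *any* input by construction, since the algorithm consumes
only counts.

The null false-positive experiment uses an 800-protein x 500-residue
proteome (~20,000 windows per central residue) and 1,000 replicates
(25 per central residue x 20 residues x 2 sample sizes {100, 10,000}),
a problem size chosen so the whole experiment completes in seconds
while sampling every stratum.  Two conservative mechanisms drive the
observed rate to zero: at n=100 the smallest significant count (18)
sits below the support threshold (20), and at n=10,000 drawing half the
pool without replacement leaves the hypergeometric spread well inside
the binomial test's assumed variance.

## Design decisions taken where the design was open

* **Test form**: one-sided exact binomial survival probability — the
  test of the Motif-X lineage and the only form consistent with the
  (k, n, p0) structure of per-position enrichment; evaluated by stable
  survival-function computation, never `1 − CDF` in floating point.
* **Bonferroni family size**: `w x (20 + #groups)` per scan.  Each
  recursion level re-tests a fresh subset, so the family is per-scan,
  not global.
* **Match-matrix null**: the expected probability of matching a motif
  is the product of its per-offset background frequencies (positional
  independence), the natural extension of the per-position test;
  position-specific frequencies by default.
* **Emission bookkeeping**: motifs are emitted only when pair-extension
  branches terminate; remainder branches scan on but emit nothing,
  preventing duplicate emission of a prefix.
* **Isoform-ambiguous accessions** resolve to the first exact match in
  the proteome index; unmapped sites are counted and reported.
* **Reduced-background minimum size**: none is imposed; a branch whose
  background empties terminates (with emission) rather than falling
  back to pooled frequencies, which would silently change the null
  mid-recursion.

## Limitations

* Motifs are fixed-width, gapless, and enrichment-only (no depleted
  residues, no variable spacing).
* The positional-independence null of the match matrix ignores residue
  covariation between offsets.
* Very deep fixation chains exhaust realistic backgrounds; branches
  then terminate with the pairs fixed so far.  This is inherent to
  recompiling an empirical background rather than assuming a factorized
  model.
* No mass-spectrometry search-engine parsing: inputs are pre-aligned
  windows, FASTA proteomes and generic site tables.
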