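# Methods

This note documents the statistical model behind chromlink, the meaning
and default of every tunable parameter, what the synthetic-data
generator does and does not emulate, and the numerical conventions. It
makes no empirical claims beyond what the test suite computes.

## Data model

An **interaction set** is a pair of equal-length anchor lists
(`anchor_one[i]`, `anchor_two[i]`), a positive integer supporting count
per pair, and optional per-pair metadata columns (typically `p_value`
and `fdr`). Anchors are genomic ranges in **1-based, fully closed**
coordinates; the BED family's 0-based half-open convention is converted
exactly once, at the I/O boundary. A pair is *cis* when both anchors
share a chromosome, *trans* otherwise.

Three distance conventions are provided for cis pairs (trans distance is
undefined and reported as `None`):

- `midpoint`: |mid₁ − mid₂| with mid = ⌊(start + end)/2⌋ — the default,
  robust to anchor width.
- `inner`: max(0, laterStart − earlierEnd) — the gap between anchors;
  0 when they touch or overlap.
- `outer`: laterEnd − earlierStart + 1 — the outer span, consistent with
  the closed-coordinate width convention (width = end − start + 1).

## Self-ligation threshold

In ChIA-PET, a fragment that circularises on itself yields a short-range
read pair whose two tags fall on opposite strands; true inter-fragment
contacts have no strand preference. Both estimators bin cis tag pairs by
midpoint distance (default `bin_width = 500` bp, `max_distance =
50 000` bp — comfortably above plausible fragment sizes) and scan the
bins from short to long, returning the left edge of the first bin whose
strand composition is statistically compatible with balance, confirmed
by `k_consecutive = 2` further compatible bins (a single quiet bin
inside the skewed region should not end the scan). If no such run
exists the estimators return `None` (`NO_THRESHOLD` on the CLI).

- **Binomial estimator**: per bin, an exact two-sided binomial test of
  n_same successes out of n_same + n_opposite trials against p = ½.
- **Strand-composition estimator**: the baseline same-strand fraction is
  taken from pairs at ≥ `baseline_min_distance = 100 000` bp (requiring
  `min_long_range = 100` such pairs, otherwise a precondition error);
  each bin is then compared to the baseline *sample* with Fisher's exact
  two-proportion test. Comparing two samples, rather than treating the
  baseline point estimate as exact, keeps the test honest when the
  long-range sample is small (a few hundred pairs, SE ≈ 0.03): a
  plug-in binomial test against the point estimate is anticonservative
  and rejects truly balanced bins. `test="binomial"` restores the
  plug-in behaviour for comparison.

Both estimators apply Benjamini–Hochberg correction across bins by
default (`bh_correct=True`). The scan asks ~100 bins the same question
at `alpha = 0.05`; without correction, false rejections in the balanced
region routinely push the estimate upward by several bins. BH controls
the false discovery rate across the scan while leaving the astronomically
small p-values of genuinely skewed bins untouched. Set
`bh_correct=False` for the uncorrected per-bin scan.

`alpha = 0.05` is the conventional level; the estimate is insensitive to
it within an order of magnitude because p-values in skewed bins are
< 1e-40 while balanced bins sit near 1.

## Tag-pair preprocessing and merging

Positional duplicates (identical end coordinates and strands, in either
end order) are collapsed to the first occurrence — the standard PCR
duplicate heuristic. Merging assigns each tag to the anchor containing
its midpoint (anchors must be non-overlapping, enforced); pairs with
both tags in the same anchor are tallied as self-pairs, pairs with an
unassigned tag as unassigned, and the rest accumulate counts on their
anchor pair.

## Annotation and summaries

Feature sets are named, ordered lists of ranges with ids. An anchor's
**node class** is the name of the *first* feature set (in the order
given) with any overlap, else `distal`; ids of *all* overlapping
features of every set are retained. The interaction-type label joins the
two node classes in priority order (distal last), so
`enhancer + promoter → promoter:enhancer` regardless of anchor order.

Per-feature summaries use **anchor-wise accumulation**: for each pair
and each anchor overlapping the feature, the pair's count is added to
the feature's total (a pair with both anchors in the same feature
contributes twice). Distinct partners are the other anchor's feature ids,
keyed by the other anchor's node class, excluding the feature itself;
classes with no distinct partner are omitted. Ranking sorts descending
by the requested column with ties broken by feature id for determinism.

Virtual-4C viewpoints select pairs with ≥ 1 anchor overlapping the
viewpoint region and deposit the partner signal into bins tiling the
window (last bin truncated). `midpoint` mode deposits each count once,
in the bin containing the partner midpoint, so the profile total equals
the total selected signal (conservation); `overlap` mode deposits the
full count into every bin the partner anchor overlaps (a coverage-style
view that intentionally double-counts across bin boundaries).

## Synthetic data generator

`chromlink.fixtures` draws everything from `numpy.random.default_rng(seed)`;
the same config reproduces byte-identical files.

Tag pairs are a two-component mixture (default `n_tag_pairs = 20 000`,
`self_fraction = 0.5`):

- self-ligation: distance ~ Uniform[0, `self_ligation_distance` = 5 000),
  opposite strands with probability `self_opposite_prob = 0.95`;
- inter-ligation: distance ~ truncated Pareto with tail index
  `inter_distance_alpha = 0.8` on [`1 000`, `2 000 000`] bp — a
  heavy-tailed contact-distance law — with strands uniform over the four
  configurations. With these defaults a library of 20 000 pairs yields a
  few hundred pairs beyond 100 kb, satisfying the strand-composition
  baseline precondition by construction.

Interactions place anchors uniformly (widths uniform in
`anchor_width_range = (1 000, 5 000)`), are trans with probability
`trans_fraction = 0.1`, and take supporting counts from a shifted
geometric distribution with `count_geom_p = 0.4` (support ≥ 1,
long-tailed like real PET counts). `p_value` is u³ for u ~ U(0,1)
(skewed toward small values) and `fdr = min(1, p·U(1,5))`. An optional
hub promoter receives `hub_extra_interactions` extra promoter:enhancer
pairs, recorded in the ground truth.

The generator emulates the gross statistical features of interaction
libraries — the short-range opposite-strand excess, a heavy-tailed
distance law, long-tailed counts — and nothing more: there are no TADs,
compartments, chromatin-state correlations, mappability or GC biases,
and p-values/FDRs are decorative noise, not test results.

## Numerical and determinism choices

- Exact binomial p-values come from `scipy.stats.binomtest`; the test
  suite checks them against an independent pmf tail summation (at
  p = ½ the two-sided region is the symmetric set |i − n/2| ≥ |k − n/2|)
  to relative error < 1e-10 over 1 000 random bins.
- Written BEDPE is sorted by (chrom₁, start₁, end₁, chrom₂, start₂,
  end₂), so write→read identity holds relative to that deterministic
  order; floats are serialised with `repr` for exact round trips.
- Figures suppress embedded timestamps and fix the SVG hash salt so
  repeated renders are byte-identical; every figure is backed by a plain
  data table computed before any drawing.
- CLI exit codes: 0 success, 1 I/O error, 2 format/usage error,
  3 method precondition not met.

## Problem sizes

Test and acceptance sizes (200 round-trip sets, 20 threshold replicates,
1 000 binomial bins, 50 annotation seeds × 1 000 pairs, 100 viewpoint
fixtures) are this package's own choices: large enough that stochastic
checks have negligible flake probability, small enough that the full
suite runs in well under a minute per module on one CPU.

## Limitations

- The threshold estimators assume a monotone decay of the self-ligation
  component; libraries with multimodal short-range structure may yield
  early thresholds.
- Annotation is overlap-based only; no distance-weighted or
  nearest-feature assignment.
- The generator's ground truth validates algorithmic correctness, not
  biological realism; recovery rates on synthetic data do not predict
  performance on real libraries.
- SAM/BAM import keeps primary, mapped, properly flagged pairs above a
  mapping-quality cutoff; it does not perform alignment-level repair.
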