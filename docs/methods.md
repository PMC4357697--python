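# Methods

This note documents the models, conventions, defaults and design choices
behind `minicleave`, in the order data flows through the pipeline.

## Cut geometry

A duplex segment is stored as its top strand (5′→3′); the bottom strand is
the exact reverse complement — the package models perfect duplexes only.
All coordinates are 1-based and residue-inclusive, and a scissile bond is
named by the residue immediately 5′ of it on the named strand, in that
strand's own numbering. Bottom-strand positions convert to reference
coordinates via `ref = L − pos + 1`.

With a signed overhang *v* (positive = 3′ overhang; Mini-III leaves +2),
the two cuts of one double-strand cleavage satisfy

```
b_bottom = L − i_top + v        (bottom-strand numbering)
v        = i_top + b_bottom − L
```

On the reference axis, the bottom strand is severed at reference bond
`i_top − v`, so the bottom fragment downstream of the cut exposes its new
3′ end at reference position `i_top − v + 1` — for v = 2, position
`i_top − 1`. That offset is the strand-pairing signature that site calling
exploits.

Primer-extension stops convert to bonds as `bond = stop − 1`: the strong
reverse-transcription termination marks the template's cleavage-generated
5′-terminal residue. The weaker band one residue further is attributed to
non-templated nucleotide addition by the reverse transcriptase and is
deliberately discarded.

## Site calling

End tracks hold per-strand counts of fragment 3′-end positions in
reference coordinates. A site at bond *i* is called iff the top track has
≥ `min_support` (default 1) ends at *i* and the bottom track ≥
`min_support` ends at `i − v + 1`; the site weight is the summed support.
Segment-terminal positions (top at L, bottom at 1) are excluded — in an
uncleaved control library essentially all ends sit there, so they are
library features, not cleavage evidence. The `terminus_fraction` statistic
(share of all end counts on the 2 × n_segments terminal positions) is the
library-level control: ≈ 0.93 for the emulated uncleaved control, ≪ 0.5
after digestion. No peak merging or statistical calling is attempted
beyond the pairing-and-threshold rule; adjacent sites are all reported.

Position-X interpretation: the bottom-strand end paired with a top end at
*i* is at reference position *i − 1* (for v = 2). The alternative
own-strand-numbering reading is inconsistent with the 14|15 / 18|19 worked
example and is rejected.

## Motif discovery

**Enrichment route.** Positives are windows of up to 14 nt centred on
called sites (7 nt each side of the bond, truncated and flagged at segment
ends), weighted by read support; the background is every 14-nt sliding
window of the genome. For a motif matching weighted count *k* of *K*
positives and *b* of *B* background windows, significance is the one-sided
hypergeometric tail `P(X ≥ k)` with population `N = K + B` containing
`n = k + b` matches — Fisher's exact enrichment. Tails are computed and
compared in natural-log space throughout (probability-scale values
underflow at sequencing depth); `hypergeom_tail` exposes the probability
scale and `hypergeom_log_tail` the log scale.

Seeds are all exact w-mers present in the positives, counted in forward
and reverse-complement orientation (a seed and its reverse complement are
one motif; the lexicographically smaller string represents it). The best
seeds (default 10–20) are generalized greedily: one base added to one
position per step, a step accepted only if the log tail strictly
improves. No position may be generalized to all four bases — an all-N
position carries no information, and keeping every position informative is
what lets the incremental width search detect when a width exceeds the
signal. Results are ranked by log p, ties broken by fewer degenerate
letters then lexicographically; each result also reports its *core*, the
heaviest exact word among the positives that the motif matches, which is
the concrete sequence a degenerate motif stands for. An E-value
(p × number of seeds tested) is reported for context; no multiple-testing
correction is applied because the output is a ranking.

**Width selection.** Discovery runs at widths 4, 5, … 14; per width the
best motif's *presence* (weighted fraction of positives matched) and
*diversity* (distinct exact words matching it) are recorded. The chosen
width is the largest consecutive width with presence ≥ τ_p × presence(4)
and diversity ≥ τ_d × diversity(previous width), τ_p = τ_d = 0.5 by
default. The thresholds operationalize "no dramatic drop"; the full trace
is always returned so the call can be inspected.

**EM route.** The top-200 unique 8-nt end-proximal reads (ties broken
lexicographically) are fit with a one-occurrence-per-sequence EM: each
sequence contains the motif exactly once at a uniform-prior start;
non-motif positions follow a uniform 0.25 background. The M-step adds a
pseudocount of 0.25 per base, so the monotone objective is the Dirichlet-
penalized log posterior, which is what the returned trace reports. One
restart is deterministic (initialized from the most frequent exact word at
0.7/0.1); four more use seeded random initializations; the best final
objective wins. Consensus rendering per PWM column: a single letter when
the top base reaches 0.5 and twice the runner-up; a two-base IUPAC code
when the top two jointly reach 0.8; otherwise N.

## Saturation-mutagenesis consensus

`design_saturation` produces the 42 single-substitution variants of a
14-nt window. `derive_consensus` requires the complete table; per position
the tolerated set is the wild type plus every base with relative rate ≥ θ
(default 0.5 — the tolerance cutoff is not a measured quantity, so θ is a
parameter and is echoed in output metadata), and the preferred base is the
rate argmax with the wild type at 1. Rendering lists the preferred base
first, then tolerated bases by descending rate, trims fully unconstrained
flanks and places `^` at the bond.

## Scanning and digestion

IUPAC motifs and PWMs are matched on both strands; a bottom-strand match
at bottom bond *b* is canonicalized to `i_top = L − b + v`. PWM scores are
summed log-odds against a uniform background; the default threshold is
80% of the maximal achievable score (pass an explicit threshold to
override; passing `None` is an error so a PWM scan is never silently
unthresholded). In-silico digestion treats sites as cut simultaneously
(complete digestion): k sites give k + 1 products, per-strand lengths sum
to the segment length, and a product's apparent gel size is the longer
strand's length — staggered ends migrate approximately with total span.
Banding tables list apparent sizes in gel order, dropping products below
`min_visible` (default 20 nt).

## Kinetics

Fraction cleaved is Σproducts / (substrate + Σproducts) from densitometric
band intensities (scale-invariant per lane). Initial rates are OLS slopes
of fraction vs time, with an intercept by default (gel backgrounds at
t = 0); a `through_origin` flag forces the line through zero. Slopes carry
standard errors and are normalized per unit enzyme; relative-rate tables
divide by a reference (which maps to exactly 1) and also report the
percentage reduction. Time courses with any fraction above 0.5 trigger a
warning that the linear initial-rate assumption may be bending. No
significance testing is attached to rate ratios.

## Synthetic data generator

The generator's defaults are the study conditions the rest of the package
is validated under:

* **Genome**: three linear dsRNA segments of 6374, 4063 and 2948 bp
  (the Φ6 bacteriophage L/M/S segments), uniform random sequence except at
  planted site windows.
* **Preference model**: a width-14 multiplier table anchored at the bond,
  encoding the (G/A/U)(A/U)CC^(U/A)(C/A/U)(G/A/U) consensus. The obligate
  CC core admits no substitution (multiplier 0); the core-adjacent A and U
  positions are strongly graded (preferred 1, tolerated 0.38 — the
  measured relative rate of a substituted-core substrate — disallowed
  0.05); the three-base flank positions are mildly graded (1 / 0.7 / 0.2).
  A site's score is the product of multipliers over its window; a bond
  with anything but CC at the core scores 0.
* **Planting**: 10 sites per segment by default (no site count is
  published; roughly one per 300–600 bp reproduces a complex-banding
  digest while leaving most of the genome as background), at least a
  window apart and clear of segment ends. Planted bases are drawn in
  proportion to their multipliers, so preferred bases dominate planted
  windows the way they dominate the measured logo. Ground truth contains
  every planted position plus every bond whose scanned score reaches 0.5 —
  chance consensus occurrences are reported as real sites because the
  simulated enzyme cannot tell them apart.
* **Digestion**: each bond is severed within time *t* with probability
  `1 − exp(−(k_s·score + k_ns)·t)` — the simplest memoryless first-order
  law, with independent sites. Defaults: k_s = 0.12 min⁻¹ (a score-1 site
  is ~70% cut in the 10-min digest — limited digestion, not completion),
  k_ns = 2×10⁻⁶ bond⁻¹ min⁻¹ (a fraction of a nonspecific cut per
  molecule), t = 10 min, 20 molecules per segment. Cuts are recorded, and
  the resulting per-strand intervals tile each molecule exactly.
* **End capture**: 3′ ends of all fragments are sampled multinomially to
  the expected depth (default 236,860, the size of a real uniquely-mapped
  library); a `background_break_fraction` share (default 0.07, matching an
  uncleaved control that keeps ~93% of its ends terminal) is instead drawn
  uniformly over positions and strands. No PCR-duplicate or sequencing-
  error model: the analysis weights by counts, so duplication modelling
  would add nothing testable.
* **Reads**: each sampled internal end also emits the reference-oriented
  8-mer centred on its implied bond. This is an idealization of mapped-read
  context: a physical one-sided read cannot span the bond (the cut
  splits ACC|U between the products), so the generator collapses the
  mapped location to its bond-centred genomic context in reference
  orientation, which is what the PWM/EM route consumes. Control mode skips
  digestion, leaving only terminal (plus background) ends.
* **Orientation**: sites are planted and scored on the top strand only.
  Reverse-complement behaviour of calling and discovery is exercised by
  property tests on transformed data rather than by the generator.

All randomness flows from the single config seed; identical configs give
identical outputs, including byte-identical files.

What passing tests on this generator do **not** show about real data:
alignment artifacts, PCR bias and duplicates, sequencing error, RT
drop-off, RNA secondary structure, bulged or mismatched duplexes, and any
deviation of real cleavage kinetics from the first-order independent-site
law are all outside the emulation.

## Problem sizes used in validation

The recovery panels run twenty (enrichment route) and ten (EM route)
independent simulations of a 3-kb segment with 20 planted sites, 4,000
sampled ends and 10% background breakage — ≥ 500 weighted site instances
per run, which is the regime where exact-core recovery is expected in
≥ 95% of runs. Monte-Carlo estimator checks use 10³ replicates (slope
recovery) and 3×10⁴ molecules (cut-rate ratios). These sizes keep the full
suite around a minute while leaving comfortable statistical margins.

## Known limitations

Perfect-duplex assumption throughout; no structured-substrate modelling
(the natural 23S pre-rRNA context is out of scope); complete-digestion
product prediction only (no partial-digest band mixtures); single-motif
discovery (no multiple motifs per run, gapped motifs or priors);
initial-rate kinetics only.
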