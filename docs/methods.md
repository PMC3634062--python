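# Methods

This note documents the statistical procedures implemented in `crossatlas`,
the synthetic-data model used to validate them, the defaults and why they
were chosen, and the known limitations.

## Detection and filtering

**RNA-Seq detection.** A gene is expressed in a tissue when the lower bound
of the two-sided t confidence interval (default 95%, df = n_rep − 1) on its
mean replicate FPKM exceeds zero, and expressed overall when that holds in
at least one tissue.  The interval is recomputed from replicate FPKMs
because the package consumes expression tables, not upstream quantifier
internals; a caller with a precomputed lower bound can apply it directly.
Constant positive replicates have SD = 0, so the bound equals the value and
any all-positive constant profile is detected; an all-zero profile never is
(the rule is strict).

**Microarray detection.** Mean intensity strictly above 200 in at least one
tissue (a `>=` variant is available; the strict form is the default because
that is the sharper reading of an "exceeding" rule).  Expression bins
partition [0, ∞): 0 → none, (0, 5] → low, (5, 200] → medium, (200, ∞) →
high, on the FPKM scale.

**Transforms.** Microarray intensities get log2 with values below 1 floored
to 1; RNA-Seq FPKM gets asinh(x) = ln(x + √(x²+1)), which compresses the
platform's larger dynamic range and behaves linearly below 1.  Double
transformation is refused via the units tag.  The stringent network filter
keeps genes with max tissue FPKM strictly above 5.

## Concordance

Replicate QC and cross-platform comparisons are Pearson correlations on
log2-floored values.  Tissue clustering is complete-linkage agglomeration on
the distance 1 − r between tissue columns, with deterministic tie-breaking
by the lexicographically smallest member label (the merge heights are
verified against SciPy's complete linkage in the tests; the hand-rolled
agglomeration exists only to pin down tie behavior).  Ordination summarizes
genes into k k-means clusters (fixed seed, 10 restarts) and then runs PCA on
the tissues × cluster-centroid matrix, centered (scaling optional), so
tissues are the ordinated observations.

## Tissue specificity and paralogs

Shannon entropy H = −Σ pₜ log₂ pₜ is computed on linear replicate-averaged
expression (the convention for this specificity measure; a log-scale flag
exists).  Genes not detected on a platform are excluded from that platform's
sample, all-zero profiles are excluded and recorded.  Platform samples are
compared on the shared gene universe by a Mann–Whitney U test (exact null
for combined n ≤ 20 without ties, tie-corrected normal approximation
otherwise), reporting which platform has the lower median entropy (= more
tissue-specific).

Paralog-pair correlations are Pearson r across tissues on the
platform-appropriate transformed values.  The null is r over uniformly
sampled unordered gene pairs (no self-pairs, no listed paralog pairs;
default 10× the pair count, minimum 100, seeded).  A pair is "highly
correlated" when r > null mean + 2 × null SD.

## Networks and expression conservation

Co-expression networks are all-pairs Pearson correlations of transformed,
replicate-collapsed gene profiles over tissues.  Edges are Fisher
z-transformed — atanh with |r| clamped to 1 − 1e−7 — then standardized to
mean 0 / SD 1 over the upper triangle (min–max rescaling is available
behind a flag).  Network similarity is the Pearson R between the two
upper-triangle edge vectors.  Dense storage caps the gene count at 5,000.

**Mixed-platform bootstrap.** Before mixing, every tissue column of each
transformed matrix is z-scored over genes, so a mixed profile is not
dominated by platform units; the observed pair is processed identically.
Per bootstrap replicate a fair coin per tissue assigns the platform-A
profile to pseudo-network 1 and the platform-B profile to pseudo-network 2,
or the swap.  The two pseudo-datasets are complementary by default — every
tissue contributes exactly one platform to each network — with independent
sampling behind a flag.  The null distribution of pseudo-network similarity
answers whether the observed single-platform similarity is platform-driven:
under exchangeability the observed value is one more draw from this null.

**EC scores.** EC(g) is the Pearson correlation between gene g's edge-weight
row in the two normalized networks, excluding the self-edge.  EC is
symmetric in the networks and undefined (reported missing) for constant
rows.

**EC significance.** For each bootstrap replicate the per-gene EC between
the two mixed pseudo-networks is recorded.  The default reference
distribution pools the null draws of all genes; the empirical one-sided
p-value is (1 + #{null ≤ observed}) / (#null + 1), flagged at α = 0.01
(one-sided low because divergence is loss of conservation; two-sided by
flag).  The pooled default is a deliberate design choice: with
complementary mixing a gene's own B draws include coin sequences
arbitrarily close to the pure split, so the per-gene p (available via
`pooled_null=False`) has an effective floor around B × P(|split| ≥ 15/18)
≈ 1.5 expected tail draws at B = 200 and cannot resolve below 0.01 even
for a gene whose profile one platform has completely destroyed.  Pooling
keeps the per-gene statistic but borrows the tail of the whole network,
which calibrates correctly under exchangeability (measured type-I error
≈ 0.01 at α = 0.01 across seeds) and gives usable power.

**Connectivity and classification.** Degree is the count of off-diagonal
normalized edges ≥ τ = 2.0 (≈ "2 SD" edges; inclusive).  A flagged gene is
`more_in_a` when degree_a ≥ 2 × degree_b + 5, symmetrically `more_in_b`,
else `similar`; the factor-2-plus-5 dominance rule and τ are package
conventions, exposed as options and recorded in output metadata.  Two
expression-defined clusters of divergent genes are reported: genes high on
both platforms with microarray mean at or above the 99th-percentile
saturation quantile, and genes with RNA-Seq median expression exactly zero.
Enrichment of flagged genes in an annotation set is an upper-tail
hypergeometric test; the low-expression diagnostic is a one-sided
Mann–Whitney test that a gene set's mean expression is below the rest of
the genome.

## Synthetic data model

Both platforms observe one latent log-expression surface
`latent[g, t] = baseline_g + loading_g · f_{m(g)}(t) + w_g · f_{m2(g)}(t) + ε`,
with per-gene baselines N(3, 1) on the natural-log FPKM scale, 20-gene
co-expression modules whose tissue factors are N(0, 1) — drawn once per
tissue group so grouped tissues co-cluster — a secondary-module loading
(weight uniform on [0, 0.6]) so within-module correlations stay below 1,
and N(0, 0.15²) gene × tissue noise.  The default tissue panel is 18
tissues: two coherent 3-tissue groups (leaf-like, seed-like) plus twelve
developmentally distinct singletons.  Grouping more tissues into fewer
blocks makes every profile low-rank and collapses the network geometry, so
the singleton-rich layout is both the more realistic reading of a
developmental panel and necessary for the co-expression statistics to have
reasonable effective dimension.  Transcript lengths are log-uniform on
[0.5, 5] kb.

**RNA-Seq.** Per replicate, counts are negative-binomial (dispersion 0.05)
with mean ∝ depth × exp(latent) × length, normalized per tissue; FPKM =
1e6 × count / (total counts × length in kb).  The length factor in the mean
cancels in FPKM — so the two platforms remain exchangeable in the
infinite-depth limit — while short transcripts receive fewer fragments and
hence noisier estimates, which is the reason lengths are modeled at all.
Default depth is 5 million single-end fragments per replicate, in the range
of the emulated study.

**Microarray.** intensity = min(ceiling, floor + scale · exp(latent) + Σ
bleed × scale · exp(partner latent)) × exp(N(0, 0.15²)) per replicate, with
floor 32, scale 400 and ceiling 2¹⁶ − 1 (the scanner word size; the true
ceiling of the emulated platform is not published).

**Planted artifacts**, recorded as ground truth (`divergent_genes`):

* *Saturation* (2% of genes): the whole latent profile is shifted so the
  top `n_saturated_tissues` (default all 18) tissues sit above the array
  ceiling; the array sees flat signal at the maximum measurable value while
  RNA-Seq tracks the full profile.  This emulates genes expressed outside
  the array's dynamic range.
* *Low counts* (7%): expected counts are a flat 0.1 fragments per replicate
  in every tissue — below the detection limit the capture rate is
  background-dominated — so most tissues yield zeros and the remaining
  singleton spikes carry no profile information.  The count-sampling
  mechanism is preserved (no post-hoc zeroing), reproducing the spurious
  correlations that arise among barely-detected genes.  A flat rate rather
  than a scaled copy of the true profile is used deliberately: scaled means
  concentrate the rare spikes in the gene's true top tissues, which leaves
  recoverable signal and defeats the purpose of the artifact.
* *Probe bleed* (4% of genes form paralog pairs, alternating mismatch
  classes): pair members are tissue-group-specific (contrast +2 natural-log
  units in a preferred group) with a moderate own baseline N(1.4, 0.4) so
  peaks stay inside the array range; the first member is the abundant copy
  (+1.4).  Probes 2–3 mismatches from the partner pick up 30% of its
  signal; 5+ mismatch probes are clean.  The quiet member of a
  cross-hybridizing pair whose partner prefers a different tissue group is
  the recovery target — bleed paints the partner's contrasting profile over
  its array signal, the mechanism behind spuriously correlated duplicates
  on arrays.

The low:saturation ratio (7%:2%) follows the qualitative structure of the
phenomenon being emulated, where divergence attributable to low expression
far outnumbers divergence at the saturation end.

`SyntheticConfig.exchangeable()` switches every artifact off (bleed 0, no
saturation or low-count depletion, negligible floor) for null-calibration
experiments.  One caveat discovered during design and retained as a
documented limitation: even with artifacts off, genes with FPKM ≪ 1 are not
platform-exchangeable, because asinh is linear below 1 while log2-floor is
not — a genuine transform mismatch, not a bug.  The default baseline
distribution therefore describes a well-expressed analysis set (as after
detection filtering); behavior for weakly expressed genes is exercised
through the explicit low-count artifact instead.

## What the synthetic tests do and do not show

Passing the validation battery shows the pipeline (i) controls type-I error
of the EC test under platform exchangeability, (ii) recovers strongly
planted saturation/low-count/bleed divergence with high sensitivity and a
low false-flag rate, (iii) reproduces the directional cross-platform
phenomena (the FPKM > 5 filter raises network similarity; array paralogs
clear the 2-SD rule more often than RNA-Seq ones when bleed is on; RNA-Seq
entropy is shifted toward specificity), and (iv) recovers planted tissue
structure by clustering and ordination.  It does not show performance on
real data with batch effects, probe-specific biases, isoform mixtures or
annotation error, none of which are simulated; nor does it calibrate the
absolute magnitudes of real cross-platform correlations, which depend on
the actual platforms.

## Problem sizes and numerical choices

Validation experiments use 500 genes × 18 tissues × 3 replicates with
B = 200 bootstrap replicates and ten generator seeds (the entropy contrast
uses 2,000 genes); these sizes give stable statistics for every property
tested while keeping the full battery to a couple of minutes.  atanh is
clamped at |r| = 1 − 1e−7; edge standardization uses the sample SD
(ddof = 1) of the upper triangle; column z-scoring uses the population SD.
Monte-Carlo p-values always carry the +1 correction.  K-means uses a fixed
seed with 10 restarts; dendrogram and ranking ties break lexicographically
so every output is reproducible bit-for-bit under a fixed seed.  All
randomness flows from one integer seed through named substreams.
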