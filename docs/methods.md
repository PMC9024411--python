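# Methods

This note documents the models, defaults and numerical choices behind
`lncmodnet`, what the synthetic generator does and does not emulate, and
the known limitations of each stage.

## The synthetic study generator

The generator emulates a 24-sample drug-treatment experiment in a neuronal
cell model: six groups of four replicates (DMSO, water, lamotrigine,
quetiapine, lithium, valproate), with each drug compared against its own
vehicle (DMSO for lamotrigine/quetiapine, water for lithium/valproate).

**Latent-factor model.** Each planted module *m* has a per-sample latent
eigengene u_m = z + s(group), with z ~ N(0, 1) i.i.d. across samples and
s(·) a fixed treatment pattern. A member gene's natural-log expression is
`baseline + loading · u_m + ε`, with ε ~ N(0, noise_sd²); baselines are
log-normal (median 100, log-sd 1). Counts are Poisson (negative binomial
with configurable dispersion as an option) around library-size-scaled
relative abundances, with libraries uniform on 8–12 million reads. All
randomness flows from one `numpy` Generator seeded by the config.

**Defaults and why.**

- *Five modules of 60 genes + 700 background genes; loadings uniform on
  0.6–0.9; one designated hub lncRNA per module at loading 0.95;
  noise_sd 1.0.* These are the study conditions every recovery and
  calibration test runs under.
- *Treatment patterns.* Every planted module carries a distinct response
  pattern: module 1 responds coherently (+) to all four drugs and module 2
  coherently (−) to three — these two are the planted *key* modules — while
  module 3 responds in only two contrasts and modules 4 and 5 with mixed
  signs, providing genuine negatives for the key-module rule. At these
  loading and noise levels a module with *no* treatment response carries a
  within-module correlation of only ~0.3, which at 24 samples is below the
  level any method can assign genes to reliably; giving each module an
  identifiable latent signature is what makes planted recovery a
  well-posed benchmark. The five patterns were chosen so that no pair of
  module signatures is positively correlated (anti-correlated pairs are
  separable by sign; positively correlated ones are not).
- *Shift magnitude δ = 6* latent standard deviations, from an a-priori
  power analysis: a shift δ on a unit-variance latent gives a
  point-biserial correlation δ/√(δ²+4) ≈ 0.95 in an 8-sample contrast,
  which keeps the adjusted-p < 0.05 coherence rule well powered across
  three-contrast patterns.
- *Minimax-centred group shifts.* The shift is split across the vehicle
  family so the drug-minus-vehicle difference is exactly δ while no group
  moves more than δ/2 from baseline. Piling the full shift on the drug arm
  either lets responsive modules swallow >90% of the sequencing library
  (breaking TMM's majority-unchanged assumption) or pushes the opposite
  arm into single-digit counts where Poisson noise dominates the log
  scale — and it corrupts the highest-loading (hub) genes first.
- *Weak global covariation*: every gene carries small loadings
  (sd 0.25) on five global latent factors, emulating the pervasive
  sample-level technical/biological covariation (library preparation,
  culture state) of real RNA-seq. Background genes still have zero loading
  on all module factors. Without this layer the connectivity histogram of
  the fixture is bimodal (tight modules vs. pure noise) and the
  scale-free fit index plateaus near 0.7 for every power; with it the
  fixture shows the smoothly decaying connectivity continuum of real
  data. The strength is set low enough that no sign-coherent global
  "following" reaches the minimum module size.
- *Hub designation.* Non-hub lncRNAs draw loadings from the lower third
  of the loading range (0.6–0.7), reflecting the generally lower
  expression and connectivity of lncRNAs and giving the designated hub a
  margin over its within-biotype competitors.
- *Toy genome*: three chromosomes, genes on a 250 kb TSS grid (so no
  unplanned pair falls within the 100 kb cis window), gene bodies of
  1 kb, random strands. Planted cis pairs are same-module lncRNA/coding
  pairs at controlled TSS distances including one at exactly 100 kb;
  planted TF-binding intervals sit inside the strand-aware −30/+10 kb
  promoter window of a same-module lncRNA, with decoys outside the window
  and one abutting its half-open edge.
- *Replicates* redraw latent factors, noise and library sizes under a new
  seed while keeping gene identities, baselines, loadings and the global
  covariation loadings — an independent dataset with the same module
  structure. The `scramble_module` mode permutes the (module, loading)
  assignments of one module's genes jointly with the background pool,
  producing a negative control whose original members lose their shared
  factor.

**What the generator does not emulate**: read-level artefacts (mapping,
GC/length bias), batch structure, realistic genome coordinates,
dropout-like zero inflation, and any dependence of dispersion on
expression level. Passing tests demonstrate that the implementation
recovers structure it is statistically entitled to recover — not that it
would perform identically on data with those additional features.

## Preprocessing

CPM filtering keeps a gene when CPM ≥ 1 in at least *n* samples, *n* the
smallest contrast group (4). TMM follows the classic recipe: reference
sample = the one whose upper-quartile CPM is nearest the mean upper
quartile; genes zero in either sample excluded; M-values doubly trimmed
(30% on M, 5% on mean abundance); inverse-delta-method-variance weights;
factors rescaled to geometric mean one. A sample pair whose M-values are
all numerically zero short-circuits to factor 1 to avoid trim artefacts
on technical replicates. log-CPM uses offsets of 0.5 (count) and 1.0
(effective library) for strict reproducibility of the zero case.

Differential expression is deliberately simple — a per-gene Welch t-test
on log-CPM per contrast with BH correction. It exists to annotate hub
genes, not to reproduce count-model inference; a negative-binomial GLM
would be the tool of choice for a real DE study. Zero-variance/equal-mean
cells get p = 1 by convention.

## Network construction and module detection

- Biweight midcorrelation with tuning constant 9 on the unscaled MAD,
  zero weight beyond |u| ≥ 1, Pearson-centring fallback for zero-MAD
  vectors, error on constant vectors. Note that with strong treatment
  effects the sample distribution per gene is bimodal and the biweight
  down-weights the minority arm; this is inherent to the estimator.
- Soft power: lowest power in 1..20 with signed scale-free R² ≥ 0.8
  (10 equal-width connectivity bins, log-log regression of bin frequency
  on bin mean, sign = −sign(slope)). If no power qualifies, the fallback
  takes the best-fitting power **at or above** the sample-size-based
  default for unsigned networks (8 at 20–30 samples): the low-power end
  of the fit curve measures the unthresholded correlation noise floor,
  and an argmax there can select a power at which the network is
  effectively unthresholded and no module is detectable.
- Unsigned adjacency |r|^β, TOM with unit diagonal, average-linkage
  clustering of 1 − TOM, static cut at absolute height 0.99 (capped at
  the 99th percentile of merge heights so a dendrogram that merges
  entirely below 0.99 still yields branches).
- **Branch refinement.** A static cut attaches background leaves to real
  branches and, in an unsigned network, fuses anti-correlated gene sets.
  Each candidate cluster is therefore refined by a single sign-coherent
  selection pass: compute the cluster eigengene (first principal
  component of the standardized members, oriented to positive mean
  correlation), keep members with signed kME ≥ 0.5, and recurse into the
  shed remainder so the anti-correlated half of a fused branch — or a
  second factor hidden behind the first — is recovered as its own module.
  A refined cluster is accepted only with ≥ 30 genes and an eigengene
  variance share ≥ 0.45. The selection pass is deliberately *not*
  iterated against re-estimated eigengenes: with hundreds of genes and 24
  samples, iterated re-selection provably drifts towards arbitrary noise
  directions and manufactures fake modules. The two thresholds are set
  from the null behaviour at n = 24 (kME sampling sd ≈ 0.21, so 0.5 is a
  ≈ 2.4σ bar; random same-size gene sets reach eigengene variance shares
  of ~0.1–0.3 depending on size, well under 0.45, while genuine planted
  modules score ≥ 0.6).
- Modules whose eigengene dissimilarity 1 − cor drops below 0.25 are
  merged iteratively to a fixed point; labels are renumbered by
  decreasing size with ties broken by smallest member id.

## Module preservation

Six statistics per module, all "higher = more preserved": density in the
test data (mean within-module adjacency, eigengene variance share, mean
own-module kME) and reference-vs-test connectivity correlations (kIM,
kME, within-module correlation entries). The permutation null draws
`n_perm = 100` random same-size gene sets uniformly from all genes; child
seeds derive from (seed, module label) so adding a module never perturbs
another module's null. Z = (obs − null mean)/null sd; Zdensity and
Zconnectivity are medians of their class; Zsummary is their mean;
statistics with zero null sd are excluded from the medians. medianRank is
the median across the six statistics of the module's rank (average ranks
on ties).

A note on calibration: in data with shared gene-level structure (modules,
global covariation), random gene sets themselves carry reproducible
connectivity, so the null means of the connectivity statistics are far
from zero and the connectivity Z of a uniform planted module can sit near
zero. Zsummary is then carried by the density class — which is exactly
the "is this set of genes densely connected in the test data" question —
and planted modules score ≈ 18–22 against a faithful replicate while
random sets stay within ±2 and a scrambled module drops to ≈ 0.

## Module-trait analysis

Each contrast contributes a binary trait over its own eight samples
(vehicle = 0, drug = 1); the module eigengene, defined over all 24
samples, is restricted to those eight for the Pearson correlation and
Student asymptotic p (t with n − 2 df; p = 0 at |r| = 1). Correlating
within the contrast rather than over all 24 samples is a deliberate
choice: each trait is a drug-versus-its-own-vehicle comparison and the
other 16 samples carry no information about it. BH runs over the full
module × contrast family. The key flag requires ≥ 3 significant contrasts
(adjusted p < 0.05) with a single sign; it is invariant to a global sign
flip of the eigengene.

## lncRNA-mRNA subnetworks and hubs

Module graphs keep pairs with ≥ 1 lncRNA endpoint and connection weight
≥ 0.15 (inclusive). The default weight is the absolute biweight
midcorrelation — the scale on which a fixed 0.15 threshold is meaningful
regardless of the selected soft power; TOM and adjacency weights are one
config switch away, with the caveat that at powers above ~10 the TOM
scale collapses below any fixed threshold. Hub ranking: raw degree, ties
broken by weighted degree then lexicographic id; hubs are reported per
module (intramodular hubs).

At the default study conditions the designated hub's loading margin
(0.95 vs. ≤ 0.7 among lncRNAs) translates into roughly 1.4σ of any
correlation-derived ranking statistic at 24 samples, so the planted hub
tops its module's ranking in only ~70% of module-seed trials — a sample
size limitation of hub identification itself, not of any particular
statistic; the test suite documents this with an intentionally strict
check.

## Genomic context

All coordinates are 0-based half-open (BED convention); TSS = start on
the + strand, end − 1 on the − strand. Cis: same chromosome and
|ΔTSS| ≤ 100 kb, boundary inclusive, distance signed (mRNA minus
lncRNA). The promoter window spans 30 kb upstream to 10 kb downstream of
the TSS in the lncRNA's orientation ([t−30000, t+10000) on +,
[t−9999, t+30001) on −, clipped at zero); binding intervals overlap it
under half-open semantics, so an interval ending exactly at the window
start does not count. TFs absent from the binding table are logged, not
errors.

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k) over the universe of
filter-surviving genes (a whole-annotation universe is a config option).
Map nodes are sets with raw p < 0.001 (q-values are reported alongside;
the node filter is deliberately on raw p). Edges require the combined
coefficient 0.5·Jaccard + 0.5·overlap ≥ 0.375, inclusive. Clusters are
connected components labelled by the most frequent underscore-token of
member set names (ties broken lexicographically) — a naming heuristic,
nothing more.

## Problem sizes

The default conditions used throughout tests and the acceptance script
are 1,000 genes × 24 samples, 100 preservation permutations and ten
seeds for power/recovery summaries; a full pipeline run takes a few
seconds on one core, and the entire test suite a couple of minutes.

## Known limitations

- The tree-cut/refinement combination is tuned for the regime the
  package targets (a few dozen to a few hundred samples' worth of
  structure in ~10³–10⁴ genes); it is not a general replacement for
  dynamic tree cutting on weakly modular data.
- The Welch-t DE stand-in ignores count dispersion structure.
- Preservation's reduced statistic battery (3 + 3) follows the composite
  Zsummary structure but omits several statistics of the full published
  battery (e.g. separability measures).
- Hub identification reliability is bounded by sample size, as above.
- The enrichment map treats gene sets as flat sets; no ontology topology
  or term-redundancy reduction beyond the similarity clustering.
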