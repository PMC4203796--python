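# Methods

This note documents the models, defaults and design decisions behind
`crossdev`, in the spirit of a statistical methods appendix. It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Expression model

Tag counts are modelled per sample as x ~ Poisson(N·λ) with library size
N and expression rate λ (tags per library-size unit). With the Jeffreys
prior Gamma(½, 0) the posterior is Gamma(x + ½, N); the prior keeps
zero-count samples finite (posterior mean ½/N) while adding less than
one pseudo-count of information.

A gene's profile is standardized by its *lowest sample*: the stage with
the smallest posterior-mean rate becomes the reference (ties go to the
earliest stage of the canonical grid), the point level at stage t is the
ratio of posterior means, and the 95% bounds are the 2.5%/97.5%
quantiles (linear interpolation on sorted draws) of the ratio
λₜ/λ_ref over 10,000 joint posterior draws by default. The
"lowest sample" is interpreted per gene, matching how per-gene fold
profiles are plotted; it is not a global library. The reference stage's
interval is the self-ratio, exactly [1, 1]. As a numerical safeguard the
Monte-Carlo quantiles are clamped to bracket the ratio-of-means point
estimate, which in extreme-skew corner cases they could otherwise miss
by a draw's width.

This conjugate, per-sample-independent formulation deliberately replaces
the multi-sample MCMC machinery of LOX-style estimators. The output
contract — relative levels standardized by the lowest sample, with
credible intervals — is the same, every quantity has a closed-form or
directly simulable check, and the frequentist coverage of the ratio
intervals is verified empirically (93–97% band at mean counts ≥ 20) by
the acceptance suite.

Genes with zero counts at every stage carry no information about shape;
they are flagged `uninformative` rather than reported as flat profiles
with wide intervals, and all downstream stages exclude them.

Per-gene reproducibility: every gene draws from its own RNG stream keyed
by (seed, species id, gene id), so results are invariant to the order in
which genes are processed and bit-identical across reruns.

## Ortholog triads

Similarity hits are read from BLAST outfmt-6-style tables, filtered at
e-value ≤ 10⁻⁴ (boundary inclusive), deduplicated per (query, subject)
keeping the best bitscore, and reduced to one best subject per query
(max bitscore, then min e-value, then lexicographic subject id — the tie
chain is fixed purely for determinism). A triad requires all three
pairwise links to be reciprocal best hits; RBH uniqueness guarantees
each gene joins at most one triad.

Phylogenetic family refinement (gene-tree construction and clade-based
completion) is intentionally not implemented; the RBH intersection is
the core of such methods, and a pre-computed triad table can be supplied
to bypass this stage entirely. Within-species hit tables are not
accepted; species namespaces are disjoint by construction.

## Clustering

The clustered object is the triads × (3 species × stages) matrix of
relative levels. Rows are z-scored (sample standard deviation, n−1);
constant rows are excluded with a warning because Pearson correlation is
undefined for them. Distance is 1 − r (not 1 − |r|: anti-correlated
trajectories are biologically opposite, not similar), giving d ∈ [0, 2].

UPGMA is implemented directly (Lance–Williams size-weighted update,
which for average linkage equals the unweighted mean over all
inter-cluster leaf pairs) rather than delegated to a library, because
the contract fixes a deterministic tie rule — merge the lowest
row-index pair among minimal distances — that library implementations do
not guarantee. The implementation is cross-checked in the tests against
scipy's average linkage and against a from-scratch leaf-pair-averaging
oracle. UPGMA is reducible, so merge heights are non-decreasing; the
k-cluster partition is obtained by discarding the k−1 highest merges
(k = 8 by default), with labels assigned in order of first row
occurrence.

## Enrichment

Overrepresentation of a category in a gene set uses the upper tail
P(X ≥ x) of Hypergeometric(M, K, n) via scipy's log-gamma-based survival
function, verified against exact rational enumeration. Hierarchical
dot-path categories roll up to ancestors by default (a gene annotated
"01.03.16" also counts under "01.03" and "01"). Genes without any
annotation are pooled under an `unclassified` pseudo-category, so the
per-set unclassified count is always part of the report. Benjamini–
Hochberg q values are added across all tests of one analysis with
significance defaulting to q < 0.05; raw p values are preserved. Inside
the pipeline the universe is the ortholog-triad set that survived
profile estimation — a configurable choice; a whole-genome universe can
be supplied instead.

## Candidate ranking

The per-stage, per-pair score is the conservative credible-interval gap:
zero when the two 95% intervals overlap, otherwise the lower bound of
the higher species minus the upper bound of the lower species. Ranking
uses the six post-crossing stages 2–144 h; `BC` is a pre-crossing
baseline and 120 h is excluded by default (the sampled-stage status of
120 h is ambiguous in the source protocols; a config flag or explicit
stage list re-includes it). Widening any interval can only shrink a gap,
so the screen is monotone-conservative by construction.

Per-gene aggregation over stages is the **maximum** gap ("the single
biggest confident change"); a summed-gap statistic is available via
`stat="sum"`. Qualification and combination follow two modes:

* `all-pairs` (library default): positive score in all three pairwise
  comparisons; combined score = minimum across the three.
* `focal`: positive score in the two comparisons involving a named focal
  species; combined score = minimum of those two. This is the screen for
  genes whose expression diverged specifically in the focal lineage.

Ties in the final ordering break lexicographically by triad id. If
fewer than M genes qualify, all are returned with a warning. The planted-
truth validation experiments run in `focal` mode: the generator plants
divergence in one focal species while the other two species share levels
exactly, so a planted gene's non-focal pair gap is ~0 by construction
and `all-pairs` qualification would reject every planted gene. The
screen is deterministic given the profiles; no statistical calibration
or FDR is applied to the candidate list (it is a conservative screen,
not a test).

## Synthetic data

The generator emulates the study design it is meant to stress: three
species, eight canonical stages, one pooled library per sample, and
single-copy triads for every gene.

* **Baseline rates**: log-normal, default median 10⁻⁵ per library-size
  unit with log-sd 1.0, giving a median of ~200 tags per sample at the
  default library size of 2×10⁷ (the order of a pooled lane).
* **Trajectories**: per-gene random walk on the log scale (step sd 0.4),
  shared by all three species.
* **Divergence**: a configurable fraction (default 130/2352 ≈ 5.5%) of
  genes gets its focal-species level multiplied by a fold change
  (log-uniform in [8, 16] by default) at a contiguous block of 2–4
  post-crossing stages; the two non-focal species keep the shared level
  exactly. Divergence on a stage *subset* is essential: a fold applied
  to every stage would cancel under lowest-sample standardization.
* **Archetype mode**: optionally, trajectories are drawn from k shared
  archetype walks (step sd 1.2) plus small per-gene jitter (sd 0.05).
  Archetypes are redrawn until mutually distinct (pairwise correlation
  of expression-scale shapes < 0.7) and until each spans 1.5–3 log units
  across stages: a flat archetype has no shape signal any
  correlation-based clustering could recover, and an extreme span pushes
  a gene's lowest stage below measurable depth, making its
  reference-standardized profile noise-dominated. These bounds make
  "planted archetypes" mean what the recovery experiments assume.
* **Counts**: Poisson with mean depth × rate — the pooled-library design
  leaves no replicate structure to estimate dispersion from, so pure
  Poisson is the honest default; a negative-binomial option
  (`nb_dispersion`) exists for sensitivity analyses.
* **Support files**: the true triad table; six directed hit tables in
  which true ortholog pairs carry mutual top bitscores, decoys score
  strictly lower, and optional above-cutoff decoys (e-value 10⁻³) score
  higher — exercising the e-value filter; and a FunCat-style annotation
  in which a marker category (88.01) is planted in divergent genes with
  probability 0.8 versus 0.02 background.
* **Seeding**: one master seed; every operation and species draws from a
  deterministically derived sub-stream, so identical (config, seed)
  yields byte-identical outputs.

What the generator does **not** emulate: read-level artifacts (mapping
bias, multi-mapping, positional coverage), replicate-level biological
variance, correlated gene programs beyond the archetypes, genuinely
missing orthologs, or annotation noise. Passing recovery tests therefore
demonstrates the correctness and calibration of the pipeline machinery
under its own model assumptions, not performance on real libraries.

## Validation problem sizes

The acceptance experiments use: the full-size screen at 2,352 triads
with a 14% divergent fraction (~330 planted genes, ≥ 300 qualifying) and
1,500 posterior draws; recall curves at 600 triads with 100 planted
genes per fold ∈ {1.5, 2, 4, 8}; archetype recovery at 400 triads,
narrow baseline spread (log-sd 0.3) and 2×10⁸-tag libraries so that
every stage of every gene is well measured (the separation ≫ noise
premise); interval coverage at 5,000 two-stage genes with mean counts
50–500 and 4,000 draws; 500 random matrices (n ≤ 8) for the UPGMA
oracle; every hypergeometric parameterization with M ≤ 12; 50-gene hit
tables for the exhaustive RBH cross-check; and a 500-triad end-to-end
run, twice, for manifest byte-identity.

## Reproducibility and the manifest

`run_pipeline` writes `manifest.txt` containing the seed, the flattened
configuration and the sha256 checksum of every artifact. Stage timings
are logged to the logging stream, not the manifest, so manifests are
byte-identical across reruns of the same (config, seed). Any stage
failure aborts with the stage name and cause.

## Known limitations

* The Gamma–Poisson layer treats samples independently; it does not
  share information across stages or genes as a hierarchical model
  would, so intervals at very low counts are wide (which the CI-gap
  screen converts into conservatism, not false positives).
* The CI-gap screen compares *relative* profiles; a uniform fold change
  across all stages is invisible by design.
* RBH triads miss families with recent duplications; this mirrors the
  single-copy-family restriction of the screen.
* The `unclassified` pseudo-category participates in BH adjustment like
  any category; its "enrichment" is reported for completeness, not
  interpretation.
* UPGMA at n triads costs O(n³) time in the worst case via repeated
  argmin scans; at a few thousand rows this is seconds, but the
  implementation is not meant for 10⁵-row matrices.
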