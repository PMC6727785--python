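# Methods

This note documents the models, parameters and numerical choices behind
`nktime`, and what the synthetic-data results do and do not establish.

## Germline filtering

A call is a germline event when its VAF lies in [0.45, 0.55]
(heterozygous) or above 0.90 (homozygous).  The windows are inclusive at
0.45/0.55 and strict at 0.90 — the boundary convention is ours, chosen so
the three labels partition [0, 1] exactly.  "Functional" means a scaled
deleteriousness score ≥ 15, the conventional screen for a CADD-style
scaled score; the threshold is a parameter everywhere it is used, not a
constant.  VAF is computed from the VCF `DP`/`AD` fields; multi-allelic
records are rejected rather than decomposed, and the variant→gene mapping
is read from the `GENE` annotation, never recomputed.  Gene collapsing is
an indicator (≥ 1 passing call), so duplicated calls cannot inflate
burden.  Optional depth filtering is deliberately absent: the minimal
dialect carries depth, and a user who needs a depth cut can pre-filter
calls.

## TIME subtyping

Samples are clustered on the immune-panel genes after log10(x+1):
agglomerative clustering, average linkage, 1 − Pearson correlation
distance, tree cut at k = 3 (`scipy.cluster.hierarchy`).  Average linkage
with correlation distance is the common choice for expression heatmaps;
both are flags (`--linkage`, `--metric`), as is k.  Clusters are named
rich / intermediate / poor by descending mean transformed panel
expression — an operational rule that makes the labels well-defined
whatever the dendrogram looks like.  Clustering is deterministic: there
is no random initialization anywhere in the stage.

Signature genes are the NK-cytotoxicity and Wnt pathway genes that differ
between rich and intermediate+poor tumors (two-sided Welch t on
log10(x+1), BH within the pathway-gene family, q ≤ 0.05).  Transfer to an
external cohort restricts both matrices to the signature, z-scores each
gene within its own cohort (a deliberately simple cross-platform
harmonization), and takes a majority vote of the k = 5 nearest reference
neighbors under 1 − Pearson correlation, with ties resolved to
intermediate/poor (the conservative call for a therapy-response setting).

## TIL scoring

Abundance of each TIL type is the single-sample rank-based enrichment of
its marker set: rank genes by expression (average ranks on ties), walk
them in descending order, and accumulate the difference between the
weighted in-set cumulative fraction (weights rank^α, α = 0.25) and the
uniform out-of-set fraction.  Scores are invariant to any strictly
increasing transform of a sample's expression vector, comparable across
samples within a cell type but not across cell types, and are not
absolute fractions.  The scoring function is pluggable (`score_fn`), and
min–max normalization to [0, 1] per cell type is a flag.

## NKD-gene discovery

Per gene: 2×2 table of functional mutation × (rich vs
intermediate+poor), χ² without continuity correction, switching to
Fisher's exact test when any expected count is below 5 (the switch is
recorded per gene in the report).  q-values are BH over the family of
genes actually tested in the call.  Genes with no mutations at all get
the p = 1 convention with direction 0.  The expression filter drops a
candidate only when it is expressed significantly *higher* in TIME-rich
tumors (one-sided Welch t, BH within the candidate family, q ≤ 0.05) —
the direction is implemented as stated in the source analysis even
though one might expect NK markers to be rich-high; the opposite
direction can be obtained by swapping the strata labels.  ITAM-signaling
genes passing the same mutation test are merged in with per-gene
provenance; a gene in both sets is reported once as `nk_specific`.

## Association statistics

*Survival.*  The log-rank test is built from explicit risk tables: at
each distinct event time the observed events and the hypergeometric
expectation and variance are accumulated; χ² = (O₁ − E₁)²/V with 1 df.
The hazard ratio is the O/E (Pike) estimate (O₁/E₁)/(O₂/E₂) with a
log-scale CI from variance 1/E₁ + 1/E₂ — chosen because it derives from
quantities the log-rank test already computes; it is reported as
"HR (O/E)" and is *not* a Cox estimate (the O/E estimator is known to be
slightly anti-conservative for strong effects).  Kaplan–Meier curves are
the product-limit estimates; both are cross-checked against `lifelines`
in the test suite but computed independently.

*Groups.*  High/low burden groups are the top/bottom 30% after sorting
by burden with ties broken by sample id (the tie policy is logged via a
warning when burden is constant).  The ligand analysis takes the
bottom-10% (and separately top-10%) burden samples, scores each by mean
log10(x+1) ligand expression, median-splits into high/low ligand groups
(sizes differ by ≤ 1), and Welch-tests each TIL type between them.

*Case–control and per-gene enrichment.*  Same 2×2 machinery as
discovery; odds ratios use the Haldane–Anscombe 0.5 correction when any
cell is zero.  Two-sided Fisher p-values follow the probability-mass
convention (sum of tables with point probability ≤ observed).

*Randomization test.*  The observed statistic — by default the mean over
cell types of Pearson r(burden of the candidate set, TIL score); a
top/bottom-30% log-rank χ² variant is selectable — is compared with the
same statistic for `n_perm` equally sized gene sets drawn uniformly
without replacement from the universe.  The empirical p uses the +1
convention, (1 + #{null at least as extreme})/(1 + n_perm), so it is
never 0 and never exceeds 1.

*Multiple testing.*  BH step-up (via statsmodels) at q ≤ 0.05
throughout; the family is always the set of hypotheses tested in the
call, not the genome.

## The synthetic cohort generator

The generator plants the structure the analysis assumes; its defaults
are the study conditions for all tests.

* **Subtypes**: drawn with probabilities (0.254, 0.329, 0.417) — the
  reported mean prevalences of the rich/intermediate/poor subtypes.
* **Burden**: a designated 25-gene NKD subset of the 157-gene
  NK-specific set; per-patient count ~ Poisson with mean (0.3, 1.7, 2.7)
  by subtype.  These rates put ≥ 1 defective gene in ~72% of patients
  (matching the reported ">60%") and give per-gene mutation-frequency
  contrasts detectable after FDR at cohorts of several hundred to a
  thousand patients — the scale of a per-cancer cohort.  The remaining
  132 NK-specific genes mutate at a subtype-independent background rate
  (Poisson mean 0.4 per patient), so false-discovery behavior is
  measurable.  Two ITAM genes are planted defective at rates
  (0.02, 0.12, 0.12).
* **Variants**: depth ~ Poisson(60); heterozygous alt counts
  Binomial(depth, 0.5) conditioned into the [0.45, 0.55] VAF window
  (10% homozygous, Binomial(depth, 0.98) conditioned above 0.90) — the
  conditioning keeps the emitted truth exactly recoverable by the
  filter; deleteriousness ~ U(15, 40).  Noise variants carry benign
  scores U(0, 10) and somatic-like VAFs (Beta(2, 8), resampled out of
  the germline windows), so the filter has something to reject on both
  axes.
* **TIL abundance**: per cell type,
  clip(mean_subtype − 0.05·burden + ligand effect + N(0, 0.08), 0, 1)
  with subtype means (0.75, 0.50, 0.30).  A standard-normal per-sample
  ligand latent scales ligand-gene expression (log-scale 0.8 per unit)
  and boosts abundance with weight 0.08·exp(−burden): ligands recruit
  TILs only while the activating receptors are intact, which is exactly
  the contrast the ligand-stratification analysis measures (an effect in
  the bottom burden tail, none in the top).
* **Expression**: lognormal with per-gene baseline means (log-scale
  spread 1.0, hash-derived per gene) and within-gene noise sdlog 0.5.
  Immune-panel and NK-cytotoxicity genes respond to the subtype's immune
  level with a per-gene log effect U(0.7, 2.3) and a per-gene response
  shape (early/linear/late activation: the intermediate subtype sits at
  0.15, 0.5 or 0.85 of the full effect), keeping per-gene means strictly
  ordered rich > intermediate > poor while giving the three subtypes
  distinguishable correlation structure.  Wnt genes respond in the
  reverse direction (immune-excluded phenotype).  Marker genes scale as
  exp(2.2 · abundance).  Two design points matter and were found the
  hard way: (i) if all panel genes share one response profile the
  subtype centroids are collinear in log space and
  correlation-distance clustering cannot separate them — the response
  shapes break the collinearity; (ii) without per-gene baseline spread
  the lowest subtype has no internal correlation and average linkage
  chains.  Both properties (baseline spread, response heterogeneity) are
  generic features of real expression data, not tuning tricks.  Gene
  effects derive from a hash of the gene id, not the cohort seed, so
  independently simulated cohorts (reference and trial) share the same
  expression geometry — necessary for transfer learning to be testable.
* **Survival**: exponential with hazard (1/1500 days)·exp(0.17·burden),
  censored by an independent U(0, 3650 days) time.  0.17 per gene sizes
  the top-vs-bottom-30% contrast near the reported hazard ratio of
  ~1.77 under the default burden spread.
* **Control cohort**: the subtype-averaged mutation process with all
  rates × `control_rate_factor` (default 0.25); no expression/survival.
* **Trial cohort**: same expression process; response ~ Bernoulli(0.6)
  for rich, Bernoulli(0.12) otherwise, so responders are enriched in the
  rich subtype at roughly the reported strength.

**What the generator does not emulate**: sequence-level realism (no real
loci, linkage, or mutational signatures), batch effects and platform
differences beyond a global per-cohort z-score, cancer-type
heterogeneity (one cohort = one cancer type), virus-infected tumors,
competing risks, and correlated marker sets across cell types.  Passing
tests therefore demonstrate that the *statistical machinery* recovers
planted effects of realistic size — not that the biological findings
replicate on real cohorts.

## Problem sizes

The test suite and the acceptance script run the chain at the scale of
one per-cancer cohort: 500–2000 patients, a 6000-gene universe, 20-seed
replications for power statements, 200–500 permutations for the
randomization null.  These sizes give Monte-Carlo error comfortably
below every margin asserted.

## Known limitations

* The ssGSEA-style score stands in for the cited deconvolution method;
  scores are relative, and cross-cell-type comparisons are meaningless
  by design.
* The O/E hazard ratio is not a Cox estimate; with heavy censoring or
  strong effects it drifts away from the true rate ratio.
* The expression filter's direction (drop rich-high genes) is
  implemented as stated in the source analysis; its biological rationale
  is debatable.
* k = 3 subtypes, k = 5 neighbors, α = 0.25, and the q ≤ 0.05 level are
  defaults with flags, not claims of optimality.
* Multi-allelic sites, indels vs SNVs, and annotation quality are out of
  scope: the filter trusts its input annotations.
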