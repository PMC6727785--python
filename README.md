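# nktime

Germline variant burden in natural-killer (NK) cell genes and the tumor
immune microenvironment (TIME): a reusable, testable analysis pipeline.

## The scientific problem

NK cells are the innate immune system's first line of defense against
tumors; their activating and inhibitory receptors are germline-encoded.
Inherited functional variants in NK-cell genes ("NK-deficiency" or NKD
genes) may therefore shape how strongly a tumor is infiltrated by immune
cells — and, through that, prognosis and immunotherapy response.
`nktime` implements the inference chain that links these quantities for a
cohort with paired germline variant calls and tumor RNA-seq:

1. **Germline filtering.** A variant is a functional germline event when
   its variant allele fraction (VAF = alt reads / depth) falls in the
   heterozygous window [0.45, 0.55] or the homozygous window (0.90, 1.0],
   and its scaled deleteriousness score (CADD-style) is ≥ 15.  Calls
   collapse to a binary gene × sample matrix; the **burden** of a sample
   is its count of mutated genes within a gene set.
2. **TIME subtypes.** Tumors are clustered on a 1294-gene immune panel
   (log10(x+1), average linkage, 1 − Pearson correlation distance, tree
   cut at k = 3) into *rich* / *intermediate* / *poor* subtypes, named by
   descending mean panel expression.
3. **TIL deconvolution.** Per-sample abundance of each tumor-infiltrating
   lymphocyte (TIL) type is scored from its marker set by single-sample
   rank-based enrichment (ssGSEA, weight rank^0.25):
   score = Σ_i [P_in(i) − P_out(i)] over the descending expression
   ranking.
4. **NKD-gene discovery.** Per gene, a 2×2 test of mutation frequency
   (rich vs intermediate+poor; χ² without continuity correction, Fisher
   exact when an expected count < 5; Benjamini–Hochberg FDR), followed by
   an expression filter that removes genes expressed significantly higher
   in TIME-rich tumors; significantly defective ITAM-signaling genes can
   be merged in.
5. **Associations.** Top/bottom-30% burden groups compared by the
   Mantel–Cox log-rank test with the O/E (Pike) hazard-ratio estimate
   (O₁/E₁)/(O₂/E₂) and Kaplan–Meier curves; burden–TIL Pearson
   correlations; ligand stratification of the burden tails; case–control
   mutation comparison; a seeded randomization (permutation-null) test of
   whether an equally predictive gene set arises by chance; and
   hypergeometric pathway over-representation.
6. **Cohort transfer.** Differential NK-cytotoxicity / Wnt pathway genes
   form a signature used by a correlation-distance kNN vote (per-cohort
   z-scoring) to assign external trial tumors to
   {rich, intermediate/poor}, e.g. to relate subtype to immunotherapy
   response.

Because the cohorts this kind of study uses are access-restricted, the
package ships a **synthetic-cohort generator** that plants the assumed
statistical structure (subtype prevalences, graded immune programs,
burden-dependent TIL abundance and survival, a lower-burden control
cohort, a response-enriched trial cohort) with full ground truth, so
every stage is verifiable end to end.

## Worked example

Run the whole chain on a simulated 600-patient cohort:

```bash
nktime run-all --n-samples 600 --seed 1 --out-dir demo
```

This writes 27 files (inputs, per-stage reports, and a `manifest.json`
that makes the run reproducible).  Highlights from this exact run:

* `nkd_genes.tsv` — 21 candidate NKD genes (19 NK-specific + 2 ITAM).
* `survival.json` — high- vs low-burden groups (180 vs 180 patients):
  observed/expected events 148/120.7 vs 120/147.3, log-rank χ² = 11.39,
  p = 7.4 × 10⁻⁴, HR (O/E) = 1.51 (95% CI 1.18–1.91): more defective NK
  genes, shorter survival.
* `correlation.tsv` — burden vs TIL score, Pearson r from −0.61 (NK) to
  −0.68 (γδ T), all p < 10⁻⁶⁰: burden anti-correlates with infiltration.
* `randomization.json` — observed mean burden–TIL r = −0.654 vs
  permutation null mean −0.252; empirical p = 0.005 at 200 permutations:
  the discovered set is not a chance artifact.
* `trial_response.json` — of 25 trial responders, 17 (68%) were assigned
  to the TIME-rich subtype (Fisher p = 2.8 × 10⁻⁸).

Each stage is also available separately (`nktime simulate`, `filter`,
`subtype`, `deconv`) and as library functions (`nktime.discovery`,
`nktime.stats`, ...).

## Layout

```
src/nktime/
  gene_sets.py   GMT/expression/clinical IO, fixture gene universe
  simulate.py    synthetic cohorts with planted ground truth
  germline.py    VAF + deleteriousness filtering, mutation matrix, burden
  subtypes.py    TIME clustering, signature genes, kNN transfer
  til.py         ssGSEA-style TIL scoring
  discovery.py   NKD-gene discovery
  stats.py       survival, correlation, Fisher, case-control,
                 randomization, enrichment
  pipeline.py    end-to-end orchestration + manifest
  cli.py         click command-line interface
docs/methods.md  model, parameters, numerical choices, limitations
```
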