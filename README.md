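# caremod

Analysis toolkit for studies of intracellular Ca²⁺ remodeling in
cancer cells and its pharmacological reversal — built around the
comparison of normal (NCM460) and colorectal-cancer (HT29) colonic
cells with and without the polyamine-synthesis inhibitor DFMO, and
fully exercisable on synthetic data with known ground truth.

It is aimed at researchers who combine single-cell calcium imaging
with transcriptomics and need the statistics layer to be reproducible
and testable:

* **Calcium traces → features.** Fura-2 F340/F380 recordings under the
  three-phase CPA protocol (baseline, store release in Ca²⁺-free
  medium, Ca²⁺ re-addition / SOCE) are summarised per cell as the
  resting level (median of the first 30 s) and the baseline-subtracted
  Δmax and trapezoidal AUC of the release and SOCE responses.
* **Hierarchical condition comparison.** Cells nest in coverslips and
  days, so features are fitted by REML linear mixed models
  `g(y) ~ line * treatment + (1|day) + (1|coverslip:day)` with
  profile-likelihood Box–Cox selection of `g`, information-criterion
  choice of the random structure, residual diagnostics, and a
  parametric bootstrap. Conditions are compared with Tukey-adjusted
  pairwise contrasts and summarised as a compact letter display: an
  edge joins conditions with adjusted p ≥ α, all maximal cliques are
  enumerated (Bron–Kerbosch with pivoting), and cliques become letters
  — conditions share a letter iff they are not distinguishable.
* **Differential expression.** Summarised log2 matrices are quantile-
  normalised, IQR-filtered (with an override retaining the 89-gene
  Ca²⁺-transport panel), fitted gene-wise with
  `log2 expr ~ line + treatment + line:treatment + day`, moderated by
  empirical Bayes (posterior variance `(d₀s₀² + d·s²_g)/(d₀+d)`,
  moderated t with `d₀+d` df), and adjusted by Benjamini–Hochberg.
* **Concordance and reversal.** Two platforms' (q, logFC) pairs are
  combined: DE iff one platform has q < 0.05 or both have q < 0.10,
  with concordant signs required. A gene is *reversed* when its
  cancer-vs-normal change and its (significant) treatment response in
  cancer cells point in opposite directions.
* **QC and qPCR.** Sample-level PCA with PC70% retention, robust
  within-class Mahalanobis outliers (MCD), Ward clustering, RLE
  summaries; and Livak ΔΔCt relative quantification (log2 fold =
  −ΔΔCt) with Bonferroni-corrected t-tests.
* **Synthetic data.** Generators for traces, paired-platform
  expression matrices and Ct tables reproduce the study design (4
  days × 2 coverslips × 4 conditions; 16-sample 2×2×day expression
  layout; triplicate qPCR) and return their ground truth.

## Worked example

```sh
caremod all --seed 7 --out report.json
```

runs the full chain (simulate → extract → mixed fits → letters;
simulate → QC → DE ×2 platforms → concordance → reversal →
selectivity; simulate → ΔΔCt) and prints:

```
letters: {'resting': {'NCM460:control': 'ab', 'NCM460:DFMO': 'a', 'HT29:control': 'c', 'HT29:DFMO': 'b'},
          'store_dmax': {'NCM460:control': 'c', 'NCM460:DFMO': 'b', 'HT29:control': 'a', 'HT29:DFMO': 'b'},
          'store_auc': {'NCM460:control': 'c', 'NCM460:DFMO': 'b', 'HT29:control': 'a', 'HT29:DFMO': 'b'},
          'soce_dmax': {'NCM460:control': 'a', 'NCM460:DFMO': 'a', 'HT29:control': 'c', 'HT29:DFMO': 'b'},
          'soce_auc': {'NCM460:control': 'a', 'NCM460:DFMO': 'a', 'HT29:control': 'c', 'HT29:DFMO': 'b'}}
selectivity: {'treatment_affected_normal': 0, 'treatment_affected_cancer': 315,
              'treatment_affected_normal_panel': 0, 'treatment_affected_cancer_panel': 17,
              'reversed_total': 55, 'reversed_panel': 12}
```

Reading the SOCE letters: both NCM460 conditions share `a`
(indistinguishable), untreated HT29 sits alone in `c` (highest SOCE),
and DFMO-treated HT29 forms its own intermediate group `b` — the
treatment pulled the cancer line toward, but not onto, the normal
phenotype. The selectivity block shows the planted cancer-selective
treatment effect: hundreds of genes respond in HT29, none in NCM460,
with 17 responders inside the Ca²⁺-transport panel.

The same steps are available piecewise (`caremod simulate calcium`,
`caremod calcium`, `caremod stats`, `caremod de`, `caremod concord`,
`caremod reversal`, `caremod qpcr`, `caremod qc`) over plain
CSV/TSV/JSON files, and as library functions in `caremod.*`.

## Layout

```
src/caremod/
  simulate.py   trace / expression / qPCR generators (+ feature-level MC generator)
  features.py   protocol windows, resting / Δmax / AUC extraction
  mixed.py      Box–Cox, REML mixed fits, structure selection, diagnostics, bootstrap
  grouping.py   Tukey contrasts, similarity graph, Bron–Kerbosch, letters
  diffexpr.py   quantile normalisation, IQR filter, gene-wise OLS, eBayes, BH
  reversal.py   cross-platform concordance, reversal calls, selectivity
  qc.py         PCA/PC70%, MCD outliers, Ward clustering, RLE
  qpcr.py       ΔCt / ΔΔCt, Bonferroni t-tests
  panel.py      the 89-gene Ca²⁺-transport panel (six categories)
  pipeline.py   end-to-end orchestration;  cli.py  the `caremod` command
docs/methods.md model assumptions, defaults, numerical choices, limitations
```
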