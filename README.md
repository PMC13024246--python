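# lipidlens

Analysis toolkit for targeted plasma lipidomics case-control studies, built
around the design of choline-centric panels (Biocrates p180-style): ~124
lipid species in five classes — phosphatidylcholines (PC),
lysophosphatidylcholines (LPC), sphingomyelins (SM), ether-linked
phosphatidylcholines (PC O-) and acylcarnitines (CAR) — quantified in a few
dozen plasma samples split into a case group (e.g. newly diagnosed,
treatment-naive leukemia patients) and healthy controls.

It is aimed at analysts who receive a wide concentration table (samples x
species, names in LIPID MAPS shorthand) plus a sample/group table and want a
reproducible path from raw names to biological statements:

1. **Nomenclature** — parse shorthand names (`"SM 18:1;O2/26:0"`,
   `"PC O-34:2"`, dialects such as a Unicode minus or `";2.0"` for `;O2`)
   into acyl-chain structures; derive LIPID MAPS taxonomy codes (GP0101,
   GP0102, SP0301, ...), species-level Total FA composites (cumulative
   carbons : double bonds ; oxygens over all esterified chains), saturation
   classes, and qualitative membrane-biophysics labels (bilayer thickness,
   lateral diffusion, intrinsic curvature, function, cellular component)
   from a packaged, versioned rule table.
2. **Synthetic cohorts** — a log-normal generator that emulates the study
   design (30 cases vs 11 controls by default): per species j and sample i,
   log2 x_ij = b_j + d_j·1[case] + e_ij with e_ij ~ N(0, s²). Every
   downstream stage is testable without any data download.
3. **Differential abundance** — two-sided Wilcoxon–Mann–Whitney tests with
   Benjamini–Hochberg correction per annotation level (species, class,
   Total FA, saturation, biophysics strata, ...); effect sizes as pseudo
   fold changes log2((med_case + eps)/(med_control + eps)); significance =
   adjusted p < alpha AND fold-change magnitude > threshold. Plus PCA on
   standardized log abundances and hierarchical clustering.
4. **Stability selection** — Boruta-style shadow-attribute selection:
   features must beat the maximum importance of freshly permuted shadow
   copies, decided by a Bonferroni-adjusted binomial test on hit counts;
   wrapped in a two-condition protocol (R1 runs on stratified 70%
   subsamples, R2 runs on the full data; stable = confirmed in >50% of
   runs in both), ranked by medianImp with Ratio_to_ShadowMax/Mean
   signal-to-noise diagnostics. The default importance backend is a fast
   vectorized random-ferns out-of-bag permutation importance.
5. **ROC screening** — AUC as the normalized Mann–Whitney U with DeLong 95%
   confidence intervals, Youden-J-optimal thresholds, and strict screening
   gates (AUC > 0.80, sensitivity > 0.70, specificity > 0.80).
6. **Gene–lipid networks** — map significant species to lipid-metabolism
   genes (CPT2, LPCAT1-4, SMPD3, ENPP6, ...) through a packaged selector
   table, drop uninformative generic nodes, and build a bipartite graph
   with degree-centrality node sizing and Kamada–Kawai coordinates.

## Worked example

```python
from lipidlens.cohort import CohortDesign, cll_like_effects, generate
from lipidlens.diffabund import de_by_level
from lipidlens.nomenclature import annotate_table
from lipidlens.rocscreen import evaluate_feature

table = generate(CohortDesign(seed=7), cll_like_effects())
annot = annotate_table(table.species)
print(de_by_level(table, annot, "class")[
    ["feature_id", "log2fc", "p_value", "adj_p", "significant"]
].round(4).to_string(index=False))

report = evaluate_feature(
    "CAR 12:0",
    table.group_values("CAR 12:0", "case"),
    table.group_values("CAR 12:0", "control"),
)
print(f"CAR 12:0: AUC={report.auc:.3f} [{report.ci_low:.3f}, {report.ci_high:.3f}]")
```

prints

```
feature_id  log2fc  p_value  adj_p  significant
     PC O-  0.5354   0.0000 0.0000         True
       LPC  0.2869   0.0000 0.0000         True
       CAR  0.2078   0.0193 0.0242         True
        PC  0.1468   0.0193 0.0242         True
        SM  0.1834   0.2220 0.2220        False
CAR 12:0: AUC=0.988 [0.965, 1.000]
```

The generator implanted enrichment across all five classes (strongest on
ether lipids and lyso species at the class level in this draw) and a +2
log2 shift on CAR 12:0; class-level aggregation recovers the enrichment,
and the implanted acylcarnitine is an essentially perfect single-species
discriminator (AUC 0.988 with the DeLong interval well above the 0.80
screening gate).

The same stages are available from the shell:

```bash
lipidlens simulate --effects cll-like --seed 7 --out cohort/
lipidlens de --abundance cohort/abundance.csv --metadata cohort/metadata.csv \
    --levels species,class,total_fa --out de/
lipidlens select --abundance cohort/abundance.csv --metadata cohort/metadata.csv \
    --r1 100 --r2 100 --seed 11 --out select/
lipidlens run-all --abundance cohort/abundance.csv --metadata cohort/metadata.csv \
    --seed 7 --out results/
```

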