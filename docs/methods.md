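# Methods

This note records the models, conventions and numerical choices behind
`lipidlens`, and what the synthetic-data tests do and do not establish.

## Lipid nomenclature and annotation

The parser covers the five classes a choline-centric targeted panel
quantifies (CAR, PC, PC O-, LPC, SM) in LIPID MAPS shorthand. Species-level
names ("PC 36:0") are stored as one aggregate chain; molecular-species
names ("SM 18:1;O2/26:0") resolve per chain. No chain split is ever
invented for sum compositions: the kits report sums, and fabricating sn
assignments would add information the measurement does not contain. Two
dialects are normalised on input and logged: the Unicode minus in
"PC O−..." and a bare numeric oxygen suffix (";2.0" is read as ";O2"; the
token appears in practice and matches no LIPID MAPS production). The ";O"
suffix is stored generically as an oxygen-modifier count without asserting
hydroxyl regiochemistry, which shorthand at this resolution cannot support.

Taxonomy is a closed deterministic map: CAR -> FA/FA07/FA0707 (acyl
carnitines), PC -> GP/GP01/GP0101, PC O- -> GP/GP01/GP0102, LPC ->
GP/GP01/GP0105 (monoacyl-GPC), SM -> SP/SP03/SP0301. Total FA sums
carbons, double bonds and oxygen modifiers over all esterified chains and
formats as "C:DB" with ";O<k>" appended when oxygens are present (k
omitted at 1). Saturation is classified on the species-level double-bond
total (0 / 1 / 2 / >=3), matching the Total-FA-level presentation of the
stratified analyses rather than per-chain voting.

Membrane-biophysics labels are a pure table lookup, not a simulation. The
packaged table (`data/biophys_rules.tsv`, first match wins, wildcard
bounds) encodes coarse empirical headgroup/chain relationships: lyso
species promote positive intrinsic curvature and diffuse fast; ether
bonds rigidify and slow lateral mobility; bilayer thickness grows with
total chain carbons; sphingomyelins partition to ordered plasma-membrane
domains; acylcarnitines are mitochondrial shuttle metabolites rather than
bilayer formers. The carbon/double-bond bin edges are approximate by
construction and documented row by row in the file; any species outside
coverage raises an annotation-gap error rather than silently defaulting.

## Synthetic cohorts

The generator draws log2 concentrations as baseline + shift·1[case] +
N(0, sigma²) and exponentiates, i.e. log-normal within group with
homoscedastic log-scale noise — the standard working assumption for
concentration panels, and sufficient for the rank-based tests downstream.
Defaults emulate the reference study design: 30 cases vs 11 controls; a
124-species panel with class counts PC 50 > LPC 20 >= SM 20 > PC O- 19 >
CAR 15; per-species baselines fixed in `data/panel.tsv` from class-typical
plasma ranges (PC tens-to-hundreds of µM down to CAR well below 1 µM) with
a frozen per-species jitter — they are plausible, not estimates of any
real cohort. noise_sigma defaults to 0.5 so that a log2 shift of 1 is a
standardized effect of 2. The `cll_like_effects` pattern implants +1 on
the 18 species reported enriched in disease plasma (CAR 12:0 at +2 as the
most dysregulated), −1 on the two depleted PC species, zero elsewhere.

What the generator does *not* emulate: batch effects, limit-of-detection
censoring, heteroscedastic or correlated noise (an equicorrelated class
block is available but off by default), and biological covariates. Tests
passing on these cohorts demonstrate algorithmic correctness and power
under the declared model, not robustness to real-data pathologies.

## Differential abundance

Group comparison is the two-sided Wilcoxon–Mann–Whitney test: exact null
enumeration when the pooled sample is <= 16 and tie-free, otherwise the
normal approximation with tie and continuity correction (the regime of
the 30-vs-11 design). BH correction runs within one annotation level —
species form one family, each stratification its own — because class-level
adjusted p-values are reported as a separate family from species-level
ones. Stratum abundance is the per-sample SUM over member species (total
class abundance; sums preserve mass, and the class-level aggregation
conserves the per-sample total by construction).

Effect sizes are pseudo fold changes (med_case + eps)/(med_control + eps)
with eps = 0 when both medians are positive, else half the smallest
positive pooled value; log2 of that ratio is reported with positive values
meaning higher in cases. The "fold change > threshold" filter is applied
to the magnitude max(fc, 1/fc), symmetric in direction, since both
enriched and depleted species must be callable; at the default threshold 1
it only excludes exact ties. Preprocessing is log2(x + delta) with delta =
half the smallest positive value per species when zeros occur (all-zero
species are dropped with a warning). PCA standardizes features to zero
mean and unit variance first and drops constant features; clustering uses
Euclidean distance with complete linkage on per-species z-scores — no
metric/linkage is canonical here, so the defaults are declared and
configurable.

## Stability selection

A shadow run follows the Boruta scheme: each iteration appends freshly
permuted shadow copies of every feature still in the model (confirmed and
undecided; rejected features leave, and the pool is padded back to at
least `min_shadows` columns), fits the importance backend on real plus
shadow columns, and credits an undecided feature a hit when its importance
exceeds the iteration's maximum shadow importance. Hit counts are tested
two-sided against Binomial(n, 1/2) from iteration 5 onward at p < 0.01
Bonferroni-divided by the feature count — the multiplicity adjustment
canonical Boruta applies by default. Features undecided at max_iter stay
tentative and count as not confirmed everywhere downstream (conservative).

The default importance backend is a vectorized random-ferns out-of-bag
permutation importance (1000 ferns, depth 3): a fern is a set of random
(feature, uniform-threshold) splits whose 2^depth leaves carry
Laplace-smoothed class frequencies from a bootstrap draw; importance is
the mean drop in out-of-bag log-score when a feature's contribution is
permuted, averaged over its uses. Two properties motivated this choice
over tree-ensemble impurity or permutation importance. First, ferns
sample features uniformly, so equally informative features receive
comparable importance; impurity importance on a few dozen samples is
winner-take-most — whichever of several equal-effect species happens to
split best captures the root of every tree and starves the others, which
destroys the per-feature hit rates the binomial decision needs. Second, a
ferns call costs milliseconds, which matters when the protocol multiplies
~100 Boruta iterations by 200 resampling runs. Depth 3 (8 leaves) keeps
leaves populated at n ≈ 30–40 where depth 5 (32 leaves) fragments them.
An extremely-randomized-trees impurity backend ships behind the same
pluggable interface.

The stability protocol runs R1 shadow runs on stratified 70% subsamples
(per-group proportional, round half up — simple subsampling could leave
almost no controls) and R2 runs on the full data, with run seeds derived
from one base seed. Stable = confirmed in more than half the runs of both
conditions. medianImp is the median over all confirming runs (both
conditions pooled) of the feature's mean within-run importance — stable
against runs of different lengths; Ratio_to_ShadowMax / Ratio_to_ShadowMean
divide medianImp by the median over runs of the per-run mean shadow
maximum / shadow mean.

## ROC screening

AUC is the Mann–Whitney U normalized by n1·n2 with half-credit for ties,
oriented so AUC >= 0.5 with the direction recorded. Confidence intervals
use the DeLong placement-value variance with a normal interval truncated
to [0, 1]; when that variance degenerates to zero (perfect separation), a
seeded percentile bootstrap (2000 resamples) takes over — DeLong is the
declared default since the choice between DeLong and bootstrap is
otherwise open. The operating point maximizes Youden's J over midpoints
between consecutive distinct pooled values plus infinite sentinels
(transform-stable and standard); ties prefer higher sensitivity, then the
lower threshold. Screening gates are strict inequalities (AUC > 0.80,
sensitivity > 0.70, specificity > 0.80), read literally from the
reported thresholds.

## Gene–lipid networks

The packaged association table (`data/gene_lipid_map.tsv`) is an explicit
curated stand-in seeded from the fifteen lipid-metabolism genes a
pathway-mapping analysis of such panels implicates, paired with their
substrate classes by standard enzyme annotation (CPT2 ↔ acylcarnitines,
LPCAT1-4 and lysophospholipases ↔ LPC, phospholipases ↔ PC, ENPP6 ↔
lyso/ether choline lipids, SMPD3 ↔ SM); every row carries a provenance
note and the file is user-replaceable. Selectors resolve as exact species
(canonical or dialect name), headgroup class, or LIPID MAPS subclass;
duplicate matches collapse. Generic metabolite aliases (e.g. the trade
name "Carnicor") are filtered before construction. The graph is strictly
bipartite; degree centrality is degree/(n−1); node size is that
centrality min-max scaled to [1, 10] (uniform-degree graphs get the
midpoint 5.5). Kamada–Kawai coordinates are deterministic; the seed only
resolves coincident points to enforce a minimum separation.

## Pipeline

`run_all` executes annotate → DE (all configured levels) → PCA/clustering
→ stability selection → ROC on the stable features → network on the
significant species. One root seed derives stage seeds by fixed offsets.
Outputs are TSVs with comment headers (stage, version, parameters) plus a
JSON manifest (input SHA-256, seeds, parameters, per-stage outputs);
equal configs give byte-identical tabular outputs. A failing stage raises
with the stage name and cause and leaves its partial files suffixed
`.partial`.

## Problem sizes in the test suite

The suite exercises the full study geometry (41 samples × 124 species)
but scales Monte-Carlo depth to desk scale: the recovery check runs the
reduced protocol (R1 = R2 = 25) for 10 protocol seeds on the default
cohort; the pure-noise selection check uses 50 cohorts; DE null
calibration uses 20–30 cohorts; coverage and property checks use
200–1000 random instances. Generator calibration is checked at n =
500/500 with the median-difference averaged over three cohorts (single-
cohort medians have sampling noise ≈ 0.04 log2 units, so a 0.1 band on a
124-species maximum needs the averaging, not a wider band).

## Known limitations

Shadow-attribute selection is optimistically biased at this sample size,
and one acceptance-suite test documents it by failing. With 124 features
and 41 samples, the most chance-correlated noise feature has
point-biserial |r| ≈ 0.48 (the expected maximum of 124 draws), which is a
property of the cohort and persists across iterations, while the shadow
maximum is redrawn fresh each iteration. Conditional on an unlucky
cohort, that feature's per-iteration hit probability can sit well above
1/2, and no binomial test on hit counts can distinguish it from a real
effect — its distribution across cohorts is approximately uniform, so a
non-negligible fraction of pure-noise cohorts yields at least one
confirmed feature regardless of the decision threshold. The configuration
space was mapped explicitly: keeping the shadow pool at full width
throughout suppresses these false confirmations (≈75% of noise cohorts
clean at best) but then the 70% subsample condition's hit bar (the
maximum of ~124 fresh chance draws at n = 29, r ≈ 0.55) sits exactly at
the realized effect size of genuine standardized-effect-2 species, and
the protocol stops recovering them; the canonical shrinking pool recovers
the implanted species reliably but lets the top chance features through
on noise. The defaults follow canonical Boruta (shrinking pool,
Bonferroni-adjusted decisions); the two-condition stability vote and the
downstream ROC gates are the practical mitigations, and findings at this
sample size should be treated as candidates for validation, not
discoveries. Other limitations: no covariate adjustment or paired
designs; biophysics bins are qualitative approximations; the gene–lipid
table is curated, not measured; DeLong intervals are asymptotic and
anti-conservative at extreme AUC.
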