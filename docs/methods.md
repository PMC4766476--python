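# Methods

## Screen hit calling

The dual-reporter design measures pathway activity as the ratio of an
ARE-driven firefly luciferase to a constitutive Act5C renilla luciferase in
the same well; the ratio cancels well-to-well variation in transfection
efficiency and viability. Wells with non-positive renilla signal indicate
dead or untransfected wells and are dropped with a logged failure record
rather than aborting the plate — one dead well must not void a 384-well run.

Ratios are scored as robust Z-values, `z = (ratio − median)/(1.4826·MAD)`,
computed per plate by default (`z_scope="plate"`); per-plate scoping is
standard high-throughput-screening practice because it absorbs plate-level
drifts, and the median/MAD pair resists contamination by real hits. Control
wells (pathway-positive knockdowns such as CncC/MafS, the pathway-negative
Keap1, and neutral GFP dsRNA) are excluded from the median/MAD estimation
but still scored, so assay-validation Z-values are reportable. A plate whose
non-control ratios have zero MAD is degenerate and raises an error naming
the plate. `z_scope="screen"` pools all wells for single-plate toy data.

Hit calling uses a consensus rule across a gene's dsRNAs: at the default
threshold 1.65 (the one-sided normal 5% point), a gene is an inducer if at
least `min_consistent = 2` of its 3 dsRNAs score at or below −1.65 and,
with the opposite-sign veto on, no dsRNA scores at or above +1.65;
suppressors mirror this. The 2-of-3 default, rather than a strict 3-of-3,
is forced by the data the rule must reproduce: the published hit table lists
genes (fray, Psi on the inducer side; GSK-3, Nipped-A among suppressors)
whose third reagent stayed inside the threshold, which only a 2-of-3 rule
recovers. A strict rule remains one configuration flag away.

Two properties of the rule are worth stating precisely. Without the veto,
classification is monotone in the threshold: raising it never converts a
non-hit into a hit. With the veto this can fail in a narrow regime — an
opposite-sign dsRNA sitting between the old and new thresholds releases its
veto (e.g. z = (1.0, 1.0, −0.5) is vetoed at threshold 0.5 but a suppressor
at 1.0). The property suite therefore asserts unconditional monotonicity
for the veto-free rule and covers the veto by worked examples. Second, at
the default threshold a 432-gene null screen is *expected* to produce a
handful of false consensus calls (two-sided tail 0.1 per dsRNA, compounded
to roughly 1.3% of genes); planted-recovery claims are therefore phrased as
side-correct recovery of planted hits plus a separate bound on the null
false-call count, not as global precision 1.

Ranking orders inducers by ascending mean Z (strongest reporter suppression
first) and suppressors descending, ties broken by gene id.

## Differential expression layer

Counts are normalized to counts-per-million (CPM); CPM is length-free,
deterministic, and sufficient here because every downstream criterion
consumes only log-fold-changes, q-values and condition means — the
geometric-mean inequality and all ratio criteria are invariant under a
uniform rescaling of the expression unit, so the choice of unit cannot flip
a selection decision. Fold changes are ratios of pseudocounted condition
means, `log2((mean_num + pc)/(mean_den + pc))` with `pc = 0.5` CPM, so they
are always finite.

P-values come from a two-sample t statistic on `log2(CPM + pc)`. With
triplicates, a per-gene variance estimate has ~4 degrees of freedom; a
plain Welch test then has essentially no power at genome-wide thresholds
for even 8-fold effects (per-gene power ≈ 0.45 at the BH-effective alpha in
our conditions), which would defeat a filter whose published form demands
`q < 0.05` in up to three comparisons simultaneously. The default test
therefore moderates the pooled per-gene variance with an empirical-Bayes
scaled-inverse-chi-square prior fitted across all genes of the comparison
(moment estimators on `log s²`, prior degrees of freedom from a trigamma
inversion), adding the prior degrees of freedom to the statistic — the
standard small-replicate treatment in expression analysis. `method="welch"`
retains the unmoderated unequal-variance test with Welch–Satterthwaite
degrees of freedom for designs with many replicates, and is pinned to a
hand-computed oracle in the tests. Degenerate genes follow explicit
conventions: both groups constant and equal → p = 1; constant but unequal →
variance floor 1e−12, p ≈ 0.

q-values are Benjamini–Hochberg step-up within each pairwise comparison
(not pooled across comparisons), matching per-comparison differential
output. A small qPCR utility implements the delta-Ct convention
(`2^−(Ct_target − Ct_reference)`, reference Act5C) and fold induction as
the ratio of relative expressions.

## Pattern selection

Genes with at least one read in every sample are kept (criterion 1).
Condition-mean profiles over (Control, Paraquat, Cdk12i, Cdk12i+Paraquat)
are row-standardized; zero-variance rows are flagged flat and excluded —
Pearson correlation is undefined for them, and a flat gene can never be
selected. Standardized profiles are clustered by agglomerative average
linkage under `d = 1 − Pearson` (criterion 2), the common default for
correlation-distance expression clustering. The tree is cut into `k`
clusters; each cluster is labelled per condition from the sign of its
centroid (above the gene's own mean = high, ties = low — the only
parameter-free reading of low/high), and all clusters matching the target
template are pooled before filtering, which makes the result insensitive to
over-splitting.

`k` defaults to 16. In four dimensions a standardized profile can realize
14 sign patterns; at desk scale (~500 profiles) a coarser cut (k = 8) lets
planted-pattern clusters absorb weakly correlated noise genes, whose
contribution can flip a centroid sign and mislabel the whole cluster —
under-segmentation cost us entire groups on some seeds. One to two clusters
per attainable pattern is robust; because matching clusters are pooled,
raising `k` further is harmless.

Criteria 3–5 are applied exactly as printed, with strict inequalities:

* Group A (paraquat-induced, Cdk12-dependent): `log2FC(PQ/Ctrl) > 1` with
  `q < 0.05`; `log2FC(Cdk12i/Ctrl) > −1`; and
  `mean(Cdk12i) < √(mean(Control)·mean(Paraquat))` on CPM condition means.
* Group B (Cdk12-suppressed under paraquat): `log2FC > 0, q < 0.05` in
  Cdk12i+PQ/PQ; `q < 0.05` in Cdk12i/Ctrl (no direction is stated for this
  criterion, and none is imposed); `log2FC > 0, q < 0.05` in Cdk12i+PQ/Cdk12i.

Every gene receives an audit row recording each criterion's evaluated
quantity and verdict, so the first failing criterion of any excluded gene is
inspectable. Tightening any threshold provably shrinks the selected sets
(subset property), and uniform count rescaling leaves all decisions
unchanged.

## Enrichment

For a term annotating K of N background genes with k hits in an n-gene set,
the p-value is the hypergeometric upper tail `P(X ≥ k)`. Annotations are
intersected with the background before counting; only terms with `k ≥ 1`
are tested, and the correction multiplicity m counts exactly the tested
terms (this matters: m changes corrected values, and the behaviour matches
the classic GO-term-finder convention). Bonferroni is the default
correction, BH optional; Bonferroni never falls below the raw p, and BH
never exceeds Bonferroni. No ontology-graph propagation is performed — the
annotation table is taken as-is, keeping the module ontology-agnostic;
callers wanting parent-term inheritance must pre-expand the table. Because
the statistic is discrete, null p-values are super-uniform
(`P(p < α) ≤ α`, usually strictly below); the calibration test compares the
empirical exceedance against the exactly enumerated null law rather than
against α itself.

## Synthetic data

The generators are pure functions of config + seed and return the planted
truth alongside the data.

**Screen.** 432 genes × 3 dsRNAs on 384-well plates (the screened kinome
was reported as 432 genes in one place and "a panel of 420" in another; the
generator defaults to 432 and either is one config field away). Reporter
ratios are log-normal (σ = 0.1) times the dsRNA effect, applied to Fluc
only; Rluc is an independent log-normal draw. Default effects — inducer
0.2×, suppressor 2× — put effective dsRNAs at |z| ≈ 8–10, comfortably past
the 1.65 cut, matching a screen designed to detect strong reporter effects.
Each plate carries the four validation controls with effects that echo the
published validation Z-values (CncC ≈ −4.5, Keap1 mildly positive). A
configurable fraction of hit genes (default 1/3) receives one inert dsRNA,
reproducing the partially-consistent-reagent phenomenon that motivates the
2-of-3 rule.

**Counts.** Negative-binomial counts with variance `μ + φμ²`, φ = 0.1 (a
typical biological-replicate dispersion), 3 replicates × 4 conditions,
per-sample library-size factors uniform ±20%. Group A genes follow
`μ = m·(1, 8, 1, 1)`; Group B genes `μ = m·(1, 1, 1/4, 4)` — induced only
under combined treatment, with a basal 4-fold Cdk12-dependence under
knockdown alone. That basal shift is required for the planted genes to be
*selectable at all*: the printed Group B criterion demands significance in
Cdk12i/Control, which a gene with identical means in those conditions can
never attain; its direction (down rather than up) is immaterial to the
direction-free criterion but keeps the standardized Cdk12i entry safely
below the row mean, so cluster labels do not flip under noise.
Housekeeping genes are constant at `m = 100`; 400 background genes draw
constant per-gene means around 500 (log-normal, σ = 0.5). Background
carries the bulk of library mass deliberately: in a real transcriptome a
few dozen responsive genes are a negligible share of sequenced reads, and
if planted genes dominate a small simulated library, CPM composition shifts
compress every fold change by several tenths of a log2 unit — an artifact
of the small panel, not of the study design being emulated.

What the generator does **not** model: batch effects, GC/length bias,
isoform structure, correlated genes, read-level noise. Passing tests show
the selection logic recovers planted patterns under idealized NB noise;
they do not certify performance on real libraries with those artifacts.

**Annotation.** One term per planted role annotating a configurable
fraction of its genes (default 0.8) plus a few outside genes, and 20 random
noise terms, so enrichment can be validated against a known signal.

## Problem sizes and determinism

The validation suite runs at desk scale: 500-gene × 12-sample matrices,
ten seeds for recovery claims, five null matrices plus fifty null
comparisons for false-positive control, and exhaustive oracles only where
exhaustion is cheap (hypergeometric N ≤ 12, BH vectors of length ≤ 8,
clustering of ≤ 6 profiles). Every stochastic step takes an explicit seed;
identical config + seed reproduces every table byte for byte, and the CLI
writes per-file checksums to make that checkable.

## Known limitations

* The DE layer is a two-group test per comparison, not a joint GLM across
  the 2×2 design; interaction effects are expressed only through the
  criteria combinations, as in the procedure it implements.
* CPM ignores gene length; cross-gene expression comparisons are not
  meaningful (within-gene, cross-condition ones are, which is all the
  criteria use).
* Average-linkage tie-breaking follows the linkage implementation's merge
  order; oracle comparisons use continuous data where exact ties have
  probability zero.
* The published 43- and 153-gene lists cannot be reproduced without the
  original raw sequencing data, which was not deposited; the pipeline
  validates the *procedure* on planted ground truth instead.
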