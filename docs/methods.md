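# Methods

This note documents the models and numerical choices behind `evmir`, what
the synthetic-data generator does and does not emulate, and where the
design was genuinely open.

## Ct conventions and normalization

Ct is treated as minus log2 abundance: one cycle is one log2 unit, lower Ct
means more template. All normalization arithmetic stays on the Ct scale;
the "geometric mean" of reference features on the concentration scale is
computed exactly as their arithmetic mean on the Ct scale, avoiding a
pointless exponentiation round-trip.

**Spike-in recovery adjustment.** With spike Ct `s_c` in sample `c`, every
Ct in that sample shifts by `−(s_c − mean_c s_c)`. This removes per-sample
technical yield (extraction/RT efficiency) while preserving all
within-sample Ct differences exactly; a single sample is its own mean and
passes through unchanged. The spike must be determined in every sample —
a missing spike is a hard error naming the sample, because silently
skipping the adjustment for one sample would bias every feature in it.

**Reference selection.** `normfinder_stability` implements the model-based
variance-decomposition stability of the NormFinder family. For features
i = 1..k, groups g, samples j: values are first centered per sample
(removing array-wide sample effects), giving z. Within each group the naive
mean square MS_ig of the centered values is contaminated by the centering;
with k features E[MS_i] = σ²_i(1 − 2/k) + mean_l σ²_l / k, inverted as
σ̂²_ig = k/(k−2)·(MS_ig − Σ_l MS_lg/(k(k−1))), floored at zero (for k ≤ 2
the correction is skipped). Intergroup differences d_ig (group mean minus
feature's cross-group mean) are shrunken toward zero by the empirical-Bayes
factor γ̂²/(γ̂² + σ̂²_ig/n_g), with γ̂² a method-of-moments between-group
variance pooled over features. The stability value is
ρ_i = mean_g(|shrunken d_ig| + √(σ̂²_ig/n_g)); lower is more stable.
Pair stability applies the same formula to the pair-average profile
(d averaged, sampling variance (σ̂²_a+σ̂²_b)/4n_g), searched exhaustively
over all pairs with lexicographic tie-breaks, so the ranking is
deterministic. With a single group the stability degrades to the variance
of sample-centered values (documented fallback). The decomposition is
location-invariant, so it can be run on raw or spike-adjusted Cts. The
grouping variable (default: treatment arm, all visits pooled) and the
candidate set are configuration, not inference — stability rankings depend
on both and runs log them.

**−ΔCt and fold changes.** Normalized abundance is −(Ct − reference mean)
per sample, so the reference-pair geometric mean maps to 0 everywhere and
+1 means one cycle more abundant. Relative expression is 2^(−ΔΔCt). Signed
fold change maps a log2 difference Δ to 2^Δ for Δ ≥ 0 and −2^(−Δ)
otherwise, so |fc| ≥ 1 always and the mapping is invertible.

**Undetermined wells.** "Undetermined" is carried as an explicit flag from
parsing onward and never coerced. At the change-score step the default
policy drops a subject's pair for a feature when either visit is
undetermined; an optional Ct-cap imputation (substituting a floor
abundance) is available behind a flag for sensitivity analysis. References
and the spike-in must be determined everywhere (hard error otherwise).

**Minimum-fold pre-filter.** A feature survives at threshold F iff
|mean PIO Δ − mean PLA Δ| ≥ log2 F on the change-score scale (default
F = 1.5); only sub-threshold features are removed, so the boundary case is
retained. An alternative per-arm-median mode exists because the appropriate
granularity (group effect vs typical subject) is a judgment call. The
filter runs after normalization and before model fitting, which defines
the FDR family as the filtered panel.

## Differential abundance

Per feature: response ~ intercept + arm + visit + arm×visit + covariates,
with a subject random intercept, fitted by REML through statsmodels
MixedLM. The treatment effect is the arm×visit interaction — in a balanced
complete design it equals the difference in mean week12−baseline change
between arms (a property the tests pin to 1e−8 against a change-score
oracle). Default covariates are time-varying body weight and hematocrit for
circulating measurements (weight gain and hemodilution are known systemic
effects of the treatment class) and weight alone for adipose tissue;
metformin use can be added as a sensitivity refit. Covariates are
standardized internally for conditioning — the interaction test is
invariant to affine covariate transforms. A subject missing a covariate
value is excluded from that feature's model only, with a warning.

**Inference.** Wald t tests with between-within (containment) denominator
df: terms varying within subject (visit, interaction, time-varying
covariates) are tested against N − n_subjects − q_within; between-subject
terms against n_subjects − q_between − 1. With two dozen subjects the
asymptotic normal reference is anticonservative (empirical type-I ≈ 0.06 at
nominal 0.05 in our null simulations); the containment-df t test calibrates
to ≈ 0.05, which the acceptance checks verify. `df_method="normal"`
restores the asymptotic reference. When the between-subject variance is
estimated at the zero boundary or the optimizer fails, the model
degenerates to independent errors and the fit falls back to its OLS limit
with a warning — never a crash (the noise-free synthetic cohorts exercise
this path constantly).

**Post-hoc contrasts** are linear combinations of the fixed effects
(within-arm change per arm; between-arm difference per visit), with the
identity `between(week12) − between(baseline) = interaction` holding
exactly.

**BH FDR** is the step-up transform, computed directly so that NaN p-values
(unfittable features) propagate as NaN q and are excluded from the family
size. **Directional tests** convert a symmetric two-sided p to one-sided:
p/2 on a sign match, 1 − p/2 otherwise — used where repression direction is
known a priori (upregulated miRNAs are expected to downregulate their
overtargeted transcripts).

**Partial correlation** is two-stage residual regression: both variables
regressed on covariates plus intercept, Pearson r of the residuals,
t-transform p with df = n − k − 2. Inputs for molecular features are
week12−baseline change scores of normalized (log2) values; clinical
variables enter in raw units; covariates enter as change scores. The
implementation is cross-checked against pingouin in the tests.

## Overtargeting network analysis

The database is a bipartite miRNA→gene graph from validated interactions;
with `strong_only` a record is kept iff its free-text experiments field
contains a reporter-assay or Western-blot token (case-insensitive
substring; token list configurable because evidence vocabularies vary
across releases). Duplicate interactions collapse with evidence and PMIDs
merged. Gene symbols are uppercased HGNC-style; miRNA names are miRBase
mature names with optional species-prefix stripping (arm suffixes are never
guessed).

For a query of m miRNAs, T_j is the number of query miRNAs targeting gene
j. The default global statistic is the multiplicity-weighted excess
S = Σ_j max(T_j − 1, 0): every additional co-targeting event counts. The
plain count #{j : T_j ≥ k_min} is available but is a blunter instrument —
in realistic databases many background genes reach k_min = 2 by chance, so
the count statistic dilutes genuine cooperative signal (we measured roughly
an order of magnitude difference in planted-signal separation between the
two statistics under the degree-matched null).

**Null models.** `degree_matched` (default): each query miRNA is replaced
by a database miRNA drawn from the same log2-degree bin (width 1), without
replacement within a draw; bins widen automatically (with a warning) when
too sparse. The query members themselves stay in the sampling pool — with
the query equal to the whole database every draw reproduces it and p = 1,
the correct degenerate behavior. `uniform`: unrestricted resampling of m
miRNAs. `edge_rewire`: bipartite double-edge swaps (10×|E| accepted swaps
per replicate) preserving both degree sequences exactly; it is O(B·|E|) in
pure Python and intended for small B. Every output names its null model.

**Empirical p-values** use the add-one rule p = (1 + #{null ≥ obs})/(B+1),
so min p = 1/(B+1), p-values are never zero, and identical seeds give
bit-identical results (one seeded generator per run, seed recorded).
Per-gene p_j is reported for genes hit by the query; genes with
T_j ≥ k_min additionally get BH q across that set; the overtargeted set is
{T_j ≥ k_min and p_j < α} (k_min = 2, α = 0.05 defaults). Defaults
B = 10,000; counts are computed in batched matrix products, so the default
run takes well under a minute at database scales of a few hundred miRNAs ×
a few thousand genes.

**Enrichment** is a one-sided hypergeometric upper-tail test per gene set
with BH across sets; the default universe is all genes of the filtered
database (not the genome), configurable, since the panel-induced database
is the sampling frame actually available to the test.

## Clinical indices

K_FFA = −100 × OLS slope of ln(FFA) on time over the 19–40 minute window,
endpoints inclusive; points outside the window never enter the fit; fewer
than two in-window points yields NA with a reason; duplicate time points
are rejected. Multiplying the series by a positive constant leaves K_FFA
unchanged (log-slope property). Adipo-IR is fasting FFA (mmol/L) × fasting
insulin (pmol/L).

## Synthetic data: what it emulates and what it does not

`generate_cohort` draws a 2-arm × 2-visit paired cohort (default 12
subjects/arm; 42 target miRNAs plus spike-in and endogenous control) from

    Ct = μ_f + b_if + visit·1[week12] − δ_f·1[PIO, week12] + λ·Δweight + t_s + ε

with per-(subject, feature) intercepts b (SD 0.5 cycles), residual ε (SD
0.4), and a per-sample technical shift t_s (SD 0.5) shared by all features
of a sample and captured exactly by the spike-in row. Five features —
named after the differentially expressed EV-miRNAs the pipeline is designed
around — carry a planted signed fold change of −2.0 (δ = −1 log2
abundance, +1 cycle Ct; the sign chain Ct-up = abundance-down is the
easiest place to err and is asserted in tests). Two candidate references
(miR-126/miR-30b) are generated with reduced noise so stability selection
has a right answer. Covariates drift with the arm (weight +3 kg mean and
hematocrit −1.5 pct in the treated arm — realistic magnitudes for a
12-week course of an insulin-sensitizing thiazolidinedione) but are by
default independent of the molecular noise, so covariate adjustment is
exercised without confounding the planted truth; a `covariate_confounding`
loading (cycles per kg) enables robustness tests.

Not emulated: amplification-efficiency differences, plate/batch structure
beyond the single technical shift, undetermined-well missingness mechanisms
(tests inject these explicitly), heavy-tailed noise, or any attempt to
match an unpublished real cohort's variance components. Passing tests
therefore show the pipeline recovers known truth under a well-specified
mixed model with realistic magnitudes — not that any particular clinical
dataset satisfies those assumptions.

`generate_target_db` draws background edges i.i.d. at mean degree 30
(typical of strong-evidence validated-interaction databases at panel
scale) over 200 miRNAs × 2,000 genes and wires 10 planted genes to exactly
4 of the 5 query miRNAs (background query→planted edges are cleared first
so T is exact by construction). `generate_clinical` produces
exponential-decay FFA curves (rate 0.02/min → K_FFA = 2.0, with a treated
arm improvement at week 12) and fasting tables with arm-dependent shifts.

## Verification problem sizes

The reproduction script (`scripts/acceptance.py`) and the headline tests
use: the 6×8 toy database with all C(6,3)=20 subsets enumerated vs
B = 10,000 empirical draws; the default 200×2,000 planted database at
B = 10,000 under the degree-matched null; 500 null queries at B = 2,000
(query size 10, mean degree 100, chosen so the integer statistic has a
fine enough lattice that a KS test probes calibration rather than grid
discreteness); 200 synthetic cohorts for power/bias and 200 null cohorts
(×5 features = 1,000 null tests) for type-I error; 1,000 random p-vectors
against the brute-force BH definition; and two full pipeline runs compared
by output SHA-256.

## Known limitations

- Random slopes, amplification-efficiency correction, multi-plate batch
  correction, and repeated-measures ANOVA are out of scope.
- The degree-matched null resamples miRNA sets; it does not condition on
  gene degrees (use `edge_rewire` for that, at its computational cost).
- Legacy binary `.xls` interaction tables must be converted to `.xlsx` or
  TSV before reading.
- Satterthwaite df are not implemented; the options are between-within t
  (default) or the asymptotic normal reference.
- With k ≤ 2 candidate reference features the stability model cannot
  correct for centering contamination and falls back to naive variances.
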