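# Methods

`methylspan` builds and evaluates penalized linear predictors of
species-level life-history traits — maximum life span, gestation time and
age at sexual maturity — from cytosine-methylation (β-value) profiles,
and ships a synthetic-data generator that reproduces the statistical
structure such studies face, so the whole pipeline is testable without
any external dataset.

## The modelling procedure

**Inputs.** A samples × CpGs matrix of β values in [0, 1] with a sample
sheet (species, tissue, sex, age), a species trait table (maximum life
span in years, gestation in days, age at sexual maturity in years, adult
weight in grams, taxonomic order), per-(species, CpG) median detection
p-values, and a rooted phylogeny with branch lengths.

**Probe filter.** Detection p-values are Benjamini–Hochberg adjusted
*within each species across CpGs*; a CpG is retained when adjusted
p < 0.05 in at least 85% of species (⌈0.85·n⌉, missing cells counted as
failures — the conservative reading). BH granularity is a design choice:
detection significance is a within-array, per-species property.

**Trait scale.** Recorded maximum life spans understate the truth when
few individuals were observed, so every species except *Homo sapiens*
and *Mus musculus* is multiplied by 1.3 before modelling. The factor is
a config value (`CorrectionConfig.factor`), not a constant, to allow
sensitivity analyses. Correction happens before the natural-log
transform and before any fitting; a `lifespan_corrected` flag makes the
operation idempotent. All three traits are modelled in natural
logarithms because their cross-species distributions are strongly
right-skewed. Missing life spans can be imputed from the patristically
nearest observed species (K = 1, ties broken by species name); imputed
rows carry a flag so evaluation schemes can exclude them.

**Aggregation.** Samples are averaged per species (tissue-agnostic) or
per (species, tissue) stratum (tissue-aware). Stratum means ignore
missing β values; cells still empty after aggregation are imputed with
the column mean — it completes the design matrix without inventing
trait signal. Each stratum is one observation with equal weight. A
young-animal subset (age below both the species' maturity and 5 years)
supports the early-life variant of the predictor.

**Predictor.** Elastic net with mixing parameter 0.5 (the convention in
methylation-clock work; exposed in `TrainConfig`), predictors
standardized to zero mean / unit SD at fit time, β values otherwise
untransformed. Penalty strength is selected by internal 10-fold CV
minimizing mean squared error on a 25-point path spanning a 100-fold
penalty range (`eps = 1e-2`); the path stops well before the dense
overfitting regime, which both regularizes sensibly at these sample
sizes and keeps one fit near one second. Coefficients are
de-standardized back to the β scale. Fitted values are calibrated by an
affine map matching the training predictions' mean/SD to the observed
trait's mean/SD; the map is frozen in the model and reapplied to new
data. The calibration is fitted on in-sample training predictions (not
CV predictions) of each model. Optional one-hot taxonomic-order
indicators can compete with CpGs for selection; their selection status
is reported.

**Evaluation schemes.**
* *LOSO* — one fold per species; in tissue-aware mode all strata of the
  held-out species leave training together. The penalty is re-selected
  inside every fold.
* *LOCO* — one fold per taxonomic order. Orders with more than 20
  species keep exactly their minimum- and maximum-life-span members in
  training (on the corrected scale — that is what the model sees; ties
  break lexicographically and are logged); those two species are never
  tested. Orders with ≤ 20 species are held out whole ("over 20" read
  strictly). Species with imputed life spans are excluded entirely.
* *70/30 split* — a seeded random partition by species.

Accuracy is summarized by Pearson R (two-sided p from the t transform)
and the median absolute error on the log scale.

**Phylogenetic baseline.** k-NN regression on patristic distances: a
target's log trait is the unweighted mean of its K nearest training
species (ties by name). Unweighted averaging is the plain reading of
k-NN regression; the baseline consumes exactly the same corrected,
log-transformed traits and the same CV folds as the methylation arm.

**Downstream readouts.** All p-values are reported unadjusted (callers
may correct); all operations are pure functions.
* *Sex differences* — per (species, tissue) two-sided Wilcoxon rank-sum
  on per-sample predictions (exact null for small tie-free samples,
  tie-corrected normal otherwise; cells need ≥ 2 per sex — smaller cells
  carry no rank information). Species verdict: "+" if at least one
  tissue has p ≤ 0.01 and **all** tissues at p ≤ 0.01 agree on a
  positive female-minus-male difference; "−" symmetric; "." otherwise.
  Only significant tissues vote — a non-significant opposite-sign tissue
  does not veto.
* *Age association* — per-stratum Pearson correlation of prediction
  with age (≥ 4 known ages; constant-age strata skipped with a log
  entry).
* *Weight adjustment* — OLS of observed log life span on {prediction,
  log weight} with per-coefficient Wald tests; "weight-adjusted R" is
  the partial correlation of observed and predicted given weight
  (correlation of the two weight-residual vectors) — the concrete
  algebra chosen for "adjustment".
* *Group contrasts* — per stratum, the two-group OLS Wald Z (mean
  difference over pooled-variance SE), asymptotically standard normal
  under the null; p-values use the exact t reference with n−2 degrees
  of freedom so small strata stay calibrated (with 12-sample strata the
  normal reference is visibly anti-conservative).
* *AgeAccel* — raw residual of prediction regressed on age; zero mean
  and zero age-correlation by construction.
* *Breeds* — per-breed mean of sample predictions; breed maximum life
  span derived as 1.33 × median; correlations of breed means against
  log derived life span and log weight.

## The synthetic-data generator

The generator emulates a consortium-style multi-species array study.
Everything flows from one integer seed.

* **Tree** — a seeded Yule (pure-birth) process, ultrametric, depth
  normalized to 1, strictly positive branch lengths. Taxonomic orders
  come from cutting the tree at a depth chosen to give the finest
  partition that still contains one order of > 20 species and at least
  one singleton — the size heterogeneity the LOCO scheme needs (for
  trees of ≤ 42 tips the "large" threshold scales down to n/4).
* **Traits** — log maximum life span evolves by Brownian motion (rate
  0.8 log-years per unit depth around a root of ln 15 y ≈ 15 years,
  giving a realistic ~2–90 year span). Log gestation, log maturity and
  log weight are linear in log life span plus independent noise
  (slopes 1.0/1.0/2.5, residual SDs 0.30/0.35/1.2), reproducing the
  usual tight gestation link, looser maturity link, and broad
  weight–life-span correlation.
* **Methylation** — each informative CpG's species mean is
  `logistic(baseline + slope × latent trait)`, slope magnitude
  0.25 × U(0.5, 1.5) in logit units per log-year with random sign. The
  *latent* trait is the true log life span plus a species-level
  "epigenetic residual" (SD 0.35 log-years) shared by all informative
  CpGs: it models biological deviation and trait-record error, sets a
  ceiling on attainable accuracy that CpG averaging cannot break, and
  is the knob that places default LOSO R in the 0.85–0.95 regime (0.93
  at the default seed). Independently, **every** CpG's baseline drifts
  on the tree (Brownian, 0.3 logit units per unit depth): these
  clade-marker CpGs let a model interpolate traits among relatives
  under LOSO but not under LOCO, which is precisely why LOCO is the
  harder test (default run: LOSO 0.93 vs LOCO 0.87, while k-NN K=1
  falls from 0.93 to 0.53). With drift disabled non-informative CpGs
  are null (their trait-correlation p-values are KS-uniform); that
  drift-free setting is also the *planted-signal recovery experiment*:
  only there are non-planted CpGs genuine noise, so the precision of
  the selected set against the planted CpGs is a meaningful
  false-selection measure (with drift on, selected clade-marker CpGs
  are true signal of a different kind, not errors).
* **Confounders** — per-tissue scalar β offsets (±0.02); sex effects in
  a minority of species (β shift 0.05 at informative CpGs, aligned with
  each CpG's slope sign so the effect surfaces in predicted life span,
  direction random per species); age trends (0.005 β/year at informative
  CpGs) in designated (species, tissue) strata of above-median-life-span
  species — at a fixed per-year drift only species whose sampled age
  span covers enough years accumulate a detectable change. Sample noise
  is N(0, 0.04) per cell after species-level noise N(0, 0.03); β is
  clipped to [0, 1].
* **Sample design** — 2–8 samples per species over 1–4 of four tissues,
  female/male pairs rotating through tissues (so sex stays balanced
  within strata), ages Uniform(0, 0.8 × life span). Both ranges are
  config fields; the power and null studies in the tests use larger,
  balanced designs (e.g. 12-sample strata) because rank tests at
  α = 0.01 are otherwise unable to reach significance at all.
* **Detection p-values** — per (species, CpG): failing draws
  U(0.1, 1) with probability 0.05, passing draws U(0, 1e-4). A planted
  set of 150 "unreliable" probes (drawn outside the informative set)
  fails in ~50% of species; these are what the 85% filter removes —
  under homogeneous dropout alone the filter would never remove
  anything (binomial tail). The marginal-dropout invariant holds over
  the reliable background.
* **Breeds** — optionally one host species carries 93 breed-like
  sub-populations: true log life spans scatter around the host's (SD
  0.25) while methylomes differ only by N(0, 0.01) per CpG; within the
  clade heavier breeds are shorter-lived (slope −3 of log weight on log
  life span). Breed trait variance is therefore real but invisible to
  methylation — the negative control for within-species prediction.

**What the generator does not emulate.** Probe sequences, genomic
coordinates and chromatin context; array-version differences;
normalization artefacts (β values are taken as given); non-linear
trait–methylation links; correlated noise between CpGs beyond the
low-rank latent-trait and phylogenetic components; measurement-platform
batch effects. Passing tests therefore show the *procedures* behave
correctly under the stated statistical structure, not that real data
meet that structure.

## Numerical choices and degenerate inputs

Constant responses raise `DegenerateResponseError` (calibration is
undefined at zero SD); fewer than 10 training strata raise
`InsufficientDataError`; k-NN refuses targets inside the training set
(`LeakageError`); zero-variance vectors make correlations undefined
rather than silently zero. Nearest-neighbour and k-NN distance ties
break lexicographically by species name. Feature columns with zero SD
standardize to zero (their coefficients are necessarily zero). The
internal CV folds are seeded; every stochastic step derives from a
single run seed.

## Reference problem sizes

The shipped reference study uses 120 species × 3,000 CpGs (300
informative), the null-calibration study 150 species × 1,200 strata of
12 samples, and the power study 60 species with 24-sample strata; these
sizes keep a full LOSO + LOCO + baseline comparison to a few minutes on
one core while leaving all qualitative behaviour (scheme ordering,
filter action, power, calibration) intact.

## Known limitations

* The calibration map is fitted on in-sample predictions; with heavily
  shrunken models it slightly inflates the spread of external
  predictions.
* LOCO retained-species selection uses corrected life spans; with a
  different correction factor the retained pair can change.
* The breed analysis assumes one host species; multi-species breed
  panels would need per-host clade means.
* `filter_probes` treats detection medians as given; it does not model
  per-sample detection variability.
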