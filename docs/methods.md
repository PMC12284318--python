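# Methods

This note documents the models, rules and numerical choices behind `rwemri`,
the reasoning where the design was genuinely open, and what the synthetic
data can and cannot show about real register-linked MRI data.

## Scan selection

Selection is purely metadata-based. Head examinations are recognised by
procedure code (defaults `AA1BG`, `AA1CG`, `AA1DG`); T1 eligibility is a
regex test of the free-text protocol name against an inclusion alternation
(`mpr|mprage|t1_se|sag|tra|T1|TFE`) and an exclusion pattern (`gd`,
gadolinium contrast), plus a minimum slice count (90) as a proxy for 3-D
whole-brain coverage.

Choices made where the rule is underdetermined:

- **Case sensitivity.** Matching is case-sensitive by default because the
  inclusion list distinguishes `t1_se` from `T1`; a case-insensitive switch
  exists (`SelectionConfig.case_sensitive`).
- **Unanchored substring matching.** The listed alternatives are fragments
  of protocol names, not complete names.
- **Known looseness.** Fragments like `tra` and `sag` also occur in non-T1
  names (e.g. a 3-D T2 named `t2_space_tra` passes). This is deliberate:
  the filter aims for high recall on heterogeneous clinical metadata, and
  misclassified scans are caught downstream by quality control. The
  synthetic vocabulary includes this false-positive channel so tests
  exercise it.
- **Per-visit randomness.** When a visit has several eligible scans, one is
  chosen uniformly at random from a stream derived from
  `(seed, participant, visit)` (BLAKE2 digest into a `SeedSequence`), so the
  choice is reproducible and invariant to row order.
- An *examination visit* is a unique `(participant_id, visit_id)` pair;
  acquisition-date ties play no role in grouping.

## Quality control

Stage 1 gates on the segmentation tool's image-quality percentage,
inclusive at the threshold (default 68%; a scan at exactly 68% passes).

Stage 2 compares two independent segmentation pipelines per ROI (total gray
matter; hippocampus as left+right; ventricles as the sum of left/right
lateral and inferior-lateral parts). Pipeline-A totals predict pipeline-B
totals in a robust univariate regression: iteratively reweighted least
squares with Tukey bisquare weights (tuning constant 4.685, 95% Gaussian
efficiency), intercept included, residual scale re-estimated every iteration
as 1.4826 × MAD of the median-centred residuals, convergence when the
largest coefficient change falls below 1e-8 (max 50 iterations). A scan is a
potential outlier when, for any ROI, |residual| strictly exceeds
8 × the MAD-based residual-SD estimate.

Open points resolved as follows (all configurable):

- The threshold comparison is **two-sided** — discordance in either
  direction is suspect.
- The MAD→SD conversion uses the standard Gaussian consistency constant
  1.4826, and residuals are median-centred before the MAD.
- QC is **single-pass**: the regression is not refit after removing flagged
  scans.
- Flagged scans get disposition `review`, not automatic exclusion,
  mirroring a human visual-inspection step; `auto_exclude` switches to
  unattended removal. The demo pipeline analyses only `pass` scans, so
  `review` rows are conservatively held out until reviewed.

## Register-based cognitive status

Categories are strictly ordered: NMC < SMC < MCI < dementia. Register codes
map to categories through a configurable regex code map (real national code
lists are register-specific and are not shipped; the default map is a
synthetic stand-in recognised by the simulator).

- **Baseline**: the most severe category among events dated **on or
  before** the visit (an event on the visit date counts — a code recorded at
  the MRI-triggering encounter reflects status at the visit); NMC if none.
- **Upgrade**: under the default `printed_pairs` policy, SMC is promoted to
  MCI by an MCI event, and MCI to dementia by a dementia event, inside the
  half-open window `(visit, visit + 365 days]` (calendar days, no leap-year
  adjustment). NMC and dementia baselines never change, and a two-step jump
  (SMC baseline, only a dementia event in the window) does **not** promote.
  The alternative `max_within_window` policy takes the maximum in-window
  category (still never upgrading NMC, whose premise — an existing milder
  complaint — is absent); `none` disables upgrading.

The implementation is verified against a brute-force enumerator that
literally applies these sentences, over all ≤3-event category/date
combinations at the boundary offsets (0, ±1, 365, 366, ±400 days).

## The volumetric contrast model

For each ROI, volumes are standardized to mean 0, SD 1 (sample SD, n−1)
over the **combined two-cohort analysis sample**, computed once before
modelling; TIV is standardized the same way. The design is a cell-means
parameterization of status × cohort (the interaction is required for
between-cohort differences of within-cohort contrasts to be estimable from
one model), cubic B-spline bases in age and standardized TIV (3 interior
knots at quantiles by default, sensitivity range 0–5; the first basis column
is dropped because the cell dummies absorb the constant), and
baseline-dropped manufacturer and field-strength indicators. Rows with any
missing model variable are dropped (complete case) and counted.

Inference uses the clustered sandwich covariance over participants with the
CR1 small-sample correction `G/(G−1) · (n−1)/(n−k)` (CR0 and a naive
classical covariance are available for comparison), and a t reference
distribution with G−1 degrees of freedom (normal optional). Predictive
margins follow the marginal-standardization convention: the average
prediction over all analysis rows with the cell (or, for trajectories, the
focal continuous variable) pinned and every other covariate kept at its
observed value. Margins and contrasts are linear in the coefficients, so
the delta-method standard error a′Va is exact. Spline bases are frozen to
the training range; evaluation outside the boundary knots is an error (no
extrapolation), so trajectory grids must lie inside the observed range.
No multiplicity adjustment is applied; p-values are reported raw.

## Synthetic-data generator

`simulate_cohort` emulates the joint structure of a two-decade real-world
cohort plus a single-visit research reference cohort:

- **Participants**: women born 1932–1941, split into an `OSTPRE`-like
  register cohort (~1.3 scans per participant via Poisson extra visits) and
  an `ADNI`-like reference cohort (one baseline visit each).
- **Latent cognition**: a progressive multistate process NMC→SMC→MCI→D with
  exponential waiting times (default hazards 0.07, 0.12, 0.35 per year from
  age 60) — the simplest process consistent with strictly ordered,
  non-reversing categories. Defaults give a scan-level status mix close to
  40/20/8/32% (NMC/SMC/MCI/D).
- **Register events**: one event per reached transition, dated at the
  transition plus a gamma-distributed reporting delay (shape 2, scale 45
  days ≈ 3-month mean lag), in a random register, with optional repeat
  events — so register-derived status can lag latent truth, exercising the
  upgrade rule.
- **Scan series**: each visit carries 1 + Poisson(1.2) series drawn from a
  protocol vocabulary covering every selection-filter branch (eligible 3-D
  T1s, a thin-slice 2-D T1, a contrast-enhanced T1, a 2-D FLAIR, a 3-D T2
  matching the loose pattern, an unmatched DWI); procedure codes are
  head codes except a 5% non-head admixture. Scanner mixes are
  cohort-specific (register cohort predominantly Siemens / 1.5 T, reference
  cohort more 3 T and GE).
- **Volumes** (ml, per ROI): baseline + TIV slope · (TIV − mean) + age
  slope · (age − 75) [+ optional quadratic] + scale_ml · (status effect +
  scanner offset + participant intercept + noise). Status effects are
  standardized shifts; the defaults are the published adjusted between-group
  differences for the register cohort (gray matter 0/−0.19/−0.59/−0.66,
  hippocampus 0/−0.17/−0.59/−1.01, ventricles 0/+0.09/+0.26/+0.44).
  Pipeline-B totals are pipeline-A plus concordance noise (per-ROI ml:
  gray matter 5, hippocampus 0.1, ventricles 0.8 — a free parameter, since
  inter-pipeline concordance variance is not published; chosen ≈ 1–10% of
  each ROI's between-subject SD so concordance noise is visible but
  subdominant), except injected outlier scans (default rate 1%) where one
  ROI is displaced by ±20× its concordance SD. A configurable fraction
  (default 8%) of scans receives a quality percentage below the gate.
- All dates are on a daily grid (the status window rule is day-resolved);
  a single seed drives everything, and identical config + seed reproduces
  every table byte-for-byte.

`simulate_analysis_rows` generates modelling observations directly on the
standardized scale (participant random intercept + residual, optional age
and TIV functions) for calibration studies of the statistical engine, where
simulating the full four-table structure would only add noise channels
irrelevant to the property under study.

**What the generator does not emulate**: real DICOM pixel data and actual
segmentation error (volumes are drawn from the model above, so pipeline
disagreement is pure noise plus injected displacements, not artifact-driven);
informative missingness (who gets scanned is independent of status);
mortality and loss to follow-up; site- or time-drift in scanner protocols;
register coding error other than reporting delay. Passing tests therefore
demonstrate the correctness and calibration of the *algorithms* under the
stated data-generating assumptions, not the clinical validity of any
specific threshold on real data.

## Study sizes used in the checks

The shipped checks size their simulations to characterise the methods while
remaining convenient to rerun: outlier operating characteristics pool 100
replicates of ~500-scan cohorts at a 2% outlier rate; type-I error uses
1000 null replicates of 650 scans with intra-participant correlation 0.8
and ~1.3 scans/participant; effect recovery uses 500 replicates of 1000
scans with a true NMC−D shift of 1.0; the margin-ordering check uses
monotone effects with adjacent gaps of ~0.3 SD and a balanced status mix
(strict-ordering recovery is only a meaningful target when the configured
truth is strictly separated — the default effect sizes contain a 0.07-SD
gray-matter MCI−D gap that no estimator orders reliably); trajectory
recovery compares curve shape (level-centred) against a known quadratic age
effect across 5 replicates of 2000 scans.

## Known limitations

- The selection filter inherits the printed rule's recall/precision
  trade-off; no learned sequence classifier is included (deliberately out
  of scope).
- Robust-fit scale estimation uses the plain MAD without leverage
  correction; with fewer than ~10 scans the concordance check is refused
  (minimum 5) and flags are unreliable below ~20.
- With very small status×cohort cells the cluster-robust t(G−1) intervals
  can undercover (G counts all clusters, not the cell's); the effect shows
  up in small demo runs and disappears with realistic cell sizes.
- Pipeline reports omit wall-clock timestamps from written artifacts so
  that reruns are byte-identical; provenance carries the config hash and
  seed instead.
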