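# Methods

## Model

Each class `k` is a Gaussian `N(m_k, Σ_k)` (univariate models store the SD
`s_k` rather than the variance) with prior weight `p(k)`; the weights sum to
one under the closed-world assumption, so the prior-weighted likelihood sum
is the full density of an observation — the *evidence*.  All densities are
evaluated in log space and the evidence as a log-sum-exp, so posteriors
remain exact arbitrarily deep in the tails; a case is flagged as having zero
evidence only when every class log-density is `-inf`, which finite input
cannot produce for finite parameters.  Maximum-posterior classification
breaks exact ties toward the lowest component index (deterministic and
order-stable).

**Decision boundaries (1-D).**  Boundaries are the roots of the pairwise
differences of log weighted likelihoods.  The difference is scanned on a
4096-point grid over the search range (default: data range padded by five
times the largest component SD) and each sign change is refined by Brent
bracketing (`xtol = 1e-10`); roots closer than 1e-4 are merged.  Root
refinement rather than a grid scan is used so reported boundaries are exact
to well below the two decimals at which they are usually quoted.

## The evidence threshold ε

The ABC analysis sorts positive values descending and considers the
effort/yield curve (fraction of items vs cumulative share of the total).
Set boundaries:

* **B–C limit (used for ε):** the last item whose value is at least the mean
  of all values — equivalently, the last point where the per-item slope of
  the piecewise-linear yield curve is ≥ 1 ("profit gain equals the effort").
  ε is the first value past that point, i.e. the largest member of the
  "trivial many"; the downstream comparison is strict (`evidence < ε`).
* **A–B limit (reported, unused):** the curve point closest to the ideal
  point (0, 1).
* Degenerate all-equal input: C is empty and ε is the common value, so the
  strict comparison flags nothing.

**Evidence source.**  ε is computed by default from the model evidence at
*equidistant supporting points* across the data range, not from the
empirical evidence values of the cases.  The two differ materially: sampled
cases concentrate where evidence is high, which drags the ABC break-even
point upward until 40–60% of cases fall in set C; the grid version measures
the *shape* of the evidence function instead and flags only genuinely
low-density regions.  On a normal density with a wide grid it keeps
approximately the central ±2 s (measured 1.53–1.93 s for grid ranges between
±4 s and ±8 s; 1.67 s at ±5 s), against ±3.035 s for the 1%-of-maximum
alternative.  Empirical mode remains available (`source="empirical"`).

**Grid range.**  The "data range of interest" is operationalised as the
per-feature data range padded by **one** largest-component-SD on each side,
with 1000 points in 1-D and a 128×128 mesh in 2-D.  The padding matters
because the grid mean (≈ 1/volume for a normalised density) sets the
break-even point: no padding makes ε track the sample extremes and flag
~10% of cases; very wide padding (5 s) dilutes the grid with far-field
zeros and flags under 2%.  One SD of padding puts ε between those regimes
(≈ 5–7% flagged on the worked scenarios), which matches the intended
"marginal regions only" behaviour while leaving part of the lowest-evidence
decile classified — necessary for the decile comparison below to be
defined.  This choice was fixed once, during design, and applies everywhere.

## Robust relabelling

Reasonable Bayes replaces the label with an `UNCERTAIN` sentinel where
`evidence < ε` (serialised as a missing value in CSV output).  Plausible
Bayes assigns each suspended case to the class with the nearest center,
centers being the component means (the distribution's expected value).
Nearest-center assignment is mathematically identical to Voronoi-cell
membership for point queries and needs no explicit tessellation, so it works
for any dimension.  Distances are raw Euclidean by default; an optional
z-score metric divides each feature by the prior-weighted RMS component SD.
Distance ties resolve to the lowest class index.  The step is idempotent and
never alters a classified case.

## Fitting

* **Labelled fit:** per-class sample means and SDs/covariances (`ddof = 1`).
  Default priors are *equal* rather than proportional to group size: the
  worked examples' published boundaries (150.43/159.55 cm; 159 ng/mL with
  groups of 102 vs 301) reproduce only under equal priors.  Frequency
  priors are available as an option.
* **EM fit:** standard expectation–maximisation for a `c`-component
  Gaussian mixture.  Initialisation by k-means++ seeding followed by one
  hard-assignment M-step; 5 restarts by default (3 inside the bootstrap),
  best final log-likelihood wins; convergence at relative log-likelihood
  change ≤ 1e-6; singular covariance updates receive a diagonal ridge of
  `1e-6 · trace/d`.  The winning run's per-iteration log-likelihood
  trajectory is kept on the result (`fit_info`) and is nondecreasing up to
  1e-8 — this trace is part of the tested contract, which is why EM is
  implemented here rather than delegated (scikit-learn's mixture serves as
  an independent cross-check in the tests).  Components are relabelled
  0..c-1 by ascending first-coordinate mean for determinism.

## Synthetic scenarios

The generators reproduce the statistical structure of three worked examples
so the whole pipeline is testable without downloads.  All are seeded
(`numpy.random.default_rng`) and bit-reproducible.

* **heights** — girls `N(149.8081, 0.5843)` and boys `N(151.0295, 0.5108)`,
  100 draws each, plus 16 unlabelled grid heights 140, 142, …, 170 cm.
* **biomarker** — C18Cer: patients `N(74.3881, 36.2643)` (n = 102),
  controls `N(86.8806, 29.8202)` (n = 301).  The Gaussian model admits
  negative concentrations; they are deliberately not truncated.
* **cytometry** — a three-population CD45/CD13 panel, n = 20 000:
  a broad double-negative class 1 at (0, 0) with covariance `4·I`, and two
  tight classes at (8, 4) (CD45+/CD13+) and (8, 0) (CD45+/CD13−) with
  covariance `I`, weights 1/3 each.  The real panel's mixture parameters are
  not published; these constants are documented package constants chosen to
  reproduce the qualitative geometry: the broad class has 16× the
  generalized variance of the tight ones, and a nonempty set of tight-class
  tail events (~20 per dataset) attains higher weighted likelihood under
  the broad component — the misassignment mechanism the robust rules
  target.  Plausible Bayes strictly reduces that misassignment count.

**What the generators do not emulate:** real FACS populations are not
Gaussian (bounded, skewed, with instrument artefacts), reference labels on
real data come from expert gating rather than from the generating mixture,
and real panels have more events and markers.  Passing tests therefore
demonstrate the mechanics and internal consistency of the method on its own
model assumptions, not its accuracy gains on any particular real dataset.

## Bootstrap protocol

`bootstrap_experiment` draws B = 100 resamples with replacement (a replicate
that loses an entire class is redrawn, at most 10 times), refits the model
per replicate — from the labels for two-class scenarios, by EM with a
replicate seed for mixtures (fitted components matched to truth classes by
Hungarian assignment on the contingency table) — recomputes ε, applies all
three rules, and scores them overall and on the cases below the replicate's
own 10th-percentile evidence.  Replicate accuracies are summarised as
mean ± SD with the nonparametric 95% CI (2.5th/97.5th percentiles, type-7
linear interpolation — the numpy default).  Reasonable-Bayes accuracy is
computed on classified cases only, with the suspended count reported
separately; a subset whose cases are all suspended contributes no value.

**What the decile comparison can and cannot show.**  When the classifier
uses the same model family the data were generated from, plain Bayes is the
accuracy-optimal decision rule: in any region where the nearest-center
label disagrees with the Bayes label, the Bayes label has the larger
weighted class density by construction, so *relabelling* cannot raise
expected accuracy on-model — and measured plausible-Bayes decile accuracy
is indeed a few points below plain Bayes here (≈ 90% vs ≈ 97%).  What
abstention *can* do on-model is raise the accuracy of the decisions that
are still made: the suspended cases carry the decile's highest error rates
(tail grab zones and the low-density saddle between the tight populations),
so reasonable Bayes scores ≈ 1–2 points above plain Bayes on the decile's
classified cases (≈ 98.4% vs ≈ 96.9% at B = 100).  The relabelling step's
value on real data comes from model misspecification — gated reference
labels and non-Gaussian populations — which an on-model synthetic cannot
represent; the package reports all three accuracies and asserts only the
abstention contrast.

## Numerical and interface choices

* Evidence underflow is impossible to mis-handle downstream: posteriors are
  formed in log space and a defined-flag accompanies the posterior table.
* CSV dialect: comma (tab for `.tsv`), "." decimal, UTF-8, header required;
  empty field or "NA" = missing label; parse errors name row and column.
* Model configs (JSON/YAML) round-trip exactly; pipeline outputs embed the
  full configuration, seed, ε and package version for provenance.
* All randomness flows from a single `default_rng(seed)`; derived seeds stay
  below 2³¹.

## Problem sizes used in the shipped checks

Decision-boundary and ABC-calibration checks are closed-form-scale (grids of
≤ 10⁵ points).  Moment-convergence checks use n = 10⁵ draws per group.  The
bootstrap contrast uses the full n = 20 000-event panel with B = 100
replicates and 3 EM restarts per replicate (~1 minute on one core).
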