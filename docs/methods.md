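# Methods

This note documents the models and procedures implemented in
`flocknet`, the defaults they ship with, the numerical choices that are
not obvious from the code, and what the synthetic validation does and
does not establish.

## Association definitions

All three detectors operate within a *block* — one feeder location, by
default further split by calendar date (a grouping event never spans
midnight). Co-occurrence across locations never creates a group.

**Strict time window.** Detections in a block are sorted and split at
gaps larger than Δt; each maximal chain is one grouping event. This
split is provably the transitive closure of the pairwise "within Δt"
relation (two detections are in the same component exactly when no gap
on the sorted path between them exceeds Δt), and the test suite checks
it against a union-find oracle. The default Δt of 1 s captures strict
physical and temporal proximity at the feeder. By default raw reads
feed the detector, so a continuously present bird can bridge chains; an
optional per-individual thinning (`thin_interval`) collapses repeat
reads within the hardware interval for analysts who prefer visit-level
data.

**Gathering events.** Within each block, detection times are first
pre-split at gaps longer than `presplit_gap` (default 30 min — longer
than any plausible within-event lull, which bounds the number of events
a single mixture must consider). Each segment is modelled as a 1-D
Gaussian mixture over candidate component counts K = 1 …
min(25, ⌈n/5⌉); K is chosen by BIC, each detection is hard-assigned to
its maximum-responsibility component, and an event spans the min/max of
its assigned times. This is a deliberately simple finite-mixture event
detector with model selection, not a re-implementation of any
particular published event-detection algorithm; its behaviour is
validated on synthetic bursts with known memberships. Numerical
choices: `reg_covar = 1e-3` s² floors component variances (sub-50 ms
events are below hardware resolution); a fixed `random_state` makes
fitting deterministic; the BIC scan stops after three consecutive
non-improvements (the BIC-vs-K curve is near-convex here, and the early
stop cuts the cost of dense blocks substantially); a segment whose
mixture fails to converge at every K falls back to a plain gap split at
60 s and logs a warning; blocks with fewer than two detections form one
trivial event.

**Arrival time.** An *arrival* is an individual's first detection at a
location after an absence longer than Δi (default 300 s — long enough
that the bird plausibly left the feeding area). The chain rule is then
applied to arrivals with Δt = 150 s. Arrivals are computed per
individual per location; with multiple feeders, a bird can hold an
active visit at each. Because association is measured only at the
point of arrival, a long-staying bird does not chain later arrivals to
earlier ones — the behaviour that distinguishes this definition from
the strict window.

Singleton groups are retained in the GBI: they contribute to SRI
denominators and to the degree-0 pruning performed later at the network
stage.

## Networks and metrics

The simple ratio index weights dyad (a, b) by x / (x + yₐ + y_b) with
x = joint group memberships and yₐ, y_b = memberships of exactly one.
Dyads that never co-occur get weight 0 (no edge), not NaN. Degree-0
individuals are removed before metric extraction (`prune_isolates`,
idempotent). Betweenness treats edge weights as proximities and
converts them to costs by the reciprocal 1/w — the convention of the
standard graph libraries this field uses; counts are unnormalized,
endpoints excluded, and equal-cost geodesics split fractionally.
Unnormalized counts were chosen because they are the directly
interpretable "number of shortest paths through the node" and match the
magnitudes (tens to hundreds) typical of feeder networks; a normalized
variant is not offered.

## Similarity statistics and the permutation null

Networks are aligned on the union of their node sets with missing dyads
as 0 before any matrix statistic. Jaccard similarities use strictly
positive SRI weight as edge presence, with the convention that two
empty sets are identical (similarity 1). MRQAP standardizes the
off-diagonal entries of both matrices and reports the OLS slope (for a
single standardized predictor this equals the Pearson matrix
correlation); significance comes from jointly permuting rows and
columns of the predictor matrix, two-sided. With one predictor this
simple Y-permutation coincides in expectation with the semi-partialing
variant, so the latter is not implemented. The Mantel test is one-sided
(greater), matching the common "more similar than chance" question; the
test suite cross-checks the correlation against an independent
implementation (scikit-bio) and the sampled p against exhaustive
enumeration of node permutations on five-node problems. All empirical
p-values use the (1 + k) / (1 + n_perm) correction, so the attainable
floor is 1/(1 + n_perm).

The pre-network permutation null shuffles each individual's GBI column
without replacement — each bird keeps its number of group memberships
while group composition is randomised — then rebuilds both SRI networks
and recomputes the statistic, independently re-permuting both GBIs per
replicate. Degenerate permuted networks (no edges, hence undefined
correlation) count as zero similarity rather than aborting the null
distribution. Calibration was checked by simulation: in worlds with no
social units (solo visits only), the empirical p for the similarity of
two independent weeks is approximately uniform (the 5% rejection rate
stays inside its binomial 95% band over 200 replicates).

## Repeatability

Weekly sub-networks differ in size and density, so metrics are z-scored
within each (week, metric) cell before variance decomposition; a cell
with zero spread z-scores to all-zeros rather than NaN. Individuals
pruned as isolates in a week contribute no rows for that week (they are
treated as unobserved, consistent with degree-0 removal); weeks whose
pruned network keeps fewer than two individuals are skipped with a
warning.

The estimand is the intraclass correlation R = σ²α / (σ²α + σ²ε) of the
random-intercept model y = μ + αᵢ + ε. The default estimator is the
one-way ANOVA moments method with Searle's n₀ for unbalanced designs,
truncating σ²α at zero; `method="reml"` fits the same model by
restricted maximum likelihood through statsmodels and agrees with the
moments estimator to numerical precision on balanced data. The moments
method is the default because it is closed-form, fast enough to sit
inside bootstrap loops and Δt sweeps, and exact for the balanced weekly
designs the pipeline produces. The 95% CI is a parametric bootstrap:
data are re-simulated from the fitted variance components over the
observed design and the estimator re-applied; R and both CI endpoints
are clipped to [0, 1]. Validation at 100 individuals × 10 weeks over 50
replicates gives CI coverage above 90% and mean absolute error well
under 0.1 at true R of 0 and 0.5.

Repeatability bands follow the conventional thresholds low (< 0.3),
medium (0.3–0.5) and high (> 0.5); both boundary values are assigned to
the medium band.

Cross-definition regressions are plain OLS of one definition's z-values
on another's over matched (individual, week) pairs; with two noisy
measures of a shared latent trait the slope estimates the attenuation
ratio var(latent)/var(latent + noise), which the tests verify against
the closed form.

The Δt sweep re-runs detection, network construction and repeatability
over a grid of Δt (Δi held at 300 s for the arrival method) and also
records the number of distinct associated dyads per grid point, which
must be non-decreasing in Δt for the window method (a structural
consequence of the refinement property: a smaller Δt always partitions
the groups of a larger one).

## The synthetic world

The generator is the package's ground-truth instrument; no field data
are bundled. Its generative model is deliberately minimal:

* **Social structure.** Individuals belong to one of `n_units` latent
  social units (sizes differing by at most one). Each individual
  carries a logit-scale sociability trait drawn once per world from
  N(0, σ²_social); its probability of joining a unit visit is
  logistic(logit(p_join) + trait). The trait is constant across weeks —
  it is the repeatable component the repeatability analysis estimates.
  The true association weight of a same-unit pair is pᵢ·pⱼ (the
  probability both show up at a unit visit); cross-unit pairs get a
  small constant background (default 0.01) for chance co-occurrence.
* **Visits.** Unit visits are a Poisson process per unit within each
  day's recording window (default 6:00 plus `hours_per_day`, 7 days a
  week); alternatively `visit_spacing` lays visits on a regular
  round-robin schedule, a well-separated regime used to validate that
  all detectors recover the true visit groups exactly. Joining members
  arrive at the visit time plus half-normal jitter (default SD 10 s —
  the "arriving together" signal the arrival definition exploits) and
  stay an Exp(stay_mean) time (default 60 s). Independent solo visits
  per individual model non-social feeder use.
* **Reads.** While present, a bird alternates on-antenna feeding bouts
  (Exp(2 s)) with off-antenna vigilance bouts (Exp(4 s)) and is read
  every `read_interval` (0.25 s open antenna, 0.5 s chamber/perch) with
  probability `p_read` while on the antenna. The bout structure is what
  makes per-individual read streams bursty, as real feeder logs are; a
  continuous-read model would let a 1-s window chain entire busy
  periods together and is available by setting `bout_off_mean = 0`.
  Chamber feeders serialize access (later arrivals queue) and log only
  the entry and exit reads; perch feeders distribute birds over k
  adjacent antennas that share one social location.
* **Reproducibility.** One RNG stream per (world seed, week), so weeks
  are independent and individually reproducible.

The reference study simulated by `scripts/acceptance.py` uses 40
individuals in 4 units, p_join 0.4 with σ_social 1.2, 0.4 unit visits
per unit-hour, 20 s arrival jitter, 6 h of recording per day and 8
weeks (~65k reads). These sizes keep every network stage
well-populated (weekly networks of ~40 nodes, thousands of grouping
events) while the whole analysis completes in well under a minute; the
large-unit/low-rate regime keeps inter-visit gaps long relative to the
300 s sweep ceiling, which is what produces the rise-then-plateau
sensitivity curve rather than runaway chain merging, and mirrors the
temporal sparsity of real feeder data.

What the simulator does **not** model: spatially explicit movement,
dominance or displacement at the feeder, territoriality, tag loss and
read collisions, diurnal activity rhythms, or drifting social
preferences. Passing tests therefore establish the *internal*
correctness and calibration of the pipeline and its qualitative
behaviour under controlled social structure — not that any particular
association definition is biologically right for a given field system.

## Known limitations

* The mixture event detector assumes roughly Gaussian bursts; heavily
  skewed events are split or truncated. Its K cap (25 per segment)
  relies on the pre-split to keep segments short; extremely dense
  streams with no 30-min lulls would need a smaller `presplit_gap`.
* MRQAP is single-predictor only; multi-matrix regression is out of
  scope.
* Repeatability is intercept-only (no covariates) on Gaussian z-scores;
  link-scale or covariate-adjusted repeatability is not provided.
* The arrival detector treats each location independently; birds
  commuting between nearby feeders within Δi are counted as present at
  both.
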