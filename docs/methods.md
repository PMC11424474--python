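# Methods

This note documents the models, estimators and numerical conventions behind
`spinisi`, the choices made where the design was genuinely open, and what
the synthetic-data experiments do and do not demonstrate about real data.

## Spine-size normalization and the bounded change score

Fluorescence intensity of a spine head is a proxy for synaptic strength,
but absolute intensities drift between imaging sessions. Each spine
measurement is therefore normalized to the adjacent dendritic shaft after
background subtraction,

    v = (spine − background) / (shaft − background),

which cancels session-wide gain changes. Values below background clip to
zero: sizes are non-negative by definition, and the bounds of the change
score depend on that. A shaft at or below background is a degenerate
annotation and raises an error naming the spine rather than producing a
sign-flipped size.

Changes are expressed relative to the mean baseline size `v̄_b` as

    Δ_d = (v_d − v̄_b) / (v_d + v̄_b),

a score confined to [−1, +1]: −1 is complete signal loss, +1 appearance
from nothing, 0 no change; it is antisymmetric under swapping the two sizes
and strictly increasing in `v_d`. The per-spine summary `Δ̄` averages `Δ_d`
over a configurable post-manipulation window (default: all post-baseline
sessions, days 1–4 under the default schedule). The average is taken over
per-session values, not over paired-session presentation averages: pairing
adjacent sessions (−3 with −2, −1 with 0, …) is a display convention
(`paired_session_average`) and is kept out of the statistics.

**Persistence rule.** A spine absent at any baseline or window session has
no defined `Δ̄`; it is excluded from size-change and clustering analyses
and appears only in the turnover metrics. This is deliberately strict —
classification requires a complete trajectory — and it is why synthetic
datasets with 5% per-session addition/elimination rates retain roughly 70%
of the initial cohort as persistent spines over an eight-session schedule.

**Turnover.** Addition and elimination rates on a session are counts of
newly appeared / disappeared spines divided by the spine count of the
previous session; the turnover ratio is stored as their exact sum, so the
identity `turnover = addition + elimination` holds to machine equality.
Dendrite-sessions with no spines at the previous session have undefined
rates and are skipped with a log message.

## Classification and the nearest-neighbour clustering test

Persistent spines are classified by `Δ̄` against a threshold `τ`:
increasing above `τ`, decreasing below `−τ`, stable otherwise (boundary
values are stable). The default `τ = 0.14` corresponds to one standard
deviation of baseline-session change scores in control animals;
`derive_threshold` recomputes it from data (sample s.d., n−1 denominator)
and falls back to the default with a warning when given fewer than two
values or a degenerate zero spread.

Pair construction: for every persistent spine, the closest other persistent
spine by distance along the traced path (positions are path coordinates,
not 3-D Euclidean). Each unordered pair enters once; pairs closer than
1.0 μm (overlapping ROIs) or farther than 3.5 μm are removed, with both
boundaries inclusive since only strictly-outside distances are excluded.
Equidistant ties break toward the smaller position, a deterministic
convention that makes pair lists reproducible; the test suite checks the
whole construction against a brute-force all-pairs oracle, including exact
ties and boundary distances. Restricting the search to persistent spines
matches the shuffle null, which permutes `Δ̄` values and therefore only
sees spines that have one; a flag for pairing over all annotated spines is
deliberately not offered, keeping the pairing and the null consistent.

Four metrics summarize the retained pairs: fractions in which both spines
increased, both decreased, changed in the same direction (the union of the
first two), or in opposite directions. Pairs containing a stable spine
count toward none of them, so same + opposite need not reach 100%. Stable
spines still participate in pairing and occupy positions during shuffling.
Fractions are reported per dendrite (for group comparisons; dendrites with
no retained pair are omitted from the denominators) and pooled over all
pairs (the Monte Carlo test statistic).

**The shuffle null.** Within each dendrite independently, the multiset of
persistent `Δ̄` values is permuted uniformly over that dendrite's spine
positions; geometry, presence and class counts are untouched, so the null
asks exactly: *given how many spines increased and decreased on each
dendrite, are same-direction pairs more common than random placement
predicts?* Because pair geometry is fixed across shuffles, the engine works
on integer pair counts with a common denominator and all tail comparisons
are exact; permutations are generated vectorized (argsort of uniform
draws), and one `numpy` generator seeded from the configuration drives the
whole test, so results are reproducible bit for bit.

**P-values and tails.** The p-value is the plain proportion of shuffled
counts at or beyond the observed count, ties included. The default tail is
`auto`: the side toward which the observation deviates from the shuffled
median, reported alongside the p-value — this reproduces both above-chance
clustering (excess same-direction pairs) and below-chance findings (deficit
of opposite-direction pairs) without doubling. An `include_observed` flag
switches to the add-one convention `(k + 1)/(n_pools + 1)`, which bounds p
away from zero.

Two calibration properties matter and are worth stating precisely:

- The `auto` tail is a two-sided procedure; under the null its p-values
  concentrate on (0, 0.5) and are *not* uniform. Calibration studies in
  this package therefore fix the exceedance (upper) tail, under which the
  one-sided p-value is approximately uniform.
- Even the fixed-tail p-value is slightly conservative, because the pair
  count is discrete and ties are counted in the tail. At the scale of the
  bundled calibration study (100 dendrites of ~8 spines, ≈190 pooled pairs)
  the modal atom of the null count distribution carries ~0.10–0.15
  probability, so the p-value distribution sits visibly above uniform
  (empirically, Kolmogorov–Smirnov distance ≈ 0.09 from U(0,1) over 500
  null datasets) while the 5%-level rejection rate stays nominal
  (0.035–0.046 across seeds). A tie-randomized variant of the same engine
  is exactly uniform, which is how this was verified to be the tail
  convention and not an implementation artefact. The conservative
  convention is kept because it matches the definition of the statistic
  (summing the tail of the shuffle histogram); users comparing p-values
  against a uniform reference at this problem size should expect that
  upward shift.

Measured operating characteristics at the default generator settings
(1,000 pools): type-I error of the both-decreased exceedance test ≈ 0.04;
detection rate under neighbour correlation 0.8 with global shift −0.1
≈ 0.82 (both-decreased) and ≈ 0.93 (same-direction) over 200 datasets.

## Synthetic spine data

The generator emulates the statistical structure of longitudinal spine
annotations, not the imaging physics. Per dendrite (a 1-D segment, default
20 μm):

- **Placement**: Poisson(rate × length) spine count (default rate
  0.4 μm⁻¹, matching adult-cortex densities of ~0.4–0.5 spines/μm),
  positions uniform with a hard-core minimum spacing of 0.5 μm enforced by
  bounded rejection; infeasible rate×spacing combinations fail explicitly.
- **Baseline sizes**: log-normal (default log-mean 0, log-s.d. 0.5) —
  fluorescence intensities are positive and right-skewed.
- **True changes**: one value per initial spine, marginally
  Normal(global_shift, change_sd²). Spatial correlation between adjacent
  spines is produced by a first-order autoregression along position order
  (lag-1 correlation exactly `neighbor_rho`; the simplest mechanism with a
  directly tunable neighbour correlation), with a squared-exponential
  Gaussian-process alternative (`mechanism="gp"`) whose length scale is
  mapped from `neighbor_rho` at the mean adjacent spacing for
  distance-aware decay. `neighbor_rho = 1` is the degenerate cap: one
  shared value per dendrite. The paper-facing analyses only *measure*
  clustering; the generative mechanism is this package's own choice.
- **Sizes over time**: baseline sessions hold the baseline size; post
  sessions hold `v̄_b (1 + Δ)/(1 − Δ)`, so the measured change score of a
  noiseless trajectory recovers Δ exactly (changes are clipped to |Δ| ≤
  0.99, a >4.9 σ event at the default change_sd of 0.2, to keep the
  implied size finite).
- **Dynamics**: at each session transition every present spine is
  eliminated with probability `elimination_rate` (and then stays absent:
  re-addition is off), and Binomial(n_present, addition_rate) new spines
  appear at fresh positions respecting the spacing. Default rates 0.05 per
  transition put roughly a third of the spine population in the
  added-or-eliminated category over the eight-session experiment,
  consistent with adult visual cortex. Added spines are outside the
  correlated change field — they can never be persistent, so no analysis
  reads a change value from them.
- **Measurement**: intensity triplets are synthesized around a constant
  background (100 counts) and net shaft level (1,000 counts); the net
  spine and shaft intensities carry independent multiplicative log-normal
  noise of unit mean and CV `noise_cv` (default 0.05). At `noise_cv = 0`
  the shaft-normalized size equals the true size exactly.
- **Sessions**: integer day labels −3…4 with baseline −3…0, the
  manipulation sitting between day 0 and day 1; an every-other-day design
  with a four-session baseline.
- **Randomness**: one root seed; per-dendrite substreams spawned via
  `numpy.random.SeedSequence`, so datasets are bit-identical given the
  configuration and reproducible under parallel generation.

What this does **not** emulate: point-spread-function effects and ROI
segmentation error, z-drift, spine-neck/shaft cross-contamination,
session-to-session registration failure, heterogeneous per-dendrite change
distributions, or any dependence of turnover on spine size. Passing tests
therefore certify the *analysis* — normalization algebra, pairing, the
permutation machinery, calibration under a known null — not robustness to
those real-world artefacts.

## Intrinsic-signal analysis

The periodic-stimulus movie model is, per pixel,
`amp · cos(2π f t + φ) + drift + noise` with a linear phase gradient across
rows (retinotopy), recorded at 7.5 Hz (30 Hz binned by four) for an integer
number of cycles of a 0.125 Hz stimulus by default.

**Response extraction.** Amplitude and phase come from the DFT bin nearest
the stimulus frequency, estimated by least squares jointly with an
intercept and a linear trend per pixel. On cycle-aligned data the
quadrature regressors are orthogonal and the estimate coincides with the
classical `2|c|/n`-scaled single-bin Fourier coefficient of the detrended
series; fitting the trend jointly rather than detrending first matters
because a separately fitted line is not orthogonal to the stimulus bin and
leaks a bias of order `0.6/k²` (k = cycles recorded) into the amplitude —
several percent at five cycles. The joint fit is exact for the
cosine-plus-drift signal class: noiseless recovery error is at the
floating-point level, and a pure linear ramp contributes nothing. A
stimulus frequency more than ~1.5 frames' worth of cycle off the bin grid
raises an error instructing cycle-aligned trimming; hemodynamic-delay
correction via opposed stimulus directions is out of scope (amplitude maps
from repeated measurements can be combined with `average_amplitude`, which
warns below the conventional four).

**Ocular dominance.** The binocular ROI is the ipsilateral-eye amplitude
map smoothed with a 5×5 uniform kernel (reflect padding — preserves the
map mean near borders and keeps masks bit-reproducible) and thresholded at
40% of its smoothed peak, boundary equality included, so the mask is
invariant to positive rescaling. Scores `(C − I)/(C + I)` are computed on
ROI pixels with `C + I > 0` (zero-sum pixels are excluded and counted);
the ODI is their mean. ODI is antisymmetric in the two maps and invariant
under joint positive rescaling to 1e−12, and lies in [−1, 1] by
construction. Pixel coordinates are 0-based row-major; masks serialize as
0/1 single-frame TIFFs.

## Numerical and interface conventions

- Day labels are integers relative to the manipulation (day 0 = last
  pre-manipulation session); baseline sessions are a prefix of the
  schedule and made explicit in configuration rather than inferred.
- CSV interchange is comma-separated UTF-8 with a mandatory header, one
  row per spine × session; missing rows read back as absences; presence
  gaps (present → absent → present) are rejected unless re-addition is
  explicitly allowed. An optional `dendrite_length_um` column carries the
  traced segment length, which density needs and positions alone cannot
  provide; readers without it fall back to the maximum position with a
  warning.
- Both-zero sizes make the change score undefined; the affected
  spine-session is excluded with a logged reason rather than silently
  producing 0/0.
- Problem sizes in the bundled studies (500 null datasets and 200
  clustered datasets of 100 dendrites each at 1,000 pools; 10,000 pools
  for single-dataset analyses) were chosen to estimate rejection rates to
  ±2–3 percentage points; the permutation engine's vectorization keeps a
  full dataset's test under ~50 ms, so larger designs scale linearly.

## Known limitations

- The permutation test conditions on per-dendrite class counts; it has no
  power against clustering expressed purely *between* dendrites.
- The AR(1) change field correlates spines by rank order, not distance;
  use the GP mechanism when inter-spine distances vary strongly.
- The single-bin estimator assumes a stationary sinusoidal response;
  slow amplitude drifts beyond linear are not modelled.
- Group-level comparisons between genotypes (t-tests/ANOVA over
  per-dendrite fractions) are left to standard statistical software; the
  package emits the per-dendrite tables they consume.
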