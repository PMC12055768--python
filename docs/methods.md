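# Methods

## Scope and data model

The package operates on two representations of a coded dyadic
interaction:

* **Code streams** — one SPAFF code per second per actor. The 20-code
  registry is fixed; codes group into five meta-states (Positive
  Affect = Affection/Humor/Surprise-Joy; Facilitate = Low/High
  Validation/Interest; Negative Affect = Anger/Sadness/Whining/Disgust/
  Contempt/Tension/Tense Humor; Control = Belligerence/Low and High
  Domineering/Criticism/Defensiveness/Stonewalling; Neutral) and into a
  positive/negative valence split used for session totals. Tense Humor
  is counted on the negative side: although some code lists group it
  with the positive codes, the published session-total arithmetic and
  the meta-state grouping both place it with the tension-related codes,
  and the totals only reproduce under that convention.
* **Weighted window series** — each second's code replaced by a signed
  weight and summed over half-open windows `[6k, 6k+6)`; trailing
  partial windows are dropped. The default weights (±4 strong, ±2/−1
  mild, −2…−4 hostile, Neutral +0.1) follow the weighting conventions
  of the marital-interaction literature this model family comes from;
  they are an implementer default, fully overridable from a YAML
  config, and never treated as ground truth. All downstream statistics
  that matter here are invariant to the choice in the relevant sense
  (the KS references are location-scale/scale families; the model is
  estimated on whatever scale the weights induce).

Session descriptives (seconds, percentages, valence totals,
meta-states) are exact integer arithmetic on the stream; percentages
always come from exact seconds divided by the session's total coded
seconds. Session lengths are not stored separately: the total is the
row sum of the per-code seconds, which is also what reproduces the
published percentages (2700 s typical, 2621 s in session 2, 1800 s in
the client's session 4).

## Kolmogorov–Smirnov session comparison

Per code (or meta-state), the n per-session percentages are tested
against a reference distribution **fitted to the sample**: a normal
with the sample mean and n−1 SD, or an exponential with rate 1/mean.
The statistic is

    D = max_i max( F_n(x_i) − F(x_i), F(x_i) − F_n(x_i⁻) )

with left limits at ties — essential here, since sparse codes produce
many repeated zeros, and with an exponential reference the entire
statistic is often the jump of the empirical CDF at zero (k zeros of n
give D ≥ k/n). The reference family is a caller decision: the packaged
fixtures pin, per variable, the family under which each published D
value reproduces (fitted normal for the therapist's per-code tests and
the client's meta-state test; fitted exponential on exact percentages
for the client's per-code tests and the therapist's Control
meta-state).

Two p-value conventions are provided and labelled, because they differ
materially at n = 6:

* `exact_kolmogorov` — the classical exact finite-n null
  P(Dₙ ≥ D) (scipy's `kstwo`), which ignores that the reference
  parameters were estimated. Under it, D ≈ 0.36–0.50 at n = 6 is not
  significant at α = 0.05.
* `monte_carlo` — a parametric bootstrap (simulate n draws from the
  fitted family, refit, recompute D, repeat) that accounts for
  estimation, in the spirit of the Lilliefors correction. Both
  references are (location-)scale families, so D's null distribution
  does not depend on the fitted parameter values and simulation from
  the standard member is exact. This null is stochastically smaller,
  so the same D is more significant.

Identically zero variables are flagged degenerate rather than tested;
constant samples cannot support a fitted-normal reference and are
likewise flagged in scans (an error in the low-level call).

## The dyadic model and its estimation

The windowed scores evolve by the simultaneous-update map given in the
README. Design choices:

* **Discrete time.** The model family is often written in derivative
  notation, but the reported parameters (an inertia multiplier, a
  steady state a/(1−r)) are only consistent with the discrete map;
  one time step is one 6-s window.
* **Simultaneous update** of both actors, since the therapy dyad has
  no prescribed turn structure.
* **Influence** I(z) is continuous piecewise-linear with a dead zone:
  `neg_slope·(z − nth)` for z ≤ nth, 0 between the thresholds,
  `pos_slope·(z − pth)` for z ≥ pth. Thresholds need not straddle
  zero (several published sessions have both negative). One absent
  threshold gives a bilinear function, both absent the null function.
* **Repair** R(z) = sr for z ≤ kr (else 0) — a discontinuous constant
  boost, read as threshold kr / strength sr, matching the sign pattern
  (kr ≤ 0, sr > 0) of all published rows.

Estimation proceeds in stages, all ordinary least squares:

1. **(a, r)** from transitions where the partner is neutral —
  window score within |z| ≤ ε. The default band in `fit_dyad` is
  ε = 0.25; note that under the default weight table a fully Neutral
  window scores 0.6, so callers working with mostly-neutral real
  streams will want ε = 0.6 (the CLI exposes `--epsilon`). With
  ε = None every transition is used, appropriate when the partner is
  known to exert no influence.
2. **Influence thresholds** by exhaustive scan over the distinct
  observed partner scores, fitting regime slopes to the stage-1
  residuals. The two regimes have disjoint support, so the slope fits
  decouple and each candidate's SSE reduction has the closed form
  (Σe·u)²/Σu²; the scan is O(k²) in the number of distinct scores with
  O(1) work per pair. A regime needs ≥ 3 supporting points, mirroring
  the published "N/A" cells; SSE ties break toward the smallest total
  threshold magnitude (preferring the simpler/most local kink).
3. **Repair** by scanning negative candidate thresholds with ≥ 3
  points at or below. For each candidate the strength is refitted
  *jointly* with the influence slopes (the regressors overlap below
  kr; the marginal mean residual would be biased whenever influence is
  active — the joint fit reduces to the mean lift when influence is
  null). The term is kept only if the best candidate has positive
  strength and survives a partial F-test at α = 0.05 against the
  no-repair fit; a free parameter would otherwise always "activate"
  under noise.
4. **Joint refinement.** With thresholds profiled, all linear
  parameters — a, r, both slopes, the repair strength — are refitted
  in one regression over *every* transition (dead-zone windows simply
  contribute zero regime columns). This is the standard
  profile-the-thresholds-then-LS treatment of piecewise-linear models
  and roughly halves the (a, r) error relative to using only the
  partner-neutral subset.

## Phase portraits

The influence/repair breakpoints partition the (client, therapist)
plane into rectangles on which the map is affine, so critical points
are found exactly: solve the 2×2 fixed-point system per region, keep
solutions lying in their own region (edge tolerance 1e-9), verify
against the true map (tolerance 1e-8 — this also resolves points on
the discontinuous repair boundary), and deduplicate at 1e-6.
Stability comes from the region Jacobian `[[r_T, s_T], [s_C, r_C]]`:
attractor if both eigenvalue moduli < 1, saddle if exactly one > 1,
repeller otherwise. Outer (unbounded) regions can hold genuine fixed
points far outside any plotting window; consumers should filter to
their domain of interest.

Portrait defaults: a [−12, 12]² lattice at step 1 of starting
coordinates (covering ±4 weights × 6-s windows with moderate
persistence), 10 iterations per trajectory, with an overflow guard
truncating divergent paths. The session's projected trajectory starts
from the mean of the first 10% of windows per actor (client on x,
therapist on y). Because the published parameter tables omit the
influence slopes, portraits rebuilt from a parameter CSV take slopes
from configuration (default 0.5 per active regime) and support only
qualitative reading — quadrant structure and attractor count — not
coordinate-level reproduction. Rendering is deterministic
(byte-identical PNGs for identical portraits).

## Synthetic data

Two generators provide ground truth where no raw streams exist:

* **Sticky Markov streams** — with probability `persistence` repeat
  the previous second's code, else draw from the stationary
  propensities. This emulates the long Neutral runs of real coded
  sessions (realistic settings: ~0.9 Neutral propensity, persistence
  0.6–0.8, 1800–2700 s). It does **not** emulate cross-actor
  contingency at the code level, within-session drift, or coder
  disagreement — so passing tests demonstrate pipeline correctness,
  not behavioral realism.
* **Dyad series** — iterate the map from the steady states plus a
  Gaussian start perturbation (sd 1), adding independent Gaussian
  window noise each step. Additive Gaussian noise is the perturbation
  consistent with least-squares estimation; it propagates through the
  dynamics, making the series a proper (piecewise) vector
  autoregression.
* **Exact inverse** — `stream_for_series` emits per-second codes whose
  windowed weighted sums reproduce a given series exactly, via dynamic
  programming on the integerized weight grid (weights must live on a
  0.01 grid), preferring balanced compositions and breaking ties with
  the seeded rng. Unachievable scores raise with the window index.

All generators are bit-reproducible under a fixed seed.

The parameter-recovery study (the pipeline's principal validation,
since raw session streams are unavailable) uses 100 dyads with
per-actor a ~ U(−0.3, 0.3), r ~ U(0.2, 0.6), trilinear influence with
thresholds ±0.8 and slopes 0.5 in both directions, noise sd 0.5, 150
windows, estimated with ε = 0.25 (inside the true dead zone, so
partner-neutral selection is exact under the truth). Median absolute
errors observed: ≈ 0.06 for a and r, ≈ 0.4 for the thresholds. The
threshold design keeps the kinks inside the scores' typical range; far
thresholds relative to the score spread are intrinsically hard to
localize, which is also why several published sessions lack one.

## Numerical conventions and degenerate inputs

* Sample SD uses the n−1 denominator throughout (the convention of the
  common commercial packages; confirmed by the reproduction of the
  published D values).
* Threshold-scan SSE ties: relative tolerance 1e-9, then smallest
  threshold magnitude.
* r = 1 has no steady state and is rejected in `steady_state`; the
  portrait machinery skips regions whose fixed-point system is
  singular (det < 1e-14).
* Iteration truncates when |state| exceeds an overflow guard (default
  1e9); the dyad simulator raises with the offending window index.
* Empty streams, unknown codes (reported with time index/line number),
  duplicated or non-contiguous seconds, and constant samples under a
  normal reference are all rejected with specific messages.

## Known limitations

* A handful of published table entries are internally inconsistent
  (three totals differ from their own row sums by a few seconds;
  several percentages do not follow from their seconds). The fixtures
  record the printed values verbatim and derived quantities always use
  the row-sum arithmetic; the exceptions are listed in
  `affectdyn.fixtures`. Two published D values (client High Validation
  0.424, therapist Positive Affect meta 0.486) are not reproduced by
  any reference/variable combination tried and are kept for the record
  only.
* The repair term is identified only when the partner actually spends
  ≥ 3 windows below a candidate threshold; with positive-leaning
  partners it is structurally inactive.
* Influence slopes are not part of the published parameter layout, so
  round trips through a parameter CSV lose them by design.
* The KS scan applies no multiple-testing correction, matching the
  analysis it reimplements; at 20 codes per actor some significant D
  values are expected by chance.
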