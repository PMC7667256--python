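# Methods

## Decision problem and perspective

The package models a two-arm comparison of glioma surgery with and without
low-field intraoperative MR (LF-iMR) guidance from a hospital perspective:
only direct health costs, EUR 2018, one-year analytic horizon, no
discounting. Effectiveness endpoints are the mean postoperative Karnofsky
performance status (pKPS, 0–100 in steps of 10), the composite R-KPS
(gross-total or subtotal resection with conserved or improved KPS,
expressed in percentage points so ICERs read "EUR per additional
percentage point"), and 1-year progression-free survival as the restricted
mean of PFS days censored at 365. Overall survival at one and two years,
complication and resection rates are computed descriptively; they do not
enter the ICERs because the underlying study found no significant arm
difference.

## Costing model

Per-patient cost is additive over five categories:

* **Operating room** — surgical minutes × 5 EUR/min, plus the surgical
  pack (1,150 EUR), neuronavigation (862 EUR), prosthesis (272 EUR) and
  the amortized device cost when each was used. The device enters this
  category: 1,000,000 EUR spread over a 10-year life cycle at 120
  interventions/year = 833.33 EUR per case.
* **ICU** — ICU days × 555 EUR/day. Days among admitted patients are not
  published; they are calibrated from the published ICU category costs:
  717/(0.67×555) ≈ 1.93 d (conventional), 472/(0.34×555) ≈ 2.50 d (LF-iMR).
* **Imaging** — postoperative image counts × modality prices (MR with
  contrast 203, MR 138, PET 566, X-ray 15, portable X-ray 32, SPECT 166,
  CT 72 EUR). Only postoperative images are priced: the postoperative
  means × prices reconstruct the published "diagnostic images" category to
  within rounding, whereas adding preoperative images overshoots it by
  more than 45%. Preoperative counts stay in the data model and can be
  reported separately.
* **Hospitalization** — ward days × 422 EUR/day.
* **Residual** — a per-arm constant (381 EUR conventional, 706 EUR LF-iMR)
  that reconciles the four published category means with the published
  per-patient totals (10,810 / 11,599 EUR), which do not otherwise sum.
  The source does not itemize this gap; carrying it as an explicit
  constant keeps the totals faithful without distorting any category.

Costs are homogeneous of degree one in unit prices and additive over
resource items; both properties are asserted by tests.

## Base case and scenario analysis

The base case can be built from the published summary inputs
(exact-reproduction mode) or from synthetic cohorts (simulation mode);
both are first-class entry points. In exact-reproduction mode the
incremental cost is 789 EUR and the incremental effects are 7.1 pKPS
points, 17 R-KPS percentage points and 38 PFS days. One published
inconsistency is resolved in favour of the incremental column: the source
base-case table prints arm pKPS means of 77.1 and 84.3 together with an
incremental of 7.1 (and an ICER of 111 that only 7.1 reproduces), so the
model stores the intervention value as 77.1 + 7.1 = 84.2 while anchoring
scenario shifts at the sensitivity table's 84.

Scenarios apply overrides to named parameters (absolute values or
mean ± k·SD shifts) and re-run the incremental analysis:

* **A / B** — intervention effectiveness at mean ∓ SD using the published
  SDs (pKPS 9, R-KPS 10.4 points, PFS 76 days). The published scenario
  table lists PFS extremes of 255/410 where mean ± SD gives 257/409; the
  shifts are computed, not copied, since no SD reproduces the printed pair
  and the resulting ICER classifications are unchanged.
* **C** — device price 800,000 EUR, amortized over the base-case horizon
  (10 y × 120/y), reducing the incremental cost by 166.67 EUR. The
  published per-intervention figure of 408 EUR implies amortization over
  the 196 study patients, which contradicts the amortization convention
  that reproduces the published ICERs; the 120-interventions convention is
  used throughout.
* **D** — the high-grade-glioma sub-group, taken from its published arm
  summaries (costs 11,608/10,853; pKPS 84.1/75.5; R-KPS 55/31;
  PFS 322/284).

ICERs are reported rounded half-away-from-zero to integer euros; dominant
and dominated cells are labelled textually. Published entries that cannot
be reproduced from their own printed inputs (scenario A R-KPS 118 vs
computed 120; C R-KPS 36 vs 37; D R-KPS 44 vs 31) are not treated as
checks.

## Probabilistic sensitivity analysis

Second-order Monte Carlo: each draw samples all varied parameters
independently, rebuilds both arms' expected per-patient cost through the
costing model, samples each endpoint's arm means, and records one
(ΔE, ΔC) point per endpoint. Distribution assignments follow the
published families:

* Gamma, moment-matched (shape = (m/s)², scale = s²/m), for surgical
  minutes, length of stay, image counts, all unit prices and the
  effectiveness means; the device price uses its published SD of
  200,000 EUR.
* Beta from event counts (α = events, β = non-events) for the prosthesis
  and ICU admission proportions; Beta moment-matched to the published
  mean/SD for the R-KPS proportions.
* A 20% coefficient of variation wherever no SD is published (ICU days
  among admitted, unit prices).
* Parameters flagged "not varied" (pack, navigation and device usage
  indicators) stay fixed, and no correlation structure is imposed — the
  source reports none; independence is a modelling assumption.

Arm-level means are sampled with the *patient-level* SDs, mirroring the
spreadsheet-style PSA of the source analysis; this overstates the
uncertainty of a mean relative to its standard error and is what makes
the cost difference cross zero often enough for the dominant-quadrant mass
to be informative. Quadrant proportions assign exact-zero deltas to the
positive side (a measure-zero tie rule for continuous draws). The
deterministic model evaluated at all parameter means gives ΔC ≈ 875 EUR
rather than the published 789 EUR because the published category means are
rounded; Monte Carlo means converge to the model's own base case
(asserted at 3 MC standard errors), not to the rounded published total.
At 10,000 draws the R-KPS south-east (dominant) quadrant holds ≈ 33% of
the cloud, against the published 35%.

## Synthetic cohorts

The generator emulates the published arm-level marginals so the pipeline
runs without any deposited data: Gamma draws (moment-matched, hence
positive) for surgical minutes, length of stay, ICU days among admitted
and PFS; discretized Gamma (rounded, floored at zero) for image counts;
Bernoulli for usage, complication, reintervention, extent-of-resection
and survival indicators (2-year survival nested within 1-year). KPS
scores are latent-Normal draws rounded to the nearest 10 and clipped to
the published ranges (pre 70–100, post 60–100); the latent location is
calibrated by root-finding so the discretized mean equals the profile mean
exactly — naive rounding/clipping would bias the conventional arm's mean
by almost a point. PFS draws are censored at 365 days with
`progression_event = (draw ≤ 365)`; consequently the restricted mean
undershoots the uncensored profile mean (≈294 vs 295 conventional, ≈316 vs
333 LF-iMR), which is inherent to censoring a distribution whose mass
crosses the horizon and is why moment-recovery tests target uncensored
fields.

Parameters the publication does not print were fixed once at field-
plausible values: subtotal-resection probabilities 0.30 / 0.22 (partial
resections ≈ 14% / 8%), ICU-day SD equal to its mean (exponential-like
stays), PFS SDs taken from the sensitivity table (40 / 76 days), and
demographic marginals (age 54±15 / 53±15, ~40% female, 72% / 62%
high-grade) used only descriptively. The generator reproduces marginal
summaries, not joint structure: postoperative KPS is generated
independently of preoperative KPS and of resection class, so passing tests
demonstrate calibration of marginals and correctness of the downstream
arithmetic, not patient-level realism. With these marginals the synthetic
R-KPS proportions nevertheless land near the published 35% / 52%, and the
log-rank comparison of PFS rejects at the 5% level in almost all seeds,
consistent with the published p = 0.03.

## Numerical conventions and reproducibility

All randomness flows through explicit integer seeds into
`numpy.random.default_rng`; the same seed gives byte-identical cohorts,
PSA draws and output files. PSA parameters are sampled in sorted-name
order from a single generator, which both fixes the stream and enables
draw-wise coupling arguments (e.g. scaling the device-price distribution
scales its draws exactly, so ΔC rises draw-wise). Zero-variance
distributions collapse to fixed values; the zero-variance PSA reproduces
the deterministic base case exactly. Degenerate inputs raise explicit
errors: empty cohorts, non-positive amortization denominators, samples
with no events in the log-rank test, out-of-range CSV fields (reported
with row and field). Problem sizes in the test suite — 10,000-patient
cohorts for moment recovery, 10,000 PSA draws, 100 seed replicates for
the log-rank power check — were chosen as the smallest sizes at which the
3–4 standard-error bands are meaningfully tight.

## Known limitations

* No quality-adjusted life years, willingness-to-pay threshold or
  acceptability curves; the source analysis fixes no threshold.
* No joint modelling of demographics or of KPS with resection class; no
  competing-risks treatment (deaths before progression count as
  progression events).
* The residual cost category is a calibration constant, not an itemized
  cost, and the PSA leaves it fixed.
* One-year cost and effectiveness horizon; nothing is said about longer-
  term cost-effectiveness.
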