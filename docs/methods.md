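# Methods

## The model

The analysis treats each unit (25 districts plus a NATIONAL pseudo-unit) ×
indicator (IMR, MMR; deaths per 1,000 live births) as an interrupted time
series with a single break at the 1983 onset of war.  Its counterfactual is
deliberately minimal: continue the pre-war average annual proportional rate
of change from the 1982 baseline and compare the projection with what was
achieved by the conflict endpoint (2002, the third ceasefire; 1999 where
2002 data are unavailable).

**Trend estimator.**  r = ((V_end − V_start)/V_start)/n over a window; a
two-point estimator, not a regression — the sources are sparse annual
administrative series and the published analysis is defined this way.  The
district pre-war window is 1975–1982; national analyses use 1977–1982
(5-year) and 1972–1982 (10-year) variants.  If the window's start year is
unobserved, the earliest observation inside the window substitutes and the
actual span is recorded.  Fewer than two usable observations, or a zero
base value, make the window *not assessable*; this propagates as a value,
never an exception, because unassessable districts are a finding (they
appear in the published tables as "Unable to determine").

**Projection shapes.**  The default is discrete annual compounding,
V(t) = V₀(1+r)ᵗ.  The published description says "linear change", but the
published numbers decide the question: compounding 34.0 at the printed
−0.04 for 20 years gives 15.03 against the printed counterfactual 15.04,
and 0.60 at −0.08 gives 0.1132 → 0.11 exactly as printed, while an
arithmetic-linear projection (34·(1−0.04·20) = 6.8) contradicts every
printed value.  Three alternatives exist for the sensitivity analysis —
LINEAR V₀(1+rt), EXPONENTIAL V₀e^{rt}, LOGARITHMIC V₀(1+r·ln(1+t)).  The
exponential and logarithmic forms are declared conventions of this package
(the source never wrote them down): each anchors at the baseline and shares
the same first-order slope, so they isolate the effect of curvature alone.
Projections may cross zero under LINEAR/LOGARITHMIC with steep declines;
values are never clamped (one district's worsening rate makes sign
behaviour a real case) — a warning fires exactly when a projection is
negative.

**Classification.**  Rate flag: WORSE iff r_conflict > r_prewar + τ (lost
momentum), BETTER iff below −τ, else SAME.  Endpoint flag: WORSE iff
actual > counterfactual + τ for these lower-is-better indicators.  The tie
tolerance τ defaults to 0 (strict inequality on unrounded values) and is
configurable because the published tables treat ties inconsistently (a
printed 4.7 vs 4.7 is labelled "better").  Labels compose the flags into
the published vocabulary; a defined rate with an unassessable endpoint
keeps its half ("Rate is worse"), matching the published treatment of the
one district with a missing MMR endpoint; an unassessable rate yields
"Unable to determine".

**Impact index.**  Weight = number of WORSE flags among {IMR rate, IMR
endpoint, MMR rate, MMR endpoint}; SAME and BETTER contribute nothing.  A
district is not scored when either indicator is wholly unassessable — the
rule that reproduces the published count of four insufficient-data
districts (two late-created, two lacking pre-war columns).

**Tallies.**  Computed over districts only.  "Outside the conflict zone"
means conflict class ≠ high-conflict; intermittent-conflict border
districts count as outside.  Headline IMR counts are recomputed from the
raw district columns, which reproduce the published 10 / 8 / 16 exactly.
Headline MMR counts are taken from the packaged printed labels, because the
raw MMR columns contradict the printed labels for two districts (below);
both paths are computed and `reconcile_labels` reports every disagreement.

## Fixtures and irreproducible cells

The published tables are packaged as CSV fixtures (checksum-pinned), with
printed "n/a" normalized to empty cells and recorded in a provenance
column; variant district spellings are normalized through an alias table.
Four published quantities cannot be recomputed from published inputs, and
the package surfaces rather than patches them:

* **District counterfactual cells.**  No shape maps the printed 2-decimal
  rates onto the printed counterfactuals for several districts (e.g. 27 at
  −0.066 over 20 years ≈ 6.9 against a printed 6.2); the unrounded inputs
  were never published.  `counterfactual_reconciliation()` quantifies every
  gap (printed rate → recomputed endpoint, printed endpoint → back-solved
  rate).
* **The 10-year national IMR trend.**  The printed counterfactual 16.83
  back-solves to −0.0345, which rounds to −0.03, not the printed −0.04 —
  the 10-year column most plausibly repeats the 5-year value.  The other
  three national counterfactuals invert exactly to their printed trends.
* **Printed labels vs raw columns.**  Hambantota IMR (tie printed
  "better"), Vavuniya MMR (0.60 vs 0.06 printed "same"), Mannar MMR (a
  positive wartime change printed "Rate is better").
* **The published weight histogram.**  Recounting the published tables
  gives N/A 4, then 1/2/6/8/4 against the published 4, 0/3/8/7/3; the
  fixture preserves the histogram as printed and nothing asserts it.

## Synthetic data generator

`generate_panel` emulates the data regime the analysis assumes: per-unit
annual series 1975–2002, baseline 1982, a pre-war proportional improvement
(default −0.058/yr, the median published district pre-war IMR rate), a
conflict-period rate scaled by a multiplier (default 0.5 — momentum
halved, the typical published slowdown), multiplicative lognormal noise
with unit mean (default CV 0.05; mortality rates are positive and
right-skewed, matching the erratic district swings in the sources),
interior years missing at random (default 5%), two late-created units per
25, and roughly the published share of 1999 endpoints (30%).  Baseline
levels are lognormal around 27 (IMR) and 0.6 (MMR).  The same seed always
reproduces the panel bit-for-bit.

Two constructions make the generator exactly analysable:

* the pre-war segment is *pinned*: V_start = V_b/(1+rk), geometric
  interpolation in between, so the two-point estimator recovers the
  configured rate exactly on noise-free data;
* the conflict segment compounds at r × multiplier, so a multiplier of 1
  continues the compound counterfactual exactly and every endpoint flag is
  SAME under the null.

These two conventions cannot be reconciled for the *rate* flag: the
analysis compares an arithmetic two-point average over a 7-year pre-war
window with one over a 20-year conflict window, and those two averages of
one smooth compounding path never agree (((1+r)^T−1)/T ≠ r for T > 1).
The oracle (`expected_flags`) therefore computes both flags in closed form
from the true parameters — including the WORSE-biased null rate flag,
which is a genuine artifact of the method's window-length mismatch, worth
knowing about when interpreting the real slowdown counts.  Missingness
never hits the window-bound years (pre-war start, baseline, endpoint),
mirroring the published design where endpoint availability, not interior
gaps, decides assessability.

What passing synthetic tests show: the pipeline recovers the flags implied
by its own model of the data (piecewise-proportional change, independent
multiplicative noise) essentially perfectly at these effect sizes.  What
they do not show: robustness to the features real district series have and
the generator omits — serially correlated shocks, reporting breaks and
boundary changes, under-registration that co-varies with conflict
intensity, and spatial correlation between districts.

## Numerical choices

* Rates and projections are computed and stored unrounded; rounding
  (half-up, as the published tables round) happens only at report time,
  default 2 decimals.
* Null-effect synthetic tests use a tie tolerance of 1e-9: the pinned
  construction makes actual and counterfactual equal only up to float
  round-off, and a strict-zero tolerance would flip SAME flags on ~1e-15
  relative noise.
* Back-solving uses closed forms for every shape; COMPOUND is
  (target/baseline)^{1/t} − 1.  `back_solve_rate ∘ project` is identity to
  1e-10 on valid domains (positive targets).
* Deterministic output: result rows sort by unit id, CSV uses a fixed
  line terminator, manifests differ across reruns only in their timestamp.

## Problem sizes

Everything runs in seconds on one CPU: the fixture analyses are 25-district
arithmetic; synthetic validation uses 100 units noise-free and 500 units at
CV 0.05 (1,000 unit × indicator flags per run), sizes at which the
stochastic acceptance check (≥95% flag recovery) has comfortable margin.

## Known limitations

The method itself is descriptive: two-point trends are sensitive to the
endpoint years chosen, no uncertainty accompanies the classifications (the
source provides none), and the counterfactual admits no exogenous drivers
— it answers "what if momentum had continued", not "what did the war
cause".  The package inherits those properties by design and confines
itself to making every step of the computation explicit, reproducible and
checkable.
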