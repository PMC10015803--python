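# Methods

## The exposure model

One measurement campaign observes, for each worker-shift (salon *s*,
worker *w*), a censored concentration vector over an analyte panel, in
µg/m³ toluene equivalents. Two analyte classes share the table: VOCs
(quantified against a toluene calibration, reporting limit 3 µg/m³) and
aldehydes (externally calibrated, reporting limit 0.3 µg/m³). A value
below the class reporting limit is a non-detect: it is moved to the
sample's censored set at ingest and never carries a number, so every
downstream computation — TVOC, descriptives, hazard indices — sees one
canonical censored dataset. No substitution (e.g. RL/√2) is applied;
statistics run on detected values only. A configuration hook naming an
imputation strategy is left as future work.

Risk screening uses the cumulative toolkit:

- HQᵢ = Cᵢ / RVᵢ, the hazard quotient of chemical *i*;
- HI = Σᵢ HQᵢ over every quantified analyte with a resolvable limit
  value; HI ≥ 1 flags potential non-cancer risk. The comparator is ≥ by
  default; a strict `>` variant is exposed in `RunConfig` because the
  boundary convention differs between sources. The boundary case is
  logged either way.
- MCR = HI / max HQᵢ, in [1, n]: MCR near 1 means one substance drives
  the risk, MCR near n means the mixture does.

### Limit-value resolution

Each chemical resolves to a single RVᵢ through a strict tier order:
chronic reference value, then Swedish OEL, then lowest Nordic OEL, then
lowest international OEL. The hierarchy is by tier, not magnitude: a
numerically lower OEL never overrides an existing RV, because chronic
RVs and 8-hour OELs answer different questions and the fallback is a
data-availability ordering, not a minimum search. "Nordic" is a data
attribute (a country tag on the registry row), not hard-coded. Within
the Nordic and international tiers, which may carry several national
values, the lowest is chosen. A chemical with no value in any tier is
excluded from HI — logged, never fatal — but still counts toward TVOC;
since OELs are generally far higher than RVs, and roughly half of a
realistic panel resolves to nothing, the HI is a lower bound on mixture
risk by construction.

CAS is the primary join key (grouped analytes match on any member of
their CAS list); case-insensitive, whitespace-collapsed name matching is
the fallback for analytes without a CAS. The packaged registry
reproduces the published panel's limit values verbatim, including one
misprinted formaldehyde CAS (59-00-0; the standard registry number is
50-00-0) kept as printed with a note rather than silently corrected.

### TVOC

TVOC is defined analytically as the summed peak area of everything
eluting between hexane and hexadecane. Re-expressed over quantified
concentrations — the only form available downstream of identification —
it is the sum of concentrations of analytes flagged `tvoc_included`.
Aldehydes are included by default (matching "TVOC including aldehydes"
reporting); clearing the flag reproduces a strict elution-window TVOC.
This re-expression cannot capture unidentified peak area, so the
package's TVOC is a lower bound relative to an integrated-chromatogram
TVOC; comparisons between the two should expect that gap.

### Salon aggregation

A salon-scope result is built from the arithmetic mean of the member
samples' HQ maps (a chemical absent from a sample counts 0), with HI,
maxHQ and MCR recomputed from the mean map. Averaging commutes with the
HI summation, so the salon HI equals the arithmetic mean of the sample
HIs — the aggregate used when salons are screened by their mean index.
TVOC aggregates the same way.

### MCR substance groups

The raw group definitions (I: maxHQ > 1; II: HI < 1; IIIA: MCR < 2 with
HI > 1; IIIB: MCR > 2 with maxHQ < 1) overlap and leave boundaries open,
so classification is by strict precedence I → II → IIIA → IIIB with
configurable boundary assignment: maxHQ = 1 goes to I and MCR = cutoff
goes to IIIB by default, both logged. Under this precedence the four
regions partition the classifiable space (property-tested over
randomized HQ vectors). The parenthetical condition "HI > MCR"
sometimes attached to group I is an algebraic consequence of maxHQ > 1,
not an extra test.

Substances of concern: group I names every chemical at HQ ≥ 1; IIIA
names the dominant chemical; IIIB names the chemicals jointly
contributing ≥ 90% of HI in descending HQ order. The 90% rule is this
package's convention — published IIIB case reports name the substances
without stating a rule — and is deliberately conservative (always at
least the top contributor, never a chemical adding < 10% after the
cutoff is reached).

## Statistics

Descriptives per chemical: AM, sample SD (n − 1), GM = exp(mean ln x),
GSD = exp(sd ln x), median, range — detected values only. GSD of a
singleton or constant series is defined as 1, the multiplicative
identity, even though some legacy tables print 0 there; 0 is not a
possible value of a geometric standard deviation.

Variance components use the one-way random-effects method of moments:
within = MS_within, between = max(0, (MS_between − MS_within)/n₀) with
n₀ the standard unbalanced-design coefficient. One-way ANOVA reports
F = MS_between/MS_within on (g−1, N−g) df; the degenerate zero-within-
variance case with unequal means reports F = +∞, p = 0 and a flag
rather than an exception. Bonferroni pairwise comparisons are pooled-
variance two-sided t-tests with p multiplied by the number of pairs,
capped at 1. OLS regression (scipy's linregress behind a thin contract)
reports slope, intercept, R², and the slope's two-sided t-test on n − 2
df; a constant response returns slope 0, R² 0, p 1. Analyses run on the
untransformed scale by default, matching practice when log and linear
analyses agree; callers pass log values where multiplicative structure
is wanted.

## The synthetic campaign generator

Defaults are the study conditions: 10 salons × 3 workers, a 29-chemical
panel mirroring the published exposure table (per-chemical GM, GSD and
detection frequency, e.g. acetone GM 42 µg/m³, GSD 2.0, detected 29/30),
between-salon share of log-scale variance 0.28, reporting limits 3 and
0.3 µg/m³. One panel chemical (a fragrance compound without a published
structure or statistics) carries GM 8 µg/m³, GSD 2.0 — a mid-panel
guess consistent with its detection frequency.

Per chemical: detection is a Bernoulli gate (absence = never
identified); a detected concentration is exp(μ + b_s + e) with
μ = ln GM, σ = ln GSD, b_s ~ N(0, between_frac·σ²) one draw per
(salon, chemical), e ~ N(0, (1 − between_frac)·σ²); detected values
below the reporting limit are then censored, so both real non-detect
mechanisms occur. Chemicals are independent given the salon — there is
no global salon factor shared across chemicals and no cross-chemical
correlation (a noted extension); a consequence is that simulated TVOC
and HI are less correlated than in real salons, where product use moves
many chemicals together. Climate generation draws salon CO₂ around
628 ppm (CV 32%), temperature 23.2 °C (CV 4.4%), RH 37.9% (CV 31%), and
can couple CO₂ to salon mean TVOC with a chosen slope to plant a
ventilation-style association.

What passing tests on generated data do **not** show about real data:
the generator has no task structure (dyeing/bleaching events), no
within-shift dynamics, no product-driven co-occurrence of chemicals, and
its censoring is exact at the limit rather than instrument-dependent.
It validates the pipeline's arithmetic and statistical behaviour, not
field sampling strategy.

### Parameter recovery

Lognormal consistency is checked directly: at n = 10 000 single-chemical
samples, the empirical GM and GSD sit within 2% of the planted 42 and
2.0.

Recovering the between-salon variance share needs care. A single
intraclass-correlation estimate from one response (e.g. the HI) over 10
salons × 3 workers has a standard error near 0.2 at a true share of
0.28 — far too noisy to pin the parameter down per campaign. The truth
record therefore carries the complete uncensored concentration matrix,
and `CampaignTruth.recover_between_fraction` pools per-chemical one-way
components of ln(concentration): each chemical is standardized by its
**planted** σ = ln GSD (standardizing by a data-derived scale
self-normalizes and biases the pooled ratio upward by about +0.06 at
this size; measured), per-chemical moment estimates are summed without
per-chemical truncation (truncating each at zero biases upward by about
+0.07; measured), and only the pooled between-sum is floored at zero.
Because salon effects are independent across the K ≈ 24 informative
panel chemicals, pooling shrinks the error by ~√K: measured over 200
replicates at the default conditions the estimator is unbiased with SD
≈ 0.043, and 97% of replicates land within ±0.10 of the planted 0.28.
For observed (censored, detection-gated) data the field-facing
estimator `stats.pooled_between_fraction` applies the same pooling to
detected values with a ≥ 50% detection filter against left-truncation
bias; its replicate-level coverage at ±0.10 is necessarily lower
(roughly 70–85% at these conditions) and it should be read as a
descriptive split, not a precise parameter estimate.

## Numerical conventions

- Full precision everywhere internally; rounding to 1 significant
  figure (configurable) only in report display columns, alongside the
  full-precision value.
- maxHQ ties break to the lexicographically first chemical name, logged.
- MCR with maxHQ = 0 is absent (undefined), never a division by zero.
- An empty contribution set yields HI 0 with a prominent warning and an
  unclassifiable (not erroneous) group assignment.
- Report CSVs write floats via `repr`, so a read round trip reproduces
  values exactly (tested to 12 significant digits).

## Problem sizes used in the test suite

Randomized invariants run over 10 000 synthetic samples; GM/GSD
consistency uses one chemical at n = 10 000; variance-share recovery
uses 200 replicate campaigns at the default 10 × 3 design; planted
substance-group recovery uses 100 campaigns per group region; ANOVA null
calibration uses 500 simulations. These sizes keep the full suite under
a minute while leaving Monte-Carlo margins comfortably wider than the
assertion tolerances.

## Known limitations

- Concentration-sum TVOC omits unidentified peak area (above).
- HI understates risk where limit values are missing or where only an
  OEL (typically much higher than an RV) exists.
- No dermal route, no carcinogenic-risk indicators, no time-resolved
  within-shift modelling.
- The generator's independence across chemicals weakens TVOC–HI
  coupling relative to real campaigns; regressions of HI on TVOC over
  simulated data are expected to be weaker than field reports.
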