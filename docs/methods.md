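# Methods

## Model and assumptions

All quantities are closed-form functions of four country-year inputs:
stillbirth count *SB* (fetal deaths at ≥ 28 completed gestation weeks —
the pragmatic cut-off that also excludes essentially all voluntary
abortion), live-birth count *LB*, neonatal death count *NM*, and life
expectancy at birth *LE*. Total births *TB = SB + LB* are always derived,
never stored, so the two rate definitions

    SLBR = 1000·SB/LB      STBR = 1000·SB/TB

can never drift apart: the gap identity SLBR − STBR = SLBR·STBR/1000 and
the interconversions SLBR = 1000·STBR/(1000 − STBR), STBR =
1000·SLBR/(1000 + SLBR) hold to machine precision by construction. Both
rates rank countries identically; the gap grows with the rate itself, so
the choice of denominator matters most exactly where stillbirth is most
common.

The stillbirths-adjusted life expectancy treats the person-years lived by
1000 live births, 1000·LE, as the yield of the 1000 + SLBR total births
behind them:

    SALE = 1000·LE/(1000 + SLBR)
    LE − SALE = SLBR·LE/(1000 + SLBR)       (increasing in both arguments)
    YLL = (LE − SALE)·LB                    (person-years)

The YLL formula is deliberately a pure years-of-life-lost construction:
stillbirths have no life expectancy of their own, so the usual
deaths-times-remaining-expectancy rule cannot apply, and no
gestational-age weighting or morbidity component is modelled. Uncertainty
is not propagated anywhere — inputs are point estimates and so are
outputs.

Implicit assumptions worth stating: the life expectancy of live births is
taken as exogenous (adjusting it for stillbirths does not feed back into
the life table), and counts are treated as non-negative *reals* — live
births back-derived as 1000·NM/NMR are fractional, and forcing integers
would break the algebraic identities the tests rely on.

## Growth decomposition

Since NMR = SLBR/(SLBR:NMR), growth rates satisfy the exact relation
(1 + g_NMR) = (1 + g_SLBR)/(1 + g_ratio); in log growth rates the
decomposition is exactly additive, and in simple percentage changes the
familiar g_NMR ≈ g_SLBR − g_ratio is only first-order accurate. For the
two-income-group 2000→2015 comparison the changes are large (≈ −35% and
+35%) and the additive rule overstates the NMR decline by nearly 20
percentage points (−69.9 vs the exact −51.7 for the richer group), so
`growth_decomposition` always reports both variants, labelled, and never
substitutes one for the other.

A related reference-value wrinkle: the published narrative of the richer
group's ratio increase is internally inconsistent (a printed difference of
25.6 against endpoints 75.1 → 101.5, whose true difference is 26.4, and a
printed percentage of 35.1 against the printed quotient 25.6/75.1 =
34.1%). The library computes from the formula — 35.2% at 1 dp — and a
dedicated test pins that value and the inconsistency so it cannot be
silently "corrected" toward any of the printed numbers.

## Aggregation choices

- **Pooled vs cross-country.** Group rates are computed from summed counts
  (equivalently the live-birth-weighted mean of member rates); the
  unweighted mean, SD and CV of member-country values are reported
  separately. Group mean LE/SALE/decrement are unweighted country means;
  birth-weighted variants can be had by pooling counts explicitly.
- **SD denominator.** Sample (n−1) throughout. The convention is not
  dictated by the arithmetic being reproduced, and per-country source data
  for the published group dispersion are not embedded, so the choice
  cannot be adjudicated against them; n−1 is the standard for
  cross-country summaries and is documented here prominently.
- **Missing data.** A row that fails validation is excluded from every
  summary with a counted, machine-readable error — never imputed, never a
  NaN propagated into a pooled rate.
- **Group labels are data.** The eight MDG-region codes and the two-way
  income split are defaults, overridable by a YAML config (replacement
  label sets and per-country overrides), since groupings are analysis
  choices, not facts about a country.
- **Threshold counts.** A country "passes" a reduction threshold only if
  its rate *fell* by more than the threshold percentage; increases never
  qualify regardless of magnitude, and countries present in only one year
  are skipped with a logged warning.

## Units, rounding, degenerate inputs

Internal arithmetic is always on unrounded values; rounding happens only
in writers and the CLI (2 dp for rates and years, 1 dp for percentages and
the SB:NM ratio ×100, which is stored dimensionless). YLL is stored in
person-years with display units of 10⁵ (table convention), 10⁶ (running
text), or raw years. Zero live births, zero total births, and a zero NMR
denominator are domain errors, not NaNs; NMR = 0 alongside NM > 0 is
flagged as an inconsistency, and NMR = 0 with NM = 0 leaves live births
indeterminate — the caller is told to supply them directly. Published
tables are rounded from unrounded inputs, so tests that feed *printed*
values through exact formulas allow one unit in the last printed digit
(e.g. the highest-rate country's converted STBR lands at 43.14 against a
printed 43.15).

One published header ambiguity is handled by documented fiat: the group
YLL column is labelled in hundreds of thousands, but its values can only
be millions — the country-level table *is* consistent with 10⁵ (its
largest entry, 392.0, is quoted in text as 39.2 million), and that single
country already exceeds every group total on a 10⁵ reading, while the
narrative quotes the group column's world total, 165.3, directly as
millions. The embedded group fixture therefore names the column
`yll_millions` and treats the printed header as the error.

## Synthetic panels

`generate_panel` emulates the joint structure the metrics assume, per
country: SLBR uniform within an income-tier range (richer 2–15, poorer
10–50 per 1000, bracketing observed group spans), an SB:NM ratio from
N(0.9, 0.2²) truncated at 0.1 (the floor keeps the derived NMR = SLBR/ratio
bounded so neonatal deaths cannot exceed live births), live births
log-uniform on [10⁴, 2×10⁷], and LE = tier baseline (78 rich / 62 poor)
− 0.25·SLBR + N(0, 1) noise, floored at 1 year. Between the two panel
years each tier's SLBR declines multiplicatively (35% rich, 25% poor,
echoing the observed proportionate declines). Defaults chosen once:
tier_mix 0.5; panel of 30 countries in the test fixtures — ample for the
identities and orderings under test, and the whole suite runs in seconds.

Counts are real-valued so every latent draw is recovered exactly by the
metric layer (the ground-truth table records them all); an `integerize`
flag rounds counts, degrading the identities by ~0.5/LB — the documented
gap between rate algebra and count data. What the generator does *not*
emulate: within-country structure, gestational-age composition,
cause-of-death mix, measurement error, or any realistic covariance beyond
the linear LE–SLBR link (asserted association only, so the minimal
monotone structure is used). Passing tests therefore certify the algebra
and the aggregation plumbing on data shaped like the real panel — not
distributional fidelity to any real dataset.

## Known limitations

- Point estimates only; no uncertainty intervals.
- Two-point trend comparison only; no time-series modelling.
- No estimation of stillbirth counts from surveillance data; the package
  starts from counts (or rates) someone else estimated.
- Country matching is exact (ISO3 preferred, else name); no fuzzy joins,
  by design — a silent mis-join is worse than a loud miss.
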