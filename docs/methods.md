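# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Instrument scoring

The instrument has 37 ordinal items across six domains. Published totals
give 30 five-point and 6 three-point items; the scale of the remaining item
is not stated, and it is treated as five-point. The packaged default map
allocates items as cognitive 12, fine motor 5, gross motor 5, language 7,
positive behaviour 4, negative behaviour 4, with the six three-point items
in the behaviour domains. This allocation is a package convention — the
instrument's true item-level layout is configuration, not code, and any
map can be supplied as YAML.

Scaled scores use per-item min–max normalisation: item score *x* on a
*k*-point scale contributes (x−1)/(k−1); the domain score is 100 × the mean
contribution over *answered* items. Rationale: the mixed 3/5-point scales
are the stated motivation for scaling, and the formula reproduces the
[0, 100] support with attainable endpoints seen in the published table
(0.0 minima, 100.0 ceilings). Consequences asserted by tests: all-minimum
→ 0, all-maximum → 100, all-midpoint → 50 under any scale mix, and
monotonicity in every single response. Missing responses are prorated
(mean over answered items); proration is preferred to zero-filling because
cohort missingness is low (<2%) and zero-filling would conflate
missingness with poor performance. Completeness thresholds are inclusive
(completeness ≥ threshold passes); default minimum completeness 0.8 per
domain. Note that with four-item domains a single missing item yields
completeness 0.75, so the 0.8 default intentionally flags any missingness
in the behaviour domains.

## Exclusion cascade

Rules, in flow order: preterm (<37.0 decimal weeks; weeks+days parsed as
weeks + days/7), postnatal neurological morbidity (consumed as a boolean —
operationalising it from raw morbidity lists is out of scope), maternal
mental-health diagnosis, incomplete assessment, assessment age outside
[22, 30] months (inclusive), CBCL subscale centile strictly above 97.
A missing CBCL subscale never flags; with both subscales missing the flag
is indeterminate and the record is routed to incomplete-assessment
handling. Attribution is first-match, mirroring flow-diagram accounting;
the retained set is provably independent of rule order (asserted by a
permutation property test), only the attribution counts depend on it. The
audit also stores per-rule, per-site counts so intermediate flow boxes
(e.g. the "eligible" box before the CBCL rule) can be reconstructed —
needed because the published per-site contributions describe that
intermediate box (they sum to 1209, not to the 1181 retained).

## Harrell–Davis centiles

The estimator is the canonical untruncated form: weights are increments of
the regularized incomplete beta function I_x((n+1)q, (n+1)(1−q)) over the
cells [(i−1)/n, i/n], evaluated with `scipy.special.betainc`; the estimate
is the weighted sum of order statistics. Weights sum to 1 within 1e-12 and
match adaptive quadrature of the beta density to 1e-8 for n ≤ 50 across
seven probabilities (tested); the implementation is also cross-checked
against an independent library implementation on continuous data. A
distribution-free estimator is used because no single transformation
normalises all domains; smoothing-based methods (LMS/GAMLSS) are
deliberately out of scope, as are centile confidence intervals.

Centile tables are computed on a single pooled sample per domain, one
equal-weight observation per child, no site weighting; pooling is
justified separately by the variance decomposition. Estimated centiles are
monotone in q by construction of the estimator; sub-1e-9 floating-point
inversions (which occur at 100.0 ceiling plateaus) are ironed out by a
cumulative maximum, and any larger inversion raises. Domains under a
configurable minimum n (default 20) are flagged low-confidence but still
computed.

Sex comparisons use the Wilcoxon rank-sum test: exact enumeration when
both groups have ≤10 untied observations, otherwise the normal
approximation with mid-ranks, tie correction and continuity correction
(via `scipy.stats.mannwhitneyu`). A fully tied comparison returns p = 1.

## Screening chart

Normality thresholds are the 10th centile with "≥" for higher-is-better
domains and the 90th with "≤" for negative behaviour (lower is better).
Zones: normal at/inside the threshold; monitor between the 3rd and 10th
(mirrored 90th–97th) with the exact c3/c97 values assigned to monitor;
urgent strictly beyond. The mirrored negative-behaviour zone rule is an
inference from the positive-domain description; it is the only reading
that keeps the three zones total and direction-consistent. Boundary ties
(the published negative-behaviour row has c3 = c10 = 0) collapse the
monitor band to an empty interval; classification remains total, which is
property-tested on random charts.

## Variance decomposition

One-way random-effects ANOVA by the method of moments: σ²_w is the pooled
within-site mean square; σ²_b = max(0, (MS_between − MS_within)/n₀) with
the unbalanced-design effective group size n₀ = (N − Σn_j²/N)/(k−1);
the between-site share is σ²_b/(σ²_b + σ²_w). The publication reports a
variance-share argument without naming an estimator; method of moments is
the standard choice for this design and is exactly recoverable by hand on
small fixtures (tested). Sites with fewer than two children are dropped
with a warning; fewer than two usable sites is an error. Negative moment
estimates truncate to zero.

With only five sites a single domain's share estimate has sampling SD of
roughly share·√(2/(k−1)) ≈ 0.7·share, so recovery at a ±0.03 tolerance is
assessed on the mean share across the six domains, whose site intercepts
are drawn independently (≈√6 variance reduction).

## Vision and milestones

Both Cardiff measures (logMAR acuity, contrast threshold in %) are better
when lower, so centile labels map to flipped quantiles: the value reported
at label c is the (1−c) quantile, making columns decrease down the table
with better performance at higher labels. Norm ranges are editable config
constants with source labels, not hard-coded science: acuity [0.0, 0.6]
logMAR and contrast [0.5, 3.0]% for 24–30-month-olds. The WHO gross-motor
windows of achievement are likewise config: sitting without support
3.8–9.2, standing with assistance 4.8–11.4, hands-and-knees crawling
5.2–13.5, walking with assistance 5.9–13.7, standing alone 6.9–16.9,
walking alone 8.2–17.6 months. Milestone proportions count "never
observed" (encoded +inf) as outside the window and exclude missing ages
from the denominator. CBCL T-scores/centiles are consumed, never computed
(proprietary scoring); cut-offs are 93rd (borderline) and 97th (clinical).

## Synthetic generator

The generator is a stated world, fixed up front:

* five sites × 260 children (the realized multi-site design averaged ~261
  assessed children per site); 52% girls;
* assessment age normal 24.8 (SD 1.6) months truncated to [22, 30], with a
  planted 0.1% out-of-window rate (matching "99.9% between 22 and 30
  months");
* latent-ability model: latent = domain mean + site intercept + sex shift
  + child effect N(0, 1); item response = ordinal bin of latent + item
  noise N(0, 0.8) under asymmetric thresholds (five-point: −2.0, −1.2,
  −0.5, 0.3; three-point: −0.5, 0.5). Asymmetric thresholds produce the
  right-shifted, ceiling-prone scaled-score distributions (fine-motor-like
  100.0 plateaus) and floor-concentrated negative behaviour;
* domain latent means 0.8/1.3/1.0/0.6/1.2/−1.0 (cognitive/fine motor/gross
  motor/language/positive behaviour/negative behaviour), chosen once for
  shape plausibility;
* sex effects (female − male, latent SD units): +0.15 cognitive, +0.15
  language, −0.15 negative behaviour — the direction of the reported
  trends (girls ahead on cognition/language, boys higher on negative
  behaviour);
* site intercepts drawn once per site per domain (random-intercept
  structure); their SD is set from a latent-scale variance-share target
  (default 0.05): site_sd = child_sd·√(t/(1−t)). Ordinal binning and item
  noise attenuate the realized share on the *score* scale to roughly
  0.6–0.75 of the latent target; the realized share is therefore computed
  by a many-site Monte-Carlo ANOVA and recorded in the ground truth, and
  recovery is judged against that realized value, not the latent target;
* planted rates: preterm 4.0%, neuro morbidity 3.0%, maternal
  mental-health 2.7%, CBCL clinical 2.3%, incomplete 0.5% (consistent with
  the flow counts 54/1339, ~40/1339, ~36/1339, 28/1209);
* vision: discrete Cardiff-style levels with probabilities set so the raw
  10th/50th/90th quantiles match the published pattern (acuity 0.3/0.2/0.1
  logMAR, contrast 2.0/1.5/1.0%); milestone ages truncated normals sitting
  inside the WHO windows with ~2–6% spill, 0.2% "never", 1% missing.

Ground truth comes from a 10⁶-draw Monte-Carlo oracle under a fixed seed
independent of any cohort seed: scaled-score quantiles per domain (site
and sex marginalised as random effects) and the realized between-site
share (300-site ANOVA). A separate oracle utility estimates the sampling
SE of a cohort quantile under the replicated few-site design; recovery
tests use a band of 4 such SEs plus a 0.5-point floor for score
discreteness. The dominant variance term at five sites is the random
site-mean shift, which an iid binomial SE would understate several-fold.

What the generator does **not** emulate: real item content or difficulty
ordering, cross-domain correlation of abilities within child (domain
latents are drawn independently), psychometric covariance with reference
instruments, or the published cohort's actual score distributions. A green
recovery test therefore establishes that the pipeline recovers the truth
of *this* generative family at the stated design size — not that it would
reproduce the published centile values, whose underlying data are not
deposited. The published thresholds are verified directly from the
packaged chart fixture instead.

## Participant-flow fixture

A deterministic synthetic cohort replicates the published flow: 1339
assessed; 54 preterm; 76 further exclusions split 40 morbidity / 36
maternal mental health (the split between the assessed and eligible boxes
is not published — this is a documented convention); 1209 eligible with
the published per-site totals (147, 305, 296, 301, 160 — which sum to
1209, i.e. they describe the eligible box); 28 CBCL clinical-range
children (split 6/6/6/5/5 across sites, a convention); 1181 retained.
Every excluded child carries exactly one flag so attribution counts are
rule-order invariant.

## Interfaces and numerical conventions

CSV dialect: UTF-8, comma-separated, header row, empty fields for missing;
the literal `never` only in the milestone age column. Floats are written
with 17 significant digits and parsed with round-trip precision so
simulate → read is lossless. Exit codes: 0 success, 2 validation failure,
3 configuration error. Every stage logs n_in/n_out and writes a manifest
with a config hash; no silent row drops. All randomness flows through one
seeded generator per run; the oracle seed is fixed and separate.

## Known limitations

* The standardised-scaling formula and the item→domain map are
  reconstructions from the published totals and support; both are
  configuration and should be replaced if the instrument's supplementary
  definitions are available.
* The exact-enumeration rank-sum path is limited to ≤10 untied
  observations per group; beyond that the corrected normal approximation
  is used even where exact computation is feasible.
* Between-share recovery at five sites is intrinsically noisy; only the
  cross-domain mean is a stable target at the ±0.03 level.
* The post-hoc power computation behind the published 0.84 figure is not
  reproduced (its configuration is not stated).
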