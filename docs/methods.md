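# Methods

This note documents the models, numerical conventions and design choices
behind `heartperm`, and what the simulation results do and do not establish.

## Phenotype scoring

Classification is a pure decision table over hemisegment counts. In
*svp-lacZ* mode (`SVP_LACZ`), where β-galactosidase perdurance makes both
Svp CCs and Svp PCs visible:

| (svp_cc, svp_pc) | call |
|---|---|
| (2, 2) | none (wild-type census) |
| (1, 1), (3, 3) | `svp_earlier` — the superprogenitor's symmetric division produced 1 or 3 progenitors, each completing asymmetric division |
| (1, 3), (3, 1) | `svp_asymmetric` — one progenitor produced two PCs or two CCs |
| (2, 1) | `svp_asymmetric` — karyokinesis arrest: one enlarged CC nucleus instead of a CC/PC pair |
| anything else | `unclassified_svp` |

`tin_symmetric` := (tin_cc ≠ 4) is scored independently of the Svp flags: a
single hemisegment can carry one defect of each lineage and counts once in
each category. In antibody mode (`SVP_ANTIBODY`) the PCs are not visible
and the only Svp call is `svp_combined` := (svp_cc ≠ 2); the karyokinesis
signature is invisible there because its CC count is normal.

Design choices where the scoring rules were genuinely open:

* **Unenumerated Svp censuses** (e.g. (2,3), (0,2)) are flagged
  `unclassified_svp`, reported as their own category, excluded from the
  three defect numerators but kept in every denominator. Inventing
  generalisations would contaminate the category counts.
* **The enlarged-nucleus flag is advisory.** The karyokinesis call rests on
  the (2,1) count signature alone, because counts are the only
  machine-readable signal; the flag is carried through IO untouched.
* Per-embryo proportions are exact `Fraction`s in the object API and
  rounded only at output (1 decimal for percentages, "17.9"-style;
  p-values to 4 decimals with a "<0.0001" floor).

## Synthetic cohorts

The generator emulates the statistical structure of scored cohorts, not the
biology of individual divisions (no lineage trees, positions or images).

* Each embryo contributes `segments` hemisegments (default A2–A8 × {L, R} =
  14).
* Per-hemisegment defect probabilities are **additive on the probability
  scale**: baseline + genotype main effect (+ interaction effect δ for the
  genotype with role `double_het`), clipped to [0, 0.95] to keep the logit
  finite. Additivity on this scale makes the additive-sum synergy
  definition exactly representable: the interaction truth is
  rate(double) − rate(single1) − rate(single2) = δ − baseline.
* **Within-embryo correlation** enters on the logit scale: per category,
  each embryo draws one u ~ Normal(0, embryo_sd²) added to logit(p). With
  embryo_sd > 0 the variance of per-embryo proportions exceeds the binomial
  variance at the same mean (the overdispersion that invalidates
  hemisegment-level contingency tests); with embryo_sd = 0 it is exactly
  binomial. The default embryo_sd = 0.5 is a modeling choice — no estimate
  of the within-embryo correlation magnitude is available from scored data
  — chosen to produce clearly non-binomial but not degenerate cohorts.
* **Marginal-rate mode** (`rates_are_marginal=True`): the logit-normal
  mixing raises the marginal defect frequency above the latent rate for
  rates below ½ (Jensen), so "additive in configured rates" is only
  additive in *observed frequencies* at embryo_sd = 0. Since synergy is
  defined on marginal percentages (the additive-expectation dashed line is
  a sum of observed frequencies), this mode solves the latent logit
  intercept by bisection against a 64-node Gauss–Hermite quadrature so
  that E_u[expit(logit(p) + u)] equals the configured rate exactly. All
  simulation scenarios use it; the default is off so that the latent
  parameterisation remains available.
* Defective hemisegments are materialised by count signature: Tin defects
  draw tin_cc uniformly from {3, 5} (the minimal ±1 deviations;
  configurable, e.g. {2, 6}); `svp_earlier` draws (1,1)/(3,3);
  `svp_asymmetric` draws (1,3)/(3,1)/(2,1), setting the enlarged-nucleus
  flag for (2,1). If both Svp categories fire on one hemisegment,
  `svp_earlier` takes precedence — an arbitrary but deterministic rule,
  logged at debug level.
* A configured rate of exactly 0 with embryo_sd > 0 has no logit; it is
  substituted by 10⁻⁶ with a warning (once per genotype × category). With
  embryo_sd = 0 a zero rate is honoured exactly.
* One RNG stream per cohort, seeded once; the seed fully determines the
  output byte-for-byte.

What passing tests on these cohorts do **not** show about real data:
real embryos may have segment- or side-specific defect rates, scorer error,
non-logit-normal embryo effects, and correlation *between* categories
within a hemisegment; none of these are emulated.

## Permutation inference

* **Two-group test**: statistic β̂₁ = ȳ₁ − ȳ₀; the embryo is the
  exchangeable unit (labels are shuffled among embryos, never among
  hemisegments). If C(n, n₁) ≤ `exhaustive_threshold` (default 10⁵) all
  distinct label arrangements are enumerated; otherwise N Monte-Carlo
  shuffles.
* **p-value conventions.** Monte-Carlo: p = (n+1)/(N+1). Exhaustive: the
  standard exact-test convention — the identity arrangement counts once in
  both numerator and denominator — which the result object stores as
  N = (#arrangements − 1) and n = #non-identity arrangements meeting the
  tie rule, so p = (n+1)/(N+1) holds verbatim in both modes. p is always
  in (0, 1], never 0.
* **Tie rules.** `strict` (default) counts permuted statistics strictly
  exceeding the observed one; `geq` counts ties as exceedances. Per-embryo
  proportions live on a k/14 grid and tie heavily; strict counting then
  undercounts the tail and is measurably anti-conservative (two-group null
  rejection ≈ 0.075 at nominal 0.05 under the null scenario below), while
  `geq` is valid (≈ 0.048). The simulation harness and all operating-
  characteristic results therefore use `geq`; `strict` remains the default
  for single analyses where it matches the "estimates which exceed"
  counting convention. Tie comparison uses a 10⁻⁹ absolute tolerance so
  that float noise in permuted sums of identical values does not convert
  ties into exceedances.
* **Tails**: `upper` (default; synergy and mutant-excess claims are
  directional) or `two_sided` on |statistic|.
* **Interaction (Smith) test.** The intercept-free three-group model is
  saturated, so β̂₃ = ȳ_D − ȳ_P − ȳ_Q identically (asserted to 10⁻¹⁰
  against least squares). The interaction column g = Ip·Iq is
  orthogonalized against Z = [Ip, Iq] (two-pass projection, orthogonality
  to 10⁻¹⁰ relative tolerance), and the permutation statistic is

      stat(π) = π(g⊥)·M_Z y / ‖g⊥‖².

  The identity permutation reproduces β̂₃ exactly, so observed and permuted
  statistics share one formula and are exchangeable under H₀. The
  alternative of *refitting* the full model per permutation and taking the
  coefficient on π(g⊥) puts a random quantity (π(g⊥)ᵀM_Z π(g⊥)) in the
  denominator of a non-pivotal statistic; this widens the permutation
  distribution and measurably deflates size (rejection 0.027 instead of
  0.051 at embryo_sd = 0, where the additive null is exactly binomial;
  1500 reps, N = 499). The projection form was therefore adopted. A
  pivotal t with refitting was also examined and was likewise conservative
  (0.028). Freedman–Lane and Manly schemes are out of scope; the result's
  `scheme` field leaves the door open.
* Exhaustive enumeration for the Smith test runs over the *distinct*
  arrangements of the multiset of g⊥ values (entries are grouped after
  rounding to 12 decimals; within a balanced group the projection produces
  bit-identical values), each of which carries equal weight under uniform
  permutation.
* **Controls and the intercept.** The literal intercept-free model uses
  only the three mutant groups, making β₃ exactly the additive-sum
  departure; `with_intercept=True` adds β₀ and admits control (0,0)
  embryos (with three groups and an intercept the interaction column is
  collinear, so the intercept variant requires controls). Constant
  response under the intercept-free model gives β₃ = −ȳ — the double group
  cannot equal the sum of the singles — which the test suite asserts
  rather than the superficially intuitive β₃ = 0 (true only with an
  intercept).
* **Synergy call**: synergistic iff β̂₃ > 0 and p ≤ α (default 0.05); a
  negative β̂₃ — merely additive or sub-additive defects — is never
  synergistic.
* `n_permutations` defaults to 10⁶ in the library (highly reproducible
  p-values); the CLI defaults to 10⁴ with a flag to restore 10⁶.

## Simulation scenarios and study sizes

The scenario builders freeze the study conditions used by the test suite
and `scripts/acceptance.py`; all use 15 embryos per genotype, embryo_sd
0.5, marginal-rate mode, N = 499 permutations, α = 0.05, `geq` ties.

* **Two-group null**: both genotypes at a marginal Tin-defect rate of
  0.10, the middle of the range where mutant-vs-control comparisons
  operate (single-digit to low-twenties percent). 1000 replicates.
* **Interaction null**: with no intercept, *equal* rates across the three
  groups imply β₃ = −rate ≠ 0, so the model's null is additivity. The null
  scenario is marginal rates 0.05 / 0.05 / 0.10 (zero baseline in the
  tested category + main effects only), giving β₃ truth exactly 0. A
  second additivity scenario uses unequal mains 0.04 / 0.08 / 0.12. 1000
  replicates each.
* **Power and recovery**: synergy grades δ ∈ {0, 0.05, 0.10, 0.15} on top
  of the additive configuration; 500 replicates per grade. In
  marginal-rate mode E[β̂₃] = δ at any embryo_sd, so the same run checks
  power monotonicity and parameter recovery (mean β̂₃ within 2 SE of δ).
  Measured rejection climbs from ≈ 0.04 at δ = 0 to ≈ 0.95 at δ = 0.15.

Residual mild conservatism of the interaction test under overdispersion
(≈ 0.04 at nominal 0.05) is structural: the logit-normal mixing skews
per-group means right, and β̂₃ = ȳ_D − ȳ_P − ȳ_Q inherits *left* skew from
the two negated single groups while the permutation reference inherits the
pooled residuals' right skew; the upper tail is therefore slightly thin.
This direction of error is safe (the test under-rejects).

Replicate counts were chosen to give binomial standard errors of ~0.007
(nulls) and ~0.02 (power) on one CPU in a couple of minutes; the per-rep
pipeline always runs generation → classification → summarisation → test in
full.

## Known limitations

* Category p-values are unadjusted for multiple testing across the three
  categories, matching standard reporting practice for this assay.
* The Smith scheme's exchangeability is approximate under heteroscedastic
  groups; the measured size error is small and conservative (above).
* The generator's `truth()` interaction identity is on configured rates;
  in latent mode at embryo_sd > 0 the marginal truth differs by the Jensen
  gap (use marginal mode when the marginal truth matters).
* Anterior aorta, lymph gland, and pericardial subtypes other than Svp PCs
  are out of scope; segment labels carry no ordering semantics beyond
  uniqueness.
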