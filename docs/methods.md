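# Methods

`pcmckit` implements the post-conflict / matched-control (PC–MC) method of
quantitative ethology for consolation and reconciliation, together with an
agent-based generator that emulates the observational structure of a
semi-free-ranging bonobo sanctuary study (two mixed-age groups, 36
non-infant subjects, ~450 observation hours). This note records the models,
the parameter choices and their rationale, and what the synthetic data can
and cannot establish.

## The PC–MC comparison

Every recorded conflict yields a 10-minute focal follow of the victim
starting at conflict end (PC) and a matched control follow (MC) of the same
victim, 1–2 days later at the same time of day (±1 h), run only when both
former opponents are within 10 m of each other and the focal has been
conflict-free for ≥10 min (otherwise the MC is postponed; pairs whose
window elapses unmatched are dropped and flagged). For a chosen
relationship — bystander→victim contact (consolation) or opponent–opponent
contact (reconciliation) — each PC/MC pair is labelled

* **attracted** if the first qualifying contact came earlier in the PC than
  in the MC, or only in the PC,
* **dispersed** in the mirror case,
* **neutral** if contact came at the same time (1-s recording resolution)
  in both, or in neither.

Victim-initiated affiliation never counts as consolation; the direction
rule is enforced by the contact's recorded initiator. Contact tendencies
aggregate labels as `TCT = 100·(A − D)/N` per victim (any-bystander
relationship) or per victim–bystander dyad; the opponent–opponent analogue
is the conciliatory contact tendency (CCT). The per-dyad consolation index
is the fraction of a bystander's opportunities (PCs in which it was present
in both follows) in which it was the *globally first* consoler of that
victim. Presence is recorded per follow, so "present in both periods"
means seen at any point of each follow; a per-instant presence rule is not
representable in this record format.

## Statistical battery

* **Occurrence.** Per-focal proportions of attracted vs dispersed pairs are
  compared with a paired Wilcoxon signed-rank test. Zero differences are
  dropped before ranking. For n ≤ 40 informative pairs the two-sided
  p-value comes from the exact tie-corrected distribution of W⁺ (dynamic
  programming over doubled ranks); larger samples use the normal
  approximation with tie correction and no continuity correction. The
  Z statistic is always reported on the normal scale. The exact branch is
  used well past the usual n = 25 because the per-focal proportions are
  discrete and the normal approximation over-rejects slightly at n ≈ 30.
* **Latency.** First-contact latencies, right-censored at the 600-s follow
  end (one observation per follow), are compared between PC and MC with the
  Mantel–Cox log-rank test; Kaplan–Meier curves are returned for plotting.
  Both are computed by `lifelines`.
* **Stress proxies.** Self-scratching (bouts/min) and self-grooming
  (s/min) are compared across outcome categories {MC, PC without
  affiliation, PC with consolation}, excluding reconciled PCs from the two
  consolation cells to remove that confound. The three planned pairwise
  Wilcoxon comparisons use the Bonferroni-corrected α = 0.05/3, truncated
  to three decimals (0.016), matching conventional reporting.
* **Determinants (GLMM).** Each (conflict × eligible bystander) is one row
  with a binary outcome (that bystander's pair label attracted) and
  covariates: proximity band, bystander age class/sex/rearing, victim
  attributes, mother–offspring kinship to victim and aggressor,
  log-transformed dyadic affiliation, feeding context, conflict intensity,
  reconciliation and redirection. Random intercepts: victim, aggressor,
  bystander, group and conflict identity.
* **Relationship dynamics (LMM).** Per-dyad TCT and consolation index are
  modelled with Gaussian mixed models (random intercepts: victim,
  bystander, group); coefficient significance in the best model uses
  10,000 seeded draws from the estimated sampling distribution
  (posterior-simulation p-values in the tradition of early lmer workflows).

### Binomial mixed models

No installed Python library fits a binomial GLMM with crossed random
intercepts under a likelihood that supports AIC comparison, so the fit is
implemented here. For fixed variance components θ (one SD per factor) the
fixed effects and random modes are found by penalised IRLS; the marginal
likelihood is the Laplace approximation

    ℓ(β, θ) = ℓ_bin(β, û) − ½ û'D⁻¹û − ½ log|D| − ½ log|Z'WZ + D⁻¹|,

and θ is profiled by bounded derivative-free optimisation
(log-SD ∈ [−6, 3]). The joint-mode step alone (lme4's fast `nAGQ = 0`
flavour) attenuates fixed effects by several percent, which destroys
confidence-interval coverage; β is therefore refined on the Laplace
objective itself, with the log-determinant's β-dependence in the gradient
(analytic for a single factor via the diagonal Z'WZ; numeric L-BFGS for
several factors). The result matches `glmer`'s default Laplace ML to ~1e-2
in coefficients, SEs and log-likelihood on test fixtures, and 95% Wald
intervals achieve ≈95% coverage in simulation. Standard errors come from
the fixed-effect block of the inverse joint observed information.
Degenerate outcomes (all 0/1, separation) are flagged, not estimated.

**Model selection** enumerates every subset of the candidate pool (capped
at 12 main effects) plus any listed two-way interactions whose parents are
present; subsets containing a collinear pair (|r| > 0.7) are skipped, and
AIC = −2ℓ + 2k with k = fixed effects + variance components (+ residual
variance for Gaussian fits). With five random factors the variance
components are estimated once on the largest admissible model and frozen
during enumeration; the selected and null models are then refitted with
full profiling. This is the documented fallback that keeps "all possible
models" tractable; AIC *ranking* is insensitive to the frozen-θ
approximation in our checks. The best model is compared to the
random-effects-only null by likelihood ratio.

## The synthetic colony

The generator emulates the study conditions: the default roster reproduces
the two study groups' demographic cells (36 non-infants + 6 dependent
infants), conflicts arrive as a Poisson process at 356/453 per observation
hour split across groups in proportion to size, victim and aggressor
classes follow the published shares (adolescent males 33.1% and juvenile
females 32.5% of victims; adult females 51.2% and adult males 25.4% of
aggressors; remainders uniform), intensity follows the published six-level
distribution, and 10/356 of PCs lose their matched control. Dyadic
affinity is Beta-distributed around `expit(μ₀ + kin_boost·kin)`
(μ₀ = logit 0.12, concentration 40); a dyad's affinity is also its
per-scan engagement probability, so the scan-based affiliation index is a
binomial estimate of the latent value.

Each conflict draws a context, proximity-banded bystander roster
(presence 0.25 per groupmate; bands 0.3/0.3/0.4) and an optional
redirection (0.25 for adult-female victims, 0.08 otherwise, per the
published redirection pattern). Reconciliation occurs by a logistic model
on opponent affiliation, ages and victim rearing; consolation contact is a
per-bystander Bernoulli with logit linear in proximity, bystander age
class and rearing, log affinity, kinship, feeding context, reconciliation
and redirection — the covariate set the GLMM is meant to recover. PC
latencies are exponential (scale 90 s, censored at 600 s), matching the
published first-minute peak; MC contacts are flat per-bystander Bernoulli
draws with uniform latencies. The two intercepts and the MC baseline are
set analytically so that ≈58% of PCs show consolation and ≈26%
reconciliation with ≈20% dispersed pairs — the published occurrence
fractions. Self-scratching is a Poisson process whose rate switches from
0.43 to 0.19 bouts/min at the first consolatory contact (0.37 in MCs, the
published rates); groom bouts (0.08/min) carry exponential durations tuned
to the published s/min means. `ResponseModel.null()` defines the
calibration condition: identical per-bystander contact probability and
latency law in PC and MC and equal scratch rates; the null *condition*
additionally requires identical bystander presence in both follows
(`mc_presence_prob = 1`), since subsampled MC presence makes total contact
hazards unequal by construction.

What the generator does **not** emulate: dominance dynamics, spatial
movement, behavioural autocorrelation within follows, demographic change,
observer effects, and any latent per-individual propensity beyond the
modelled covariates (variance components in the test colonies are
therefore near zero, and the GLMM's random intercepts act as pure
controls). Passing tests establish that the estimators recover known
generative parameters and hold their nominal error rates under these
conditions — not that the field study's specific coefficient values are
reproduced, which is impossible without the undeposited raw observations.

## Numerical and design choices

* Times are compared at 1-s resolution (recording granularity); exact ties
  within a PC are broken by time then lexicographic id.
* The affiliation index uses scan-level OR over the five affiliative
  states ("any" encoding, default) to avoid double-counting within a scan;
  a "sum" encoding is available. The log transform's zero offset defaults
  to half the smallest positive index; dyads never co-present receive the
  observed floor plus a missingness flag.
* Only mother–offspring dyads are coded kin; sanctuary histories provide
  no other verified pedigree.
* Problem sizes in the test-suite simulations (campaign hours, replicate
  counts 500/200/100/50, 2000-row recovery tables, 8-predictor pools) are
  the package's chosen study conditions for calibration and recovery and
  are fixed in the suite.
* Determinism: every stochastic routine takes an explicit seed; stage
  sub-seeds derive from one master seed via `SeedSequence`. Identical
  config + seed reproduces byte-identical CSV output, which the manifest's
  SHA-256 checksums make auditable.

## Known limitations

* The Laplace likelihood is approximate; with few levels per factor or
  variance components at the boundary, AIC differences of < ~2 should not
  be over-interpreted (true of `glmer` as well).
* Gaussian LMMs with several near-boundary variance components rely on a
  cascade of `statsmodels` optimisers; non-converged candidates are
  excluded from selection rather than rescued.
* The exact Wilcoxon branch assumes exchangeability of the paired
  differences; with heavily discrete per-focal proportions the test is
  conservative rather than exact at the nominal level.
* `validate_matched_control` checks clock alignment via seconds-within-
  session, which assumes sessions start at the same clock time each day.
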