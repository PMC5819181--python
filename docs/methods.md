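# Methods

This note documents the statistical models, the choice-set construction
rules, the synthetic colony generator, and the numerical decisions behind
`nestchoice`. Units: time is integer seconds from the study epoch
(1 day = 86,400 s); geometry is in centimetres.

## 1. The question and the data model

Female house mice in a barn population give birth in nest boxes and often
nurse communally: two (rarely more) females pool their litters in one box and
nurse all pups indiscriminately. The data consist of

- an **RFID event stream**: `(tag, box, entry_s, exit_s)` stays of
  transponder-tagged adult females in antenna-equipped nest boxes,
- a **birth record**: `(mother, birth_day, box, litter_size)` obtained by
  monitoring and genetic assignment of pups,
- **microsatellite genotypes** (default 25 loci) for adult females, and a
  reconstructed **pedigree**,
- a **box layout** with coordinates, and monthly **nest-check** timestamps.

### Home areas and association

A female's **home area** at a birth is the set of boxes she entered for a
cumulated total of **≥ 300 s during the 30 days before the birth**
(`tracking.REGULAR_USE_THRESHOLD_S`, `tracking_window_days = 30`). The 300 s
rule separates regular use from antenna-triggering pass-throughs; 30 days
covers roughly one gestation of box use before the decision. Pairwise
**association** is the exact summed overlap of two females' stay intervals in
the same box within a window, computed by a two-pointer sweep over the merged
interval lists (no discretisation; verified against a 1-s brute force).

### Choice sets

For each observed birth of a focal female, the **options** are other females
whose litters are **0–16 days old** on the focal birth day
(`option_window_days = 16`; pups are weaned around day 17, after which a
litter no longer invites pooling) and whose litter box lies in the focal
female's home area. Bookkeeping rules:

- Events are **excluded** (with a recorded reason) if the mother has no
  regular boxes, no options exist, or the mother was itself an undetected
  ("cryptic") second litter discovered only as a mixed litter.
- Litters found mixed in one box form **communal** nests; chains of births in
  the same box within the window are linked transitively. When two litters
  are discovered already mixed, which female "chose" is unobservable; the
  tie is resolved by a seeded deterministic draw and such events are flagged.
- The **nest-availability covariate** `P` is the proportion of the focal
  female's home-area boxes occupied by qualifying litters.
- The outcome `y` is 1 if the focal litter was communal. For modelling the
  partner, the **chosen** option is the female whose litter shares the box.

## 2. Statistical models

### Power-function availability null

If a female picks a box uniformly at random among her `n` home boxes, of
which `k` are occupied, then `Pr(communal) = k/n = P` exactly. The test model
is `y ~ P^a`, fitted by nonlinear least squares; `a = 1` is the
"by-product of availability" null, `a < 1` attraction, `a > 1` avoidance.
The NLS objective in `a` is minimised by a damped Newton step with a bounded
Brent fallback; `P = 0` rows are dropped (the model value is 0 regardless of
`a`), the reported test is `t = (â − 1)/SE(â)` on `n − 1` degrees of freedom,
and the fit is flagged unidentifiable when all `P = 1`.

### Discrete-choice models

- **Binary decision model**: logistic regression of `y` on event-level
  covariates (number of options, home-area size, focal age, prior communal
  experience, density, season), fitted by IRLS; constant covariates are
  dropped with a flag and complete separation triggers a flagged ridge.
  Coefficients match `statsmodels` GLM to 1e-6.
- **Partner model**: conditional (McFadden) logit over the options of each
  communal event, fitted by Newton's method with step-halving. On strictly
  two-option events it is algebraically identical to paired logistic
  regression on covariate differences without intercept, which is used as a
  correctness oracle. Covariates are z-scaled option-level quantities
  (relatedness, association time, age difference, pup age, litter sizes,
  shared regular boxes); scaling factors are stored for back-transformation.

### Rank and permutation tests

`mann_whitney` returns the U statistic with midranks. The p-value is exact by
complete enumeration (doubled smaller tail, the `wilcox.test` convention)
when `min(n, m) ≤ 8` and `C(n+m, n) ≤ 200,000`, else a tie-corrected normal
approximation without continuity correction. Group comparisons across choice
events use an event-level permutation test so that options of one event move
together — a conservative stand-in for the random-effect structure a mixed
model would use.

## 3. Relatedness

- **Pedigree kinship** is computed by the recursive coancestry algorithm;
  `expected_r = 2φ` (non-inbred convention). Verified against Monte-Carlo
  gene dropping. Dyad classes: full siblings (0.5), parent–offspring (0.5),
  half siblings (0.25), and "unrelated" defined as contemporaneous pairs
  sharing no ancestor within two generations (expected ≈ 0 but not exactly 0
  in a closed colony — see Limitations).
- **Marker estimators**: the Wang moment estimator (weighted least squares on
  the three allele-sharing category indicators, weights from the reference
  allele-frequency moments `a2…a4`; `r̂ = φ/2 + Δ`) and the symmetrised
  Queller–Goodnight ratio-of-sums estimator (directions with a zero
  denominator, i.e. a focal homozygous for a fixed allele, are skipped).
  Monomorphic and missing loci are excluded per dyad. Reference frequencies
  are cohort (birth-year) allele frequencies, mirroring field practice where
  each year's sample defines its own background.
- **Estimator calibration** samples `n` dyads per pedigree class (seeded,
  without replacement) and reports the Pearson correlation between
  pedigree-expected and marker-estimated r, plus per-class means. A guard
  returns NaN when either side is numerically constant (σ ≤ 1e-12).

## 4. Spatial genetic autocorrelation

Females located at the same monthly nest check (box occupancy at the check
instant, half-open stay intervals `[entry, exit)`) form the per-check sample.
For each check, squared multilocus genetic distances (allele-count mismatch
per locus, missing loci skipped) are double-centred to a covariance-like
matrix `C`. The autocorrelation for a distance class pools, across checks,
the off-diagonal entries of in-class dyads over the corresponding diagonal
terms. Distance classes are the same-box class `{0}` followed by half-open
100 cm rings.

**Finite-sample centring.** Double-centring on the sample makes the expected
off-diagonal entry `−tr(C)/(N(N−1))` under random relabelling, so the raw
statistic has a small negative null mean. Each dyad's numerator contribution
is therefore shifted by `+tr(C)/(N(N−1))`, making the permutation null mean
zero by construction (the output's `null_mean` column verifies this
empirically). The null distribution is obtained by permuting genotype labels
within checks (999 draws by default); `p` is the upper-tail rank of the
observed r. Bootstrap CIs resample in-class dyads.

## 5. The synthetic colony generator

`simulate.generate_colony` produces a fully ground-truthed dataset emulating
a two-year study of a free-living barn population: ~40 nest boxes in four
sections (no movement barriers), a closed pedigree from 16 founders,
overlapping generations, and RFID-style event streams for adult females.

What it emulates, and the defaults chosen to match the observed system:

| parameter | default | rationale |
|---|---|---|
| `n_founders` | 16 | with `pup_survival` gives ~300 observed births over two years, matching the scale of the field dataset |
| `study_days` | 730 | two year-cohorts, as in a two-year field study |
| `litter_mean` | 5.0 | Poisson truncated at 1; house-mouse litters of 3–8 |
| `pup_survival` | 0.4 | high juvenile mortality; controls population growth |
| `mate_fidelity` | 0.6 | probability of reusing the previous sire; creates full-sib pools |
| `n_loci`, `alleles_per_locus` | 25, 6 | 25 microsatellites; 6 alleles + 5% missing calls yields calibration R ≈ 0.80, the informativeness of a real microsatellite panel (8 pristine alleles gives R ≈ 0.9, unrealistically clean) |
| `genotype_missing_rate` | 0.05 | per-locus missing-call probability |
| `home_boxes_mean` | 5.0 | females regularly use ~5 boxes |
| `dispersal_mean_cm` | 100 | mother–daughter home-centre distance; set to 50 to strengthen kin clustering |
| `rest_hours` | (4, 7) | daily long stays in home boxes that dominate association time |
| `discovery_age_days` | (1, 12) | lag between birth and discovery at checks |
| `option_window_days` | 16 | analysis constant (see above) |

Movement is generated per female-day: one long rest stay in a home box, a few
short visits, and occasional exploration of distant boxes, with per-female
interval streams kept non-overlapping. Genotypes follow Mendelian
transmission from Dirichlet(1) founder frequencies. The decision rule is
configurable: `random_box` (uniform over home boxes — the availability null),
`power` (communal with probability `P^a`), or `preference` (logit over
options with configurable weights on relatedness, association, pup age). The
ground truth of every decision (P, options, chosen partner, rule parameters)
is stored in `truth.json`.

`simulate.simulate_dyad_panel` is a separate generator of independent nuclear
families for estimator validation: it yields exactly `n` disjoint dyads per
class whose members share no ancestry across families, so class expectations
are exact (see Limitations for why colony-sampled dyads are not suitable for
unbiasedness checks).

## 6. Numerical choices

- NLS in one parameter: damped Newton from `a = 1` with a bounded Brent
  fallback on `[1e-6, 64]`; convergence to |gradient| < 1e-10.
- Wang estimator: closed-form 2×2 WLS solve per dyad; loci with reference
  `a2 ≥ 1 − 1e-12` (monomorphic) are skipped.
- Conditional logit: Newton with step-halving on the log-likelihood;
  non-positive-definite information at the optimum yields NaN standard errors
  rather than a crash.
- Association overlap: exact integer-second interval arithmetic, two-pointer
  merge, O(n log n) in the number of stays.
- Permutation and bootstrap draws use `numpy.random.default_rng` with
  explicit seeds throughout; all pipeline stages are deterministic given the
  configuration seed.

## 7. Limitations

- **Background relatedness.** In a closed colony descending from 16 founders,
  pedigree-"unrelated" females (no shared grandparent) still share deeper
  ancestors, so marker estimates referenced to colony allele frequencies are
  compressed and class means deviate from the nominal 0/0.25/0.5 values in
  both directions (drift in the reference sample vs. shared deep ancestry).
  This mirrors real systems — field estimates of full-sib means around 0.53
  are typical — and is why estimator unbiasedness is validated on the
  independent-family dyad panel instead.
- **Cryptic communal litters.** When two litters are discovered already
  mixed, the chooser is unobservable. The analysis assigns it by a seeded
  draw and flags the event; ground-truth comparisons of the chooser identity
  are only meaningful for non-cryptic events.
- **No random effects.** Repeated events by the same female are treated as
  independent in the regression models; the event-level permutation test is
  provided as the robust alternative for group comparisons.
- **Movement model simplicity.** The generator's day-structured movement has
  no social dynamics beyond home-area overlap; association time is a function
  of spatial overlap, not partner preference, unless the `preference`
  decision mode is used.
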