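# nestchoice

Analysis pipeline for **female nursing-partner choice** in group-living house
mice, with a synthetic colony generator for end-to-end validation.

## Scientific problem

In barn-dwelling house mouse populations, females give birth in nest boxes and
frequently pool their litters with another female, nursing all pups communally.
Two questions drive the analysis:

1. **Is communal nursing an active choice, or a passive by-product of nest-site
   availability?** A female whose regular nest boxes are mostly occupied by
   other litters may end up sharing simply because free boxes are scarce. The
   null model here is a power function: if a female picks a box uniformly at
   random among her home-area boxes, the probability of nursing communally is
   `y ~ P^a` with `a = 1`, where `P` is the proportion of her home-area boxes
   occupied by potential partners. `a < 1` means females seek out occupied
   boxes (attraction); `a > 1` means they avoid them.
2. **If partners are chosen, what predicts the choice?** Candidate covariates
   include pairwise genetic relatedness, prior social association (seconds of
   nest-box cohabitation from RFID tracking), age difference, and litter state.

Answering these requires several supporting pieces that the package provides as
reusable modules:

- **`tracking`** — home-area (regularly used boxes) and pairwise association
  time from RFID entry/exit event streams, with exact interval overlap.
- **`choices`** — choice-set construction: for each observed birth, the set of
  lactating "option" females (litters 0–16 days old in the mother's home
  area), the occupancy proportion `P`, the communal/solitary outcome, and the
  identity of the chosen partner, with explicit exclusion bookkeeping.
- **`relatedness`** — pairwise relatedness from microsatellite genotypes (Wang
  moment estimator and Queller–Goodnight), pedigree kinship by recursive
  coancestry, and an estimator-calibration procedure that correlates
  pedigree-expected `r` with marker estimates over known dyad classes.
- **`spatial`** — multilocus spatial genetic autocorrelation between females
  cohabiting nest boxes at monthly checks, with distance-class permutation
  tests and bootstrap confidence intervals.
- **`stats`** — nonlinear least squares for the power null model, binary and
  conditional (within-choice-set) logistic regression, exact/asymptotic
  Mann–Whitney tests and event-level permutation tests.
- **`simulate`** — a ground-truthed synthetic colony: pedigree, microsatellite
  genotypes with Mendelian transmission and missing calls, box layout, RFID
  event streams, births, and configurable decision rules (uniform-random box,
  power-law availability, or covariate-driven preference).

## Worked example

Run the full pipeline on the default synthetic colony (two simulated years,
40 nest boxes, 16 founders):

```console
$ nestchoice pipeline --seed 1 --out run1
[1/6] simulating colony (seed=1) ...
[2/6] home areas ...
[3/6] choice sets ...
[4/6] relatedness calibration ...
[5/6] spatial autocorrelation ...
[6/6] model fits ...
done; manifest at run1/manifest.json
```

`run1/summary.json` then holds the headline numbers (actual output):

```json
{
 "n_births_observed": 311,
 "n_choice_events": 267,
 "n_excluded": 44,
 "communal_fraction": 0.47191011235955055,
 "mean_options": 3.756554307116105,
 "mean_regular_boxes": 5.352059925093633,
 "mean_females_met": 48.39700374531835,
 "power_a": 0.9995055156231882,
 "power_t": -0.005820072210439988,
 "power_p": 0.995360642892815,
 "calibration": {
  "qg": 0.8038025972396384,
  "wang": 0.7777471608213021
 },
 "spatial_first_ring_r": 0.014746780055372555,
 "spatial_first_ring_p": 0.001
}
```

Reading this: 311 births yielded 267 usable choice events (44 excluded with
reasons in `run1/choices/excluded.csv`); 47% were communal; mothers used on
average 5.4 boxes regularly and had 3.8 potential partners per event. The
default generator lets mothers pick a home box uniformly at random, and the
fitted availability exponent `a = 1.000` (t = −0.006, p = 0.995) correctly
fails to reject the `a = 1` null. Marker-based relatedness correlates with
pedigree expectation at R ≈ 0.78–0.80, and females sharing a nest box are
genetically more similar than expected (first distance class r = 0.0147,
permutation p = 0.001).

`run1/stats/fits.json` adds the discrete-choice fits — e.g. the conditional
logit over 126 communal events with 2+ options (coefficient, SE):
`pup_age −0.356 (0.120)`, `r_hat 0.223 (0.118)`,
`association_s −0.458 (0.158)`. Under the uniform-random decision rule these
reflect availability structure, not preference; rerun with
`decision_mode: preference` in a YAML config to generate and recover true
preference weights.

Each stage is also available separately (`nestchoice simulate`, `track`,
`choices`, `relatedness`, `spatial`, `navail`, `choice-model`); see
`nestchoice --help`.

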