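# Methods

## The mechanistic model

The response is the viable cell count after 7 days of HSPC culture on a
scaffold. Each sample is described by three condition constants and twelve
measured secreted-factor concentrations, combined linearly:

```
N = Σx Ax·cx·w_auto(n) + Σx Bx·cx·w_para(n) + C·n + D·a·w_adh(n) + E·h + N0
```

* `cx` — per-cell factor level, pg/mL per cell: the supernatant concentration
  divided by the day-7 cell count of the same sample. Division by cell number
  removes the trivial population-size effect so that the factor terms carry
  secretion/response information.
* `n` — cell–cell contact number: 1 in single-cell 15 µm cavities, 3.6 in
  40 µm cavities (hexagonal packing with on average 9 of 12 possible
  neighbors interacting), 6 on planar surfaces. The value 3.6 is used as a
  fixed constant of the encoding, not re-derived.
* `a` — material adhesion strength: 1 for FN-functionalized PDMS, 0.5 for
  tissue-culture plastic, 0 for PEG-based hydrogels.
* `h` — heparin indicator: 1 for starPEG–heparin scaffolds, else 0. Heparin
  acts by sequestering heparin-affine factors into the hydrogel bulk, so its
  coefficient summarizes depletion of both measured and unmeasured mediators.

Weight functions encode the mechanistic directions: autocrine signaling is
strongest for isolated cells (`w_auto(n) = 1/n`), paracrine signaling needs
neighbors and grows with occupancy (`w_para(n) = n − 1`, zero at n = 1), and
cell–ECM adhesion acts reciprocally to cell–cell contact (`w_adh(n) = 1/n`,
more bottom/side contact area in small cavities). Only the directions are
mechanistic commitments; the functional forms are the simplest monotone
choices with `w_para(1) = 0` and are configurable (`encoding.*` keys, with
`n`, `1/n`, `n − 1` and material-only variants). With only three distinct
`n` values any monotone choice spans the same qualitative space. The model is
deliberately restricted to linear influences; interaction and saturation
terms would overfit a ~50-sample design.

## Preprocessing

Tables are CSV (UTF-8, one header row, empty cells or `NA` missing). Factor
levels are per-cell normalized, then samples missing exactly one factor are
completed with that factor's mean per-cell level across the usable samples;
samples missing two or more factors are excluded from modeling with a
warning, and do not contribute to imputation means. Imputation operates on
per-cell levels because those are what the model consumes. Units are
validated, never converted: the mean-0/SD-1 scaling makes the fit invariant
to any per-column unit change.

## PLS fit

Predictors and response are centered and scaled to SD 1 (n−1 denominator).
Single-response NIPALS extracts components `w = X'y/‖X'y‖`, `t = Xw`,
`p = X't/t't`, `q = y't/t't`, deflating `X ← X − tp'`; `y` is not deflated
(equivalent in exact arithmetic for one response). Weight signs are fixed by
making the first nonzero entry non-negative, so fits are platform-
deterministic. Extraction stops early when `‖X'y‖` falls below 1e-12 of its
initial value; rank is determined by singular values above 1e-10 of the
largest. Scaled coefficients are `B = W(P'W)⁻¹q`; raw-scale coefficients and
the intercept are recovered by inverting the scaling. VIP scores use
`VIPj = sqrt(p·Σa SSYa·w²ja / Σa SSYa)` with `SSYa = q²a·t'ata`, so
`mean(VIP²) = 1` by construction.

## Component selection and pruning

K-fold cross-validation (default k = 7, folds stratified by material ×
geometry, seeded) computes PRESS per candidate component count. Scaling is
re-estimated inside every training fold; held-out residuals are taken on the
raw count scale and divided by the full-data SD of the response, making PRESS
comparable across folds (the one place the procedure needed a definition the
field convention leaves open). A training fold that loses all variance in a
column drops that column for that fold with a warning.

The Van der Voet T² test compares each candidate against the PRESS optimum by
sign-flip randomization of the paired squared-residual differences —
exhaustive over all 2ⁿ assignments for n ≤ 12 pairs, otherwise 10,000 seeded
draws with add-one smoothing. The chosen count is the smallest with p > 0.10
that also explains ≥ 90% of cumulative X and y variance; if no count
satisfies both, the PRESS optimum is used and flagged. The α = 0.10 and k = 7
defaults follow the conventions of the commercial PLS implementation this
procedure mirrors; both are configurable. Note the chosen count can exceed
the PRESS optimum when the variance rule binds.

Variables with VIP < 0.8 (the conventional relevance cutoff) are deleted and
the entire selection re-run on the reduced design. Classification then reads
each retained `auto_*`/`para_*` column as a signaling call (direction from
the coefficient sign; significance = VIP at/above threshold and a nonzero
coefficient); `cellcell`, `adhesion` and `heparin` are reported separately as
environment effects.

## External validation and stepwise rebuild

A frozen model applied to an external condition set is scored by regressing
observed on predicted counts: R², slope and intercept, plus a classical
pointwise prediction interval of that simple regression at the 90% level (the
construction is stated because "prediction range" has no unique definition).
A slope far from 1 at high R² indicates a global rescaling of proliferation
(e.g. a different cytokine background) rather than structural failure.

The stepwise rebuild applies the full model's scaled coefficients over
cumulative variable sets ordered by decreasing VIP (default cut points 1.6,
1.3, 1.1, then the remainder) without refitting; the empty set predicts the
response mean and the full set reproduces the fitted values exactly
(telescoping identity, asserted to 1e-10 in tests). The distance
`‖ŷ_S − ŷ_full‖` is not asserted to shrink monotonically: with correlated
contributions of mixed sign it need not, and the tests check the exact
telescoping identity instead. The global response mean is used at every step
(no per-material intercepts).

## Synthetic data generator

The generator emulates the culture design: 7 material × geometry conditions
(PDMS-FN, starPEG-heparin and starPEG hydrogels at 15/40 µm, planar TCP), by
default 4 donors × 2 replicates = 56 samples at 10 ng/mL cytokine background.
Four donors per condition match the upper end of the emulated study's design;
with only two donors the donor-level secretion variability is too poorly
sampled to separate the strongly collinear autocrine predictors (the
`auto_*` columns share the `1/n` × cavity structure and correlate at ~0.9),
which occasionally flips the sign of the weaker autocrine coefficient.

Per-cell secretion of factor x is
`baseline_x · m(cavity) · (1 − ρx·h) · LN(donor) · LN(replicate)`:

* baselines 0.005–0.05 pg/mL per cell (a multiplex panel read against ~4×10⁴
  cells), highest for ANG-2, HGF, RANTES, TGF-β1, VEGF;
* `m(CAV15) = 1.3` encodes the higher per-cell secretion observed in
  single-cell cavities; 40 µm and planar are 1.0;
* ρx is the sequestered fraction on heparin scaffolds, factor-specific
  (0.3–0.8 for the heparin-affine factors; 0 for IL-12, ANG-2, TGF-β1 and
  VEGF, which behaved as non-sequestered);
* log-normal multiplicative noise: σ = 0.30 per sample×factor (typical
  biological CV between parallel cultures) and σ = 0.10 per donor×factor.
  Concentrations are positive and right-skewed, hence multiplicative noise;
  counts get additive Gaussian noise (default SD 3000 cells, ~7% of the mean)
  truncated at zero and rounded.

Raw supernatant levels are emitted as per-cell level × realized count, so
per-cell normalization inverts the generator exactly. Missingness knocks out
at most one factor per sample at rate 0.05. The default truth activates six
effects mirroring the qualitative pattern of the emulated system — heparin
+15,000 cells, adhesion −13,500, autocrine HGF −1.5e5 and RANTES +1.5e5
(cells per pg/mL/cell), paracrine IL-12 +2.4e5 and ANG-2 −2.2e4, intercept
40,000 cells — with magnitudes (free parameters; the emulated study reports
only scaled coefficients) spaced so the scaled effects are distinct, ordered
to match the reported importance pattern, and spanning VIP ≈ 0.8–1.8. All
other coefficients are zero.

What passing recovery tests shows — and what it does not: the generator
reproduces the collinearity structure, positivity, skew, missingness and
noise scales of the assay, so recovery results demonstrate that the pipeline
correctly inverts its own model class under realistic correlation. They do
not certify behavior under model misfit (nonlinear dose–response, factor
interactions, non-Gaussian count noise, batch effects between donors run on
different plates), which real data may contain.

A known property worth stating: VIP measures a predictor's weight in the
projection, i.e. marginal association, not causal effect size. Under this
design the adhesion column's VIP is inflated by its correlation with the
material structure and paracrine VIPs are deflated by their correlation with
occupancy; a zero-truth paracrine column crosses VIP = 0.8 in a substantial
fraction of runs even at low noise, although it never enters the top ranks.
Significance calls at the 0.8 threshold should therefore be read as
"relevant to prediction", not "causally active".

## Numerical and testing choices

Degenerate inputs fail loudly: zero-variance columns name themselves, a zero
cell count with measured factors refuses per-cell normalization, fewer than
three samples refuse scaling, an over-aggressive VIP threshold that would
empty the model raises. Ties in PRESS resolve to the smaller component count.
All stochastic stages (fold assignment, randomization draws, simulation) take
explicit seeds and the pipeline is a pure function of (data, config, seeds);
output bundles are byte-reproducible.

Test problem sizes are chosen to exercise the mathematics at desk scale:
oracle comparisons on 8×5 designs, exhaustive randomization up to 2¹⁶
assignments, 1000-replicate type-I calibration, 50-seed recovery and pruning
simulations on the default preset; the full suite runs in well under a
minute. scikit-learn's PLS appears only as an independent cross-check in one
test, never in the implementation.

## Limitations

* The linear model ignores saturation and factor interactions by design.
* `n = 3.6` and the adhesion constants are printed encoding constants; the
  pipeline treats them as given (overridable via lookup tables).
* The capacity calculator uses ideal hexagonal packing without edge
  correction (agreement with the printed two-significant-figure values is
  within 3%).
* Imputation assumes missingness is technical (missing completely at random,
  one factor at a time); systematic dropout would bias the factor means.
* Donor pooling: rows are kept as replicates; no donor random effect is
  modeled. With 2–4 donors a mixed model would be under-identified.
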