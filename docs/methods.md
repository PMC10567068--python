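# Methods

## Scope and model

The package predicts intrinsic aqueous solubility, log S₀ (log10 molar, the
uncharged species at 25 °C), from user-supplied descriptors: clogP, melting
point, the five Abraham solvation descriptors (A, B, Sπ, E, V) and — computed
from SMILES when a structure is given — the Kier molecular flexibility index
Φ. It deliberately trades accuracy ceilings for transparency: every model is
a short closed-form expression whose terms map onto physical drivers of
solubility (lipophilicity, crystal lattice energy, H-bonding, molecular
flexibility).

Key assumptions:

* solubility refers to the neutral form; no ionization/pKa correction is
  applied, and multi-fragment SMILES (salts) are reduced to the largest
  fragment before descriptor calculation;
* melting behaviour enters only through (mp − 25), clamped to zero for
  liquids and compounds melting at or below 25 °C (the standard convention
  for applying the GSE to liquids);
* Abraham descriptors are inputs, not computed from structure — their
  estimation is a separate problem with its own error budget.

## The flexibility descriptor

Φ = ¹κ·²κ/NHA, with ¹κ = A(A−1)²/P₁² and ²κ = (A−1)(A−2)²/P₂², where A is the
heavy-atom count, P₁ the bond count and P₂ the number of two-edge simple
paths on the hydrogen-suppressed skeleton. Bond orders and aromaticity do not
enter the path counts. The alpha-modified variant (default) replaces A by
A + α and each Pᵢ by Pᵢ + α, with α the Hall–Kier covalent-radius/
hybridisation correction (sp³ carbon is the zero reference; α is taken from
RDKit). Both variants are exposed because the closed-form identities used in
testing (Φ of an A-node unbranched alkane equals A − 1; cyclohexane
Φ = 1.5432) hold for the unmodified form, while drug-like predictions use the
alpha-modified kappas, which match RDKit's implementation to 1e−6 (checked in
the suite as an independent oracle). Molecules with fewer than three heavy
atoms have no defined ²κ; their Φ is reported missing and model selection
routes them to the classic GSE.

## Coefficient functions and their parameters

The flexible-acceptor model's eight b-parameters (stored to published
precision) define:

| function | form | default | role |
|---|---|---|---|
| c₀(x) | b₀ + b₁e^(−b₂x) | −4.456 + 6.049e^(−0.0817x) | intercept: liquid-state solubility, falls with flexibility/acceptor strength |
| c₁(x) | b₃ + b₄(1−e^(−b₅x)) | −1.326 + 1.058(1−e^(−0.1226x)) | clogP slope: lipophilicity penalty damps out for flexible acceptors |
| c₂(x) | b₆ + b₇x | −0.941 + 0.0389x | crystal-lattice term per (mp−25)/100, near the classic −0.01 per degree |

x = Φ + B. b₂ and b₅ are constrained positive (decaying exponentials). Note
the melting term is scaled by 100 relative to the classic GSE, so c₂ ≈ −1
corresponds to the classic −0.01.

The grouped-ABSOLV table holds one row of a₀–a₆ per group; all six rows
include the A·B cross term. Group assignment precedence: a user-supplied
class always wins; otherwise MW > 800 Da → big, then a permanently charged
nitrogen without an acidic group → quaternary, then a SMARTS-based net-charge
heuristic at pH 7.4 (carboxylic/sulfonic/phosphonic acids, tetrazoles and
imides count as acidic; aliphatic amines, amidines and guanidines as basic;
both → zwitterion; neither → neutral). The heuristic is intentionally coarse
— it exists so structure-only inputs can be routed somewhere sensible, not to
replace a proper pKa calculation.

## Model selection

The XOR decision tree partitions [0, ∞) in Φ into half-open intervals. The
crossovers 1.66 (below: classic GSE) and 10.83 (above: GSE(Φ,B)) are fixed;
the middle domain's per-interval winners come from the shipped bin profile,
with interval edges at midpoints between consecutive bin-average Φ values
(the bin centred at 5.0 spans [4.5, 5.5)). This reproduces the published
winners deterministically without the raw training database. A documented
alternative lower crossover of 1.95 appears in the source material's
decision-tree figure; the text value 1.66 is adopted. `profile_bins` +
`decision_rule_from_profile` rebuild the rule from any retrained dataset.
The simplified recommendation (`recommended_select`) is: consensus for
Φ < 11, GSE(Φ,B) otherwise.

In `closest_prediction`, ties are broken by input column order (first listed
wins).

## Training procedure

`FlexibleAcceptorGSE.fit()` performs the two-step procedure:

1. records sorted on x = Φ + B (stable sort, so duplicate keys stay
   contiguous) and split into n_bins contiguous bins — quantile (equal-count)
   binning by default, equal-width by flag. Equal counts are the default
   because they stabilise the per-bin regressions, matching the near-equal
   bin populations the published training reports;
2. per bin, OLS of log S₀ on [1, clogP, (mp−25)/100]; rank-deficient designs
   (constant clogP or mp within a bin) raise a training error naming the bin;
3. the three coefficient functions are fitted to the per-bin (x̄, c₀, c₁, c₂)
   points: c₂ by ordinary least squares (exact linear sub-problem), c₀ and c₁
   by bounded nonlinear least squares (decay rates > 0) with multi-start over
   rate initial values {0.01, 0.03, 0.1, 0.3, 1.0}, offsets/amplitudes
   initialised from the curve tails, convergence tolerance 1e−10 on the
   objective, best-of selection by SSE. Per-curve Pearson r² and RMSE are
   reported as diagnostics.

OLS stands in for the partial-least-squares regression used historically:
with two near-orthogonal predictors and n ≫ p a full-rank PLS fit converges
to OLS, and OLS removes a latent-component count that was never specified.
At least 8 bins are required (8 parameters). `GroupedAbsolv.fit()` runs the
seven-term OLS per group with a floor of 8 records per group; undersized
groups are reported unfit rather than extrapolated.

## Synthetic data

`simulate_records` emulates the descriptor table of a large curated
solubility database: independent uniform draws with Φ ∈ [0.4, 43],
B ∈ [0.4, 12.9], clogP ∈ [−5.8, 8.7], mp ∈ [25, 350] °C (the published
database ranges) and A ∈ [0, 3], Sπ ∈ [0.5, 6], E ∈ [0, 6], V ∈ [0.5, 10]
(drug-like choices; V spans roughly 70–1400 Da of McGowan volume). Charge
classes are multinomial with the published group counts
(1578/945/641/4246/93/39). log S₀ is the chosen generating model's value plus
N(0, σ) noise, σ = 0.5 by default — the scale of the per-bin RMSE the models
achieve on real data. Draws are consumed per record, so extending n leaves
earlier records byte-identical.

Two deliberate departures from realism, and what they imply:

* descriptors are independent by default, whereas real databases couple size,
  flexibility and acceptor count (the "comet" joint structure). The optional
  correlated mode links Φ linearly to MW with 20 % jitter for tests that need
  a realistic joint range. Passing recovery tests on synthetic data therefore
  demonstrates the estimator's correctness, not the models' accuracy on real
  chemistry;
* `key_levels` restricts Φ+B to a discrete grid (split 70/30 into Φ and B).
  This exists because exact (σ = 0) end-to-end recovery of the b-parameters
  is only well-posed when x is constant within each bin — with continuous x,
  per-bin OLS estimates c(x̄) only to the order of the bin width. The
  noiseless inversion study uses 20 levels with width binning (bins align
  with levels, recovery is machine-precision); the noisy study uses the
  continuous default.

## Metrics

r² is the validation form, 1 − SS_res/SS_tot about the observed mean — it can
be negative, which is informative (the model is worse than predicting the
mean). Bias is mean(obs − pred): overestimated solubility ⇒ negative bias.
MPP is the percentage of residuals within ±0.5 log, boundary inclusive (the
inclusive reading is fixed so results are bit-stable). Non-finite pairs are
excluded and counted. Metrics require n ≥ 2 and non-zero observed variance.

## Numerical conventions

* Predictions are carried at full float precision; the CLI rounds to 2
  decimals on output unless `--full-precision` is given.
* Ties in per-bin best-model selection are broken GSE(Φ,B) > ABSOLV(GRP) >
  GSE(classic), favouring the model recommended for flexible chemical space.
* CSV: comma-separated, UTF-8, header required, "." decimal, missing as empty
  or "NA"; column names case-insensitive with a documented alias map.
* Exit codes: 0 success, 2 input error, 3 configuration error, 4 training
  failure.
* Problem sizes in the test suite and acceptance script: 10,000-record tables
  for recovery studies, 20 bins, 25-replicate Monte-Carlo checks — sizes at
  which the law-of-large-numbers tolerances quoted in the tests hold
  comfortably while the whole suite runs in seconds.

## Known limitations

* The heuristic charge classifier is substructure-based and will misclassify
  unusual ionizable groups; supply `charge_class` explicitly when known.
* No uncertainty is attached to individual predictions; the per-bin RMSE
  profile is the closest available error statement.
* The shipped bin profile (and hence the XOR rule's middle domain) reflects
  one training database; retrain the profile before trusting the XOR
  selector on a differently distributed dataset — or use the consensus,
  which is the published prudent default for Φ < 11.
* Abraham descriptor quality bounds ABSOLV(GRP) accuracy; the package treats
  them as exact inputs.
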