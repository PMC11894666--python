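# Methods

This note documents the models, the synthetic ground truth, the numerical
choices, and the points where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Domain model

A *peptidoform* is an upper-case amino-acid sequence plus localized
modifications plus precursor charge; charge is part of its identity because
fragment intensities and CCS both depend on it. Modification positions are
1-based on residues with 0 = N-terminus and n+1 = C-terminus, at most one
modification per position. The text notation is ProForma-style:
`AC[+57.02146]DK/2`, with `[name]` accepted for a small built-in table
(carbamidomethyl, oxidation, acetyl, phospho, methyl, dimethyl,
deamidation). Monoisotopic element masses follow CODATA/NIST; residue
masses are derived from elemental formulas so fragment, precursor and
composition arithmetic are mutually consistent.

Spectrum identifiers in PSM tables are matched to MGF titles by exact
string comparison; no fuzzy vendor-specific normalization is attempted.

## Fragment annotation and normalization

Only singly charged b and y ions are computed (the series the intensity
models cover); no neutral losses, no isotope peaks. Matching takes, for
each theoretical ion, the nearest observed peak within tolerance (default
10 ppm); one observed peak may serve several theoretical ions, each
theoretical ion takes at most one peak, and ties resolve to the closest
m/z. Observed intensities are divided by the spectrum's **full** total ion
current — all peaks, not only annotated ones — then transformed as
log₂(x + 0.001). The pseudocount keeps unmatched ions finite
(log₂ 0.001 ≈ −10) and is configurable; the TIC denominator is also
configurable to annotated-only, but full-spectrum is the default because
"total ion current" conventionally means the whole spectrum. Annotation
plus normalization is invariant to rescaling all intensities by any c > 0.

## Intensity model

Each cleavage site is one training row: 20 composition counts over the
±1-residue window, four physicochemical scales (Kyte–Doolittle
hydrophobicity, a gas-phase basicity scale, Chou–Fasman helicity,
isoelectric point) at the four window positions and as prefix/suffix
means, windowed and prefix/suffix modification mass, and global
descriptors (length, site index, site fraction, charge, neutral
mass/1000). Two XGBoost regressors (b and y) are fitted to the normalized
log₂ intensities; hyperparameters (trees, depth, learning rate) come from
a small random search (default 20 draws) with 5-fold cross-validation,
selected on the b-ion targets and shared by both regressors. Training
refuses fewer than 50 unique peptidoforms. Minimum peptide length is 4;
below that the window encoding degenerates.

Evaluation correlates the concatenated b+y vector per PSM (all PSMs of a
test peptidoform, not only the best) and reports medians per peptide-type
label. PSMs with fewer than two matched ions are excluded and counted.
Splits are peptidoform-disjoint under charge-aware identity and stratified
by label.

**The replicate ceiling.** The intra-peptidoform baseline is the PCC
between observed spectra of the same peptidoform. Note a statistical
subtlety: with independent noise, two replicates correlate at
r = σ²ₛ/(σ²ₛ+σ²ₙ), while a model that predicts the *noiseless* signal
correlates with one replicate at √r. The attainable ceiling for
model-vs-observed PCC is therefore √(replicate PCC), and the property test
bounds the model by √r + 0.02, not by r itself. On real data trained
models sit below the replicate PCC because model error dominates; on clean
synthetic data a good model legitimately exceeds it.

## CCS model

### Encoding

Four paths, padded to a fixed maximum length of 60 residues (covering the
usual 8–50 search range) with an explicit padding channel:

1. per-residue atomic composition (C, H, N, O, S) plus a modification-mass
   channel; modification composition deltas are added at the modified
   residue's row;
2. diamino (consecutive residue pair) composition, with modification
   contributions in both overlapping rows;
3. one-hot encoding of the unmodified sequence;
4. global block: length, charge, total atomic composition (including
   modifications), relative frequencies of histidine, bulky (F/W/Y),
   acidic (D/E) and K/R residues, and the compositions of the first two
   and last two residues.

"Composition at specific positions" is interpreted as the two terminal
residues at each end. Modifications with unknown composition fall back to
a nearest-mass approximation in oxygen and hydrogen counts, with a
warning. The encoder exposes two switches used by the harnesses:
`ignore_modification` (zeroes one modification's composition and mass
everywhere) and `substitute` (replaces a residue's identity in all paths,
e.g. by glycine).

### Backends

*Gradient-boosted reference backend (default).* Gradient boosting with
**linear** base learners (xgboost `gblinear`, cyclic coordinate descent,
no regularization) on the standardized global block. Linear boosters were
chosen deliberately: boosted stumps/trees approximate smooth monotone
structure with plateaus, cannot extrapolate beyond the training range, and
in side-by-side trials on linear ground truth stall at an irreducible test
error, whereas boosted linear learners converge to the least-squares
solution — exact parameter recovery, sane extrapolation to unseen
modification compositions, and deterministic to the byte. Tree boosters
(`gbtree`) and the fully flattened four-path encoding remain configuration
options for nonlinear ground truth.

*Four-path convolutional backend.* A compact numpy network: width-4
convolution + ReLU + global max pooling per matrix path, a dense layer for
the global path, concatenation, then a stack of six dense layers ending in
one linear unit. Weights initialize from N(μ=0, σ=1); training is
mini-batch Adam on standardized targets, at most 300 epochs with early
stopping (patience 10) on the validation split, best weights restored.
This backend exists to honor the architecture class; the reference backend
is what the fast deterministic tests and the acceptance script use.

Training splits are 89.1% / 0.9% / 10% (train/validation/test) over
deduplicated peptidoforms; duplicates collapse to their mean CCS with a
warning; an empty validation split is an error. Predictions are floored at
1 Å² (CCS is physically positive). The model log records split sizes, the
stopping iteration and held-out MAE/PCC.

### Alignment, merging, isomers

`align_datasets` fits reference = a·other + b by ordinary least squares on
overlapping peptidoform-charge pairs (minimum 10; attenuation bias from
noise in the regressor is negligible at CCS spreads of tens of Å²).
`merge_datasets` maps the second dataset through the fit, averages
overlapping pairs and returns a deduplicated union; merging a dataset with
itself is the identity. `collapse_isomers` averages records that differ
only in isomeric modification placement (same sequence, same modification
mass multiset, same charge), logging group sizes.

### Leave-one-out harnesses

The modification harness trains on all non-carriers of a named
modification and evaluates on the carriers twice: composition encoded vs
composition ignored. The amino-acid harness trains on peptides lacking a
residue and evaluates carriers with the true identity vs the residue
replaced by glycine in every path. Both report MAE and PCC for the two
scenarios, their difference, and the carrier count. Glycine itself is not
a valid target (it is the substitution baseline).

### Ion-mobility conversion

1/K₀ (Vs/cm²) ↔ CCS (Å²) uses the Mason–Schamp low-field relation with a
nitrogen drift gas (28.00615 Da) and a default drift-gas temperature of
305 K, reduced mass from the ion's mass, and the Loschmidt number density
at standard conditions. The test suite cross-checks the closed form
against an independent assembly of the same physics from
`scipy.constants`.

## Rescoring

### Q-values

Target-decoy competition with the conservative +1 correction:
FDR(t) = (#decoys ≥ t + 1) / max(#targets ≥ t, 1), q-value = running
minimum over thresholds, ties share one threshold so input order is
irrelevant, decoys receive q-values but never count as accepted. An exact
consequence of the +1 term: accepting anything at q ≤ 0.01 requires at
least 100 targets above the threshold, so small studies should read
q-values at coarser thresholds. Peptide-level rollup keeps the best PSM
per charge-agnostic peptidoform (charge-aware is a switch); protein level
assigns each accession its best peptide score, competes each target
accession against its decoy counterpart (prefixes `rev_`, `DECOY_`,
configurable) and keeps the winner — picked-protein FDR, no parsimony
inference.

### Calibration and features

CCS predictions are calibrated before feature computation: among target
PSMs at q ≤ 0.01 under the *search* score, the best-scoring 75% (score
rank, not q rank, since "most confident" naturally reads as best-scoring)
are reduced to unique precursors and observed = a·predicted + b is fitted;
under 10 eligible precursors the calibration degrades to identity with a
warning. Features per PSM: search block (engine score plus any numeric
engine columns), spectrum block (PCC of predicted vs observed normalized
b+y intensities, matched-ion count and fraction), optional RT block, CCS
block (observed, calibrated predicted, absolute error, percent error).
Missing values are explicit NaNs, median-imputed inside each training
split with companion missing-indicator features.

### Semi-supervised loop

Three folds by default. Per training split: the initial direction is the
single feature (either sign) maximizing accepted targets at q ≤ 0.01;
then, for 10 iterations, targets at q ≤ 0.01 under the current score
become positives, all decoys negatives, and an L2-regularized logistic
scorer on standardized features is refitted. Held-out folds are scored by
their training model and merged by z-scoring each fold against its own
decoy distribution. That merge is an affine map estimated from a finite
decoy sample, so cross-fold ordering is preserved only up to sampling
noise — rescoring on the search score alone reproduces the original
ranking with rank correlation ≈ 0.998, not exactly 1. Feature weights are
averaged absolute standardized coefficients across folds; the weight
report ranks features and also aggregates total |weight| per block,
because an L2 learner splits a block's signal across correlated features
(e.g. spectrum PCC and matched fraction) and the block-level sum is the
stable statistic.

### Reports

`compare_runs` computes gained/shared/lost accepted sets at 1% and 0.1%
thresholds. `entrapment_analysis` reports the raw percentage of
entrapment-only hits among accepted targets and a variant normalized by
the entrapment/sample database size ratio; both are reported because the
field uses both conventions.

## Synthetic ground truth

The generators define the study conditions; they are pure functions of
(config, seed).

*Peptides*: random sequences, lengths 8–30 by default, tryptic fraction
ending in K/R, up to two variable modifications, charges 1–4 weighted
toward 2–3.

*Spectra*: peaks at the theoretical b/y m/z with intensities from a
closed-form law — a Gaussian positional profile along the backbone
(y centred at site fraction 0.45, width 0.22; b weaker, centred 0.60)
modulated by the basicity of the residue C-terminal to the cleavage
(y ions) and the hydrophobicity of the residue N-terminal (b ions) —
times multiplicative log-normal noise, plus uniform noise peaks
rejection-sampled to stay 3× the tolerance away from true ions. The law
lives in the encoder's feature space, so the intensity model faces a
learnable but non-trivial target.

*CCS*: a linear form over the global encoding block (intercept 120 Å²;
+1.1/residue, +26/charge, small composition terms, grouped-frequency
terms), plus Gaussian noise. A modification's CCS shift is realized
*through its atomic composition* (a synthetic modification carrying
δ/β_O oxygens shifts the truth by exactly δ): this is the only
construction under which a model that never saw a carrier can recover the
shift, which is precisely what the leave-one-modification-out harness
measures. An optional (a, b) drift emulates a second instrument.

*Benchmarks*: correct targets pair each peptidoform with its own spectrum,
CCS and RT; incorrect targets and decoys pair with a **precursor-window
neighbour** — the nearest neutral mass at the same charge — because search
engines only propose candidates inside the precursor tolerance. This makes
CCS error a moderate discriminant (similar mass → similar CCS) and
fragment correlation a strong one, the hierarchy rescoring tools observe
in practice. Decoys are pseudo-reversed sequences; search scores are two
overlapping Gaussians, with decoy scores identically distributed with
incorrect-target scores (exchangeability, verified by a
Kolmogorov–Smirnov check in the tests). Default sizes for the calibration
benchmark are 2,000 correct + 2,000 incorrect targets and 4,000 decoys;
the gain and null-safety studies use 600/600/1,200.

**What passing on synthetic data does and does not show.** The generators
have no chimeric spectra, no isotope envelopes, a linear RT model, and
noise that is independent across ions; real fragmentation and mobility
data violate all of these to some degree. Tests on this ground truth
validate the *statistical machinery* — estimator correctness, parameter
recovery, calibration behavior, gain mechanics — not the accuracy of any
shipped predictor on real spectra, and the package deliberately ships no
pretrained weights.

**FDR conservatism under these conditions.** With 4,000 decoys but only
2,000 incorrect targets, E[decoys above t] ≈ 2·E[false targets above t],
so the (D+1)/T estimator over-estimates FDR by the factor 1/π₀ = 2 and the
realized false-discovery proportion at q ≤ 0.01 concentrates near 0.5%.
This is the well-known conservatism of target-decoy estimation when the
decoy population is larger than the false-target population; the
acceptance script reports the measured proportion rather than adjusting
the estimator, because a π₀-corrected estimator would require knowledge no
real search provides.

## Numerical choices and degenerate inputs

- Floats in PSM tables are written with 10 significant digits so text
  round-trips are exact to ≥ 9 digits.
- Pearson correlation of a constant vector is defined as 0 with a warning.
- Zero-TIC spectra normalize every ion to log₂(pseudocount).
- All-decoy inputs get q = 1 with a warning; folds without positives fall
  back to the initial direction.
- Random draws everywhere go through `numpy.random.default_rng(seed)`;
  repeated seeded runs are byte-identical, which the tests assert.
- Problem sizes in the test suite (hundreds of peptides, 600–2,000-PSM
  benchmarks, 20-seed studies) were chosen so the whole suite and the
  acceptance script each run in minutes on one CPU while keeping the
  statistical assertions well-powered.

## Known limitations

- Only singly charged b/y ions; no neutral losses or higher fragment
  charges.
- Protein inference is picked-protein competition only.
- The convolutional backend is a faithful but small-scale rendition of the
  four-path architecture; it is not tuned for accuracy parity with the
  reference backend.
- mzML support is not implemented; MGF is the interchange format.
- No posterior error probabilities; q-values only.
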