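# Methods

This note documents the statistical conventions, default parameters, and
design choices behind `hydrosar`, and what the synthetic benchmarks do
and do not demonstrate.

## Data model

A panel is a samples × 18 matrix of percent amino-acid composition over
the pooled labels Asx, Thr, Ser, Glx, Pro, Gly, Ala, Cys, Val, Met, Ile,
Leu, Tyr, Phe, His, Lys, Arg, Trp (acid hydrolysis cannot distinguish
Asn/Asp or Gln/Glu, hence the pooled Asx/Glx records). Rows are expected
to sum to ~100; the accepted window is [95, 105] to absorb rounding in
printed tables, and violations warn rather than fail by default because
partial panels (e.g. fractions with a residue destroyed during
hydrolysis) are legitimate inputs. Composition values are used exactly
as given — no re-normalisation to 100 — because the bundled reference
group sums reproduce only from the unnormalised values.

Activities are per-sample scalars (percent scavenging, or absorbance for
ferric reducing power) whose sample ids may be a proper subset of the
composition's (one bundled-panel assay covers 11 of 16 samples).

The z-scale table is the Hellberg 3-z set of principal-property scores
(z1 hydrophilicity, z2 side-chain bulk, z3 electronic character) for the
20 standard residues; Asx and Glx records are arithmetic means of their
constituents. Three qualitative orderings any admissible table must
satisfy (electronic character led by Cys > Pro > Asx > His > Trp;
hydrophobicity led by Phe; small bulk led by Gly) are verified at load
time, so a user-substituted scale with permuted columns fails loudly.

## Descriptors

The Σz descriptors are weighted sums Σz_i = Σ_X z_i(X)·c_X with c_X in
percent — not fractions — so their magnitude is on the order of ±100
z-units; since all variables are autoscaled before modeling, only the
relative spread matters. Group sums use the fixed definitions
SCAA = Cys+Met, PCAA = Arg+Lys+His, AcAA = Asx+Glx, AAA = Phe+Tyr+Trp,
HAA = Pro+Ala+Cys+Val+Met+Ile+Leu+Tyr+Phe+Trp. The combined descriptor
block is always ordered AA (canonical label order), then the five
groups, then Σz1..Σz3, so coefficient and VIP indices are stable across
runs and platforms.

Autoscaling centers each column and scales to unit *sample* standard
deviation (n−1 denominator — the n/n−1 choice is a constant factor
common to all columns and cancels in R², VIP and the latent directions).
A constant column is a hard error naming the column: the descriptor
blocks have fixed widths (18/5/3/26) and a silent drop would corrupt
column bookkeeping downstream.

## PLS1 (NIPALS)

For a single response the NIPALS weight extraction is closed-form per
component (w_a ∝ X_aᵀ y_a); there is no inner iteration and no
convergence tolerance. X is deflated by t_a p_aᵀ and y by c_a t_a per
component (y-deflation is mathematically redundant for PLS1 but kept for
symmetry). Sign indeterminacy is fixed by making the largest-magnitude
element of each weight vector positive. Coefficients are recomposed as
b = W(PᵀW)⁻¹c, and prediction through b is identical (to 1e−10) to
prediction through the scores. At A = rank(X) the fit coincides with the
least-squares projection — this equivalence, score orthogonality, and
the VIP normalisation ΣVIP² = p are asserted by the test suite on random
instances, and predictions are cross-checked against an independent
NIPALS implementation (scikit-learn's) which is never used as the
production path.

Requesting more components than the rank of the scaled X is an error;
a response exactly orthogonal to all columns yields a well-defined
zero-R² component rather than a crash.

## Cross-validation and component selection

Default scheme: 7 exclusion groups assigned round-robin in sample order
("venetian blinds"), the convention of the chemometrics software family
this pipeline mirrors; leave-one-out is available. Both were considered;
round-robin is the default because it is deterministic, needs no seed,
and degrades gracefully at n = 11–16. Centering and scaling are
recomputed on each training part — the held-out samples never influence
the scaling, even though published workflows are often silent on this.

PRESS(a) is the held-out squared error of the a-component model,
accumulated in globally scaled response units so it is commensurate with
SS(a), the residual sum of squares of the full-data model after a
components (SS(0) = n−1). Conventions:

- per-component Q²(a) = 1 − PRESS(a)/SS(a−1),
- cumulative Q²cum(A) = 1 − Π_{a≤A} PRESS(a)/SS(a−1) (product rule).

The selected component count A is the longest prefix with per-component
Q²(a) ≥ 0.05; A = 0 is a legitimate outcome meaning "no valid model" and
is never silently promoted to 1 (reports then carry 1-component
statistics as diagnostics, flagged invalid). Folds whose training part
has a constant column or fewer than 2 samples are errors; rank-deficient
training folds carry their deepest available model forward.

On pure-noise responses (n = 16, 5 descriptors) the cumulative Q² is
negative in expectation and grows strongly negative with a_max — the
product rule compounds PRESS/SS ratios above 1 — and no component is
selected in ≈93% of replicates. Both behaviours are exercised by the
acceptance checks (200 replicates).

## Permutation validity test

The response is permuted uniformly at random (identity rejected) 20
times by default; each permuted model is refit with the same A and CV
scheme. Straight lines are fit by ordinary least squares through the 21
points (|Pearson r| between permuted and original response, statistic),
including the unpermuted model at |r| = 1, separately for R²cum and
cumulative Q²cv; the published criterion — R² intercept < 0.4 and Q²
intercept < 0.05 — declares validity. Whether the Q² axis uses the
cumulative or per-component value is not fixed by the sources this
mirrors; the cumulative convention is implemented (for the A = 1 models
that dominate in practice the two coincide). All randomisation flows
from an explicit seed and reproduces bit-identically.

On planted-signal panels (signal fraction 0.7, n = 16, five group
descriptors) the test passes in 50/50 seeds, with R² intercepts landing
in ≈0.04–0.25 — inside the range published for real hydrolysate models —
and Q² intercepts well below 0.

## Interpretation

VIP_j = sqrt(p·Σ_a SSY_a (w_ja)²/Σ_a SSY_a) with SSY_a = c_a²·t_aᵀt_a
computed from scores and y-loadings on scaled data; weights are already
unit-norm. Classification: strong iff VIP > 1.0, weak for 0.5 ≤ VIP ≤
1.0, unimportant below 0.5 — boundary values deliberately fall in the
weaker class (the published wording "VIP > 1.0" is strict, and assigning
ties downward is conservative). Signs come from the scaled coefficient;
an exactly-zero coefficient gets sign "none". Within a class, variables
are ordered by descending VIP with ties broken by the fixed column
order.

## Synthetic data

Compositions are drawn from a Dirichlet distribution scaled to 100%, so
the closed-sum constraint of real amino-acid analyses — and the
collinearity it induces — is preserved by construction. Concentration
weights are proportional to the bundled panel's mean composition with
total concentration 30: the largest total (least overdispersion) whose
n = 1000 per-residue ranges still bracket the real panel's extrema, with
one structural exception (the panel contains an exact 0.00% entry,
unreachable by a continuous sampler). Smaller totals make scarce
residues (Cys, Met, Trp) far spikier than any real panel; a total
matched purely to the panel's dispersions (~174) would no longer span
the printed ranges.

Activities are y = Σ β_d·descriptor_d + ε with descriptors computed by
the production descriptor code — never a duplicated formula — and ε
Gaussian. Noise can be given directly or solved from a target signal
fraction R² (sd_ε = sd_signal·sqrt((1−R²)/R²)), so experiments state
"planted R²" directly. The default benchmark mimics the bundled panel's
shape: 16 samples, four activities with signs echoing the qualitative
composition–activity relations the pipeline is designed to detect, one
activity restricted to 11 samples.

What the generator does **not** emulate: assay chemistry (dose–response,
kinetics), inter-assay correlation, measurement error in the
compositions themselves, and the milder relative dispersion of scarce
residues in real panels (a single Dirichlet concentration cannot match
both the dominant and the scarce residues' variability). Passing the
synthetic benchmarks therefore demonstrates the correctness and
calibration of the machinery under known truth, not that any particular
real panel will yield valid models.

A consequence worth knowing: planted effects on *scarce, highly skewed*
residues (e.g. an SCAA effect) are recovered with the correct
coefficient sign in ≈97% of 16-sample draws, but are classified
*strong* in only ~85–90% — in the remaining draws the residue carries
almost no in-sample variance, so it genuinely is not a strong
contributor in that dataset. The planted-recovery benchmark therefore
plants balanced effects on stable-spread groups (+AcAA, −PCAA), where
joint strong-classification recovery is ≥95%.

## Problem sizes and runtime

Defaults keep every check fast: fixture checks are exact and instant;
PLS/least-squares agreement uses 20 random ≤10×8 instances; null
calibration uses 200 replicates at n = 16; permutation validity 50 seeds
× 20 permutations; contributor recovery 100 seeds. The full test suite
runs in well under a minute, the acceptance script in seconds.

## Known limitations

- Bulk-composition QSAR only: sequence position, residue interactions
  and peptide length are outside the model by design.
- PLS1 only (each activity modeled separately); no multi-response PLS,
  no orthogonalised variants.
- The permutation intercept is a line-fit summary of 21 points; with
  few permutations its seed-to-seed spread is substantial even though
  the validity verdict is stable on structured data.
- The published activity values for the bundled panel live in the
  article's supplementary material and are not redistributed here;
  numerical replication of the published model table requires attaching
  them via the documented loader.
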