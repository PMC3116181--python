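# hydrosar

Composition→activity modeling of antioxidant food protein hydrolysates.

Enzymatic protein hydrolysates are peptide mixtures; their antioxidant
potency (DPPH radical scavenging, ferric reducing power, H₂O₂ and
superoxide scavenging) depends on bulk amino-acid composition rather than
any single sequence. `hydrosar` implements the chemometric pipeline used
to ask *which residues matter*: descriptor construction from an
amino-acid analysis, partial-least-squares (PLS1) regression, rigorous
model validation, and classification of each residue or residue group as
a strong/weak, positive/negative contributor to each assay.

## What it computes

**Descriptors (X).** From a samples × 18 percent-composition table
(Asn+Asp pooled as Asx, Gln+Gln as Glx):

- `AA` — the 18 residue percentages themselves;
- `gAA` — five physicochemical group sums: SCAA = Cys+Met,
  PCAA = Arg+Lys+His, AcAA = Asx+Glx, AAA = Phe+Tyr+Trp, and the ten
  hydrophobic residues HAA;
- `z` — Hellberg 3-z scale sums, Σz_i = Σ_X z_i(X)·c_X over the 18
  residues with c_X the percent composition (z1 hydrophilicity, z2
  side-chain bulk, z3 electronic properties).

**Model.** NIPALS PLS1 on unit-variance autoscaled blocks: latent
components t_a = X_a w_a with w_a ∝ X_aᵀy_a, X (and y) deflated between
components; coefficients b = W(PᵀW)⁻¹c; R² the cumulative explained
fraction of response sum of squares.

**Validation.** Cross-validated Q² (round-robin "venetian" groups or
leave-one-out, PRESS with training-fold rescaling, product-rule
cumulative Q²), per-component significance for selecting A, and a
response-permutation (y-scrambling) test: intercepts of the R²cum and
Q²cv vs |correlation| lines at zero correlation must fall below 0.4 and
0.05 respectively for a valid model.

**Interpretation.** VIP_j = sqrt(p·Σ_a SSY_a w_ja²/Σ_a SSY_a), with
VIP > 1.0 strong, 0.5–1.0 weak, < 0.5 unimportant; sign from the scaled
coefficient.

The bundled dataset ships the published 16-sample hempseed/pea
hydrolysate composition panel, the published group-sum reference block,
and the Hellberg z-scale table. Assay values are not bundled; attach your
own with `load_sd1_activities`. A synthetic-data module generates
hydrolysate-like panels (Dirichlet compositions summing to 100%) with
planted, known composition–activity relationships for end-to-end testing.

## Worked example

```python
import hydrosar as h

# synthetic benchmark: 16 samples, planted dpph truth {+0.6·HAA, −0.7·PCAA},
# noise set so the planted signal carries ~70% of the variance
ds, truths = h.make_benchmark()
report = h.validate_model(ds, "dpph", "gAA")
print(report)
```

```
ValidationReport(n=16, x_set='gAA', a=1, r2=0.690, q2cv=0.298,
                 perm_r2_intercept=0.139, perm_q2_intercept=-0.737,
                 valid=True, activity='dpph')
```

One significant component explains 69% of the activity variance with 30%
cross-validated predictive power, and both permutation intercepts are
below their limits — a valid model. Interpreting it:

```python
from hydrosar import PLSRegressionNIPALS, assemble_x, interpret_model

y = ds.activities["dpph"]
x = assemble_x(ds, "gAA").loc[y.index]
m = PLSRegressionNIPALS(n_components=1).fit(x, y)
print(interpret_model(m, "dpph", "gAA").frame().round(3))
```

```
variable   vip  coefficient  importance     sign
    SCAA 0.513        0.145        weak positive
    PCAA 0.204       -0.058 unimportant negative
     HAA 1.775        0.503      strong positive
    AcAA 1.075       -0.304      strong negative
     AAA 0.622       -0.176        weak negative
```

The planted positive HAA effect is recovered as the strongest
contributor. The planted −PCAA effect surfaces partly through the
correlated AcAA column instead — compositions are closed (rows sum to
100%), so negatively planted share is redistributed among collinear
groups; this is exactly the caveat to keep in mind when reading such
contributor tables for real panels.

The same workflow is available from the shell:

```sh
hydrosar simulate --n 16 --seed 0 --out sim/
hydrosar run --composition sim/composition.csv --activities sim/activities.csv --out results/
hydrosar reproduce            # bundled-panel fixture checks
```

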