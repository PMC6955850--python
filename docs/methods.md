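# Methods

## Problem

Transcatheter aortic valve (TAV) leaflets are laser-cut from flat pericardial
sheet and sutured onto a stent.  A leaflet design is controlled by three
parameters: the attachment-curve coefficient `a` (mm), the suturing-line shape
coefficient `b` (dimensionless) and the suturing-line length `SSL` (mm).
Assessing a candidate design normally requires building a finite-element (FE)
model and running mounting and pressurization simulations; this package
implements the surrogate alternative: deep networks trained on a population of
(design → deformed shape, design → stress field) pairs that answer the same
question in milliseconds.

## Geometry model

The flat leaflet contour is bounded below by the attachment edge
`ya(x) = a·exp(0.1053·x²)` and above by the free edge

    yf(x) = h · (1 − (exp(|x|³ − m³) − 1) / (exp(−m³) − 1)),   m = 10.9 mm,

with `h = 13.3 + 9.6·(SSL − 19.1)` mm.  The printed source expression for
`yf` is typographically ambiguous; this parse is the only one with sane
boundary behaviour (`yf(0) = 0`, `yf(±m) = h`), and the cubic is taken in
`|x|` so the profile is symmetric like the physical leaflet.  It is evaluated
through `expm1` in factored form `(|x|−m)(x²+|x|m+m²)` because the exponent
reaches −1295 over most of the domain: a naive evaluation loses the boundary
identities to rounding.

The half-width `xmax` of the blank is not free: the arc length of the
attachment edge over `[−xmax, xmax]` is required to equal SSL (the suturing
line is inextensible), and `xmax` is solved by bracketing + Brent refinement
on the adaptive-quadrature arc length.  The free edge stored on the contour is
`yf` shifted vertically so the two edges meet at `x = ±xmax`; over the
realized half-widths (≈3 mm) `yf` is numerically flat, so the closed contour
is a scallop with a nearly straight top chord.

In 3D the suturing line is `z = p·exp(b·|θ|)` with `p = 0.20` mm on a cylinder
whose radius is solved (same bracket + Brent scheme) so the 3D arc length over
`θ ∈ [−π/3, π/3]` (one of three identical leaflets) again equals SSL.  SSL
conservation 2D ↔ 3D holds to 1e−6 relative by construction and is verified
in the test suite.

### Mesh

The region between the edges is triangulated by transfinite interpolation:
equispaced x-stations, columns of nodes from the attachment edge (v = 0) to
the free edge (v = 1), end stations collapsed to the two commissure points.
`target_nodes = inner_columns × rows + 2`; the row count is the divisor of
`target_nodes − 2` closest to `sqrt((target_nodes − 2)/3)` (a wide grid), so
the default 1381 nodes factor as 197 × 7 + 2 and a field of all three
components has 4143 values.  Node ordering is a pure function of
`target_nodes`, which makes nodal fields from different designs comparable
vectors — the property the surrogates rely on.  Node counts whose
`target_nodes − 2` is prime are rejected.

## Synthetic ground truth

The FE results this method was originally trained on are not publicly
deposited, so ground truth is produced by a documented synthetic generator
whose only contract is structural fidelity, not mechanics:

* **Mounting** places attachment nodes on the suturing curve by matching
  normalized arc length (the suturing line is inextensible), sends the free
  edge to the commissure chord pulled 75% toward the valve axis (the coapted
  position) and blends interior nodes linearly in v.
* **Pressurization** adds a belly-bulge displacement `amp·v²·4u(1−u)` pointing
  inward/downward, exactly zero on the attachment edge (fixed nodes), linear
  in the applied pressure (default 120 mmHg, the diastolic closure load) and
  smooth in the design parameters (amplitude ≈0.5–0.9 mm at 120 mmHg).
* **Stresses** are bounded smooth shape functions of the parametric
  coordinates, peaking near the attachment edge and commissures, with
  magnitude coefficients (500, 120, 180) kPa for (S11, S22, S12) so the
  circumferential component dominates on average, as in pressurized leaflets;
  S12 is antisymmetric about the leaflet midline.  Resulting mean |S11| is a
  few hundred kPa with peaks near 1000 kPa — the magnitude regime of
  pericardial TAV leaflets at 120 mmHg.
* **Noise** is optional multiplicative Gaussian (default 0: the data the
  generator emulates are deterministic simulation outputs), seeded per
  (dataset seed, sample index).

What the generator does *not* emulate: leaflet-to-leaflet contact and friction
(no contact analog exists in a per-leaflet analytic map), equilibrium of any
constitutive model, bending stiffness, and FE discretization error.  Passing
tests therefore demonstrate that the surrogate pipeline recovers smooth
deterministic design→field maps of the right dimensions and magnitude
structure — not that it reproduces real FE mechanics.

A **low-rank mode** makes every field an exact linear combination of 8 fixed
smooth modes with design-dependent coefficients spanning all 8 directions.
Because an 8-component PCA reconstructs such data perfectly, this mode is an
oracle for the autoencoder: its held-out reconstruction R² must approach 1.

## Material model

The strain-energy density of the leaflet tissue (exponential-isotropic variant
of the Gasser–Ogden–Holzapfel model with two fiber families) is implemented
for energy evaluation only:

    W = C10(e^{C01(Ī1−3)} − 1) + k1/(2k2) Σᵢ (e^{k2(Ī4ᵢ−1)²} − 1) + (J−1)²/D

with porcine-pericardium constants C10 = 2.196, C01 = 13.48, k1 = 22.14,
k2 = 107.27 (interpreted in kPa), dispersion κ = 1.16e−7 and fiber angle
7.81°.  The printed form of the energy does not show where κ enters; the
default evaluation follows the printed form, and the classical GOH blend
`Eᵢ = κ(Ī1−3) + (1−3κ)(Ī4ᵢ−1)` is available behind `fiber_dispersion=True`
(numerically indistinguishable at this κ).  `D` is not printed; the default
1e−4 gives a near-incompressible penalty and is configurable.  No stress
tensors or FE updates are derived — the generator above, not this energy,
produces the training fields.

## Surrogates

Two families, each trained separately for shape and stress:

* **ML-model-a** (autoencoder-based): mapping net 3 → 16 → 16 → 8 (Softplus
  hidden, linear output) composed with a decoder 8 → 512 → field (Softplus,
  linear).  The decoder comes from an autoencoder (encoder: Softplus hidden →
  linear 8-code → normalization) trained unsupervised on the training fields;
  the mapping net is then fitted to the encoder's codes; finally the composite
  is fine-tuned end-to-end.  The encoder hidden width is not pinned by the
  architecture description; the default mirrors the decoder (512).  The code
  "normalization" layer defaults to per-sample scaling to unit Euclidean
  length, with per-code batch standardization as the documented alternative
  (`code_normalization="standardize"`) — both are plausible parses and the
  choice is recorded in every manifest.
* **ML-model-d** (direct): 3 → 32 → 64 → 256 → field, Softplus hidden, linear
  output.

Design parameters are min-max scaled to [0, 1] by the design-space bounds;
fields are standardized per feature with training-set statistics stored on the
model (constant features get unit scale).  Both families minimize a single
equally-weighted MSE over all field components — which is why the largest
component (S11) carries the largest kPa error — using Adamax at its standard
defaults (lr 0.002, β₁ 0.9, β₂ 0.999, ε 1e−7).  The network engine is a small
in-package numpy implementation (dense layers, Softplus/linear, L2-normalize,
Glorot-uniform init, mini-batch backprop); everything is seeded and
bit-reproducible on a single CPU thread.

Default schedule (all configurable via `TrainConfig`): autoencoder 150 epochs,
mapping 4000 (the tiny net converges slowly under Adamax and is nearly free),
fine-tune 80, direct 400; batch 32; no early stopping — sizes chosen so a full
cross-validation round of either family completes in tens of seconds on one
CPU at the study sizes below.  An optional one-step learning-rate decay
(`lr_decay`, applied at 80% of each phase) is off by default and used by the
long low-rank autoencoder runs.  Fine-tuning restores the warm-start weights
if its final training MSE exceeds the assembled model's, so the three-phase
pipeline never leaves the model worse than its parts.

## Evaluation protocol

Shape errors: MeanE = mean nodal Euclidean distance (mm), MaxE = its maximum;
NMeanE/NMaxE divide by the radius R of the circumcircle through the valve's
three commissures on the true valve (percent).  The three commissures are the
120° rotations of the leaflet's attachment-edge endpoint about the stent axis
(threefold valve symmetry), taken from the true deformed coordinates.

Stress errors per component: MeanE = mean |ΔS| (kPa); NMeanE divides by the
true component's range; MaxE = |max|S| − max|S̃|| compares peak magnitudes
(locations may differ); NMaxE divides by the true peak.  A constant truth
field makes NMeanE undefined and is reported as an error, never as zero.

Monte-Carlo cross-validation: ρ% of designs drawn without replacement for
training (test set = exact complement), full from-scratch training per repeat,
per-test-sample metrics averaged within a repeat, mean ± sd across repeats;
per-repeat seeds derive deterministically from the master seed.  The
mean-field predictor (always output the training mean) is evaluated under the
same protocol as the variation-scale baseline.

## Study sizes and observed behaviour

The packaged acceptance study uses 500 Latin-hypercube designs on a 121-node
mesh (363-value fields), ρ = 90 with 10 repeats (5 in the acceptance script),
and 200 designs for the low-rank study — sizes chosen so the whole suite runs
on one CPU in minutes.  Under these conditions model-a reaches shape NMeanE
well below 1% and per-component stress NMeanE below 2%, the mean-field
baseline is more than an order of magnitude worse, and model-d degrades when
the training fraction drops from 90% to 50%.  One caveat is recorded rather
than asserted as an ordering: on these smooth three-parameter fields the
direct model is not handicapped by overfitting, so model-a and model-d land
within a factor of two of each other and the direct model can be marginally
more accurate; the corresponding check asserts comparability and records both
values.

## Known limitations

* The generator is not a mechanics solver; absolute error magnitudes are not
  comparable with FE-trained results, only the pipeline's qualitative regime.
* Geometry follows the printed contour equations literally; the resulting
  blanks are narrow (half-width ≈ 3 mm for feasible designs) because the
  attachment curve is steep, and no claim is made that they match any
  commercial leaflet blank.
* Fixed code dimension 8 and fixed architectures; no architecture search, no
  joint shape+stress model, no fluid–structure interaction, no elliptical
  deployment.
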