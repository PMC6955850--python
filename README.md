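# tavsurrogate

Machine-learning surrogates for transcatheter aortic valve (TAV) leaflet
design: from three leaflet design parameters, predict the pressurized 3D
leaflet shape and the in-plane stress field in milliseconds instead of running
a finite-element study.

**Who it is for.** Valve-design engineers and cardiovascular-biomechanics
researchers exploring a leaflet design space `{a, b, SSL}` — attachment-curve
coefficient (4.57–6.35 mm), suturing-line shape coefficient (3.0–3.4), and
stent-suturing-line length (18.4–20.1 mm) — who want a fast, differentiable
stand-in for the simulate-every-design workflow.

**What is inside.**

* Parametric leaflet geometry: scallop contour (`ya = a·e^{0.1053x²}`, free
  edge `yf` with free-edge height `h = 13.3 + 9.6·(SSL − 19.1)` mm), a
  structured 1381-node triangulation with design-independent node ordering,
  and the 3D suturing curve `z = 0.20·e^{b|θ|}` with SSL arc length conserved
  between the flat blank and the stent (both solved to 1e−6 relative).
* A fiber-reinforced hyperelastic (GOH-variant) strain-energy evaluator with
  porcine-pericardium constants.
* A synthetic pseudo-FE generator producing deformed coordinates and nodal
  S11/S22/S12 fields (4143 values each on the default mesh) that vary smoothly
  and deterministically with the design — a documented stand-in for
  non-deposited simulation data (see `docs/methods.md` for what it does and
  does not emulate).
* Two surrogate families built on an in-package numpy network engine:
  * **model-a** — autoencoder-based: design → 8-number field code
    (3→16→16→8) → decoded field (8→512→4143); trained unsupervised
    (autoencoder), then supervised (mapping), then fine-tuned end-to-end;
  * **model-d** — direct: 3→32→64→256→4143, all Softplus hidden, linear out;
  both trained with equally-weighted MSE and Adamax defaults.
* Evaluation: MeanE/NMeanE/MaxE/NMaxE for shapes (normalized by the
  commissure-circumcircle radius) and per-component stresses (normalized by
  range/peak), Monte-Carlo cross-validation (ρ% train, repeated seeded
  splits, mean ± sd), and a mean-field baseline.
* I/O + CLI: HDF5 datasets, model checkpoints, CSV metrics, legacy-ASCII VTK
  (ParaView) and STL export, YAML run configs.

## Worked example

```bash
tav-surrogate generate-designs --n 200 --seed 2 --out designs.csv
tav-surrogate simulate --designs designs.csv --nodes 121 --seed 2 --out ds.h5
tav-surrogate train --dataset ds.h5 --model a --target stress --seed 1 --out ckpt
tav-surrogate predict --model-dir ckpt --a 5.0 --b 3.2 --ssl 19.1 --out field.csv
tav-surrogate evaluate --dataset ds.h5 --model a --target stress --rho 90 --repeats 3 --seed 3 --out cv.csv
```

The `predict` step prints

```
[2026-09-21T06:04:30] predicted model_a_stress for (a=5.0, b=3.2, ssl=19.1) in 0.3 ms -> field.csv
```

and writes the flattened stress field (S11, S22, S12 per node, kPa).  The
`evaluate` step writes per-metric mean ± sd over the Monte-Carlo repeats; on
this 121-node dataset the first rows are

```
family,target,rho,repeats,metric,mean,sd
model_a,stress,90.0,3,s11_mean_e,0.7728582721491372,0.15629057457346873
model_a,stress,90.0,3,s11_n_mean_e,0.12324275498149688,0.025149638925800934
```

i.e. the surrogate's mean S11 error is ≈0.8 kPa, about 0.12% of the S11
range — the sub-percent regime in which these surrogates operate.  The same
objects are available as a library (`tavsurrogate.build_dataset`,
`fit_model_a`, `monte_carlo_cv`, ...).

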